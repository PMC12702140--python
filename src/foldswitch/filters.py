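"""Post-prediction filters for proteome-scale fold-switching calls.

Positive predictions are post-processed in three steps: (i) a putative
fold-switch region is called as the contiguous stretch of high rolled
entropy around the track's maximum; (ii) regions with more than 50%
residue overlap with the consensus of two disorder predictors are
rejected — intrinsically disordered segments also sample diverse
secondary structure and would otherwise flood the positive set;
(iii) regions are classified against domain annotation: a region that
misses every annotated domain is excluded from the final set, while
proteins with no domain annotation at all are retained in their own
category.  Disorder and domain annotations are consumed as interval
tables; no predictor or web service is called.

All user-facing intervals are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from foldswitch.scoring import ResidueScoreTrack, rolling_average

DOMAIN_OVERLAP = "domain_overlap"
NO_DOMAIN_ANNOTATION = "no_domain_annotation"
NO_OVERLAP = "no_overlap"

DEFAULT_REGION_FRACTION = 0.8
DEFAULT_MIN_COPROP = 0.05


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}]")

    def residues(self) -> set[int]:
        return set(range(self.start, self.end + 1))

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class FoldSwitchRegion:
    """The called fold-switch region of one protein."""

    protein_id: str
    interval: Interval
    peak_entropy: float


def _residue_set(intervals: Iterable[Interval]) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out |= iv.residues()
    return out


def call_region(
    track: ResidueScoreTrack,
    ww: int,
    threshold: float | None = None,
    fraction: float = DEFAULT_REGION_FRACTION,
) -> FoldSwitchRegion:
    """Call the fold-switch region from a protein's entropy track.

    The entropy track is rolled with width ``ww``; the region is the
    maximal contiguous run of rolled windows with value >= threshold
    (default: ``fraction`` of the track's rolled maximum) that contains
    the arg-max window, converted back to residue coordinates.  A track
    with no entropy signal anywhere (all defaults) has no region and
    raises.
    """
    rolled = rolling_average(track.entropy, ww)
    peak = float(rolled.max())
    if peak <= 0.0:
        raise ValueError(
            f"{track.protein_id}: no entropy signal; no region to call"
        )
    if threshold is None:
        threshold = fraction * peak
    above = rolled >= threshold
    argmax = int(np.argmax(rolled))
    lo = argmax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = argmax
    while hi < len(rolled) - 1 and above[hi + 1]:
        hi += 1
    ww_eff = min(ww, len(track))
    start = int(track.positions[lo])
    end = int(track.positions[hi + ww_eff - 1])
    return FoldSwitchRegion(
        protein_id=track.protein_id,
        interval=Interval(start, end),
        peak_entropy=peak,
    )


def disorder_overlap_filter(
    region: FoldSwitchRegion,
    disordered_a: list[Interval],
    disordered_b: list[Interval],
    mode: str = "intersection",
) -> tuple[bool, float]:
    """Reject regions dominated by predicted intrinsic disorder.

    The consensus disordered set is the residue-wise intersection of the
    two predictors' intervals (``mode="union"`` merges them instead).
    Returns (keep, fraction) where fraction is the share of the region's
    residues in the consensus; the region is kept when the fraction is
    at most 0.5 — rejection requires *more* than 50% overlap.
    """
    set_a = _residue_set(disordered_a)
    set_b = _residue_set(disordered_b)
    if mode == "intersection":
        consensus = set_a & set_b
    elif mode == "union":
        consensus = set_a | set_b
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    region_res = region.interval.residues()
    fraction = len(region_res & consensus) / len(region_res)
    return fraction <= 0.5, fraction


def domain_overlap_filter(
    region: FoldSwitchRegion, domains: list[Interval]
) -> str:
    """Classify a region against the protein's domain annotation.

    Returns ``domain_overlap`` when the region intersects at least one
    annotated domain (retained), ``no_overlap`` when domains exist but
    none intersects (excluded from the final set), or
    ``no_domain_annotation`` when the protein has no annotated domain
    (retained, reported separately).
    """
    if not domains:
        return NO_DOMAIN_ANNOTATION
    region_res = region.interval.residues()
    for dom in domains:
        if region_res & dom.residues():
            return DOMAIN_OVERLAP
    return NO_OVERLAP


def _has_coprop_run(track: ResidueScoreTrack, min_coprop: float,
                    min_len: int) -> bool:
    both = np.nan_to_num(track.h, nan=0.0) >= min_coprop
    both &= np.nan_to_num(track.e, nan=0.0) >= min_coprop
    run = 0
    for flag in both:
        run = run + 1 if flag else 0
        if run >= min_len:
            return True
    return False


def shortlist_candidates(
    tracks: Mapping[str, ResidueScoreTrack],
    predictions: Mapping[str, tuple[str, float]],
    min_coprop: float = DEFAULT_MIN_COPROP,
    domain_status: Mapping[str, str] | None = None,
    min_run: int = 8,
) -> list[str]:
    """Pick strong experimental candidates from the positive calls.

    A protein is shortlisted when it is predicted fold-switching, has a
    contiguous run of at least ``min_run`` scored positions where helix
    and strand propensity are simultaneously >= ``min_coprop`` (the
    signature of a segment compatible with both folds), and — when
    domain verdicts are supplied — its region overlaps an annotated
    domain.
    """
    out = []
    for pid, (label, _conf) in predictions.items():
        if label != "fold_switching":
            continue
        if domain_status is not None and domain_status.get(pid) != DOMAIN_OVERLAP:
            continue
        track = tracks.get(pid)
        if track is None:
            continue
        if _has_coprop_run(track, min_coprop, min_run):
            out.append(pid)
    return sorted(out)
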