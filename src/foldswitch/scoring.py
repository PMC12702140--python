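"""Secondary-structure diversity scoring of fragment hits.

Each window's unique-cluster hits are reduced to 3-state propensities
(h, e, l) of the scoring residue, from which four per-position scores
are computed:

* diversity index  DI = 1 / (h^2 + e^2 + l^2), in [1, 3];
* Shannon entropy  -h ln h - e ln e - l ln l, in [0, ln 3];
* substitution score: mean pairwise dissimilarity of the hits' 3-state
  classes under a fixed 3x3 matrix (helix-strand 0.7, helix-loop 0.3,
  strand-loop 1.0, zero diagonal), in [0, 1];
* uncertainty = exp(-0.5 * n_unique_clusters), a Hoeffding-motivated
  penalty for sparsely sampled fragments, in (0, 1].

Windows with no surviving hits receive the defaults (1, 0, 0, 1.0) so
that missing data never inflates the diversity signal.  A rolling
average (width 8 for proteins up to 251 residues, 18 beyond) smooths
the first three tracks; the classifier feature vector is the maximum of
each rolled track plus the plain mean of the uncertainty track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from foldswitch.picking import WindowHits, collect_window_hits
from foldswitch.fragdb import FragmentIndex

HELIX, STRAND, LOOP = "helix", "strand", "loop"

#: DSSP 8-state -> 3-state class.  H/G/I are helix types, E/B strand
#: types; T, bend S and unassigned '-' all fall in the loop class.
SS3_MAP = {
    "H": HELIX, "G": HELIX, "I": HELIX,
    "E": STRAND, "B": STRAND,
    "T": LOOP, "S": LOOP, "-": LOOP,
}

#: Pairwise dissimilarity of 3-state classes: symmetric, zero diagonal.
SUBSTITUTION_MATRIX: dict[tuple[str, str], float] = {
    (HELIX, HELIX): 0.0, (STRAND, STRAND): 0.0, (LOOP, LOOP): 0.0,
    (HELIX, STRAND): 0.7, (STRAND, HELIX): 0.7,
    (HELIX, LOOP): 0.3, (LOOP, HELIX): 0.3,
    (STRAND, LOOP): 1.0, (LOOP, STRAND): 1.0,
}

#: Scores assigned to a window with no hits: minimum diversity, zero
#: entropy and substitution, maximum uncertainty.
DEFAULT_SCORES = (1.0, 0.0, 0.0, 1.0)

WW_SHORT = 8
WW_LONG = 18
WW_LENGTH_THRESHOLD = 251


@dataclass(frozen=True)
class PropensityTriple:
    """Fractions of unique hits in helix, strand and loop classes."""

    h: float
    e: float
    l: float

    def __post_init__(self):
        for v in (self.h, self.e, self.l):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"propensity {v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h, self.e, self.l)


@dataclass
class ResidueScoreTrack:
    """Per-position scores of one query protein.

    Arrays are aligned on ``positions`` (1-based query residue indices,
    running scoring_offset .. L - k + scoring_offset).  Positions with
    no hits carry the default scores and NaN propensities.
    """

    protein_id: str
    sequence: str
    positions: np.ndarray
    h: np.ndarray
    e: np.ndarray
    l: np.ndarray
    diversity: np.ndarray
    entropy: np.ndarray
    substitution: np.ndarray
    uncertainty: np.ndarray
    n_unique_clusters: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        """Per-residue score table: one row per scored position."""
        return pd.DataFrame(
            {
                "position": self.positions,
                "aa": [self.sequence[p - 1] for p in self.positions],
                "h": self.h,
                "e": self.e,
                "l": self.l,
                "diversity": self.diversity,
                "entropy": self.entropy,
                "substitution": self.substitution,
                "uncertainty": self.uncertainty,
                "n_unique_clusters": self.n_unique_clusters,
            }
        )


@dataclass(frozen=True)
class FeatureVector:
    """The four classifier features of one protein."""

    max_rolled_diversity: float
    max_rolled_entropy: float
    max_rolled_substitution: float
    mean_uncertainty: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.max_rolled_diversity,
                self.max_rolled_entropy,
                self.max_rolled_substitution,
                self.mean_uncertainty,
            ]
        )


def ss3_class(ss8_letter: str) -> str:
    """Map a DSSP 8-state letter to its 3-state class."""
    try:
        return SS3_MAP[ss8_letter]
    except KeyError:
        raise ValueError(f"unknown DSSP letter {ss8_letter!r}") from None


def propensities(window: WindowHits) -> PropensityTriple:
    """Fractions of the window's unique hits in each 3-state class."""
    n = window.n_unique_clusters
    if n == 0:
        raise ValueError(
            "window has no unique hits; use default_scores() instead"
        )
    counts = {HELIX: 0, STRAND: 0, LOOP: 0}
    for hit in window.hits_unique:
        counts[ss3_class(hit.ss_state)] += 1
    return PropensityTriple(counts[HELIX] / n, counts[STRAND] / n, counts[LOOP] / n)


def diversity_index(p: PropensityTriple) -> float:
    """Inverse sum of squared propensities: 1 for a pure state, 3 uniform."""
    return 1.0 / (p.h ** 2 + p.e ** 2 + p.l ** 2)


def entropy(p: PropensityTriple) -> float:
    """Natural-log Shannon entropy of the triple, with 0*ln 0 = 0."""
    return -sum(v * math.log(v) for v in p.as_tuple() if v > 0.0)


def substitution_score(window: WindowHits) -> float:
    """Mean pairwise class dissimilarity over the window's unique hits.

    Averages the substitution-matrix entry over all unordered pairs of
    hits; a single hit (no pairs) scores 0.
    """
    classes = [ss3_class(h.ss_state) for h in window.hits_unique]
    n = len(classes)
    if n < 1:
        raise ValueError("window has no unique hits")
    if n == 1:
        return 0.0
    total = sum(
        SUBSTITUTION_MATRIX[classes[i], classes[j]]
        for i in range(n)
        for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def uncertainty(n_unique_clusters: int) -> float:
    """exp(-0.5 n): 1 with no hits, strictly decreasing in the hit count."""
    if n_unique_clusters < 0:
        raise ValueError(f"negative hit count {n_unique_clusters}")
    return math.exp(-0.5 * n_unique_clusters)


def default_scores() -> tuple[float, float, float, float]:
    """(diversity, entropy, substitution, uncertainty) for a hitless window."""
    return DEFAULT_SCORES


def window_width(sequence_length: int, threshold: int = WW_LENGTH_THRESHOLD,
                 short: int = WW_SHORT, long: int = WW_LONG) -> int:
    """Rolling-average width: ``short`` up to ``threshold`` residues, else ``long``."""
    if sequence_length < 7:
        raise ValueError(f"sequence length {sequence_length} < 7")
    return short if sequence_length <= threshold else long


def rolling_average(track: Sequence[float], window_width: int) -> np.ndarray:
    """Moving mean: output[i] = mean(track[i : i+WW]).

    Output length is len(track) - WW + 1.  A track shorter than the
    window falls back to a single window spanning the whole track, so
    short proteins still produce one rolled value.
    """
    if window_width < 1:
        raise ValueError(f"window_width must be >= 1, got {window_width}")
    arr = np.asarray(track, dtype=float)
    if arr.size == 0:
        raise ValueError("empty track")
    ww = min(window_width, arr.size)
    return np.convolve(arr, np.ones(ww) / ww, mode="valid")


def score_windows(windows: list[WindowHits], protein_id: str,
                  sequence: str) -> ResidueScoreTrack:
    """Turn one protein's window hits into its per-residue score track."""
    n = len(windows)
    track = ResidueScoreTrack(
        protein_id=protein_id,
        sequence=sequence,
        positions=np.array([w.query_position for w in windows], dtype=int),
        h=np.full(n, np.nan),
        e=np.full(n, np.nan),
        l=np.full(n, np.nan),
        diversity=np.empty(n),
        entropy=np.empty(n),
        substitution=np.empty(n),
        uncertainty=np.empty(n),
        n_unique_clusters=np.array([w.n_unique_clusters for w in windows], dtype=int),
    )
    for i, w in enumerate(windows):
        if w.n_unique_clusters == 0:
            (track.diversity[i], track.entropy[i],
             track.substitution[i], track.uncertainty[i]) = DEFAULT_SCORES
            continue
        p = propensities(w)
        track.h[i], track.e[i], track.l[i] = p.as_tuple()
        track.diversity[i] = diversity_index(p)
        track.entropy[i] = entropy(p)
        track.substitution[i] = substitution_score(w)
        track.uncertainty[i] = uncertainty(w.n_unique_clusters)
    return track


def score_protein(
    index: FragmentIndex,
    sequence: str,
    protein_id: str = "query",
    scoring_offset: int = 3,
    plddt_min: float = 70.0,
    exclude_self: str | None = None,
) -> ResidueScoreTrack:
    """Full picking + scoring pipeline for one query sequence."""
    windows = collect_window_hits(
        index,
        sequence,
        scoring_offset=scoring_offset,
        plddt_min=plddt_min,
        exclude_self=exclude_self,
    )
    return score_windows(windows, protein_id, sequence)


def feature_vector(track: ResidueScoreTrack, ww: int | None = None) -> FeatureVector:
    """Reduce a score track to the four classifier features.

    The diversity, entropy and substitution tracks are rolled with
    width ``ww`` (derived from sequence length when omitted) and their
    maxima taken; uncertainty enters as the plain per-position mean,
    without rolling.
    """
    if len(track) == 0:
        raise ValueError("empty score track")
    if ww is None:
        ww = window_width(len(track.sequence))
    return FeatureVector(
        max_rolled_diversity=float(rolling_average(track.diversity, ww).max()),
        max_rolled_entropy=float(rolling_average(track.entropy, ww).max()),
        max_rolled_substitution=float(rolling_average(track.substitution, ww).max()),
        mean_uncertainty=float(np.mean(track.uncertainty)),
    )
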