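"""Query-side fragment picking: windowing, hit filtering, cluster dedup.

A query sequence of length L is decomposed into its L-k+1 overlapping
k-mers; each window's score is assigned to the query residue at the
scoring offset inside the window (default: the third residue, so scored
positions run from 3 to L-7+3 for 7-mers).  Hits are filtered on the
confidence of the scoring residue (pLDDT < 70 for predicted structures,
unobserved residues for experimental ones) and then collapsed to one
representative per 100%-identity sequence cluster, removing the PDB
redundancy bias.  The filter order is fixed: confidence first, then
cluster dedup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from foldswitch.fragdb import FragmentHit, FragmentIndex, PREDICTED

logger = logging.getLogger(__name__)

DEFAULT_PLDDT_MIN = 70.0
DEFAULT_SCORING_OFFSET = 3


@dataclass
class WindowHits:
    """All database hits for one query window, at each filtering stage.

    ``query_position`` is the 1-based query residue the window's score is
    assigned to.  ``hits_unique`` holds one representative per sequence
    cluster and its length is ``n_unique_clusters`` — the hit count the
    uncertainty score is based on.
    """

    query_position: int
    fragment: str
    hits_raw: list[FragmentHit] = field(default_factory=list)
    hits_filtered: list[FragmentHit] = field(default_factory=list)
    hits_unique: list[FragmentHit] = field(default_factory=list)

    @property
    def n_unique_clusters(self) -> int:
        return len(self.hits_unique)


def window_fragments(
    sequence: str, k: int = 7, scoring_offset: int = DEFAULT_SCORING_OFFSET
) -> list[tuple[int, str]]:
    """Enumerate the (query_position, fragment) windows of a sequence.

    The window starting at 1-based residue s is assigned to query
    position s + scoring_offset - 1; positions therefore run from
    scoring_offset to L - k + scoring_offset.
    """
    L = len(sequence)
    if L < k:
        raise ValueError(
            f"sequence of length {L} is shorter than the fragment size {k}"
        )
    if not 1 <= scoring_offset <= k:
        raise ValueError(f"scoring_offset {scoring_offset} outside 1..{k}")
    return [
        (start + scoring_offset, sequence[start : start + k])
        for start in range(L - k + 1)
    ]


def filter_hits(
    hits: list[FragmentHit], plddt_min: float = DEFAULT_PLDDT_MIN
) -> list[FragmentHit]:
    """Drop hits whose scoring residue is unreliable.

    Predicted-source hits are removed when the pLDDT at the scoring
    residue is strictly below ``plddt_min`` (exactly 70 passes);
    experimental-source hits are removed when the residue is unobserved
    (confidence encoded 0).  With the 100/0 encoding of experimental
    observation both rules reduce to ``confidence >= plddt_min``.
    Order is preserved.
    """
    return [h for h in hits if h.confidence >= plddt_min]


def dedup_by_cluster(hits: list[FragmentHit]) -> list[FragmentHit]:
    """Keep one hit per sequence cluster.

    The representative of each cluster is the hit with the
    lexicographically smallest (protein_id, start); output is sorted by
    (protein_id, start) for determinism.  Idempotent.
    """
    best: dict[str, FragmentHit] = {}
    for h in hits:
        cur = best.get(h.cluster_id)
        if cur is None or (h.protein_id, h.start) < (cur.protein_id, cur.start):
            best[h.cluster_id] = h
    return sorted(best.values(), key=lambda h: (h.protein_id, h.start))


def collect_window_hits(
    index: FragmentIndex,
    sequence: str,
    scoring_offset: int = DEFAULT_SCORING_OFFSET,
    plddt_min: float = DEFAULT_PLDDT_MIN,
    exclude_self: str | None = None,
) -> list[WindowHits]:
    """Run the full picking stage for one query sequence.

    For every window: query the index, apply the confidence filter at
    the scoring residue, then deduplicate by cluster.  ``exclude_self``
    names a database record whose hits are discarded, for leakage-free
    validation of proteins present in the database.
    """
    windows = []
    for position, fragment in window_fragments(
        sequence, k=index.k, scoring_offset=scoring_offset
    ):
        raw = index.query(fragment, scoring_offset=scoring_offset)
        if exclude_self is not None:
            raw = [h for h in raw if h.protein_id != exclude_self]
        filtered = filter_hits(raw, plddt_min=plddt_min)
        unique = dedup_by_cluster(filtered)
        windows.append(
            WindowHits(
                query_position=position,
                fragment=fragment,
                hits_raw=raw,
                hits_filtered=filtered,
                hits_unique=unique,
            )
        )
    return windows
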