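"""Structure-annotated sequence database and exact 7-mer fragment index.

A database entry (:class:`ProteinRecord`) couples an amino-acid sequence
with a DSSP 8-state secondary-structure string, per-residue confidence
values (AlphaFold pLDDT for predicted structures; observed/unobserved
flags encoded 100/0 for experimental ones) and a 100%-identity sequence
cluster assignment.  :class:`FragmentIndex` answers exact k-mer queries
with every occurrence and the residue-level annotation at a designated
scoring position inside the matched window.

On-disk layout: sequences as FASTA; secondary structure, confidence and
cluster membership as 2-column TSVs (cluster TSV in the MMseqs2
representative-id/member-id convention).  Coordinates are 0-based
half-open internally; user-facing reports are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: DSSP 8-state alphabet: helix types H/G/I, strand types E/B, turn T,
#: bend S, and '-' for unassigned/coil.
SS8_ALPHABET = frozenset("HGIEBTS-")

#: Canonical amino acids plus X for unknown residues.  Non-canonical
#: letters (B, Z, U, ...) are indexed literally; query fragments
#: containing letters outside this alphabet return no hits.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

EXPERIMENTAL = "experimental"
PREDICTED = "predicted"


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: sequence + 8-state SS + confidence + cluster.

    ``confidence`` holds pLDDT values in [0, 100] for predicted records;
    for experimental records an observed residue is encoded 100 and an
    unobserved one 0, so a single numeric filter threshold serves both
    sources.
    """

    id: str
    sequence: str
    ss8: str
    confidence: tuple[float, ...]
    source: str = PREDICTED
    cluster_id: str = ""

    def validate(self) -> None:
        if len(self.ss8) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: ss8 length {len(self.ss8)} != "
                f"sequence length {len(self.sequence)}"
            )
        if len(self.confidence) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: confidence length "
                f"{len(self.confidence)} != sequence length {len(self.sequence)}"
            )
        bad = set(self.ss8) - SS8_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: unknown secondary-structure letters {sorted(bad)}"
            )
        if self.source not in (EXPERIMENTAL, PREDICTED):
            raise ValueError(f"record {self.id!r}: unknown source {self.source!r}")
        if not self.cluster_id:
            raise ValueError(f"record {self.id!r}: empty cluster_id")
        if any(c < 0 or c > 100 for c in self.confidence):
            raise ValueError(f"record {self.id!r}: confidence outside [0, 100]")


@dataclass(frozen=True)
class FragmentHit:
    """One exact k-mer occurrence with the annotation of the scoring residue."""

    protein_id: str
    start: int  # 0-based offset of the window in the source sequence
    ss_state: str
    confidence: float
    cluster_id: str
    source: str


@dataclass
class FragmentIndex:
    """Exact-match index over all k-mers of a record set.

    The backing store maps each k-mer to its list of
    ``(protein_id, start)`` occurrences; record objects are retained so a
    query can report the secondary-structure state and confidence at any
    in-window offset.
    """

    k: int = 7
    entries: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    records: dict[str, ProteinRecord] = field(default_factory=dict)

    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def query(self, fragment: str, scoring_offset: int = 3) -> list[FragmentHit]:
        """Return every exact occurrence of ``fragment``.

        ``scoring_offset`` is the 1-based position within the fragment
        whose SS state and confidence are attached to each hit.  Hits are
        sorted by (protein_id, start).  Fragments containing letters
        outside the amino-acid alphabet yield an empty result.
        """
        if len(fragment) != self.k:
            raise ValueError(
                f"fragment length {len(fragment)} != index k={self.k}"
            )
        if not 1 <= scoring_offset <= self.k:
            raise ValueError(
                f"scoring_offset {scoring_offset} outside 1..{self.k}"
            )
        if set(fragment) - AA_ALPHABET:
            logger.warning(
                "fragment %r contains non-amino-acid letters; no hits", fragment
            )
            return []
        hits = []
        for protein_id, start in sorted(self.entries.get(fragment, ())):
            rec = self.records[protein_id]
            pos = start + scoring_offset - 1
            hits.append(
                FragmentHit(
                    protein_id=protein_id,
                    start=start,
                    ss_state=rec.ss8[pos],
                    confidence=rec.confidence[pos],
                    cluster_id=rec.cluster_id,
                    source=rec.source,
                )
            )
        return hits

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the index (records + k) to a JSON file."""
        payload = {
            "k": self.k,
            "records": [
                {
                    "id": r.id,
                    "sequence": r.sequence,
                    "ss8": r.ss8,
                    "confidence": list(r.confidence),
                    "source": r.source,
                    "cluster_id": r.cluster_id,
                }
                for r in self.records.values()
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FragmentIndex":
        payload = json.loads(Path(path).read_text())
        records = [
            ProteinRecord(
                id=r["id"],
                sequence=r["sequence"],
                ss8=r["ss8"],
                confidence=tuple(r["confidence"]),
                source=r["source"],
                cluster_id=r["cluster_id"],
            )
            for r in payload["records"]
        ]
        return build_index(records, k=payload["k"])


def _read_tsv_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key] = value
    return out


def read_cluster_tsv(path: str | Path) -> dict[str, str]:
    """Read an MMseqs2-style cluster TSV (representative-id \\t member-id).

    Returns member-id -> cluster-id (the representative's id).
    """
    clusters: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rep, _, member = line.partition("\t")
        clusters[member.strip()] = rep.strip()
    return clusters


def load_records(
    sequence_file: str | Path,
    ss_file: str | Path,
    confidence_file: str | Path,
    cluster_file: str | Path,
    source_file: str | Path | None = None,
) -> list[ProteinRecord]:
    """Load database records from their on-disk representation.

    Parameters
    ----------
    sequence_file
        FASTA of amino-acid sequences; record ids must match the TSVs.
    ss_file
        2-column TSV ``id\\tss8`` with a DSSP 8-state string per protein.
    confidence_file
        2-column TSV ``id\\tv1,v2,...`` with per-residue confidence values.
    cluster_file
        MMseqs2 cluster TSV (``representative-id\\tmember-id``).
    source_file
        Optional 2-column TSV ``id\\t{experimental|predicted}``; records
        absent from it default to ``predicted``.

    Records lacking SS or confidence, or violating an invariant (length
    mismatch, unknown SS letter), are skipped with a logged warning that
    names the offending id; the remaining records load normally.
    """
    ss_map = _read_tsv_map(ss_file)
    conf_map = _read_tsv_map(confidence_file)
    cluster_map = read_cluster_tsv(cluster_file)
    source_map = _read_tsv_map(source_file) if source_file else {}

    records: list[ProteinRecord] = []
    for seq_rec in SeqIO.parse(str(sequence_file), "fasta"):
        rid = seq_rec.id
        if rid not in ss_map:
            logger.warning("record %r: no secondary structure; skipped", rid)
            continue
        if rid not in conf_map:
            logger.warning("record %r: no confidence values; skipped", rid)
            continue
        try:
            confidence = tuple(float(x) for x in conf_map[rid].split(",") if x)
            rec = ProteinRecord(
                id=rid,
                sequence=str(seq_rec.seq).upper(),
                ss8=ss_map[rid],
                confidence=confidence,
                source=source_map.get(rid, PREDICTED),
                cluster_id=cluster_map.get(rid, rid),
            )
            rec.validate()
        except ValueError as exc:
            logger.warning("record rejected: %s", exc)
            continue
        records.append(rec)
    return records


def build_index(records: Iterable[ProteinRecord], k: int = 7) -> FragmentIndex:
    """Index every k-mer of every record.

    A record of length L contributes max(0, L - k + 1) occurrences; the
    result is deterministic for a given input ordering.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    index = FragmentIndex(k=k)
    for rec in records:
        rec.validate()
        if rec.id in index.records:
            raise ValueError(f"duplicate record id {rec.id!r}")
        index.records[rec.id] = rec
        seq = rec.sequence
        for start in range(len(seq) - k + 1):
            index.entries.setdefault(seq[start : start + k], []).append(
                (rec.id, start)
            )
    return index


def query(
    index: FragmentIndex, fragment: str, scoring_offset: int = 3
) -> list[FragmentHit]:
    """Functional alias for :meth:`FragmentIndex.query`."""
    return index.query(fragment, scoring_offset)
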