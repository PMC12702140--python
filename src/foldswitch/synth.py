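"""Synthetic databases, queries and labelled feature sets with known truth.

The generator plants 7-mer fragments with prescribed secondary-structure
mixtures into an otherwise random database, so that the full picking +
scoring pipeline can be checked against construction-time ground truth:
a fragment planted with an h:e mixture of 5:5 across 10 distinct
clusters *must* come back with propensities (0.5, 0.5, 0) after
deduplication.  Filler sequence is rejection-sampled so that no query
window other than the planted ones ever matches the database, and no
planted k-mer occurs anywhere by accident; hit counts are therefore
exact by construction.

A "plateau" plants every window of a contiguous query segment with the
same mixture, emulating the contiguous high-entropy stretch that marks
a fold-switch region; redundant copies of a hit record (identical
sequence, same cluster, different ids) emulate the PDB redundancy that
cluster deduplication removes.

The labelled-feature generator draws class-conditional Gaussians in the
4-feature space with a separation parameter measured in units of the
noise SD, mirroring the 189 fold-switching / 198 monomorphic shape of
the training set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from foldswitch.fragdb import ProteinRecord, PREDICTED
from foldswitch.model import FOLD_SWITCHING, MONOMORPHIC, LabelledExample
from foldswitch.scoring import FeatureVector

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Representative 8-state letter written at the scoring residue of a
#: planted hit, per 3-state class.
CLASS_LETTER = {"helix": "H", "strand": "E", "loop": "T"}

_MAX_TRIES = 10_000


@dataclass(frozen=True)
class Plateau:
    """A contiguous query segment whose every window is planted.

    ``class_counts`` gives the number of distinct-cluster hits per
    3-state class for each window; ``redundancy`` > 1 adds identical
    extra copies of every hit record in the same cluster (removed again
    by cluster dedup).  ``confidence`` is the pLDDT written at every
    residue of the hit records.
    """

    start: int  # 1-based start within the query
    length: int
    class_counts: dict[str, int] = field(default_factory=lambda: {"helix": 1})
    redundancy: int = 1
    confidence: float = 100.0


@dataclass(frozen=True)
class SynthSpec:
    """Plan for one synthetic query + database scenario."""

    seed: int = 0
    k: int = 7
    scoring_offset: int = 3
    query_length: int = 60
    plateaus: tuple[Plateau, ...] = ()
    n_filler_records: int = 2
    filler_length: int = 40

    def validate(self) -> None:
        for p in self.plateaus:
            if p.length < self.k:
                raise ValueError(
                    f"plateau length {p.length} shorter than k={self.k}"
                )
            if p.start < 1 or p.start + p.length - 1 > self.query_length:
                raise ValueError("plateau outside the query")
            if any(v < 0 for v in p.class_counts.values()):
                raise ValueError("negative class count")
            if set(p.class_counts) - set(CLASS_LETTER):
                raise ValueError(f"unknown class in {p.class_counts}")
        spans = sorted((p.start, p.start + p.length - 1) for p in self.plateaus)
        for (s1, e1), (s2, _) in itertools.pairwise(spans):
            if s2 <= e1:
                raise ValueError("plateaus overlap")


def _random_seq(rng: np.random.Generator, length: int, k: int,
                forbidden: set[str]) -> str:
    """Random AA sequence none of whose k-mers is in ``forbidden``."""
    chars: list[str] = []
    while len(chars) < length:
        for _ in range(_MAX_TRIES):
            chars.append(AA20[rng.integers(len(AA20))])
            if len(chars) < k or "".join(chars[-k:]) not in forbidden:
                break
            chars.pop()
        else:
            raise RuntimeError("could not sample filler avoiding planted k-mers")
    return "".join(chars)


def _unique_kmers(seq: str, k: int) -> bool:
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    return len(kmers) == len(set(kmers))


def make_query(spec: SynthSpec) -> tuple[str, dict[int, tuple[float, float, float]]]:
    """Generate the query sequence and its ground-truth propensities.

    Returns (sequence, truth) where truth maps each planted query
    position (1-based, at the scoring offset of its window) to the
    exact (h, e, l) propensity triple the pipeline must recover.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    for _ in range(_MAX_TRIES):
        seq = _random_seq(rng, spec.query_length, spec.k, set())
        if _unique_kmers(seq, spec.k):
            break
    else:
        raise RuntimeError("could not generate a query with unique k-mers")

    truth: dict[int, tuple[float, float, float]] = {}
    for p in spec.plateaus:
        total = sum(p.class_counts.values())
        if total > 0:
            triple = (p.class_counts.get("helix", 0) / total,
                      p.class_counts.get("strand", 0) / total,
                      p.class_counts.get("loop", 0) / total)
        else:
            triple = None  # zero clusters: window must fall back to defaults
        for w in range(p.start, p.start + p.length - spec.k + 1):
            pos = w + spec.scoring_offset - 1
            truth[pos] = triple
    return seq, truth


def make_database(
    spec: SynthSpec, query: str | None = None
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Build the database records realizing the spec's planted hits.

    Every window of every plateau occurs in exactly the planned number
    of distinct-cluster records, with the planned class letter at the
    scoring residue; all other database content avoids every query
    k-mer.  Returns (records, cluster_table) with the cluster table in
    (representative-id, member-id) pairs.
    """
    spec.validate()
    if query is None:
        query, _ = make_query(spec)
    rng = np.random.default_rng(spec.seed + 1)
    k, off = spec.k, spec.scoring_offset
    query_kmers = {query[i : i + k] for i in range(len(query) - k + 1)}

    records: list[ProteinRecord] = []
    cluster_pairs: list[tuple[str, str]] = []
    rec_counter = itertools.count()

    def add_record(sequence: str, ss8: str, confidence: float,
                   cluster_rep: str | None) -> ProteinRecord:
        rid = f"syn{next(rec_counter):05d}"
        rep = cluster_rep or rid
        rec = ProteinRecord(
            id=rid,
            sequence=sequence,
            ss8=ss8,
            confidence=(confidence,) * len(sequence),
            source=PREDICTED,
            cluster_id=rep,
        )
        records.append(rec)
        cluster_pairs.append((rep, rid))
        return rec

    for p in spec.plateaus:
        for w in range(p.start, p.start + p.length - k + 1):
            kmer = query[w - 1 : w - 1 + k]
            for cls, count in sorted(p.class_counts.items()):
                for _ in range(count):
                    # pad the planted k-mer so junction k-mers stay clear
                    # of every query window
                    for _ in range(_MAX_TRIES):
                        left = _random_seq(rng, k, k, query_kmers)
                        right = _random_seq(rng, k, k, query_kmers)
                        seq = left + kmer + right
                        occurs = [seq[i : i + k] for i in range(len(seq) - k + 1)]
                        if sum(o in query_kmers for o in occurs) == 1:
                            break
                    else:
                        raise RuntimeError("infeasible plan: k-mer collision")
                    ss8 = list("-" * len(seq))
                    ss8[k + off - 1] = CLASS_LETTER[cls]
                    rep_rec = add_record(seq, "".join(ss8), p.confidence, None)
                    for _ in range(p.redundancy - 1):
                        add_record(seq, "".join(ss8), p.confidence,
                                   rep_rec.cluster_id)

    for _ in range(spec.n_filler_records):
        seq = _random_seq(rng, spec.filler_length, k, query_kmers)
        ss8 = "".join(rng.choice(list("HGIEBTS-"), size=len(seq)))
        add_record(seq, ss8, 100.0, None)

    return records, cluster_pairs


def write_database(
    records: list[ProteinRecord],
    cluster_pairs: list[tuple[str, str]],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write records in the on-disk layout the database loader consumes.

    Emits sequences.fasta, ss.tsv, confidence.tsv, clusters.tsv and
    sources.tsv under ``outdir``; byte-deterministic for a given record
    list.  Returns the path of each file keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "ss": outdir / "ss.tsv",
        "confidence": outdir / "confidence.tsv",
        "clusters": outdir / "clusters.tsv",
        "sources": outdir / "sources.tsv",
    }
    with open(paths["fasta"], "w") as fa, open(paths["ss"], "w") as ss, \
            open(paths["confidence"], "w") as cf, open(paths["sources"], "w") as sf:
        for r in records:
            fa.write(f">{r.id}\n{r.sequence}\n")
            ss.write(f"{r.id}\t{r.ss8}\n")
            cf.write(f"{r.id}\t{','.join(format(c, 'g') for c in r.confidence)}\n")
            sf.write(f"{r.id}\t{r.source}\n")
    with open(paths["clusters"], "w") as cl:
        for rep, member in cluster_pairs:
            cl.write(f"{rep}\t{member}\n")
    return paths


# ---------------------------------------------------------------------------
# labelled feature sets for the classifier

#: Center of the two class clouds in feature space and the direction of
#: the class gap, roughly matching the magnitudes diversity metrics take
#: on real proteins (diversity ~1.1-2.1, entropy ~0.1-0.8, substitution
#: ~0.02-0.25, uncertainty ~0-0.7).
_FEATURE_CENTER = np.array([1.50, 0.45, 0.15, 0.30])
_FEATURE_DELTA = np.array([0.18, 0.14, 0.06, -0.06])  # per separation unit
_FEATURE_SIGMA = np.array([0.09, 0.07, 0.03, 0.03])
_FEATURE_LO = np.array([1.0, 0.0, 0.0, 1e-9])
_FEATURE_HI = np.array([3.0, np.log(3.0), 1.0, 1.0])


def make_classifier_set(
    n_fold_switching: int = 189,
    n_monomorphic: int = 198,
    separation: float = 3.0,
    seed: int = 0,
    frac_default_negatives: float = 0.1,
) -> list[LabelledExample]:
    """Labelled feature vectors with a controlled class margin.

    Both classes are Gaussian in feature space; their means differ by
    ``separation`` noise-SD units along the fold-switching direction
    (higher diversity/entropy/substitution, lower uncertainty), so
    separation 0 gives identical distributions and separation >= ~3 a
    cleanly separable set.  A fraction of monomorphic examples sits
    exactly at the all-default feature vector (1, 0, 0, 1), emulating
    proteins whose fragments find no database hits at all.  Values are
    clipped to each feature's valid range.
    """
    rng = np.random.default_rng(seed)
    examples: list[LabelledExample] = []
    shift = 0.5 * separation * _FEATURE_DELTA
    n_default = int(round(frac_default_negatives * n_monomorphic)) if separation > 0 else 0
    for label, n, sign in ((FOLD_SWITCHING, n_fold_switching, +1),
                           (MONOMORPHIC, n_monomorphic, -1)):
        mu = _FEATURE_CENTER + sign * shift
        draws = rng.normal(mu, _FEATURE_SIGMA, size=(n, 4))
        draws = np.clip(draws, _FEATURE_LO, _FEATURE_HI)
        if label == MONOMORPHIC and n_default:
            draws[:n_default] = [1.0, 0.0, 0.0, 1.0]
        for i, row in enumerate(draws):
            examples.append(
                LabelledExample(
                    protein_id=f"{label[:4]}{i:04d}",
                    features=FeatureVector(*row),
                    label=label,
                )
            )
    return examples


def make_proteome(
    n_proteins: int = 20,
    frac_positive: float = 0.2,
    seed: int = 0,
    query_length: int = 60,
    plateau_length: int = 21,
    n_clusters: int = 10,
) -> tuple[list[ProteinRecord], list[tuple[str, str]], dict[str, str], dict[str, bool]]:
    """A synthetic proteome with a known fold-switching subset.

    Each protein is a separate query; positives carry a planted plateau
    with a 50/50 helix/strand hit mixture (high entropy), negatives a
    pure-helix plateau (zero entropy).  All proteins share one database.
    Returns (records, cluster_table, queries, truth) with truth mapping
    protein id -> is-fold-switching.
    """
    rng = np.random.default_rng(seed)
    n_pos = int(round(frac_positive * n_proteins))
    half = n_clusters // 2
    records: list[ProteinRecord] = []
    cluster_pairs: list[tuple[str, str]] = []
    queries: dict[str, str] = {}
    truth: dict[str, bool] = {}
    for i in range(n_proteins):
        positive = i < n_pos
        counts = ({"helix": half, "strand": n_clusters - half}
                  if positive else {"helix": n_clusters})
        spec = SynthSpec(
            seed=int(rng.integers(2 ** 31 - 1)),
            query_length=query_length,
            plateaus=(Plateau(start=11, length=plateau_length,
                              class_counts=counts),),
            n_filler_records=0,
        )
        query, _ = make_query(spec)
        recs, pairs = make_database(spec, query=query)
        prefix = f"p{i:03d}_"
        for r in recs:
            records.append(
                ProteinRecord(
                    id=prefix + r.id, sequence=r.sequence, ss8=r.ss8,
                    confidence=r.confidence, source=r.source,
                    cluster_id=prefix + r.cluster_id,
                )
            )
        cluster_pairs.extend((prefix + a, prefix + b) for a, b in pairs)
        pid = f"prot{i:03d}"
        queries[pid] = query
        truth[pid] = positive
    return records, cluster_pairs, queries, truth
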