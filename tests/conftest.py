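import numpy as np
import pytest

from foldswitch.fragdb import ProteinRecord, build_index
from foldswitch.synth import Plateau, SynthSpec, make_database, make_query


def make_record(rid, sequence, ss8=None, confidence=None, source="predicted",
                cluster_id=None):
    return ProteinRecord(
        id=rid,
        sequence=sequence,
        ss8=ss8 if ss8 is not None else "H" * len(sequence),
        confidence=tuple(confidence) if confidence is not None
        else (100.0,) * len(sequence),
        source=source,
        cluster_id=cluster_id or rid,
    )


def brute_force_scan(records, fragment, scoring_offset=3):
    """Independent linear-scan oracle for exact fragment search."""
    hits = []
    k = len(fragment)
    for rec in sorted(records, key=lambda r: r.id):
        seq = rec.sequence
        for start in range(len(seq) - k + 1):
            if seq[start:start + k] == fragment:
                pos = start + scoring_offset - 1
                hits.append((rec.id, start, rec.ss8[pos], rec.confidence[pos]))
    return hits


@pytest.fixture
def small_records():
    return [
        make_record("recA", "ACDEFGHIKLMNPQRSTVWY"),
        make_record("recB", "ACDEFGHACDEFGH", ss8="E" * 14),
        make_record("recC", "MNPQRST", ss8="TTTTTTT"),
    ]


@pytest.fixture
def small_index(small_records):
    return build_index(small_records, k=7)


@pytest.fixture(scope="session")
def planted_scenario():
    """Query with one mixed-SS plateau plus the ground truth, scored once."""
    spec = SynthSpec(
        seed=11,
        query_length=50,
        plateaus=(Plateau(start=11, length=18,
                          class_counts={"helix": 5, "strand": 5}),),
        n_filler_records=3,
    )
    query, truth = make_query(spec)
    records, pairs = make_database(spec, query=query)
    return spec, query, truth, records, pairs


def random_database(rng, n_records=5, min_len=5, max_len=30):
    """Random record set for oracle-equivalence property tests."""
    alphabet = "ACDE"  # tiny alphabet so repeated 7-mers actually occur
    records = []
    for i in range(n_records):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(list(alphabet), size=L))
        ss8 = "".join(rng.choice(list("HGIEBTS-"), size=L))
        conf = tuple(rng.uniform(0, 100, size=L).round(1))
        records.append(make_record(f"r{i:02d}", seq, ss8=ss8, confidence=conf))
    return records
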