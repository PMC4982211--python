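import numpy as np
import pandas as pd
import pytest

from metacoman.io_tab import M8_COLUMNS, AnnotationMap, SampleMetadata


def make_hits(rows):
    """Build a hit frame from (read_id, subject_id, e_value, bit_score) tuples."""
    records = [
        (r, s, 97.0, 100, 3, 0, 1, 100, 1, 100, e, b) for (r, s, e, b) in rows
    ]
    return pd.DataFrame.from_records(records, columns=M8_COLUMNS)


def random_hits(rng, n_reads=50, n_subjects=10, hits_per_read=(1, 4)):
    rows = []
    for i in range(n_reads):
        for _ in range(rng.integers(*hits_per_read)):
            rows.append(
                (
                    f"r{i}",
                    f"s{rng.integers(n_subjects)}",
                    10.0 ** rng.uniform(-30, 0),
                    float(rng.uniform(40, 200)),
                )
            )
    return make_hits(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def meta_2x2():
    return SampleMetadata({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


@pytest.fixture
def simple_annot():
    return AnnotationMap(
        systems={
            "KO": {"g1": {"KO1"}, "g2": {"KO2"}, "g3": {"KO1", "KO2"}},
        },
        phylum_of={"g1": "Firmicutes", "g2": "Bacteroidetes"},
    )
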