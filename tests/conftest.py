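"""Shared fixtures: hand-built corpora and random-corpus generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmcf.corpus import SearchCorpus, SearchSequence


def make_corpus(entries, start="2024-03-01 09:00:00", step_minutes=1.0):
    """Build a corpus from compact ``(physician, patient, visit, [terms])`` rows.

    Each sequence starts an hour after the previous one; terms within a
    sequence are ``step_minutes`` apart.
    """
    base = pd.Timestamp(start)
    seqs = []
    for i, (y, p, v, terms) in enumerate(entries):
        t0 = base + pd.Timedelta(hours=i)
        stamps = [t0 + pd.Timedelta(minutes=step_minutes * k) for k in range(len(terms))]
        seqs.append(SearchSequence(y, p, v, list(terms), stamps))
    return SearchCorpus.from_sequences(seqs)


def random_corpus(
    rng: np.random.Generator,
    n_physicians=3,
    n_patients=4,
    n_terms=6,
    n_sequences=8,
    max_len=5,
):
    """A small random corpus for oracle-equivalence tests."""
    entries = []
    for i in range(n_sequences):
        y = f"y{rng.integers(n_physicians)}"
        p = f"p{rng.integers(n_patients)}"
        length = int(rng.integers(1, max_len + 1))
        terms = [f"t{rng.integers(n_terms)}" for _ in range(length)]
        entries.append((y, p, f"v{i}", terms))
    return make_corpus(entries)


@pytest.fixture(scope="session")
def toy_corpus():
    """Small fixed corpus exercising several physicians/patients/terms."""
    return make_corpus(
        [
            ("y1", "p1", "v1", ["a", "b", "a", "c"]),
            ("y1", "p2", "v2", ["a", "b"]),
            ("y2", "p2", "v3", ["b", "c", "d"]),
            ("y2", "p3", "v4", ["d"]),
            ("y3", "p1", "v5", ["c", "a"]),
        ]
    )


@pytest.fixture(scope="session")
def synthetic_default():
    """Default-condition synthetic corpus plus ground truth (shared, read-only)."""
    from dmcf.synthetic import SyntheticConfig, generate_log

    return generate_log(SyntheticConfig(seed=1))
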