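"""Shared fixtures: tiny hand-built inputs and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

import singlerecall as sr
from singlerecall.io_align import ReadRecord


def make_record(read_id, symbols, qscores, start=0, strand=0, barcode=None):
    """Build a ReadRecord from symbol codes (4 = deletion) at consecutive positions."""
    symbols = np.asarray(symbols, dtype=np.uint8)
    return ReadRecord(
        read_id=read_id,
        strand=strand,
        positions=np.arange(start, start + len(symbols), dtype=np.int32),
        symbols=symbols,
        qscores=np.asarray(qscores, dtype=np.int16),
        barcode=barcode,
    )


def perfect_reads(reference, n, q=20, strand=0):
    return [
        make_record(f"p{i}", reference.codes.copy(), [q] * len(reference), strand=strand)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_exp():
    """A quick synthetic study for unit tests (independent of the standard one)."""
    return sr.simulate_experiment(
        L=120, n_hotspots=3, n_wt_reads=200, n_variants=10,
        reads_per_variant=12, mean_mutations=2.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_model(small_exp):
    return sr.SingleErrorModel().fit(
        small_exp.wt_reads, small_exp.reference, small_exp.matrix
    )


@pytest.fixture(scope="session")
def standard_study():
    """The standard synthetic study conditions: 300-nt gene, 5 systematic
    hotspots, 500 wild-type training reads, 30 variants x 20 reads,
    expected mutation load 2, seed 1."""
    return sr.simulate_experiment(
        L=300, n_hotspots=5, n_wt_reads=500, n_variants=30,
        reads_per_variant=20, mean_mutations=2.0, seed=1,
    )


@pytest.fixture(scope="session")
def standard_model(standard_study):
    exp = standard_study
    return sr.SingleErrorModel().fit(exp.wt_reads, exp.reference, exp.matrix)


@pytest.fixture(scope="session")
def standard_scored(standard_study, standard_model):
    """Model-scored library reads per barcode, plus true final sequences."""
    exp = standard_study
    groups = {
        v.barcode: standard_model.transform(exp.library_reads[v.barcode])
        for v in exp.variants
    }
    truths = {
        v.barcode: "".join("ACGT"[c] for c in v.symbols if c != sr.DEL)
        for v in exp.variants
    }
    return groups, truths
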