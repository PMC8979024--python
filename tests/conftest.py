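"""Shared fixtures: one standard simulated dataset reused across the suite.

The standard scenario (two 500-kb contigs, 40 genes, 20 TEs, coverage 30,
10 planted hypo-CG blocks) is expensive enough to build once per session;
unit tests that need small bespoke inputs construct them inline.
"""

import logging

import numpy as np
import pandas as pd
import pytest

from rrbsmeth.formats import CONTEXTS
from rrbsmeth.methcall import call_methylated_sites
from rrbsmeth.sim import SimulationConfig, simulate_dataset

logging.getLogger("rrbsmeth").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def dataset():
    """Standard two-condition synthetic dataset."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def calls_pair(dataset):
    """(control, cold) calls frames for the standard dataset."""
    return (call_methylated_sites(dataset.report_control),
            call_methylated_sites(dataset.report_treated))


@pytest.fixture(scope="session")
def null_dataset():
    """Same generator, identical truth in both conditions (noise only)."""
    return simulate_dataset(SimulationConfig(seed=8), null=True)


@pytest.fixture(scope="session")
def null_calls_pair(null_dataset):
    return (call_methylated_sites(null_dataset.report_control),
            call_methylated_sites(null_dataset.report_treated))


@pytest.fixture
def tiny_config():
    """A fast-to-simulate configuration for determinism/unit checks."""
    return SimulationConfig(seed=3, n_contigs=1, contig_length=80_000,
                            n_genes=6, n_tes=3, n_planted_dmrs=2,
                            gene_length=(2000, 3000), te_length=(1000, 1500))


def make_sites(rows):
    """Sites frame from (chrom, pos, strand, context, n_meth, n_total) rows."""
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                        "n_meth", "n_total"])
    return frame


def overlaps(a_start, a_end, b_start, b_end):
    return a_start < b_end and a_end > b_start
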