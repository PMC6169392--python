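"""Shared fixtures: tiny hand-built alignments plus session-scoped simulated
genes (the expensive fits are reused across test modules)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import codonlrt as clt

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tiny_alignment() -> clt.CodonAlignment:
    """5 species x 3 codons, no ambiguity, query first."""
    seqs = {
        "Q": "ATGAAACTT",
        "S1": "ATGAAACTT",
        "S2": "ATGAAGCTT",
        "S3": "ATGCAACTC",
        "S4": "ATGAAATTA",
    }
    return clt.CodonAlignment(list(seqs), seqs, "Q")


@pytest.fixture
def three_tip_tree() -> clt.Phylogeny:
    return clt.Phylogeny.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def uniform_model():
    return clt.build_model(0.5, np.full(4, 0.25))


@pytest.fixture(scope="session")
def sim_gene():
    """A simulated mixture gene (200 codons, 12 tips) with its fit — shared
    because the fit is the expensive step."""
    config = clt.default_config(seed=101, n_codons=200)
    aln, omega_map = clt.simulate_alignment(config)
    fit = clt.fit_gene(aln, config.tree, seed=0)
    return config, aln, omega_map, fit
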