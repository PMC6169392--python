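"""Forward simulation of codon alignments and labelled benchmark sets.

Sequences evolve on a fixed tree under the same MG94 generator the inference
uses, with a per-site omega: constrained sites (omega << 1) stand in for
functionally important codons, neutral sites evolve at omega = 1.  The default
study conditions are a 12-tip pure-birth tree scaled to a total of 20 dS —
the middle of the 10–50 dS range where gene alignments carry enough
synonymous divergence for the test — with uniform nucleotide frequencies and
a small gap-injection rate so some columns are sparse.

``simulate_benchmark`` turns such an alignment into a labelled variant panel:
"deleterious" variants are amino acid changes placed at constrained sites,
"neutral" variants at omega = 1 sites, each with a minor allele count drawn
from a neutral-spectrum-like distribution (deleterious variants skewed toward
singletons) on an 80-chromosome panel.  ``simulate_score_table`` fabricates
correlated multi-approach score tables for the evaluation machinery.
"""

from __future__ import annotations

import dataclasses
import random as _pyrandom
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .codon_model import (
    AA_OF,
    SENSE_CODONS,
    build_model,
    single_nt_neighbors,
    transition_probabilities,
    translate_codon,
)
from .io import CodonAlignment, Phylogeny, ScoreTable, VariantRecord

__all__ = [
    "SimulationConfig",
    "default_tree",
    "default_config",
    "simulate_alignment",
    "simulate_benchmark",
    "simulate_score_table",
    "BenchmarkResult",
]

#: haploid sample size of the variant panel (minor allele counts are out of this)
PANEL_CHROMOSOMES = 80


def default_tree(n_tips: int = 12, total_ds: float = 20.0, seed: int = 0) -> Phylogeny:
    """Pure-birth topology on ``n_tips``, scaled to ``total_ds`` total length."""
    rng = _pyrandom.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1}"
    phylo = Phylogeny.from_dendropy(tree)
    scale = total_ds / phylo.total_length
    return phylo.scaled(scale)


@dataclasses.dataclass
class SimulationConfig:
    """Everything that determines a simulated alignment.

    ``omega_map`` gives the true omega per codon site; the seed fully
    determines all outputs.  ``gap_rate`` is the per-(homolog, site)
    probability of replacing a codon with gaps, producing the sparse columns
    seen in real alignments; the query is never gapped so variant coordinates
    stay trivial.
    """

    tree: Phylogeny
    n_codons: int
    omega_map: np.ndarray
    pi_nt: np.ndarray
    seed: int
    query_id: str
    gap_rate: float = 0.05

    def __post_init__(self) -> None:
        self.omega_map = np.asarray(self.omega_map, dtype=float)
        self.pi_nt = np.asarray(self.pi_nt, dtype=float)
        if len(self.omega_map) != self.n_codons:
            raise ValueError("omega_map length must equal n_codons")
        if np.any(self.omega_map < 0):
            raise ValueError("omega values must be >= 0")
        if self.query_id not in self.tree.tip_labels:
            raise ValueError(f"query {self.query_id!r} not a tree tip")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must be in [0, 1)")


def default_config(
    seed: int,
    n_codons: int = 500,
    p_constrained: float = 0.5,
    constrained_range: tuple[float, float] = (0.01, 0.2),
    n_tips: int = 12,
    total_ds: float = 20.0,
    gap_rate: float = 0.05,
) -> SimulationConfig:
    """Default study conditions: half the sites constrained with omega drawn
    uniformly from [0.01, 0.2], the rest neutral (omega = 1)."""
    rng = np.random.default_rng(seed)
    omega_map = np.ones(n_codons)
    n_con = int(round(p_constrained * n_codons))
    constrained = rng.choice(n_codons, size=n_con, replace=False)
    omega_map[constrained] = rng.uniform(*constrained_range, size=n_con)
    tree = default_tree(n_tips=n_tips, total_ds=total_ds, seed=seed)
    return SimulationConfig(
        tree=tree,
        n_codons=n_codons,
        omega_map=omega_map,
        pi_nt=np.full(4, 0.25),
        seed=seed,
        query_id=tree.tip_labels[0],
        gap_rate=gap_rate,
    )


def _evolve_states(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Simulate codon states (n_nodes x n_sites) down the tree.

    Sites are grouped by omega value so each group shares one model and one
    set of per-edge transition matrices; the root draws from the stationary
    distribution, children sample from P rows along each edge in preorder.
    """
    tree = config.tree
    states = np.empty((tree.n_nodes, config.n_codons), dtype=int)
    preorder = list(range(tree.n_nodes - 1, -1, -1))  # root first (postorder reversed)
    for omega in np.unique(config.omega_map):
        sites = np.flatnonzero(config.omega_map == omega)
        model = build_model(float(omega), config.pi_nt)
        root_draw = rng.choice(61, size=len(sites), p=model.pi_codon)
        states[tree.root, sites] = root_draw
        cumP = {
            node: np.cumsum(transition_probabilities(model, tree.lengths[node]), axis=1)
            for node in range(tree.n_nodes - 1)
        }
        for node in preorder:
            if node == tree.root:
                continue
            parents = states[tree.parent[node], sites]
            u = rng.random(len(sites))
            rows = cumP[node][parents]  # (n_sites_in_group, 61)
            states[node, sites] = (rows < u[:, None]).sum(axis=1)
    return states


def simulate_alignment(config: SimulationConfig) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve an alignment under the config; returns it with the true omegas.

    Gap injection replaces whole codons of non-query homologs with '---' at
    rate ``gap_rate``; the 61-state chain makes stop codons impossible by
    construction.
    """
    rng = np.random.default_rng(config.seed)
    states = _evolve_states(config, rng)
    tree = config.tree
    sequences: dict[str, str] = {}
    order: list[str] = []
    for node in tree.tip_indices:
        label = tree.labels[node]
        codons = [SENSE_CODONS[s] for s in states[node]]
        if config.gap_rate > 0 and label != config.query_id:
            gapped = rng.random(config.n_codons) < config.gap_rate
            codons = ["---" if g else c for c, g in zip(codons, gapped)]
        order.append(label)
        sequences[label] = "".join(codons)
    aln = CodonAlignment(order, sequences, config.query_id)
    return aln, config.omega_map.copy()


# ---------------------------------------------------------------------------
# Labelled benchmark sets
# ---------------------------------------------------------------------------

def _mac_distribution(n: int, power: float) -> np.ndarray:
    """Probabilities over minor allele counts 1..n/2 proportional to i^-power.

    power=1 is the standard neutral frequency spectrum; power=2 skews strongly
    toward singletons, as expected for deleterious alleles held rare by
    selection.
    """
    counts = np.arange(1, n // 2 + 1, dtype=float)
    w = counts ** (-power)
    return w / w.sum()


@dataclasses.dataclass
class BenchmarkResult:
    alignment: CodonAlignment
    variants: list[VariantRecord]
    true_omega: np.ndarray
    site_of_variant: list[int]  # 0-based codon column per variant


def simulate_benchmark(
    config: SimulationConfig,
    n_deleterious: int,
    n_neutral: int,
    seed: int | None = None,
) -> BenchmarkResult:
    """Simulate an alignment plus a labelled variant panel on it.

    Deleterious (positive) variants are placed at constrained sites
    (omega < 1), neutral (negative) variants at omega = 1 sites; the alternate
    amino acid is drawn among single-nucleotide-reachable neighbors of the
    query codon where possible (any other amino acid otherwise, flagged with a
    ``multi_nt`` tag).  Minor allele counts on the 80-chromosome panel follow
    ~1/i for neutral and ~1/i^2 for deleterious variants.
    """
    if n_deleterious < 1 or n_neutral < 1:
        raise ValueError("variant counts must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    aln, omega_map = simulate_alignment(config)
    query_cols = aln.query_codon_columns  # all of them: query is never gapped
    constrained = [c for c in query_cols if omega_map[c] < 1.0]
    neutral = [c for c in query_cols if omega_map[c] == 1.0]
    if len(constrained) < n_deleterious or len(neutral) < n_neutral:
        raise ValueError(
            f"requested {n_deleterious}+{n_neutral} variants but only "
            f"{len(constrained)} constrained / {len(neutral)} neutral sites exist"
        )
    del_sites = rng.choice(constrained, size=n_deleterious, replace=False)
    neut_sites = rng.choice(neutral, size=n_neutral, replace=False)

    col_index = {c: i for i, c in enumerate(query_cols)}
    mac_del = _mac_distribution(PANEL_CHROMOSOMES, power=2.0)
    mac_neut = _mac_distribution(PANEL_CHROMOSOMES, power=1.0)

    variants: list[VariantRecord] = []
    sites: list[int] = []
    gene_id = "simgene"
    for label, chosen, mac_p in (
        ("positive", del_sites, mac_del),
        ("negative", neut_sites, mac_neut),
    ):
        for col in chosen:
            codon = aln.codon(config.query_id, int(col))
            ref_aa = translate_codon(codon)
            assert ref_aa is not None
            reachable = sorted(
                {
                    AA_OF[nb]
                    for _pos, nb in single_nt_neighbors(codon)
                    if nb in AA_OF and AA_OF[nb] != ref_aa
                }
            )
            tags = frozenset()
            if reachable:
                alt_aa = reachable[rng.integers(0, len(reachable))]
            else:
                others = sorted(set(AA_OF.values()) - {ref_aa})
                alt_aa = others[rng.integers(0, len(others))]
                tags = frozenset({"multi_nt"})
            mac = int(rng.choice(len(mac_p), p=mac_p) + 1)
            variants.append(
                VariantRecord(
                    gene_id=gene_id,
                    codon_pos=col_index[int(col)] + 1,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    label=label,
                    minor_allele_count=mac,
                    category_tags=tags,
                )
            )
            sites.append(int(col))
    return BenchmarkResult(
        alignment=aln, variants=variants, true_omega=omega_map, site_of_variant=sites
    )


# ---------------------------------------------------------------------------
# Synthetic multi-approach score tables
# ---------------------------------------------------------------------------

def simulate_score_table(
    n_pos: int,
    n_neg: int,
    n_approaches: int,
    signal_strengths: Sequence[float] | float = 1.0,
    correlation: float = 0.5,
    seed: int = 0,
) -> tuple[ScoreTable, np.ndarray]:
    """Fabricate per-approach scores with controlled signal and correlation.

    Each approach's score is ``strength * label + sqrt(c) * shared_noise +
    sqrt(1-c) * own_noise`` so ``correlation`` tunes how similarly approaches
    err, and ``signal_strengths`` (scalar or per-approach) tunes class
    separation.  Returns the table plus the 0/1 labels.
    """
    if not 0 <= correlation < 1:
        raise ValueError("correlation must be in [0, 1)")
    strengths = np.broadcast_to(
        np.asarray(signal_strengths, dtype=float), (n_approaches,)
    )
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    shared = rng.standard_normal(n)
    scores = (
        labels[:, None] * strengths[None, :]
        + np.sqrt(correlation) * shared[:, None]
        + np.sqrt(1.0 - correlation) * rng.standard_normal((n, n_approaches))
    )
    frame = pd.DataFrame(
        {
            "gene": ["g1"] * n,
            "codon_pos": np.arange(1, n + 1),
            "ref_aa": ["M"] * n,
            "alt_aa": ["L"] * n,
            **{f"approach_{k + 1}": scores[:, k] for k in range(n_approaches)},
        }
    )
    return ScoreTable(frame), labels
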