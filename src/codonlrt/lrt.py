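"""Per-codon likelihood ratio test of selective constraint.

At each codon of interest the test compares the log-likelihood of evolution
under a neutral model (omega fixed at 1, dN = dS) to a model allowing
constraint or relaxation (omega free, dN = omega * dS), with branch lengths
held at the per-gene fit.  The statistic 2*(lnL_alt - lnL_null) is referred
to chi-square with 1 df.  Two modes are computed per variant: *unmasked*
(alignment as-is) and *masked*, where the query sequence is replaced by
missing data so the test cannot be biased toward the reference allele.

Alignment-derived features accompany the test: Rn and An, the number of
alignment sequences whose amino acid at the column equals the query reference
and the alternate (mutant) amino acid respectively.  Rather than filtering
sites on heuristics, these features feed the downstream logistic models.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from . import codon_model
from .codon_model import MISSING_STATE, GeneFit, fit_gene, translate_codon
from .io import CodonAlignment, Phylogeny, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "P_VALUE_FLOOR",
    "CONSTRAINT_CAP",
    "SiteLRT",
    "VariantPrediction",
    "mask_query",
    "apply_caps",
    "count_alleles",
    "lrt_site",
    "run_gene",
]

#: p-values below this are set to it before entering the logistic features
P_VALUE_FLOOR = 1e-16
#: site omega estimates above this are set to it ("constraint" feature cap)
CONSTRAINT_CAP = 10.0
_OMEGA_BOUNDS = (1e-6, 50.0)
#: log-spaced bracketing grid over the omega search range
_OMEGA_GRID = (
    1e-6, 1e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3,
    0.6, 1.0, 1.7, 3.0, 6.0, 15.0, 50.0,
)


@dataclasses.dataclass
class SiteLRT:
    """Per-codon test result bundle (one mode: masked or unmasked)."""

    gene_id: str
    codon_pos: int
    masked: bool
    lnL_null: float
    lnL_alt: float
    lrt_stat: float
    p_value: float
    omega_site: float
    constraint: float
    Rn: int | None = None
    An: int | None = None
    n_ungapped: int | None = None
    flags: tuple[str, ...] = ()


@dataclasses.dataclass
class VariantPrediction:
    """Masked + unmasked test results for one variant, or an error record."""

    variant: VariantRecord
    unmasked: SiteLRT | None = None
    masked: SiteLRT | None = None
    error: str | None = None
    warnings: tuple[str, ...] = ()


def mask_query(aln: CodonAlignment) -> CodonAlignment:
    """Replace the entire query sequence with missing data ('N's).

    This is the reference-bias guard: with the query masked, the likelihood at
    a column is identical to the likelihood with the query tip pruned from the
    tree, and the query allele cannot inflate its own conservation signal.
    Idempotent.
    """
    length = len(aln.sequences[aln.query_id])
    return aln.replace_sequence(aln.query_id, "N" * length)


def apply_caps(p_raw: float, omega_site: float) -> tuple[float, float]:
    """Floor the p-value at 1e-16 and cap the constraint (site omega) at 10."""
    return max(p_raw, P_VALUE_FLOOR), min(omega_site, CONSTRAINT_CAP)


def count_alleles(
    aln: CodonAlignment,
    codon_pos: int,
    ref_aa: str,
    alt_aa: str,
    masked: bool,
) -> tuple[int, int, int]:
    """Count reference and alternate amino acids at a codon column.

    Returns (Rn, An, n_ungapped) over the translated codons at the column for
    the variant's 1-based query codon position.  Gap, missing, ambiguous and
    stop codons are excluded from all three counts.  Unmasked counts include
    the query row itself; masked counts exclude it, mirroring alignments
    "without the reference allele".
    """
    column = aln.column(aln.resolve_codon_pos(codon_pos))
    rn = an = n_ungapped = 0
    for sp, codon in column.items():
        if masked and sp == aln.query_id:
            continue
        aa = translate_codon(codon)
        if aa is None:
            continue
        n_ungapped += 1
        if aa == ref_aa:
            rn += 1
        elif aa == alt_aa:
            an += 1
    return rn, an, n_ungapped


def _column_states(
    aln: CodonAlignment, fit: GeneFit, column: int, masked: bool
) -> np.ndarray:
    tree = fit.tree
    states = np.full((tree.n_nodes, 1), MISSING_STATE, dtype=int)
    for node in tree.tip_indices:
        label = tree.labels[node]
        if masked and label == aln.query_id:
            continue
        codon = aln.codon(label, column)
        try:
            states[node, 0] = codon_model.encode_codon(
                codon, species=label, site=column + 1
            )
        except ValueError:
            logger.warning(
                "stop codon in %s at column %d treated as missing", label, column + 1
            )
    return states


def lrt_site(
    aln: CodonAlignment,
    fit: GeneFit,
    codon_pos: int,
    masked: bool,
    ref_aa: str | None = None,
    alt_aa: str | None = None,
    gene_id: str = "",
) -> SiteLRT:
    """Run the constraint LRT at one codon with branch lengths fixed at the
    gene fit's (capped) values.

    The null likelihood fixes omega = 1; the alternative maximises omega over
    [1e-6, 50] by bounded scalar search (xatol 1e-8).  The statistic is
    floored at 0 to absorb optimizer noise and referred to chi2(1); the
    p-value floor and constraint cap are applied before the result is used as
    classifier features.  Columns with fewer than 2 ungapped sequences carry
    no information and come back flagged with p = 1 instead of raising.
    """
    column = aln.resolve_codon_pos(codon_pos)
    states = _column_states(aln, fit, column, masked)
    flags: list[str] = []

    n_states = int((states != MISSING_STATE).sum())
    if ref_aa is not None and alt_aa is not None:
        rn, an, n_ungapped = count_alleles(aln, codon_pos, ref_aa, alt_aa, masked)
    else:
        rn = an = None
        n_ungapped = n_states

    if n_states <= 1:
        flags.append("degenerate_column")
        p_value, constraint = apply_caps(1.0, 1.0)
        return SiteLRT(
            gene_id=gene_id, codon_pos=codon_pos, masked=masked,
            lnL_null=0.0, lnL_alt=0.0, lrt_stat=0.0,
            p_value=p_value, omega_site=1.0, constraint=constraint,
            Rn=rn, An=an, n_ungapped=n_ungapped, flags=tuple(flags),
        )

    lnl_null = float(fit.site_lnls(states, 1.0)[0])

    def neg(omega: float) -> float:
        return -float(fit.site_lnls(states, omega)[0])

    # the profile in omega can be bimodal (a saturation shelf as omega grows
    # competes with a constrained optimum near 0), so bracket the global
    # optimum on a log-spaced grid before refining with a bounded search
    grid_vals = [neg(w) for w in _OMEGA_GRID]
    k = int(np.argmin(grid_vals))
    lo = _OMEGA_GRID[max(0, k - 1)]
    hi = _OMEGA_GRID[min(len(_OMEGA_GRID) - 1, k + 1)]
    res = minimize_scalar(
        neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    omega_hat, lnl_alt = float(res.x), float(-res.fun)
    if grid_vals[k] < res.fun:  # keep the grid point if refinement slipped
        omega_hat, lnl_alt = float(_OMEGA_GRID[k]), float(-grid_vals[k])
    if lnl_alt < lnl_null:  # guarantee nesting up to optimizer tolerance
        omega_hat, lnl_alt = 1.0, lnl_null

    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p_raw = float(chi2.sf(stat, df=1))
    p_value, constraint = apply_caps(p_raw, omega_hat)
    return SiteLRT(
        gene_id=gene_id, codon_pos=codon_pos, masked=masked,
        lnL_null=lnl_null, lnL_alt=lnl_alt, lrt_stat=stat,
        p_value=p_value, omega_site=omega_hat, constraint=constraint,
        Rn=rn, An=an, n_ungapped=n_ungapped, flags=tuple(flags),
    )


def run_gene(
    aln: CodonAlignment,
    topology: Phylogeny,
    variants: Sequence[VariantRecord],
    *,
    fit: GeneFit | None = None,
    seed: int = 0,
) -> list[VariantPrediction]:
    """Score every variant of one gene in both modes.

    The gene is fitted once (branch lengths + gene omega on the full filtered
    alignment) and the fit reused for all variants and both modes.  A variant
    whose codon position falls outside the query CDS yields a per-variant
    error record; the others are unaffected.  A supplied ``ref_aa`` that
    disagrees with the query's translated codon is flagged as a warning, not
    an error.
    """
    if fit is None:
        fit = fit_gene(aln, topology, seed=seed)
    results: list[VariantPrediction] = []
    for var in variants:
        try:
            column = aln.resolve_codon_pos(var.codon_pos)
        except IndexError as exc:
            results.append(VariantPrediction(variant=var, error=str(exc)))
            continue
        warnings: list[str] = []
        query_aa = translate_codon(aln.codon(aln.query_id, column))
        if query_aa is not None and query_aa != var.ref_aa:
            warnings.append(
                f"reference mismatch: query encodes {query_aa}, table says {var.ref_aa}"
            )
        unmasked = lrt_site(
            aln, fit, var.codon_pos, masked=False,
            ref_aa=var.ref_aa, alt_aa=var.alt_aa, gene_id=var.gene_id,
        )
        masked = lrt_site(
            aln, fit, var.codon_pos, masked=True,
            ref_aa=var.ref_aa, alt_aa=var.alt_aa, gene_id=var.gene_id,
        )
        results.append(
            VariantPrediction(
                variant=var, unmasked=unmasked, masked=masked,
                warnings=tuple(warnings),
            )
        )
    return results


def predictions_to_rows(predictions: Sequence[VariantPrediction]) -> list[dict]:
    """Flatten VariantPredictions to TSV-ready rows (one per variant)."""
    rows = []
    for p in predictions:
        v = p.variant
        row: dict = {
            "gene": v.gene_id, "codon_pos": v.codon_pos,
            "ref_aa": v.ref_aa, "alt_aa": v.alt_aa,
            "label": v.label, "mac": v.minor_allele_count,
            "error": p.error, "warnings": ";".join(p.warnings) or None,
        }
        for mode, site in (("unmasked", p.unmasked), ("masked", p.masked)):
            prefix = "" if mode == "unmasked" else "masked_"
            if site is None:
                continue
            row.update(
                {
                    f"{prefix}p_value": site.p_value,
                    f"{prefix}constraint": site.constraint,
                    f"{prefix}Rn": site.Rn,
                    f"{prefix}An": site.An,
                    f"{prefix}n_ungapped": site.n_ungapped,
                }
            )
        rows.append(row)
    return rows
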