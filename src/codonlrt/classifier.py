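"""Deleterious-probability scoring.

Two published logistic models turn the per-codon LRT output into a single
probability of being deleterious.  Unmasked features: log10 p-value,
constraint (capped site dN/dS), Rn and An.  Masked features replace the raw
counts by max(Rn, An) and |Rn - An|, which are computable without trusting the
reference allele.  The default coefficients are fixed constants; ``fit_logistic``
re-estimates a model on new labelled data and ``cross_validate`` assesses it
by stratified 10-fold AUC.  Also here: the per-codon combination rule for
nucleotide-level GERP conservation scores, and the logistic ensemble combiner
over several approaches' raw scores.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings as _warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .codon_model import AA_OF, CODON_INDEX, single_nt_neighbors
from .io import ScoreTable, KEY_COLUMNS
from .lrt import SiteLRT

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticModel",
    "UNMASKED_MODEL",
    "MASKED_MODEL",
    "features_from_site",
    "predict_probability",
    "fit_logistic",
    "cross_validate",
    "gerp_codon_score",
    "ensemble_combine",
]


@dataclasses.dataclass(frozen=True)
class LogisticModel:
    """Named logistic coefficients: log(p/(1-p)) = intercept + coef . features."""

    mode: str  # "unmasked" | "masked" | "custom"
    intercept: float
    coefficients: tuple[float, ...]
    feature_names: tuple[str, ...]
    flags: tuple[str, ...] = ()

    def linear_predictor(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != len(self.coefficients):
            raise ValueError(
                f"expected {len(self.coefficients)} features "
                f"({self.feature_names}), got {features.shape[1]}"
            )
        return self.intercept + features @ np.asarray(self.coefficients)


#: default model for the unmasked LRT (query sequence present)
UNMASKED_MODEL = LogisticModel(
    mode="unmasked",
    intercept=-2.407,
    coefficients=(-0.2139, -0.2056, 0.07368, -0.1236),
    feature_names=("log10_p", "constraint", "Rn", "An"),
)

#: default model for the masked LRT (query replaced by missing data)
MASKED_MODEL = LogisticModel(
    mode="masked",
    intercept=-2.453,
    coefficients=(-0.1904, -0.1459, 0.2199, -0.2951),
    feature_names=("log10_p", "constraint", "max_Rn_An", "abs_Rn_An"),
)


def features_from_site(site: SiteLRT, mode: str) -> np.ndarray:
    """Feature vector for one LRT result.

    Requires the caps to be in place already (p >= 1e-16, constraint <= 10),
    so log10(p) is bounded below by -16.  Unmasked order: (log10 p,
    constraint, Rn, An); masked: (log10 p, constraint, max(Rn, An),
    |Rn - An|).
    """
    if mode not in {"unmasked", "masked"}:
        raise ValueError(f"unknown mode {mode!r}")
    if site.masked != (mode == "masked"):
        raise ValueError(f"site computed with masked={site.masked}, mode={mode!r}")
    if site.Rn is None or site.An is None:
        raise ValueError("site lacks Rn/An counts")
    log10_p = np.log10(site.p_value)
    if mode == "unmasked":
        return np.array([log10_p, site.constraint, site.Rn, site.An], dtype=float)
    return np.array(
        [log10_p, site.constraint, max(site.Rn, site.An), abs(site.Rn - site.An)],
        dtype=float,
    )


def predict_probability(features: np.ndarray, model: LogisticModel) -> np.ndarray | float:
    """Deleterious probability: inverse-logit of the model's linear predictor."""
    arr = np.asarray(features, dtype=float)
    prob = expit(model.linear_predictor(arr))
    return float(prob[0]) if arr.ndim == 1 else prob


def score_sites(sites: Sequence[SiteLRT], mode: str, model: LogisticModel | None = None) -> np.ndarray:
    """Vectorised convenience: probabilities for many SiteLRT results."""
    if model is None:
        model = UNMASKED_MODEL if mode == "unmasked" else MASKED_MODEL
    feats = np.array([features_from_site(s, mode) for s in sites])
    return expit(model.linear_predictor(feats))


# ---------------------------------------------------------------------------
# Fitting and cross-validation
# ---------------------------------------------------------------------------

_RIDGE_PENALTY = 1e-6


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic regression (IRLS, tolerance 1e-8).

    Perfect separation (or other IRLS failure) falls back to a ridge fit with
    penalty 1e-6 and the returned model carries a ``separation_fallback`` flag.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, k) aligned with labels")
    if np.isnan(X).any():
        raise ValueError("missing feature values; drop or impute explicitly first")
    classes = np.unique(y)
    if len(classes) != 2 or not set(classes) <= {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 examples of each class")
    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{i}" for i in range(X.shape[1])
    )

    design = sm.add_constant(X, has_constant="add")
    flags: tuple[str, ...] = ()
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            result = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                tol=1e-8, maxiter=200
            )
        params = np.asarray(result.params, dtype=float)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 1e6:
            raise sm.tools.sm_exceptions.PerfectSeparationError("divergent fit")
    except Exception:
        logger.warning("IRLS failed (likely separation); using ridge fallback")
        clf = LogisticRegression(
            C=1.0 / _RIDGE_PENALTY, solver="lbfgs", max_iter=10000
        )
        clf.fit(X, y)
        params = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
        flags = ("separation_fallback",)

    return LogisticModel(
        mode="custom",
        intercept=float(params[0]),
        coefficients=tuple(float(b) for b in params[1:]),
        feature_names=names,
        flags=flags,
    )


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment: seeded shuffle within each class, then round-robin."""
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer members ({len(idx)}) than folds ({k})")
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validated AUC of the logistic model.

    Each fold's model is fit on the remaining k-1 folds and evaluated by AUC
    on the held-out fold; the mean over folds is the headline number.
    """
    from .evaluation import roc_curve  # local import to avoid a cycle

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    folds = stratified_folds(y, k, seed)
    aucs = []
    for fold in range(k):
        test = folds == fold
        model = fit_logistic(X[~test], y[~test])
        probs = predict_probability(X[test], model)
        aucs.append(roc_curve(probs, y[test]).auc)
    return float(np.mean(aucs)), [float(a) for a in aucs]


# ---------------------------------------------------------------------------
# GERP per-codon combination rule
# ---------------------------------------------------------------------------

def gerp_codon_score(ref_codon: str, alt_aa: str, pos_scores: Sequence[float]) -> float:
    """Combine three per-nucleotide conservation scores into one codon score.

    If the amino acid substitution can occur by a single nucleotide change at
    some codon position(s), return the score at that position (averaging when
    more than one position qualifies); otherwise — the change needs two or
    more nucleotide edits — return the mean of the first- and second-position
    scores.
    """
    if ref_codon not in CODON_INDEX:
        raise ValueError(f"{ref_codon!r} is not a sense codon")
    if AA_OF[ref_codon] == alt_aa:
        raise ValueError("alt_aa equals the codon's own amino acid")
    s = np.asarray(pos_scores, dtype=float)
    if s.shape != (3,):
        raise ValueError("pos_scores must hold exactly 3 values")
    qualifying = sorted(
        {
            pos
            for pos, neighbor in single_nt_neighbors(ref_codon)
            if AA_OF.get(neighbor) == alt_aa
        }
    )
    if qualifying:
        return float(s[qualifying].mean())
    return float((s[0] + s[1]) / 2.0)


# ---------------------------------------------------------------------------
# Ensemble combiner
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EnsembleResult:
    model: LogisticModel
    probabilities: np.ndarray  # aligned with complete rows
    complete_mask: np.ndarray  # which input rows were complete
    cv_auc: float
    cv_fold_aucs: list[float]
    n_dropped: int


def ensemble_combine(
    scores: ScoreTable | pd.DataFrame,
    labels: np.ndarray,
    approaches: Sequence[str] | None = None,
    seed: int = 0,
    k: int = 10,
) -> EnsembleResult:
    """Logistic combination of several approaches' raw scores.

    Rows with a missing score in any used approach are removed before fitting
    (and counted in ``n_dropped``); the combiner is fit on raw, unstandardised
    scores and assessed by 10-fold cross-validated AUC.  The approach column
    set is caller-configurable so score sets with incompatible coverage (for
    example a sparsely available approach) can be excluded.
    """
    frame = scores.frame if isinstance(scores, ScoreTable) else scores
    if approaches is None:
        approaches = [c for c in frame.columns if c not in KEY_COLUMNS]
    if len(approaches) < 1:
        raise ValueError("need at least one approach column")
    X_all = frame[list(approaches)].to_numpy(dtype=float)
    y_all = np.asarray(labels, dtype=float)
    if len(X_all) != len(y_all):
        raise ValueError("labels length must match score table")
    complete = ~np.isnan(X_all).any(axis=1)
    X, y = X_all[complete], y_all[complete]
    for c in (0.0, 1.0):
        if (y == c).sum() < 2:
            raise ValueError("need >= 2 complete rows per class")
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("ensemble: removed %d rows with missing scores", n_dropped)
    model = fit_logistic(X, y, feature_names=approaches)
    probs = predict_probability(X, model)
    cv_auc, fold_aucs = cross_validate(X, y, k=k, seed=seed)
    return EnsembleResult(
        model=model,
        probabilities=np.atleast_1d(probs),
        complete_mask=complete,
        cv_auc=cv_auc,
        cv_fold_aucs=fold_aucs,
        n_dropped=n_dropped,
    )
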