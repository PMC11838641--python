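"""Cross-fitted LASSO propensity scores with discrimination/calibration
diagnostics.

The propensity score is estimated by L1-penalized logistic regression
under 10-fold cross-fitting: the cohort is split into folds stratified by
treatment; for each fold the model is trained on the other nine (with the
penalty chosen by an inner 5-fold cross-validation minimizing binomial
deviance) and applied to the held-out fold.  Every patient thus receives
an out-of-fold prediction, which limits the optimism that data-adaptive
PS models otherwise leak into downstream causal estimates.

Diagnostics follow standard practice: the C-statistic (AUC, Mann-Whitney
form with ties counted 1/2) for discrimination and the mean negative
Bernoulli log-likelihood (NLL, natural log) for calibration, both computed
on the pooled out-of-fold predictions.  The number of selected predictors
reported per model comes from a full-data refit at the median of the
per-fold penalties; that refit is for reporting only — all inference uses
the cross-fitted scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

from sklearn.exceptions import ConvergenceWarning

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix

__all__ = [
    "COVARIATE_SETS",
    "CovariateSetSpec",
    "PropensityFit",
    "crossfit_lasso_ps",
    "compute_auc",
    "compute_nll",
    "PS_CLIP",
]

PS_CLIP = 1e-6

# The eight nested candidate covariate sets: researcher-specified
# variables, then cumulative claims and EHR code blocks, then one NLP
# block per model (n-grams, lexicon concepts, sentence clusters,
# contextual word clusters, word clusters).
_STRUCTURED = ("researcher", "claims", "ehr_code")
COVARIATE_SETS: dict[int, tuple[str, ...]] = {
    1: ("researcher",),
    2: ("researcher", "claims"),
    3: _STRUCTURED,
    4: _STRUCTURED + ("ngram",),
    5: _STRUCTURED + ("lexicon",),
    6: _STRUCTURED + ("cluster_sentence",),
    7: _STRUCTURED + ("cluster_contextual",),
    8: _STRUCTURED + ("cluster_word",),
}


@dataclass(frozen=True)
class CovariateSetSpec:
    model_id: int

    def __post_init__(self):
        if self.model_id not in COVARIATE_SETS:
            raise ValueError("model_id must be in 1..8")

    @property
    def sources(self) -> tuple[str, ...]:
        return COVARIATE_SETS[self.model_id]


@dataclass
class PropensityFit:
    """Cross-fitted propensity scores plus diagnostics."""

    ps: np.ndarray
    fold_id: np.ndarray
    n_candidate: int
    n_selected: int
    auc: float
    nll: float
    lambda_per_fold: np.ndarray
    model_id: int | None = None
    feature_names: list = field(default_factory=list)

    def validate(self) -> None:
        if self.ps.shape != self.fold_id.shape:
            raise ValueError("ps and fold_id must align")
        if (self.ps < PS_CLIP - 1e-15).any() or (self.ps > 1 - PS_CLIP + 1e-15).any():
            raise ValueError("ps must be clipped into [eps, 1-eps]")
        sizes = np.bincount(self.fold_id)[1:]
        if sizes.size and sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")
        if self.n_selected > self.n_candidate:
            raise ValueError("n_selected cannot exceed n_candidate")

    def save(self, prefix: str | Path, patient_ids: Sequence | None = None) -> None:
        prefix = Path(prefix)
        ids = patient_ids if patient_ids is not None else np.arange(len(self.ps))
        pd.DataFrame({"patient_id": ids, "fold_id": self.fold_id, "ps": self.ps}).to_csv(
            prefix.with_suffix(".csv"), index=False
        )
        diag = {
            "model_id": self.model_id,
            "n_candidate": int(self.n_candidate),
            "n_selected": int(self.n_selected),
            "auc": float(self.auc),
            "nll": float(self.nll),
            "lambda_per_fold": [float(x) for x in self.lambda_per_fold],
        }
        prefix.with_suffix(".json").write_text(json.dumps(diag, indent=2))


def _as_design(fm) -> tuple[sp.csr_matrix, np.ndarray, int]:
    if isinstance(fm, FeatureMatrix):
        X = fm.values
        continuous = (~fm.meta["is_binary"].to_numpy()).astype(bool)
    else:
        X = sp.csr_matrix(fm, dtype=float)
        continuous = np.zeros(X.shape[1], dtype=bool)
    return sp.csr_matrix(X, dtype=float), continuous, X.shape[1]


def _scale_matrix(X: sp.csr_matrix, continuous: np.ndarray, train_idx) -> sp.csr_matrix:
    """Scale continuous columns to unit train-split variance (no centering,
    to preserve sparsity); binary 0/1 columns pass through unscaled."""
    if not continuous.any():
        return X
    scale = np.ones(X.shape[1])
    sub = X[train_idx][:, continuous].toarray()
    sd = sub.std(axis=0, ddof=0)
    scale[continuous] = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 1.0)
    return X @ sp.diags(scale)


_DEFAULT_CS = np.logspace(-2.0, 0.0, 5)


def _fit_l1(X, y, C: float, tol: float = 1e-4, max_iter: int = 500) -> LogisticRegression:
    model = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=C, max_iter=max_iter, tol=tol,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _maybe_densify(X: sp.csr_matrix):
    """liblinear is faster on dense arrays once the design stops being
    sparse in practice (prevalent binary features)."""
    density = X.nnz / max(1, X.shape[0] * X.shape[1])
    if density > 0.15 and X.shape[1] <= 4000:
        return np.ascontiguousarray(X.toarray())
    return X


def crossfit_lasso_ps(
    fm,
    A: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    Cs: np.ndarray | None = None,
    inner_folds: int = 5,
    model_id: int | None = None,
    fold_id: np.ndarray | None = None,
) -> PropensityFit:
    """Cross-fitted L1 logistic propensity scores.

    Folds are stratified by treatment so every training split contains
    both arms.  Within each training split the penalty is chosen from
    ``Cs`` (inverse-regularization grid) by ``inner_folds``-fold CV
    minimizing binomial deviance; out-of-fold predicted probabilities are
    assembled into ``ps`` and clipped to [1e-6, 1 - 1e-6].  A precomputed
    1-based ``fold_id`` vector may be supplied to bypass the random split
    (e.g. to check permutation invariance).
    """
    A = np.asarray(A, dtype=int)
    if not np.isin(A, (0, 1)).all():
        raise ValueError("A must be binary")
    if A.sum() == 0 or A.sum() == len(A):
        raise ValueError("both treatment arms must be non-empty")
    X, continuous, p = _as_design(fm)
    if X.shape[0] != len(A):
        raise ValueError("feature matrix rows must align with A")
    Cs = np.asarray(Cs if Cs is not None else _DEFAULT_CS, dtype=float)

    n = len(A)
    folds = np.empty(n, dtype=int)
    if fold_id is not None:
        folds = np.asarray(fold_id, dtype=int)
        if folds.min() < 1 or folds.max() > n_folds:
            raise ValueError("fold_id must contain values in 1..n_folds")
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for f, (_, test) in enumerate(skf.split(np.zeros(n), A), start=1):
            folds[test] = f

    ps = np.empty(n)
    chosen_C = np.empty(n_folds)
    for f in range(1, n_folds + 1):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        y_tr = A[train]
        if y_tr.min() == y_tr.max():
            raise ValueError(
                "a training split contains a single treatment class; "
                "use a larger cohort or fewer folds"
            )
        Xs = _maybe_densify(_scale_matrix(X, continuous, train))
        X_tr = Xs[train]
        # inner CV splits are groups of outer folds, so the split is a pure
        # function of the fold assignment (invariant to patient ordering)
        other = sorted(set(range(1, n_folds + 1)) - {f})
        n_groups = min(inner_folds, len(other))
        group_of = {lab: i % n_groups for i, lab in enumerate(other)}
        inner_grp = np.array([group_of[folds[i]] for i in train])
        dev = np.zeros(len(Cs))
        for g in range(n_groups):
            itr = np.flatnonzero(inner_grp != g)
            ite = np.flatnonzero(inner_grp == g)
            if y_tr[itr].min() == y_tr[itr].max():
                raise ValueError(
                    "an inner training split contains a single treatment class; "
                    "use a larger cohort or fewer folds"
                )
            X_itr, X_ite = X_tr[itr], X_tr[ite]
            for ci, C in enumerate(Cs):
                # selection fits can run at a looser tolerance; only the
                # per-fold refit used for prediction is tightly converged
                m = _fit_l1(X_itr, y_tr[itr], C, tol=5e-3, max_iter=15)
                pr = np.clip(m.predict_proba(X_ite)[:, 1], PS_CLIP, 1 - PS_CLIP)
                y_ite = y_tr[ite]
                dev[ci] += -np.sum(y_ite * np.log(pr) + (1 - y_ite) * np.log(1 - pr))
        C_best = float(Cs[int(np.argmin(dev))])
        chosen_C[f - 1] = C_best
        m = _fit_l1(X_tr, y_tr, C_best)
        ps[test] = m.predict_proba(Xs[test])[:, 1]

    ps = np.clip(ps, PS_CLIP, 1 - PS_CLIP)

    # reporting refit: selected-predictor count at the median penalty
    C_med = float(np.median(chosen_C))
    Xs_full = _maybe_densify(_scale_matrix(X, continuous, np.arange(n)))
    refit = _fit_l1(Xs_full, A, C_med)
    n_selected = int(np.count_nonzero(refit.coef_))

    fit = PropensityFit(
        ps=ps,
        fold_id=folds,
        n_candidate=p,
        n_selected=n_selected,
        auc=compute_auc(ps, A),
        nll=compute_nll(ps, A),
        lambda_per_fold=1.0 / chosen_C,
        model_id=model_id,
        feature_names=list(fm.names) if isinstance(fm, FeatureMatrix) else [],
    )
    fit.validate()
    return fit


def compute_auc(ps: np.ndarray, A: np.ndarray) -> float:
    """C-statistic: P(ps_treated > ps_control), ties counted 1/2."""
    ps = np.asarray(ps, dtype=float)
    A = np.asarray(A, dtype=int)
    n1 = int(A.sum())
    n0 = len(A) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both treatment arms must be non-empty")
    ranks = rankdata(ps)
    return float((ranks[A == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_nll(ps: np.ndarray, A: np.ndarray) -> float:
    """Mean negative Bernoulli log-likelihood (natural log)."""
    ps = np.asarray(ps, dtype=float)
    A = np.asarray(A, dtype=float)
    if (ps <= 0).any() or (ps >= 1).any():
        raise ValueError("ps must lie strictly inside (0, 1); clip upstream")
    return float(-np.mean(A * np.log(ps) + (1 - A) * np.log(1 - ps)))
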