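"""Candidate-feature screens: prevalence filtering and IV triage.

Two screens precede propensity modelling.  First, empirically generated
binary features (claims/EHR codes and NLP output) with prevalence
strictly below a cutoff (default 0.01) are dropped — researcher-specified
and continuous covariates are exempt.  Second, features are ranked by
their marginal correlation with treatment so that the strongest treatment
predictors can be reviewed as potential instrumental variables; review
itself is expressed as a denylist of feature names to exclude, which in
simulations can be derived from the generator's ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = [
    "ScreenConfig",
    "ScreenReport",
    "prevalence_filter",
    "rank_iv_candidates",
    "apply_denylist",
    "screen_features",
]

logger = logging.getLogger(__name__)

_EXEMPT_SOURCES = frozenset({"researcher"})


@dataclass
class ScreenConfig:
    prevalence_min: float = 0.01
    iv_top_k: int = 20
    denylist: frozenset = frozenset()

    def __post_init__(self):
        if not (0.0 <= self.prevalence_min <= 1.0):
            raise ValueError("prevalence_min must be in [0, 1]")
        if self.iv_top_k < 0:
            raise ValueError("iv_top_k must be >= 0")
        self.denylist = frozenset(self.denylist)


@dataclass
class ScreenReport:
    n_input: int = 0
    n_after_prevalence: int = 0
    n_after_denylist: int = 0
    ranked_iv_candidates: list = field(default_factory=list)

    def validate(self) -> None:
        if not (self.n_after_denylist <= self.n_after_prevalence <= self.n_input):
            raise ValueError("screen counts must be non-increasing")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(
            json.dumps(
                {
                    "n_input": self.n_input,
                    "n_after_prevalence": self.n_after_prevalence,
                    "n_after_denylist": self.n_after_denylist,
                    "ranked_iv_candidates": [
                        {"feature": f, "correlation": c, "constant": k}
                        for f, c, k in self.ranked_iv_candidates
                    ],
                },
                indent=2,
            )
        )


def prevalence_filter(
    fm: FeatureMatrix, prevalence_min: float = 0.01
) -> tuple[FeatureMatrix, dict]:
    """Drop empirically generated binary features with prevalence < cutoff.

    The inequality is strict: a feature at exactly the cutoff is retained.
    Researcher-specified and continuous columns are exempt (only
    automatically generated code and NLP features are screened).
    """
    meta = fm.meta
    screened = meta["is_binary"] & ~meta["source"].isin(_EXEMPT_SOURCES)
    keep = (~screened | (meta["prevalence"] >= prevalence_min)).to_numpy()
    report = {"n_input": fm.n_features, "n_after_prevalence": int(keep.sum())}
    return fm.select(keep), report


def marginal_treatment_correlation(fm: FeatureMatrix, A: np.ndarray) -> pd.DataFrame:
    """Pearson correlation of each feature with the treatment indicator.

    For two binaries this is the phi coefficient; for continuous features
    it is the point-biserial correlation (the same Pearson formula).
    Constant features get correlation 0 and are flagged.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[0] != fm.n_patients:
        raise ValueError("A must align with the feature matrix rows")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("A must be binary")
    n = len(A)
    X = fm.values
    mean_x = np.asarray(X.mean(axis=0)).ravel()
    ex2 = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var_x = np.maximum(ex2 - mean_x**2, 0.0)
    mean_a = A.mean()
    var_a = mean_a * (1 - mean_a)
    cov = np.asarray((A @ X)).ravel() / n - mean_x * mean_a
    constant = (var_x <= 1e-300) | (var_a <= 1e-300)
    denom = np.sqrt(np.where(constant, 1.0, var_x * var_a))
    corr = np.where(constant, 0.0, cov / denom)
    return pd.DataFrame(
        {"feature": fm.names, "correlation": corr, "constant": constant}
    )


def rank_iv_candidates(fm: FeatureMatrix, A: np.ndarray, top_k: int) -> pd.DataFrame:
    """Top treatment-associated features for instrumental-variable review.

    Ordered by descending absolute marginal correlation with treatment,
    ties broken by feature name; the analyst (or a truth-derived denylist
    in simulations) decides which of these are instruments to exclude.
    """
    df = marginal_treatment_correlation(fm, A)
    df["abs_corr"] = df["correlation"].abs()
    df = df.sort_values(["abs_corr", "feature"], ascending=[False, True], kind="mergesort")
    return df.drop(columns="abs_corr").head(top_k).reset_index(drop=True)


def apply_denylist(fm: FeatureMatrix, denylist) -> FeatureMatrix:
    """Remove named columns; unknown names are ignored with a warning."""
    denylist = set(denylist)
    if not denylist:
        return fm
    present = set(fm.names)
    unknown = denylist - present
    if unknown:
        logger.warning("denylist names not in feature matrix (ignored): %s",
                       sorted(unknown)[:10])
    keep = ~fm.meta["name"].isin(denylist).to_numpy()
    return fm.select(keep)


def screen_features(
    fm: FeatureMatrix, config: ScreenConfig, A: np.ndarray | None = None
) -> tuple[FeatureMatrix, ScreenReport]:
    """Full screen: prevalence filter, IV ranking (if A given), denylist."""
    filtered, frag = prevalence_filter(fm, config.prevalence_min)
    ranked: list = []
    if A is not None and config.iv_top_k > 0:
        df = rank_iv_candidates(filtered, A, config.iv_top_k)
        ranked = list(df.itertuples(index=False, name=None))
    final = apply_denylist(filtered, config.denylist)
    report = ScreenReport(
        n_input=frag["n_input"],
        n_after_prevalence=frag["n_after_prevalence"],
        n_after_denylist=final.n_features,
        ranked_iv_candidates=ranked,
    )
    report.validate()
    return final, report
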