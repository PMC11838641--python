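"""PS weighting schemes, covariate balance, and weighted Cox estimation.

Three weighting schemes turn a propensity score ``ps`` and binary
treatment ``A`` into per-patient weights:

* IPTW:      w = A/ps + (1-A)/(1-ps)            (targets the full cohort)
* overlap:   w = A(1-ps) + (1-A)ps              (emphasizes equipoise)
* matching:  w = A min(ps,1-ps)/ps + (1-A) min(ps,1-ps)/(1-ps)

Balance is summarized by absolute standardized differences — the
between-arm difference in (weighted) prevalence or mean divided by the
square root of the average of the two arms' variances — with 0.1 as the
conventional adequacy flag (a reporting threshold, never a filter).

The treatment effect is the hazard ratio from a weighted Cox partial
likelihood with the treatment indicator as sole covariate, Breslow tie
handling, Newton-maximized to gradient tolerance 1e-9, with a robust
(Lin-Wei sandwich) variance that treats the weights as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import FeatureMatrix

__all__ = [
    "WEIGHT_SCHEMES",
    "WeightVector",
    "compute_weights",
    "standardized_difference",
    "BalanceTable",
    "balance_table",
    "EffectEstimate",
    "weighted_cox",
]

WEIGHT_SCHEMES = ("iptw", "overlap", "matching")

_Z95 = 1.96  # conventional normal quantile for the 95% CI


@dataclass
class WeightVector:
    scheme: str
    w: np.ndarray

    def __post_init__(self):
        if self.scheme not in WEIGHT_SCHEMES:
            raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}")
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or (self.w < 0).any():
            raise ValueError("weights must be finite and nonnegative")


def compute_weights(ps: np.ndarray, A: np.ndarray, scheme: str) -> WeightVector:
    """Exact per-patient evaluation of the chosen weighting formula."""
    ps = np.asarray(ps, dtype=float)
    A = np.asarray(A, dtype=float)
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("A must be binary")
    if (ps <= 0).any() or (ps >= 1).any():
        raise ValueError("ps must lie strictly in (0, 1); clip upstream")
    if scheme == "iptw":
        w = A / ps + (1 - A) / (1 - ps)
    elif scheme == "overlap":
        w = A * (1 - ps) + (1 - A) * ps
    elif scheme == "matching":
        m = np.minimum(ps, 1 - ps)
        w = A * m / ps + (1 - A) * m / (1 - ps)
    else:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}")
    return WeightVector(scheme=scheme, w=w)


# ---------------------------------------------------------------------------
# standardized differences
# ---------------------------------------------------------------------------


def _weighted_moments(x, w):
    sw = w.sum()
    m = float(np.dot(w, x) / sw)
    v = float(np.dot(w, (x - m) ** 2) / sw)
    return m, v


def standardized_difference(
    x: np.ndarray,
    A: np.ndarray,
    w: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Absolute standardized difference of one covariate between arms.

    ``d = |m1 - m0| / sqrt((v1 + v0) / 2)`` with weighted arm means and
    variances (for a binary covariate, v = p(1-p) of the weighted
    prevalence).  The unweighted quantity is the ``w = 1`` special case.
    A zero pooled variance gives 0 when the means agree and +inf
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    A = np.asarray(A, dtype=int)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    stats = []
    for arm in (1, 0):
        mask = A == arm
        if not mask.any() or w[mask].sum() <= 0:
            raise ValueError("both arms must have positive weight")
        m, v = _weighted_moments(x[mask], w[mask])
        if binary or (binary is None and np.isin(x, (0.0, 1.0)).all()):
            v = m * (1 - m)
        stats.append((m, v))
    (m1, v1), (m0, v0) = stats
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        return 0.0 if np.isclose(m1, m0) else float("inf")
    return float(abs(m1 - m0) / np.sqrt(pooled))


@dataclass
class BalanceTable:
    """Per-feature balance before/after weighting, with candidate flags."""

    table: pd.DataFrame  # feature, source, candidate, sd_unweighted, sd_weighted
    threshold: float = 0.1

    def summary(self) -> dict:
        t = self.table
        viol = t["sd_weighted"] >= self.threshold
        return {
            "n_features": len(t),
            "n_candidate": int(t["candidate"].sum()),
            "candidate_ge_threshold": int((viol & t["candidate"]).sum()),
            "noncandidate_ge_threshold": int((viol & ~t["candidate"]).sum()),
            "max_sd_weighted": float(t["sd_weighted"].max()) if len(t) else 0.0,
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _arm_sds(X: sp.csr_matrix, is_binary, A, w):
    moments = []
    for arm in (1, 0):
        mask = A == arm
        wa = w[mask]
        sw = wa.sum()
        if sw <= 0:
            raise ValueError("both arms must have positive weight")
        Xa = X[mask]
        m = np.asarray(wa @ Xa).ravel() / sw
        ex2 = np.asarray(wa @ Xa.multiply(Xa)).ravel() / sw
        v = np.maximum(ex2 - m**2, 0.0)
        v = np.where(is_binary, m * (1 - m), v)
        moments.append((m, v))
    (m1, v1), (m0, v0) = moments
    pooled = (v1 + v0) / 2.0
    diff = np.abs(m1 - m0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / np.sqrt(pooled)
    d = np.where(pooled <= 0, np.where(np.isclose(m1, m0), 0.0, np.inf), d)
    return d


def balance_table(
    fm_all: FeatureMatrix,
    candidate_mask: np.ndarray,
    A: np.ndarray,
    w: np.ndarray,
    threshold: float = 0.1,
) -> BalanceTable:
    """Standardized differences for every feature, candidate or not.

    ``fm_all`` should hold the union of all covariate sets so that
    balance can be assessed on features a given PS model could not see
    (the non-candidate assessment); ``candidate_mask`` flags the columns
    that were available to the model that produced ``w``.
    """
    A = np.asarray(A, dtype=int)
    w = np.asarray(w, dtype=float)
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if len(candidate_mask) != fm_all.n_features:
        raise ValueError("candidate_mask must align with fm_all columns")
    is_binary = fm_all.meta["is_binary"].to_numpy()
    sd_un = _arm_sds(fm_all.values, is_binary, A, np.ones_like(w))
    sd_w = _arm_sds(fm_all.values, is_binary, A, w)
    table = pd.DataFrame(
        {
            "feature": fm_all.names,
            "source": fm_all.meta["source"].to_numpy(),
            "candidate": candidate_mask,
            "sd_unweighted": sd_un,
            "sd_weighted": sd_w,
        }
    )
    return BalanceTable(table=table, threshold=threshold)


# ---------------------------------------------------------------------------
# weighted Cox regression (single treatment covariate)
# ---------------------------------------------------------------------------


@dataclass
class EffectEstimate:
    log_hr: float
    se_robust: float
    hr: float
    ci_low: float
    ci_high: float
    n_events: int
    model_id: int | None = None
    scheme: str | None = None

    def validate(self) -> None:
        if self.se_robust <= 0:
            raise ValueError("se_robust must be positive")
        if not (self.ci_low < self.hr < self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def _cox_sums(order_t, order_x, order_w, beta, risk_start):
    """S0, S1 over each subject's Breslow risk set (sorted ascending)."""
    r = order_w * np.exp(beta * order_x)
    rc0 = np.cumsum(r[::-1])[::-1]
    rc1 = np.cumsum((r * order_x)[::-1])[::-1]
    rc2 = np.cumsum((r * order_x**2)[::-1])[::-1]
    return rc0[risk_start], rc1[risk_start], rc2[risk_start]


def weighted_cox(
    time: np.ndarray,
    event: np.ndarray,
    A: np.ndarray,
    w: np.ndarray,
    model_id: int | None = None,
    scheme: str | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> EffectEstimate:
    """Weighted Cox hazard-ratio estimate with robust 95% CI.

    Single-covariate (treatment) partial likelihood with per-patient
    weights, Breslow tie handling, Newton iterations to gradient
    tolerance ``tol``, and Lin-Wei sandwich variance treating the weights
    as fixed.  Raises on negative weights and on non-identifiable fits
    (no events in one arm, so the likelihood is monotone in beta).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(A, dtype=float)
    w = np.asarray(w, dtype=float)
    if (time <= 0).any():
        raise ValueError("time must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be binary")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    for arm in (0, 1):
        mask = (x == arm) & (event == 1) & (w > 0)
        if not mask.any():
            raise ValueError(
                "non-identifiable: no (positively weighted) events in one arm; "
                "the partial likelihood is monotone in beta"
            )

    order = np.argsort(time, kind="mergesort")
    t, d, xo, wo = time[order], event[order], x[order], w[order]
    # Breslow: risk set of subject i is everyone with t_j >= t_i; with ties,
    # all tied subjects share the risk set starting at the tie group head.
    risk_start = np.searchsorted(t, t, side="left")
    ev = d == 1

    def score_info(beta):
        s0, s1, s2 = _cox_sums(t, xo, wo, beta, risk_start)
        xbar = s1 / s0
        U = np.sum(wo[ev] * (xo[ev] - xbar[ev]))
        I = np.sum(wo[ev] * (s2[ev] / s0[ev] - xbar[ev] ** 2))
        ll = np.sum(wo[ev] * (beta * xo[ev] - np.log(s0[ev])))
        return U, I, ll, s0, xbar

    beta = 0.0
    U, I, ll, s0, xbar = score_info(beta)
    for _ in range(max_iter):
        if abs(U) < tol:
            break
        if I <= 0:
            raise ValueError("non-identifiable weighted Cox fit (zero information)")
        step = U / I
        if abs(step) < 1e-13:  # at the floating-point resolution of beta
            break
        # step-halving safeguard
        new_beta = beta + step
        for _ in range(30):
            U2, I2, ll2, s0_2, xbar_2 = score_info(new_beta)
            if ll2 >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta, U, I, ll, s0, xbar = new_beta, U2, I2, ll2, s0_2, xbar_2
    else:
        # gradient tolerance is absolute; accept if the relative score is
        # at numerical noise level for the problem scale
        if abs(U) >= tol * max(1.0, abs(ll)):
            raise RuntimeError("weighted Cox Newton iteration failed to converge")

    # Lin-Wei robust sandwich with fixed weights: V = (sum r_i^2) / I^2,
    # r_i = d_i w_i (x_i - xbar(t_i)) - w_i e^{b x_i} *
    #       sum_{events t_e <= t_i} [w_e (x_i - xbar(t_e)) / S0(t_e)]
    a = np.where(ev, wo / s0, 0.0)
    G = np.cumsum(a)  # sum of w_e/S0 over event times <= t_i (same order)
    H = np.cumsum(a * xbar)
    # ties: all subjects tied at t share the same cumulative sums; take the
    # value at the end of each tie group
    tie_end = np.searchsorted(t, t, side="right") - 1
    G, H = G[tie_end], H[tie_end]
    r = np.where(ev, wo * (xo - xbar), 0.0) - wo * np.exp(beta * xo) * (xo * G - H)
    var = float(np.sum(r**2) / I**2)
    se = float(np.sqrt(var))

    est = EffectEstimate(
        log_hr=float(beta),
        se_robust=se,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        n_events=int(event.sum()),
        model_id=model_id,
        scheme=scheme,
    )
    est.validate()
    return est
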