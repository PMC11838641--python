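"""End-to-end experiment orchestration.

Runs the full proxy-adjustment experiment on a generated (or ingested)
cohort: assemble the candidate feature matrix for the union of requested
covariate sets, screen it (prevalence filter, optional IV denylist), fit
one cross-fitted LASSO propensity model per covariate set, apply the
requested weighting schemes, and emit a Table-2-style grid of weighted
Cox hazard-ratio estimates with per-cell balance summaries, plus the
unadjusted estimate as baseline (computed with unit weights through the
same weighted-Cox code path).

A single master seed deterministically fans out into per-stage seeds
(cohort generation, fold assignment, embedding, clustering) via a hashed
counter scheme, so any stage can be re-run in isolation and the whole run
is reproducible from (config, seed).  Stage failures are recorded per
grid cell and do not abort the remaining cells.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effects import (
    WEIGHT_SCHEMES,
    BalanceTable,
    EffectEstimate,
    balance_table,
    compute_weights,
    weighted_cox,
)
from .features import Lexicon, build_feature_matrix
from .propensity import COVARIATE_SETS, PropensityFit, crossfit_lasso_ps
from .screening import ScreenConfig, ScreenReport, screen_features
from .simulate import Cohort, SimConfig, generate_cohort, read_cohort

__all__ = ["RunConfig", "RunReport", "run_experiment", "replicate_experiment", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2b(f"{master}\x00{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one experiment run (YAML/JSON serializable)."""

    sim: SimConfig | None = None
    cohort_dir: str | None = None
    model_ids: tuple[int, ...] = tuple(COVARIATE_SETS)
    schemes: tuple[str, ...] = WEIGHT_SCHEMES
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_folds: int = 10
    embed_dim: int = 32
    k_clusters: int = 100
    ngram_max: int = 2
    lexicon_path: str | None = None
    denylist_from_truth: bool = False
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.model_ids = tuple(int(m) for m in self.model_ids)
        self.schemes = tuple(self.schemes)
        if not self.model_ids or not self.schemes:
            raise ValueError("at least one model and one scheme are required")
        bad = [m for m in self.model_ids if m not in COVARIATE_SETS]
        if bad:
            raise ValueError(f"unknown model ids {bad}; valid: {sorted(COVARIATE_SETS)}")
        bad = [s for s in self.schemes if s not in WEIGHT_SCHEMES]
        if bad:
            raise ValueError(f"unknown schemes {bad}; valid: {WEIGHT_SCHEMES}")
        if self.sim is None and self.cohort_dir is None:
            raise ValueError("either sim or cohort_dir must be given")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        d["screen"] = {
            "prevalence_min": self.screen.prevalence_min,
            "iv_top_k": self.screen.iv_top_k,
            "denylist": sorted(self.screen.denylist),
        }
        d["model_ids"] = list(self.model_ids)
        d["schemes"] = list(self.schemes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        if "screen" in d and not isinstance(d["screen"], ScreenConfig):
            s = dict(d["screen"])
            s["denylist"] = frozenset(s.get("denylist", ()))
            d["screen"] = ScreenConfig(**s)
        for key in ("model_ids", "schemes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one experiment run produced."""

    unadjusted: EffectEstimate
    effects: dict  # (model_id, scheme) -> EffectEstimate
    balance: dict  # (model_id, scheme) -> BalanceTable
    ps_fits: dict  # model_id -> PropensityFit
    screen_report: ScreenReport
    failures: dict  # (model_id, scheme) or model_id -> error string
    provenance: dict
    cohort_summary: dict

    def effects_frame(self) -> pd.DataFrame:
        """Table-2-analog grid: one row per (model, scheme) plus unadjusted."""
        rows = [
            {
                "model": "unadjusted",
                "scheme": "none",
                "n_candidate": None,
                "n_selected": None,
                "auc": None,
                "nll": None,
                "hr": self.unadjusted.hr,
                "ci_low": self.unadjusted.ci_low,
                "ci_high": self.unadjusted.ci_high,
                "log_hr": self.unadjusted.log_hr,
                "se_robust": self.unadjusted.se_robust,
            }
        ]
        for (m, s), est in sorted(self.effects.items()):
            fit = self.ps_fits[m]
            rows.append(
                {
                    "model": m,
                    "scheme": s,
                    "n_candidate": fit.n_candidate,
                    "n_selected": fit.n_selected,
                    "auc": fit.auc,
                    "nll": fit.nll,
                    "hr": est.hr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "log_hr": est.log_hr,
                    "se_robust": est.se_robust,
                }
            )
        return pd.DataFrame(rows)


def _load_cohort(config: RunConfig):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "cohort"))
        return generate_cohort(sim)
    return read_cohort(config.cohort_dir), None


def run_experiment(config: RunConfig, cohort: Cohort | None = None, truth=None) -> RunReport:
    """Execute the full pipeline for one cohort; see module docstring.

    A pre-generated ``cohort`` (with optional truth) may be supplied to
    skip generation, e.g. inside replicate loops.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = _time.time()
    timings: dict[str, float] = {}

    def _mark(stage: str, since: float) -> float:
        now = _time.time()
        timings[stage] = round(now - since, 3)
        logger.info("stage %-10s %.3fs", stage, now - since)
        return now

    if cohort is None:
        cohort, truth = _load_cohort(config)
    cohort.validate()
    t = _mark("cohort", t0)
    A = cohort.A

    needed_sources: list[str] = []
    for m in config.model_ids:
        for s in COVARIATE_SETS[m]:
            if s not in needed_sources:
                needed_sources.append(s)

    lexicon = None
    if "lexicon" in needed_sources:
        if config.lexicon_path is not None:
            lexicon = Lexicon.from_csv(config.lexicon_path)
        else:
            lexicon = _default_sim_lexicon(cohort)

    fm = build_feature_matrix(
        cohort,
        needed_sources,
        lexicon=lexicon,
        embed_dim=config.embed_dim,
        embed_seed=derive_seed(config.seed, "embed"),
        k=config.k_clusters,
        cluster_seed=derive_seed(config.seed, "clusters"),
        ngram_max=config.ngram_max,
    )
    t = _mark("features", t)

    screen_cfg = config.screen
    if config.denylist_from_truth and truth is not None:
        denied = frozenset(f"clm:{c}" for c in truth.iv_feature_ids)
        screen_cfg = ScreenConfig(
            prevalence_min=screen_cfg.prevalence_min,
            iv_top_k=screen_cfg.iv_top_k,
            denylist=screen_cfg.denylist | denied,
        )
    fm_screened, screen_report = screen_features(fm, screen_cfg, A)
    t = _mark("screen", t)

    unadjusted = weighted_cox(
        cohort.time_days, cohort.event, A, np.ones(cohort.n), scheme="none"
    )

    ps_fits: dict = {}
    effects: dict = {}
    balance: dict = {}
    failures: dict = {}
    fold_seed = derive_seed(config.seed, "folds")
    for m in config.model_ids:
        sources = set(COVARIATE_SETS[m])
        sub = fm_screened.select_sources(sources)
        try:
            fit = crossfit_lasso_ps(
                sub, A, n_folds=config.n_folds, seed=fold_seed, model_id=m
            )
        except Exception as exc:  # per-cell isolation
            logger.warning("PS fit failed for model %s: %s", m, exc)
            failures[m] = str(exc)
            continue
        ps_fits[m] = fit
        candidate_mask = fm_screened.meta["source"].isin(sources).to_numpy()
        for scheme in config.schemes:
            try:
                wv = compute_weights(fit.ps, A, scheme)
                effects[(m, scheme)] = weighted_cox(
                    cohort.time_days, cohort.event, A, wv.w, model_id=m, scheme=scheme
                )
                balance[(m, scheme)] = balance_table(fm_screened, candidate_mask, A, wv.w)
            except Exception as exc:
                logger.warning("cell (%s, %s) failed: %s", m, scheme, exc)
                failures[(m, scheme)] = str(exc)
        t = _mark(f"model_{m}", t)

    from .simulate import summarize_cohort

    report = RunReport(
        unadjusted=unadjusted,
        effects=effects,
        balance=balance,
        ps_fits=ps_fits,
        screen_report=screen_report,
        failures=failures,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "elapsed_s": round(_time.time() - t0, 3),
            "stage_timings_s": timings,
        },
        cohort_summary=summarize_cohort(cohort),
    )
    if config.out_dir:
        _write_artifacts(report, cohort, Path(config.out_dir))
    return report


def _default_sim_lexicon(cohort) -> Lexicon:
    """Synthetic stand-in lexicon for generated cohorts: every observed
    content token is a single-token term mapping to its own concept."""
    tokens = sorted(
        {
            t
            for docs in cohort.notes
            for _, toks in docs
            for t in toks
            if t[0] == "w" and t[1:].isdigit()
        }
    )
    if not tokens:
        tokens = ["w0000"]
    return Lexicon({(t,): f"concept_{t}" for t in tokens})


def _write_artifacts(report: RunReport, cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.effects_frame().to_csv(out_dir / "effects.csv", index=False)
    report.screen_report.to_json(out_dir / "screen_report.json")
    if report.screen_report.ranked_iv_candidates:
        pd.DataFrame(
            report.screen_report.ranked_iv_candidates,
            columns=["feature", "correlation", "constant"],
        ).to_csv(out_dir / "iv_candidates.csv", index=False)
    for m, fit in report.ps_fits.items():
        fit.save(out_dir / f"ps_model{m}", cohort.patients["patient_id"])
    for (m, s), bt in report.balance.items():
        bt.to_csv(out_dir / f"balance_model{m}_{s}.csv")
    lines = [f"config_hash {report.provenance['config_hash']}"]
    lines += [
        f"{stage:<12} {secs:8.3f}s"
        for stage, secs in report.provenance["stage_timings_s"].items()
    ]
    lines.append(f"total        {report.provenance['elapsed_s']:8.3f}s")
    (out_dir / "run.log").write_text("\n".join(lines) + "\n")
    (out_dir / "run.json").write_text(
        json.dumps(
            {
                "provenance": report.provenance,
                "cohort_summary": report.cohort_summary,
                "failures": {str(k): v for k, v in report.failures.items()},
                "balance_summaries": {
                    f"{m}_{s}": bt.summary() for (m, s), bt in report.balance.items()
                },
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Monte-Carlo replication harness
# ---------------------------------------------------------------------------


def replicate_experiment(
    config: RunConfig, n_reps: int, base_seed: int = 0
) -> dict:
    """Repeat ``run_experiment`` over independent seeds and summarize.

    Per (model, scheme) cell: mean log HR, empirical SE, CI coverage of
    the true effect, mean AUC/NLL, and balance-violation rates (fraction
    of replicates with any weighted SD >= threshold, split by candidate
    status).  Requires a simulation config (the truth defines coverage).
    Failed replicates are dropped and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if config.sim is None:
        raise ValueError("replicate_experiment requires a simulation config")
    beta_true = config.sim.beta_true
    records: list[dict] = []
    n_failed = 0
    for rep in range(n_reps):
        rep_cfg = dataclasses.replace(
            config, seed=derive_seed(base_seed, f"rep{rep}"), out_dir=None
        )
        try:
            report = run_experiment(rep_cfg)
        except Exception as exc:
            logger.warning("replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        rec = {
            "rep": rep,
            "unadj_log_hr": report.unadjusted.log_hr,
        }
        for (m, s), est in report.effects.items():
            bt = report.balance[(m, s)]
            summ = bt.summary()
            rec[f"log_hr_{m}_{s}"] = est.log_hr
            rec[f"cover_{m}_{s}"] = float(
                est.ci_low <= np.exp(beta_true) <= est.ci_high
            )
            rec[f"auc_{m}"] = report.ps_fits[m].auc
            rec[f"nll_{m}"] = report.ps_fits[m].nll
            rec[f"cand_viol_{m}_{s}"] = summ["candidate_ge_threshold"]
            rec[f"any_viol_{m}_{s}"] = float(
                summ["candidate_ge_threshold"] + summ["noncandidate_ge_threshold"] > 0
            )
        records.append(rec)
    if not records:
        raise RuntimeError("all replicates failed")
    df = pd.DataFrame(records)
    summary: dict = {
        "n_reps": len(df),
        "n_failed": n_failed,
        "beta_true": beta_true,
        "mean_unadj_log_hr": float(df["unadj_log_hr"].mean()),
        "mc_se_unadj_log_hr": float(df["unadj_log_hr"].std(ddof=1) / np.sqrt(len(df)))
        if len(df) > 1
        else float("nan"),
        "cells": {},
        "records": df,
    }
    for m in config.model_ids:
        for s in config.schemes:
            key = f"{m}_{s}"
            col = f"log_hr_{m}_{s}"
            if col not in df:
                continue
            vals = df[col]
            summary["cells"][key] = {
                "mean_log_hr": float(vals.mean()),
                "mean_abs_bias": float((vals - beta_true).abs().mean()),
                "empirical_se": float(vals.std(ddof=1)) if len(df) > 1 else float("nan"),
                "coverage": float(df[f"cover_{m}_{s}"].mean()),
                "mean_auc": float(df[f"auc_{m}"].mean()),
                "mean_nll": float(df[f"nll_{m}"].mean()),
                "frac_reps_any_violation": float(df[f"any_viol_{m}_{s}"].mean()),
            }
    return summary
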