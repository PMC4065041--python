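"""Replication-stage association under an additive covariate-adjusted model.

Candidate variant-phenotype pairs from the discovery stage are re-tested
in an independent cohort: cases are subjects with at least one code in
the phenotype's groups, controls those with none; European- and
African-ancestry subjects are analyzed separately; phenotypes with fewer
than 50 cases are skipped; the model is logistic with the minor-allele
dosage (0/1/2) entered additively, adjusting for age, sex and the first
principal components of ancestry.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import Cohort
from .phenome import PhenotypeDef

__all__ = [
    "ReplicationConfig",
    "LogisticFit",
    "ReplicationResult",
    "define_replication_phenotype",
    "fit_additive_logistic",
    "run_replication",
]

log = logging.getLogger(__name__)

# |log-OR| beyond this (OR > ~3x10^6) is treated as (quasi-)separation
_SEPARATION_LOGOR = 15.0


@dataclass(frozen=True)
class ReplicationConfig:
    min_cases: int = 50
    n_pcs: int = 3
    adjust_age_sex: bool = True
    alpha: float = 0.05
    age_min: float | None = 30.0  # replication cohorts restricted to adults
    test: str = "wald"  # or "lrt"

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.test not in ("wald", "lrt"):
            raise ValueError("test must be 'wald' or 'lrt'")


def define_replication_phenotype(cohort: Cohort, pdef: PhenotypeDef) -> pd.Series:
    """Case/control labels: case iff >= 1 group of the definition, control
    iff none.  Age restrictions are left to the cohort-level filter."""
    unknown = pdef.groups - set(cohort.diagnoses.columns)
    if unknown:
        raise ValueError(f"phenotype {pdef.name!r} references unknown groups: {sorted(unknown)}")
    return cohort.diagnoses[list(pdef.groups)].any(axis=1).rename(pdef.name)


@dataclass(frozen=True)
class LogisticFit:
    """Per-allele effect from a maximum-likelihood logistic fit."""

    log_or: float
    se: float
    p: float
    ci: tuple[float, float]
    n: int
    converged: bool
    separation: bool

    @property
    def or_per_allele(self) -> float:
        return math.exp(self.log_or)


def fit_additive_logistic(
    labels: pd.Series | np.ndarray,
    dosages: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    test: str = "wald",
) -> LogisticFit:
    """Logistic regression of case status on minor-allele dosage.

    Fit by Newton-type iteratively reweighted least squares; convergence
    declared when the score vanishes (tol 1e-8, <= 100 iterations).
    Complete or quasi-complete separation is detected (divergent dosage
    coefficient or failed convergence) and flagged rather than reported
    as a finite effect.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(dosages, dtype=float)
    keep = ~np.isnan(x)
    y, x = y[keep], x[keep]
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)[keep]
        X = np.column_stack([np.ones_like(x), x, c])
    else:
        X = np.column_stack([np.ones_like(x), x])
    n = len(y)
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("need at least one case and one control")
    if np.nanvar(x) == 0:
        raise ValueError("dosage has zero variance")

    nan = LogisticFit(math.nan, math.nan, math.nan, (math.nan, math.nan), n, False, True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, X)
            fit = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except Exception:  # PerfectSeparationError or singular Hessian
            return nan
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not fit.mle_retvals.get("converged", False) or not np.isfinite(se) or abs(beta) > _SEPARATION_LOGOR:
        return nan

    if test == "lrt":
        X0 = np.delete(X, 1, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.Logit(y, X0).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        from scipy.stats import chi2

        lr = 2.0 * (fit.llf - fit0.llf)
        p = float(chi2.sf(max(lr, 0.0), df=1))
    else:
        p = float(2.0 * norm.sf(abs(beta / se)))
    zcrit = norm.ppf(0.975)
    return LogisticFit(beta, se, p, (beta - zcrit * se, beta + zcrit * se), n, True, False)


@dataclass(frozen=True)
class ReplicationResult:
    variant: str
    phenotype: str
    ancestry: str
    n_cases: int
    n_controls: int
    fit: LogisticFit | None
    status: str  # replicated | not_replicated | skipped_min_cases | separation

    @property
    def or_per_allele(self) -> float:
        return self.fit.or_per_allele if self.fit is not None else math.nan


def _design_covariates(cohort: Cohort, idx: pd.Index, config: ReplicationConfig) -> np.ndarray | None:
    cols = []
    if config.adjust_age_sex:
        demo = cohort.demographics.loc[idx]
        cols.append(demo["age"].to_numpy(dtype=float))
        cols.append((demo["sex"] == "F").to_numpy(dtype=float))
    if config.n_pcs > 0:
        if cohort.pcs is None:
            raise ValueError("replication cohort carries no principal components")
        pcs = cohort.pcs.loc[idx].iloc[:, : config.n_pcs]
        cols.extend(pcs[c].to_numpy(dtype=float) for c in pcs.columns)
    return np.column_stack(cols) if cols else None


def run_replication(
    cohort: Cohort,
    tests: list[tuple[str, PhenotypeDef]],
    config: ReplicationConfig | None = None,
) -> list[ReplicationResult]:
    """Per-ancestry additive replication of discovery candidates.

    EA and AA subjects are analyzed separately and never pooled.
    Phenotypes with fewer than ``min_cases`` cases in an ancestry stratum
    are reported as skipped, with no estimates attached.
    """
    config = config or ReplicationConfig()
    out: list[ReplicationResult] = []
    for ancestry in ("EA", "AA"):
        mask = (cohort.demographics["ancestry"] == ancestry).to_numpy()
        if config.age_min is not None:
            mask &= (cohort.demographics["age"] > config.age_min).to_numpy()
        idx = cohort.subject_ids[mask]
        sub_diag = cohort.diagnoses.loc[idx]
        for variant, pdef in tests:
            labels = sub_diag[list(pdef.groups)].any(axis=1)
            n_cases = int(labels.sum())
            n_controls = int(len(labels) - n_cases)
            if n_cases < config.min_cases:
                out.append(
                    ReplicationResult(variant, pdef.name, ancestry, n_cases, n_controls, None, "skipped_min_cases")
                )
                continue
            dosage = cohort.genotypes.loc[idx, variant]
            called = dosage.notna()
            if called.sum() == 0 or dosage[called].var() == 0 or labels[called].nunique() == 1:
                out.append(
                    ReplicationResult(variant, pdef.name, ancestry, n_cases, n_controls, None, "separation")
                )
                continue
            cov = _design_covariates(cohort, idx, config)
            fit = fit_additive_logistic(labels.to_numpy(), dosage.to_numpy(), cov, test=config.test)
            if fit.separation:
                status = "separation"
            elif fit.p < config.alpha:
                status = "replicated"
            else:
                status = "not_replicated"
            out.append(ReplicationResult(variant, pdef.name, ancestry, n_cases, n_controls, fit, status))
    return out


def replication_results_frame(results: list[ReplicationResult]) -> pd.DataFrame:
    recs = []
    for r in results:
        fit = r.fit
        recs.append(
            {
                "variant": r.variant,
                "phenotype": r.phenotype,
                "ancestry": r.ancestry,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "or_per_allele": fit.or_per_allele if fit else math.nan,
                "ci_low": math.exp(fit.ci[0]) if fit else math.nan,
                "ci_high": math.exp(fit.ci[1]) if fit else math.nan,
                "p": fit.p if fit else math.nan,
                "status": r.status,
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "variant", "phenotype", "ancestry", "n_cases", "n_controls",
            "or_per_allele", "ci_low", "ci_high", "p", "status",
        ],
    )
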