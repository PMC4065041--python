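"""Matched-control association testing.

Candidates surviving the knowledge filter are re-tested against a random
sample of common-allele homozygotes individually matched to the
minor-allele homozygotes on age stratum (0-4, 5-19, 20-44, 45-59, 60+
years), sex, ancestry and sub-cohort.  The control count comes from a
two-proportion power calculation (detect 30% vs 10% disease prevalence
with 25 cases at alpha 0.05 and 80% power), clamped to the 800-1,800
range.  Inference on the resulting 2x2 table is exact and conditional
(see :mod:`revphewas.exact2x2`); matching covariates are balanced by
design rather than modelled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .exact2x2 import Exact2x2Result, exact_2x2_inference, fisher_exact_batch
from .phenome import PhenotypeDef, evaluate_phenotype

__all__ = [
    "PowerSpec",
    "MatchSpec",
    "MatchedSet",
    "ExactAssoc",
    "required_controls",
    "match_controls",
    "test_candidates",
    "INFEASIBLE",
]

log = logging.getLogger(__name__)

INFEASIBLE = math.inf  # sentinel: target power unreachable at any control count

_MAX_CONTROLS = 10_000_000


@dataclass(frozen=True)
class PowerSpec:
    """Design assumptions of the control-count power calculation."""

    p_case: float = 0.30
    p_control: float = 0.10
    n_cases: int = 25
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        for p in (self.p_case, self.p_control):
            if not 0 < p < 1:
                raise ValueError("proportions must be in (0, 1)")
        if not 0 < self.alpha < self.power < 1:
            raise ValueError("need 0 < alpha < power < 1")


@dataclass(frozen=True)
class MatchSpec:
    """Matching design: age-stratum bounds and the control-count range.

    Age strata are half-open: [0,5), [5,20), [20,45), [45,60), [60,inf);
    a 60-year-old falls in the top stratum.
    """

    age_bounds: tuple[float, ...] = (0.0, 5.0, 20.0, 45.0, 60.0)
    n_controls_range: tuple[int, int] = (800, 1800)

    def __post_init__(self) -> None:
        if list(self.age_bounds) != sorted(self.age_bounds) or self.age_bounds[0] != 0.0:
            raise ValueError("age bounds must be sorted and start at 0")
        lo, hi = self.n_controls_range
        if lo > hi:
            raise ValueError("control range out of order")

    def age_stratum(self, ages: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.age_bounds)[1:], ages, side="right")


def _power_normal(n0: float, spec: PowerSpec) -> float:
    """Power of the two-sided two-proportion z-test, pooled null SE."""
    n1 = spec.n_cases
    p1, p2 = spec.p_case, spec.p_control
    pbar = (n1 * p1 + n0 * p2) / (n1 + n0)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n0)
    z = norm.ppf(1 - spec.alpha / 2)
    return float(norm.cdf((abs(p1 - p2) - z * se0) / se1))


def _power_arcsine(n0: float, spec: PowerSpec) -> float:
    h = abs(2 * math.asin(math.sqrt(spec.p_case)) - 2 * math.asin(math.sqrt(spec.p_control)))
    z = norm.ppf(1 - spec.alpha / 2)
    return float(norm.cdf(h / math.sqrt(1 / spec.n_cases + 1 / n0) - z))


def _power_exact_sim(n0: int, spec: PowerSpec, rng: np.random.Generator, n_sim: int) -> float:
    a = rng.binomial(spec.n_cases, spec.p_case, size=n_sim)
    b = rng.binomial(n0, spec.p_control, size=n_sim)
    p = fisher_exact_batch(a, np.full(n_sim, spec.n_cases), b, np.full(n_sim, n0))
    return float(np.mean(p < spec.alpha))


def required_controls(
    spec: PowerSpec,
    method: str = "normal",
    seed: int = 0,
    n_sim: int = 4000,
) -> float:
    """Smallest control count reaching the target power.

    ``method``: 'normal' (pooled two-proportion z approximation),
    'arcsine' (variance-stabilized), or 'exact_sim' (Monte-Carlo power of
    the two-sided Fisher test, seeded).  Returns ``INFEASIBLE`` (inf)
    when even unlimited controls cannot reach the target, e.g. when the
    two proportions are equal.
    """
    if spec.p_case == spec.p_control:
        return INFEASIBLE
    if method == "normal":
        f = lambda n0: _power_normal(n0, spec)
    elif method == "arcsine":
        f = lambda n0: _power_arcsine(n0, spec)
    elif method == "exact_sim":
        # fresh child stream per control count: f(n0) is deterministic in
        # (seed, n0), so the bracketing search is reproducible
        f = lambda n0: _power_exact_sim(
            int(n0), spec, np.random.default_rng([seed, int(n0)]), n_sim
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    if f(_MAX_CONTROLS) < spec.power:
        return INFEASIBLE
    lo, hi = 1, 2
    while hi < _MAX_CONTROLS and f(hi) < spec.power:
        lo, hi = hi, hi * 2
    hi = min(hi, _MAX_CONTROLS)
    while lo < hi:  # first n0 with power >= target (monotone in expectation)
        mid = (lo + hi) // 2
        if f(mid) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return float(hi)


@dataclass
class MatchedSet:
    """Matched common-homozygote control sample for one variant."""

    variant: str
    control_ids: list[str]
    assignments: pd.DataFrame  # control_id, stratum columns, relaxation
    relaxations: list[str] = field(default_factory=list)

    @property
    def n_controls(self) -> int:
        return len(self.control_ids)


_FACTORS = ["age_stratum", "sex", "ancestry", "dataset"]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing to total."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def match_controls(
    cohort: Cohort,
    variant: str,
    spec: MatchSpec,
    seed: int = 0,
    n_controls: int | None = None,
) -> MatchedSet:
    """Sample common-allele homozygotes matched to the minor homozygotes.

    Controls are allocated across the case strata (age stratum x sex x
    ancestry x sub-cohort) proportionally to case counts
    (largest-remainder rounding) and sampled without replacement; every
    control matches its stratum exactly.  When a stratum's pool runs dry,
    matching is relaxed in a fixed order — drop the sub-cohort factor,
    then widen to adjacent age strata — with each relaxation recorded.
    Sex and ancestry are never relaxed.
    """
    rng = np.random.default_rng(seed)
    demo = cohort.demographics.copy()
    demo["age_stratum"] = spec.age_stratum(demo["age"].to_numpy())

    cases = demo[cohort.minor_hz_mask(variant)]
    pool = demo[cohort.common_hz_mask(variant)]
    if cases.empty:
        raise ValueError(f"variant {variant} has no minor-allele homozygotes")
    if pool.empty:
        raise ValueError(f"variant {variant} has no common-allele homozygotes")

    lo, hi = spec.n_controls_range
    target = n_controls if n_controls is not None else lo
    target = int(min(max(target, lo), hi, len(pool)))

    strata = cases.groupby(_FACTORS, observed=True).size()
    alloc = _largest_remainder(strata.to_numpy().astype(float), target)

    taken: set[str] = set()
    rows = []
    relaxations: list[str] = []
    for (key, want) in zip(strata.index, alloc):
        key = dict(zip(_FACTORS, key))
        need = int(want)
        if need == 0:
            continue
        stages = [
            ("exact", _FACTORS),
            ("no_dataset", ["age_stratum", "sex", "ancestry"]),
            ("adjacent_age", ["sex", "ancestry"]),
        ]
        for stage_name, factors in stages:
            if need <= 0:
                break
            mask = pd.Series(True, index=pool.index)
            for f in factors:
                mask &= pool[f] == key[f]
            if stage_name == "adjacent_age":
                mask &= (pool["age_stratum"] - key["age_stratum"]).abs() <= 1
            avail = [sid for sid in pool.index[mask] if sid not in taken]
            take = min(need, len(avail))
            if take > 0:
                chosen = rng.choice(avail, size=take, replace=False)
                for sid in chosen:
                    taken.add(sid)
                    rows.append({"control_id": sid, **key, "relaxation": stage_name})
                need -= take
            if stage_name != "exact" and take > 0:
                relaxations.append(f"{variant}: stratum {tuple(key.values())} relaxed to {stage_name}")
        if need > 0:
            relaxations.append(f"{variant}: stratum {tuple(key.values())} short by {need}")
    for msg in relaxations:
        log.warning("matching: %s", msg)
    assignments = pd.DataFrame(rows, columns=["control_id", *_FACTORS, "relaxation"])
    return MatchedSet(variant, assignments["control_id"].tolist(), assignments, relaxations)


@dataclass(frozen=True)
class ExactAssoc:
    """Matched-control exact association for one variant x phenotype."""

    variant: str
    phenotype: str
    a: int
    n1: int
    b: int
    n0: int
    result: Exact2x2Result

    @property
    def p(self) -> float:
        return self.result.p

    @property
    def or_point(self) -> float:
        return self.result.or_point


def test_candidates(
    cohort: Cohort,
    candidates: list[str],
    phenotype_defs: dict[str, list[PhenotypeDef]],
    match_spec: MatchSpec | None = None,
    power_spec: PowerSpec | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[list[ExactAssoc], list[str]]:
    """Matched exact association for each candidate variant x phenotype.

    Controls per variant: the power-calculation count (normal
    approximation) clamped to the matching range.  Returns all rows plus
    the retained candidates — those with at least one phenotype p <
    ``alpha``.
    """
    match_spec = match_spec or MatchSpec()
    power_spec = power_spec or PowerSpec()
    n_target = required_controls(power_spec, method="normal")
    n_target = int(n_target) if math.isfinite(n_target) else match_spec.n_controls_range[0]

    seeds = np.random.SeedSequence(seed).generate_state(max(len(candidates), 1)) % (2**31)
    rows: list[ExactAssoc] = []
    retained: list[str] = []
    for variant, s in zip(candidates, seeds):
        defs = phenotype_defs.get(variant, [])
        if not defs:
            continue
        matched = match_controls(cohort, variant, match_spec, seed=int(s), n_controls=n_target)
        case_mask = cohort.minor_hz_mask(variant)
        case_ids = cohort.subject_ids[case_mask]
        any_sig = False
        for pdef in defs:
            indicator = evaluate_phenotype(cohort, pdef)
            a = int(indicator.loc[case_ids].sum())
            n1 = len(case_ids)
            b = int(indicator.loc[matched.control_ids].sum())
            n0 = matched.n_controls
            res = exact_2x2_inference(a, n1, b, n0)
            rows.append(ExactAssoc(variant, pdef.name, a, n1, b, n0, res))
            if math.isfinite(res.p) and res.p < alpha:
                any_sig = True
        if any_sig:
            retained.append(variant)
    return rows, retained


def assoc_results_frame(rows: list[ExactAssoc]) -> pd.DataFrame:
    """Tabular view mirroring the matched-association report columns."""
    recs = []
    for r in rows:
        recs.append(
            {
                "variant": r.variant,
                "phenotype": r.phenotype,
                "total_minor_hz": r.n1,
                "affected_minor_hz": r.a,
                "total_common_hz": r.n0,
                "affected_common_hz": r.b,
                "or": r.result.or_point,
                "or_method": r.result.or_method,
                "ci_low": r.result.ci_low,
                "ci_high": r.result.ci_high,
                "p": r.result.p,
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "variant", "phenotype", "total_minor_hz", "affected_minor_hz",
            "total_common_hz", "affected_common_hz", "or", "or_method",
            "ci_low", "ci_high", "p",
        ],
    )
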