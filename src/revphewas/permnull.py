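"""Genotype-permutation null for the shared-diagnosis screen.

Shuffling each variant's genotype vector across subjects (phenotypes
untouched) preserves every marginal — genotype counts, diagnosis
prevalences, comorbidity structure — while destroying genotype-phenotype
links.  Re-running the full screen on many permuted cohorts yields the
null distribution of screen yields, against which the real-data yield is
compared; in correlated EMR data, compelling-looking diagnosis clusters
arise by chance at rates this null quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .screen import ScreenConfig, ScreenResult, screen_variants

__all__ = [
    "PermutationReplicate",
    "NullComparison",
    "permute_genotype_links",
    "summarize_screen",
    "permutation_null",
    "compare_to_null",
]


@dataclass(frozen=True)
class PermutationReplicate:
    """Screen yield summary for one (real or permuted) dataset.

    ``n_bonferroni_sig`` — variants with at least one diagnosis passing a
    Bonferroni-adjusted p < alpha (denominator per the chosen mode);
    ``mean_nominal_per_variant`` — mean number of nominally significant
    diagnoses per screened variant.
    """

    seed: int
    n_bonferroni_sig: int
    mean_nominal_per_variant: float


@dataclass(frozen=True)
class NullComparison:
    real: PermutationReplicate
    null_median: float
    null_iqr: tuple[float, float]
    percentile: float
    n_replicates: int


def permute_genotype_links(cohort: Cohort, seed: int) -> Cohort:
    """Permute each variant's genotype calls (missing included) across
    subjects, independently per variant; everything else untouched."""
    rng = np.random.default_rng(seed)
    geno = cohort.genotypes.to_numpy()
    order = np.argsort(rng.random(geno.shape), axis=0)
    permuted = np.take_along_axis(geno, order, axis=0)
    genotypes = pd.DataFrame(permuted, index=cohort.subject_ids, columns=cohort.genotypes.columns)
    return Cohort(
        cohort.demographics, genotypes, cohort.diagnoses, cohort.variants, cohort.pcs
    )


def summarize_screen(
    results: list[ScreenResult],
    alpha: float = 0.05,
    bonferroni: str = "per_variant",
    seed: int = 0,
) -> PermutationReplicate:
    """Condense a screen run into the two permutation-comparison counts.

    ``bonferroni='per_variant'`` divides alpha by each variant's own
    tested-diagnosis count; ``'global'`` divides by the total number of
    tests across all variants.
    """
    if bonferroni not in ("per_variant", "global"):
        raise ValueError("bonferroni must be 'per_variant' or 'global'")
    if not results:
        return PermutationReplicate(seed, 0, 0.0)
    if bonferroni == "global":
        denom = max(1, sum(r.n_tested for r in results))
        n_sig = sum(
            1 for r in results if len(r.rows) and (r.rows["p"] < alpha / denom).any()
        )
    else:
        n_sig = sum(1 for r in results if r.bonferroni_significant(alpha))
    mean_nominal = float(np.mean([len(r.rows) for r in results]))
    return PermutationReplicate(seed, n_sig, mean_nominal)


def permutation_null(
    cohort: Cohort,
    config: ScreenConfig | None = None,
    n_replicates: int = 100,
    base_seed: int = 0,
    alpha: float = 0.05,
    bonferroni: str = "per_variant",
) -> list[PermutationReplicate]:
    """Screen ``n_replicates`` genotype-permuted copies of the cohort.

    The variant set is fixed once, from eligibility on the real data, and
    reused in every replicate: the permutation asks how the same panel of
    screened variants behaves when its genotype-phenotype links are
    broken, so eligibility is not re-derived (per-ancestry MAFs would
    otherwise drift toward the pooled mean and change the panel).
    """
    from .screen import eligible_variants

    config = config or ScreenConfig()
    panel = eligible_variants(cohort, config)
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    out = []
    for s in seeds:
        permuted = permute_genotype_links(cohort, int(s))
        results = screen_variants(permuted, config, variants=panel)
        out.append(summarize_screen(results, alpha=alpha, bonferroni=bonferroni, seed=int(s)))
    return out


def compare_to_null(
    real: PermutationReplicate, replicates: list[PermutationReplicate]
) -> NullComparison:
    """Real-data screen yield against the permutation null distribution.

    Quartiles use linear interpolation; the percentile of the real value
    is the mid-rank fraction of replicates below it.
    """
    if not replicates:
        raise ValueError("need at least one permutation replicate")
    vals = np.array([r.n_bonferroni_sig for r in replicates], dtype=float)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    x = real.n_bonferroni_sig
    pct = float((np.sum(vals < x) + 0.5 * np.sum(vals == x)) / len(vals))
    return NullComparison(real, float(med), (float(q1), float(q3)), pct, len(vals))
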