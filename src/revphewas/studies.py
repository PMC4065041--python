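"""Canned synthetic-cohort study designs.

These functions define, in one place, the simulation studies used to
validate the pipeline (and reported by ``scripts/acceptance.py``): a
null-calibration study of the genotype-permutation comparison, a
planted-signal separation study, an end-to-end funnel-recovery study,
and a replication-stage calibration study.  Tests and reporting scripts
share these definitions so the study conditions cannot drift apart.

The synthetic screens disable the cross-list frequency filter
(``list_freq_max=1.0``): that filter exists to remove rarely-used raw
EMR codes that recur across many variants' shared lists, a phenomenon of
real many-thousand-code vocabularies.  The synthetic ontology has ~100
moderately prevalent groups, so any common group — including a planted
one — sits on most lists by construction and a literal 5% cut would
empty the screen (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .assoc import test_candidates
from .knowledge import KnowledgeBase, select_candidates
from .permnull import compare_to_null, permutation_null, summarize_screen
from .phenome import PhenotypeDef
from .replicate import fit_additive_logistic
from .screen import ScreenConfig, screen_variants
from .simulate import PlantedEffect, SimConfig, simulate_cohort, simulate_knowledge_base

__all__ = [
    "SYNTHETIC_SCREEN_CONFIG",
    "null_calibration_run",
    "planted_separation_run",
    "funnel_recovery_run",
    "replication_logor_recovery",
    "replication_type1_rate",
]

SYNTHETIC_SCREEN_CONFIG = ScreenConfig(list_freq_max=1.0)

_PLANTED_RSID = "rs100010"
_PLANTED_GROUP = "G0020"


def _null_config(seed: int, planted: tuple[PlantedEffect, ...] = ()) -> SimConfig:
    """Null-calibration cohort: 2,000 subjects, 200 variants, 100 groups.

    No missing calls in the calibration study, and the planted variant's
    true MAF (0.09) sits comfortably below the 0.10 eligibility ceiling
    so its observed MAF rarely drifts across it at this cohort size.
    """
    return SimConfig(
        n_subjects=2000,
        n_variants=200,
        n_groups=100,
        planted_effects=planted,
        planted_maf=0.09,
        planted_prevalence=0.10,
        missing_rate=0.0,
        seed=seed,
    )


def null_calibration_run(seed: int, n_permutations: int = 100) -> dict:
    """Screen a null cohort and its permutation replicates.

    Under the global null the real-data count of Bonferroni-significant
    variants is exchangeable with the permuted counts, so it should fall
    inside the replicate [min, max] about (n-1)/(n+1) of the time.
    """
    cohort, _ = simulate_cohort(_null_config(seed))
    cfg = SYNTHETIC_SCREEN_CONFIG
    real = summarize_screen(screen_variants(cohort, cfg))
    reps = permutation_null(cohort, cfg, n_replicates=n_permutations, base_seed=seed + 1)
    vals = [r.n_bonferroni_sig for r in reps]
    cmp = compare_to_null(real, reps)
    return {
        "real": real.n_bonferroni_sig,
        "null_min": min(vals),
        "null_max": max(vals),
        "null_median": cmp.null_median,
        "null_iqr": cmp.null_iqr,
        "percentile": cmp.percentile,
        "contained": min(vals) <= real.n_bonferroni_sig <= max(vals),
    }


def planted_separation_run(seed: int, n_permutations: int = 100, odds_ratio: float = 20.0) -> dict:
    """Same design with one strong planted recessive effect.

    Reports whether the real-data count strictly exceeds the permutation
    maximum, and whether the planted variant itself is Bonferroni-
    significant (the permutation replicates destroy the planted link, so
    they estimate the same null as in :func:`null_calibration_run`).
    """
    eff = PlantedEffect(_PLANTED_RSID, _PLANTED_GROUP, "recessive", odds_ratio)
    cohort, _ = simulate_cohort(_null_config(seed, planted=(eff,)))
    cfg = SYNTHETIC_SCREEN_CONFIG
    results = screen_variants(cohort, cfg)
    real = summarize_screen(results)
    planted_hit = any(
        r.variant == _PLANTED_RSID and r.bonferroni_significant() for r in results
    )
    reps = permutation_null(cohort, cfg, n_replicates=n_permutations, base_seed=seed + 1)
    vals = [r.n_bonferroni_sig for r in reps]
    return {
        "real": real.n_bonferroni_sig,
        "null_max": max(vals),
        "exceeds_null_max": real.n_bonferroni_sig > max(vals),
        "planted_bonferroni_significant": planted_hit,
    }


def funnel_recovery_run(
    seed: int,
    n_subjects: int = 8500,
    odds_ratio: float = 5.0,
    maf: float = 0.08,
    prevalence: float = 0.10,
    kb_noise: float = 0.5,
) -> dict:
    """End-to-end funnel on a planted-effect cohort.

    One recessive effect (default OR 5 at MAF 0.08, baseline prevalence
    0.10) in a cohort of 8,500 subjects, 120 variants and 80 diagnosis
    groups; the knowledge base annotates every planted gene truly and
    half the decoy genes with random terms.  The funnel is screen ->
    knowledge concordance -> matched-control exact association (p<0.05).
    """
    eff = PlantedEffect(_PLANTED_RSID, _PLANTED_GROUP, "recessive", odds_ratio)
    cfg = SimConfig(
        n_subjects=n_subjects,
        n_variants=120,
        n_groups=80,
        planted_effects=(eff,),
        planted_maf=maf,
        planted_prevalence=prevalence,
        seed=seed,
    )
    cohort, truth = simulate_cohort(cfg)
    kb = KnowledgeBase(simulate_knowledge_base(truth, decoy_term_rate=kb_noise, seed=seed + 1))
    results = screen_variants(cohort, SYNTHETIC_SCREEN_CONFIG)
    gene_of = {r: cohort.gene_of(r) for r in cohort.genotypes.columns}
    concordant = select_candidates(results, gene_of, kb)
    candidates = [c.variant for c in concordant]
    defs = {
        c.variant: [
            PhenotypeDef(name=g, groups=frozenset({g}))
            for g in sorted(kb.groups_for_gene(c.gene))
        ]
        for c in concordant
    }
    _rows, retained = test_candidates(cohort, candidates, defs, seed=seed + 2)
    decoy_candidates = [v for v in candidates if v != _PLANTED_RSID]
    decoy_retained = [v for v in retained if v != _PLANTED_RSID]
    n_decoy_annotated = len(kb.genes - {truth.gene_of[_PLANTED_RSID]})
    return {
        "planted_retained": _PLANTED_RSID in retained,
        "n_candidates": len(candidates),
        "n_retained": len(retained),
        "n_decoy_candidates": len(decoy_candidates),
        "n_decoy_retained": len(decoy_retained),
        "n_decoy_annotated": n_decoy_annotated,
    }


def replication_logor_recovery(seed: int, n_subjects: int = 5000, log_or: float = 0.5) -> dict:
    """Additive logistic fit against a planted per-allele log odds ratio."""
    from .simulate import simulate_replication_cohort

    eff = PlantedEffect(_PLANTED_RSID, _PLANTED_GROUP, "additive", float(np.exp(log_or)))
    cfg = SimConfig(
        n_subjects=n_subjects,
        n_variants=40,
        n_groups=40,
        planted_effects=(eff,),
        planted_maf=0.09,
        planted_prevalence=0.10,
        missing_rate=0.0,
        seed=seed,
    )
    cohort, _ = simulate_replication_cohort(cfg, n_pcs=3)
    labels = cohort.diagnoses[_PLANTED_GROUP]
    cov = np.column_stack(
        [
            cohort.demographics["age"].to_numpy(),
            (cohort.demographics["sex"] == "F").to_numpy(float),
            cohort.pcs.to_numpy(),
        ]
    )
    fit = fit_additive_logistic(labels.to_numpy(), cohort.genotypes[_PLANTED_RSID].to_numpy(), cov)
    return {
        "log_or_hat": fit.log_or,
        "se": fit.se,
        "z_from_truth": (fit.log_or - log_or) / fit.se,
        "within_2se": abs(fit.log_or - log_or) <= 2 * fit.se,
    }


def replication_type1_rate(seed: int, n_phenotypes: int = 100, n_subjects: int = 5000) -> float:
    """Empirical type-I rate of the additive Wald test on null phenotypes."""
    cfg = SimConfig(
        n_subjects=n_subjects,
        n_variants=1,
        n_groups=n_phenotypes,
        missing_rate=0.0,
        maf_range=(0.09, 0.10),
        block_rr=1.0,  # independent phenotypes for a clean per-test rate
        seed=seed,
    )
    cohort, _ = simulate_cohort(cfg)
    rsid = cohort.genotypes.columns[0]
    dosage = cohort.genotypes[rsid].to_numpy()
    hits = 0
    for grp in cohort.diagnoses.columns:
        fit = fit_additive_logistic(cohort.diagnoses[grp].to_numpy(), dosage)
        hits += fit.p < 0.05
    return hits / n_phenotypes
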