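"""Synthetic genotype-linked EMR cohorts.

Real EMR-linked biobank data cannot be shared, so the pipeline ships a
generator that reproduces the statistical structure the analysis relies
on: Hardy–Weinberg genotypes at ancestry-specific low minor-allele
frequencies, a multi-site cohort (three sub-cohorts, two major ancestry
groups plus "other"), correlated diagnosis-group occurrence (comorbidity
blocks), missing genotype calls, and optional planted recessive or
additive genotype->phenotype effects of known odds ratio.  A paired
knowledge-base generator emulates OMIM / knock-out-mouse gene-phenotype
annotation, with decoy entries at a configurable rate.

Default scales follow the discovery cohort the pipeline was designed
around: 8,546 subjects split roughly 3,174/1,558/3,940 across three
sub-cohorts, ~69%/20%/11% EA/AA/other, age at last encounter with mean
52 and SD 18 spanning all five matching strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "simulate_knowledge_base",
    "simulate_replication_cohort",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A true genotype->diagnosis-group effect to embed in the cohort."""

    rsid: str
    group: str
    mode: str = "recessive"  # or "additive"
    odds_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("recessive", "additive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.odds_ratio <= 0:
            raise ValueError("planted odds ratio must be positive")

    def exposure(self, dosage: np.ndarray) -> np.ndarray:
        """Per-subject exposure multiplying the log-odds (0/1 or 0/1/2)."""
        if self.mode == "recessive":
            return (dosage == 2).astype(float)
        return dosage.astype(float)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``maf_range`` bounds the per-ancestry minor-allele frequencies
    (uniform draw); ``prevalence_range`` bounds per-group baseline
    prevalences (log-uniform, matching the long tail of EMR diagnosis
    frequencies).  Comorbidity is a block model: groups are partitioned
    into blocks of ``block_size``; each subject activates a block with
    probability ``block_prob``, which multiplies the within-block group
    risk by ``block_rr`` (marginal prevalences are preserved).
    """

    n_subjects: int = 8546
    n_variants: int = 200
    n_groups: int = 100
    maf_range: tuple[float, float] = (0.01, 0.10)
    prevalence_range: tuple[float, float] = (0.005, 0.20)
    ancestry_props: tuple[tuple[str, float], ...] = (("EA", 0.694), ("AA", 0.201), ("other", 0.105))
    dataset_props: tuple[tuple[str, float], ...] = (("A", 3174.0), ("B", 1558.0), ("C", 3940.0))
    age_mean: float = 52.0
    age_sd: float = 18.0
    block_size: int = 5
    block_prob: float = 0.2
    block_rr: float = 3.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    planted_maf: float | None = None
    planted_prevalence: float | None = None
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        lo, hi = self.prevalence_range
        if not 0 < lo <= hi < 1:
            raise ValueError("prevalence_range must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.block_prob <= 1:
            raise ValueError("block_prob must be a probability")


@dataclass
class SimTruth:
    """Record of the effects actually planted, for recovery testing."""

    planted: tuple[PlantedEffect, ...]
    gene_of: dict[str, str]
    minor_hz_counts: dict[str, int]  # non-missing minor-allele homozygotes
    maf: pd.DataFrame  # variants x ancestries
    prevalences: pd.Series

    @property
    def planted_variants(self) -> set[str]:
        return {e.rsid for e in self.planted}

    @property
    def planted_groups(self) -> set[str]:
        return {e.group for e in self.planted}


def _variant_ids(n: int) -> list[str]:
    return [f"rs{100000 + i}" for i in range(n)]


def _group_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _draw_ages(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Mixture over the five matching strata: mostly adults, some children.

    90% N(mean+5, sd*0.78), 5% U(0,5), 5% U(5,20); overall mean/SD close
    to the requested values while populating every age stratum.
    """
    comp = rng.choice(3, size=n, p=[0.90, 0.05, 0.05])
    ages = rng.normal(mean + 5.0, sd * 0.78, size=n)
    ages[comp == 1] = rng.uniform(0.0, 5.0, size=int((comp == 1).sum()))
    ages[comp == 2] = rng.uniform(5.0, 20.0, size=int((comp == 2).sum()))
    return np.clip(ages, 0.0, 105.0)


def _categorical(rng: np.random.Generator, n: int, props: tuple[tuple[str, float], ...]) -> np.ndarray:
    labels = [k for k, _ in props]
    w = np.array([v for _, v in props], dtype=float)
    return rng.choice(labels, size=n, p=w / w.sum())


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Draw a full synthetic cohort; byte-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, v, g = config.n_subjects, config.n_variants, config.n_groups
    rsids = _variant_ids(v)
    groups = _group_ids(g)
    known = {e.rsid for e in config.planted_effects} - set(rsids)
    if known:
        raise ValueError(f"planted effect on unknown variant: {sorted(known)}")
    bad_groups = {e.group for e in config.planted_effects} - set(groups)
    if bad_groups:
        raise ValueError(f"planted effect on unknown group: {sorted(bad_groups)}")

    subject_ids = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    demographics = pd.DataFrame(
        {
            "sex": _categorical(rng, n, (("M", 0.472), ("F", 0.528))),
            "ancestry": _categorical(rng, n, config.ancestry_props),
            "dataset": _categorical(rng, n, config.dataset_props),
            "age": _draw_ages(rng, n, config.age_mean, config.age_sd),
        },
        index=subject_ids,
    )

    # per-ancestry MAFs (uniform in range); "other" uses the EA/AA mean
    maf = pd.DataFrame(
        {
            "EA": rng.uniform(*config.maf_range, size=v),
            "AA": rng.uniform(*config.maf_range, size=v),
        },
        index=pd.Index(rsids, name="rsid"),
    )
    planted_ids = {e.rsid for e in config.planted_effects}
    if config.planted_maf is not None:
        maf.loc[sorted(planted_ids)] = config.planted_maf
    maf["other"] = maf[["EA", "AA"]].mean(axis=1)

    # Hardy-Weinberg genotypes: dosage ~ Binomial(2, q) per ancestry
    anc = demographics["ancestry"].to_numpy()
    q = maf.loc[rsids, :].to_numpy()  # v x 3 columns EA/AA/other
    anc_idx = np.select([anc == "EA", anc == "AA"], [0, 1], default=2)
    q_subj = q[:, anc_idx].T  # n x v
    geno_true = rng.binomial(2, q_subj).astype(float)

    # diagnosis groups: comorbidity block model + planted effects
    prev = np.exp(
        rng.uniform(np.log(config.prevalence_range[0]), np.log(config.prevalence_range[1]), size=g)
    )
    if config.planted_prevalence is not None:
        planted_cols = [groups.index(e.group) for e in config.planted_effects]
        prev[planted_cols] = config.planted_prevalence
    n_blocks = -(-g // config.block_size)
    block_of = np.arange(g) // config.block_size
    z = rng.random((n, n_blocks)) < config.block_prob  # active blocks per subject
    p_hi = np.minimum(config.block_rr * prev, 0.95)
    p_lo = np.clip((prev - config.block_prob * p_hi) / (1.0 - config.block_prob), 1e-6, 1.0)
    prob = np.where(z[:, block_of], p_hi, p_lo)  # n x g

    if config.planted_effects:
        gcol = {gid: j for j, gid in enumerate(groups)}
        vcol = {rid: j for j, rid in enumerate(rsids)}
        odds = prob / (1.0 - prob)
        for eff in config.planted_effects:
            x = eff.exposure(geno_true[:, vcol[eff.rsid]])
            odds[:, gcol[eff.group]] *= eff.odds_ratio ** x
        prob = odds / (1.0 + odds)

    diag = rng.random((n, g)) < prob

    # missing genotype calls, completely at random
    geno = geno_true.copy()
    if config.missing_rate > 0:
        geno[rng.random((n, v)) < config.missing_rate] = np.nan

    genotypes = pd.DataFrame(geno, index=subject_ids, columns=rsids)
    diagnoses = pd.DataFrame(diag, index=subject_ids, columns=groups)
    variants = pd.DataFrame(
        {"gene": [f"GENE{i:04d}" for i in range(v)]}, index=pd.Index(rsids, name="rsid")
    )
    cohort = Cohort(demographics, genotypes, diagnoses, variants)

    hz_counts = {rid: int((genotypes[rid] == 2).sum()) for rid in rsids}
    truth = SimTruth(
        planted=tuple(config.planted_effects),
        gene_of=variants["gene"].to_dict(),
        minor_hz_counts=hz_counts,
        maf=maf,
        prevalences=pd.Series(prev, index=groups, name="prevalence"),
    )
    return cohort, truth


def simulate_knowledge_base(
    truth: SimTruth,
    decoy_term_rate: float = 0.5,
    n_groups: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated OMIM / KO-mouse annotation paired with a simulated cohort.

    Every planted variant's gene receives a term mapping to its true
    group; each remaining gene receives, with probability
    ``decoy_term_rate``, a decoy term mapping to a random group.  Returns
    a table with columns gene, source, term, mapped_groups (frozenset).
    """
    if not 0 <= decoy_term_rate <= 1:
        raise ValueError("decoy_term_rate must be a probability")
    rng = np.random.default_rng(seed)
    all_groups = list(truth.prevalences.index) if n_groups is None else _group_ids(n_groups)
    rows = []
    planted_genes = set()
    for eff in truth.planted:
        gene = truth.gene_of[eff.rsid]
        planted_genes.add(gene)
        source = rng.choice(["OMIM", "KO-mouse"])
        rows.append((gene, str(source), f"{eff.group} dysfunction", frozenset({eff.group})))
    for rsid, gene in truth.gene_of.items():
        if gene in planted_genes:
            continue
        if rng.random() < decoy_term_rate:
            grp = str(rng.choice(all_groups))
            source = rng.choice(["OMIM", "KO-mouse"])
            rows.append((gene, str(source), f"{grp} decoy phenotype", frozenset({grp})))
    return pd.DataFrame(rows, columns=["gene", "source", "term", "mapped_groups"])


def simulate_replication_cohort(config: SimConfig, n_pcs: int = 3) -> tuple[Cohort, SimTruth]:
    """A second, independent cohort with principal-component covariates.

    PCs mimic population structure: ancestry-shifted unit-variance
    Gaussians (EA and AA means separated by 2 units on PC1, half that on
    each subsequent axis).  Planted-effect semantics are identical to
    :func:`simulate_cohort`.
    """
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    cohort, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if n_pcs > 0:
        anc = cohort.demographics["ancestry"].to_numpy()
        shift = np.select([anc == "EA", anc == "AA"], [1.0, -1.0], default=0.0)
        pcs = {}
        for j in range(n_pcs):
            mu = shift * (1.0 / 2**j)
            pcs[f"PC{j + 1}"] = rng.normal(mu, 1.0)
        cohort.pcs = pd.DataFrame(pcs, index=cohort.subject_ids)
    return cohort, truth
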