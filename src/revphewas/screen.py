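"""The homozygote shared-diagnosis screen.

For each eligible low-frequency coding variant, the screen collects every
diagnosis group carried by at least two minor-allele homozygotes, drops
groups that recur across more than 5% of all such lists (rarely-used
codes for which one or two carriers produce spuriously strong p-values),
and tests each surviving group by a two-sided Fisher exact test of
affected minor- versus common-allele homozygotes.  Heterozygotes never
enter any count: restricting to the two homozygote classes avoids
committing to an inheritance model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .exact2x2 import fisher_exact_batch, fisher_exact_two_sided

__all__ = [
    "ScreenConfig",
    "SharedList",
    "ScreenResult",
    "eligible_variants",
    "shared_diagnosis_lists",
    "global_frequency_filter",
    "screen_variants",
    "fisher_exact_two_sided",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the shared-diagnosis screen.

    ``maf_max`` — ancestry-specific MAF ceiling (strict) applied in both
    EA and AA; ``min_minor_hz`` — minimum non-missing minor-allele
    homozygotes (inclusive); ``min_sharers`` — minimum homozygotes sharing
    a group for it to enter the variant's list; ``list_freq_max`` — a
    group on strictly more than this fraction of all non-empty lists is
    excluded everywhere; ``nominal_alpha`` — Fisher significance cut.
    """

    maf_max: float = 0.10
    min_minor_hz: int = 10
    min_sharers: int = 2
    list_freq_max: float = 0.05
    nominal_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.maf_max <= 0.5:
            raise ValueError("maf_max must be in (0, 0.5]")
        if self.min_sharers < 1:
            raise ValueError("min_sharers must be >= 1")
        if not 0 < self.nominal_alpha < 1:
            raise ValueError("nominal_alpha must be in (0, 1)")


@dataclass
class SharedList:
    """Diagnosis groups shared by >= min_sharers minor-allele homozygotes."""

    variant: str
    entries: pd.DataFrame  # columns: group, n_sharing


@dataclass
class ScreenResult:
    """Per-variant screen outcome.

    ``rows`` holds the diagnosis groups with Fisher p below the nominal
    cut (columns group, a, b, p); ``n_tested`` is the number of groups
    that survived the shared-list and cross-list filters and were tested,
    which is the per-variant Bonferroni denominator downstream.
    """

    variant: str
    n_minor_hz: int
    n_common_hz: int
    n_tested: int
    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def bonferroni_significant(self, alpha: float = 0.05) -> bool:
        if self.n_tested == 0 or self.rows.empty:
            return False
        return bool((self.rows["p"] < alpha / self.n_tested).any())


def _ancestry_maf(cohort: Cohort) -> pd.DataFrame:
    """Per-variant minor-allele frequency in EA and AA, non-missing calls only."""
    out = {}
    for anc in ("EA", "AA"):
        sub = cohort.genotypes[(cohort.demographics["ancestry"] == anc).to_numpy()]
        out[anc] = sub.mean(axis=0, skipna=True) / 2.0  # NaN when ancestry absent
    return pd.DataFrame(out)


def eligible_variants(cohort: Cohort, config: ScreenConfig) -> list[str]:
    """Variants with MAF below the ceiling in every represented ancestry
    and at least ``min_minor_hz`` non-missing minor-allele homozygotes."""
    maf = _ancestry_maf(cohort)
    hz = (cohort.genotypes == 2).sum(axis=0)
    n_called = cohort.genotypes.notna().sum(axis=0)
    keep = []
    for rsid in cohort.genotypes.columns:
        if n_called[rsid] == 0:
            log.warning("variant %s has no genotype calls; excluded", rsid)
            continue
        mafs = maf.loc[rsid].dropna()
        if (mafs >= config.maf_max).any():
            continue
        if hz[rsid] < config.min_minor_hz:
            continue
        keep.append(rsid)
    return keep


def _hz_count_matrix(cohort: Cohort, variants: list[str], dosage: int) -> np.ndarray:
    """(variants x groups) counts of homozygotes of the given dosage
    carrying each diagnosis group."""
    g = (cohort.genotypes[variants] == dosage).to_numpy()  # n x v
    d = cohort.diagnoses.to_numpy()  # n x g
    return g.T.astype(np.int64) @ d.astype(np.int64)


def shared_diagnosis_lists(
    cohort: Cohort, variants: list[str], config: ScreenConfig
) -> list[SharedList]:
    """Per variant, the diagnosis groups carried by >= min_sharers of its
    minor-allele homozygotes, with sharer counts."""
    if not variants:
        return []
    counts = _hz_count_matrix(cohort, variants, dosage=2)
    groups = np.asarray(cohort.diagnoses.columns)
    lists = []
    for i, rsid in enumerate(variants):
        sel = counts[i] >= config.min_sharers
        entries = pd.DataFrame({"group": groups[sel], "n_sharing": counts[i][sel]})
        lists.append(SharedList(rsid, entries))
    return lists


def global_frequency_filter(
    lists: list[SharedList], config: ScreenConfig
) -> tuple[list[SharedList], set[str]]:
    """Exclude groups on strictly more than ``list_freq_max`` of lists.

    The denominator is the number of variants with a non-empty shared
    list.  Returns the pruned lists and the excluded group set.
    """
    if not lists:
        return [], set()
    nonempty = [sl for sl in lists if len(sl.entries)]
    if not nonempty:
        return list(lists), set()
    n_lists = len(nonempty)
    appearances: dict[str, int] = {}
    for sl in nonempty:
        for grp in sl.entries["group"]:
            appearances[grp] = appearances.get(grp, 0) + 1
    cutoff = config.list_freq_max * n_lists
    excluded = {grp for grp, cnt in appearances.items() if cnt > cutoff}
    log.info(
        "cross-list filter: %d lists, %d groups excluded (> %.3g lists)",
        n_lists, len(excluded), cutoff,
    )
    kept = [
        SharedList(sl.variant, sl.entries[~sl.entries["group"].isin(excluded)].reset_index(drop=True))
        for sl in lists
    ]
    return kept, excluded


def screen_variants(
    cohort: Cohort, config: ScreenConfig | None = None, variants: list[str] | None = None
) -> list[ScreenResult]:
    """Run the full screen; one ScreenResult per eligible variant.

    Each result's ``rows`` holds the shared, filter-surviving diagnosis
    groups whose two-sided Fisher p (affected minor HZ vs affected common
    HZ) falls below ``nominal_alpha``.
    """
    config = config or ScreenConfig()
    if variants is None:
        variants = eligible_variants(cohort, config)
    lists = shared_diagnosis_lists(cohort, variants, config)
    lists, _excluded = global_frequency_filter(lists, config)
    if not lists:
        return []

    minor_counts = _hz_count_matrix(cohort, variants, dosage=2)
    common_counts = _hz_count_matrix(cohort, variants, dosage=0)
    n1_all = (cohort.genotypes[variants] == 2).sum(axis=0).to_numpy()
    n0_all = (cohort.genotypes[variants] == 0).sum(axis=0).to_numpy()
    col_of = {g: j for j, g in enumerate(cohort.diagnoses.columns)}

    # flatten every tested (variant, group) cell into one Fisher batch
    var_idx: list[int] = []
    grp: list[str] = []
    for i, sl in enumerate(lists):
        var_idx.extend([i] * len(sl.entries))
        grp.extend(sl.entries["group"].tolist())
    if not grp:
        return [
            ScreenResult(v, int(n1_all[i]), int(n0_all[i]), 0, _empty_rows())
            for i, v in enumerate(variants)
        ]
    vi = np.asarray(var_idx)
    gj = np.asarray([col_of[g] for g in grp])
    a = minor_counts[vi, gj]
    b = common_counts[vi, gj]
    p = fisher_exact_batch(a, n1_all[vi], b, n0_all[vi])

    results = []
    frame = pd.DataFrame({"vi": vi, "group": grp, "a": a, "b": b, "p": p})
    by_variant = dict(tuple(frame.groupby("vi")))
    for i, rsid in enumerate(variants):
        sub = by_variant.get(i)
        n_tested = 0 if sub is None else len(sub)
        if sub is None:
            rows = _empty_rows()
        else:
            rows = (
                sub.loc[sub["p"] < config.nominal_alpha, ["group", "a", "b", "p"]]
                .sort_values("p", kind="stable")
                .reset_index(drop=True)
            )
        results.append(ScreenResult(rsid, int(n1_all[i]), int(n0_all[i]), n_tested, rows))
    return results


def _empty_rows() -> pd.DataFrame:
    return pd.DataFrame({"group": pd.Series(dtype=str), "a": pd.Series(dtype=np.int64),
                         "b": pd.Series(dtype=np.int64), "p": pd.Series(dtype=float)})


def screen_results_frame(results: list[ScreenResult], cohort: Cohort | None = None) -> pd.DataFrame:
    """Flatten screen results into the tabular output format
    (variant, group, total/affected homozygote counts, p)."""
    rows = []
    for res in results:
        gene = cohort.gene_of(res.variant) if cohort is not None else ""
        for _, r in res.rows.iterrows():
            rows.append(
                {
                    "variant": res.variant,
                    "gene": gene,
                    "group": r["group"],
                    "total_minor_hz": res.n_minor_hz,
                    "affected_minor_hz": int(r["a"]),
                    "total_common_hz": res.n_common_hz,
                    "affected_common_hz": int(r["b"]),
                    "p": float(r["p"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "gene", "group", "total_minor_hz", "affected_minor_hz",
            "total_common_hz", "affected_common_hz", "p",
        ],
    )
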