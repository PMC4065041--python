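"""End-to-end orchestration: screen -> permutation null -> knowledge
filter -> matched exact association -> optional replication.

The run report records the candidate funnel (variants surviving each
stage), the permutation-null comparison, and a provenance block (seed,
configuration hash, package version) that is also embedded as a comment
header in every emitted table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import MatchSpec, PowerSpec, assoc_results_frame, test_candidates
from .cohort import Cohort
from .knowledge import KnowledgeBase, select_candidates
from .permnull import NullComparison, compare_to_null, permutation_null, summarize_screen
from .phenome import PhenotypeDef
from .replicate import ReplicationConfig, replication_results_frame, run_replication
from .screen import ScreenConfig, screen_results_frame, screen_variants
from .io import write_table

__all__ = ["RunConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    match: MatchSpec = field(default_factory=MatchSpec)
    power: PowerSpec = field(default_factory=PowerSpec)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    n_permutations: int = 100
    concordance_threshold: float = 0.0
    assoc_alpha: float = 0.05
    # emulates the post-hoc record review: (variant, phenotype) pairs to drop
    exclusions: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    funnel: dict[str, int]
    null_comparison: NullComparison | None
    screen_table: pd.DataFrame
    assoc_table: pd.DataFrame
    replication_table: pd.DataFrame | None
    candidates: list[str]
    confirmed: list[str]
    final: list[str]
    provenance: dict


def run_pipeline(
    cohort: Cohort,
    kb: KnowledgeBase,
    phenotype_defs: dict[str, list[PhenotypeDef]],
    config: RunConfig | None = None,
    replication_cohort: Cohort | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run the full discovery pipeline on a cohort.

    ``phenotype_defs`` maps variant id -> composite phenotype definitions
    to test at the matched-control stage (typically built from the same
    annotation that drives the knowledge filter).  Stages run in order
    and each stage's table is written under ``outdir`` when given.
    """
    config = config or RunConfig()
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }
    header = f"revphewas {__version__} seed={config.seed} config={provenance['config_hash']}"

    # stage 1: homozygote shared-diagnosis screen
    results = screen_variants(cohort, config.screen)
    screen_tab = screen_results_frame(results, cohort)
    screened = [r.variant for r in results if len(r.rows)]
    log.info("screen: %d eligible variants, %d with significant shared diagnoses",
             len(results), len(screened))

    # stage 2: genotype-permutation null
    null_cmp = None
    if config.n_permutations > 0:
        real = summarize_screen(results, alpha=config.screen.nominal_alpha)
        replicates = permutation_null(
            cohort, config.screen, n_replicates=config.n_permutations, base_seed=config.seed
        )
        null_cmp = compare_to_null(real, replicates)
        log.info("permutation null: real=%d, null median=%.1f IQR=%s",
                 real.n_bonferroni_sig, null_cmp.null_median, null_cmp.null_iqr)

    # stage 3: knowledge-base concordance
    gene_of = {rsid: cohort.gene_of(rsid) for rsid in cohort.genotypes.columns}
    concordant = select_candidates(results, gene_of, kb, config.concordance_threshold)
    candidates = [c.variant for c in concordant]

    # stage 4: matched-control exact association
    assoc_rows, confirmed = test_candidates(
        cohort, candidates, phenotype_defs,
        match_spec=config.match, power_spec=config.power,
        alpha=config.assoc_alpha, seed=config.seed,
    )
    assoc_tab = assoc_results_frame(assoc_rows)

    # stage 5: record-review exclusions (configurable emulation)
    excluded = {(v, p) for v, p in config.exclusions}
    final = [
        v for v in confirmed
        if any(
            (r.variant, r.phenotype) not in excluded and r.result.p < config.assoc_alpha
            for r in assoc_rows if r.variant == v and pd.notna(r.result.p)
        )
    ]

    # optional replication stage
    repl_tab = None
    if replication_cohort is not None:
        sig_pairs = [
            (r.variant, pdef)
            for r in assoc_rows
            if r.variant in final and pd.notna(r.result.p) and r.result.p < config.assoc_alpha
            for pdef in phenotype_defs.get(r.variant, [])
            if pdef.name == r.phenotype
        ]
        repl = run_replication(replication_cohort, sig_pairs, config.replication)
        repl_tab = replication_results_frame(repl)

    funnel = {
        "eligible": len(results),
        "screened": len(screened),
        "knowledge_restricted": sum(
            1 for r in results if gene_of[r.variant] in kb.genes
        ),
        "concordant_candidates": len(candidates),
        "statistically_confirmed": len(confirmed),
        "final_candidates": len(final),
    }
    if repl_tab is not None:
        funnel["replicated"] = int((repl_tab["status"] == "replicated").sum())

    report = PipelineReport(
        funnel=funnel,
        null_comparison=null_cmp,
        screen_table=screen_tab,
        assoc_table=assoc_tab,
        replication_table=repl_tab,
        candidates=candidates,
        confirmed=confirmed,
        final=final,
        provenance=provenance,
    )
    if outdir is not None:
        _write_report(report, Path(outdir), header, null_cmp)
    return report


def _write_report(
    report: PipelineReport, outdir: Path, header: str, null_cmp: NullComparison | None
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(report.screen_table, outdir / "screen.tsv", header=header, index=False)
    write_table(report.assoc_table, outdir / "matched_assoc.tsv", header=header, index=False)
    if report.replication_table is not None:
        write_table(report.replication_table, outdir / "replication.tsv", header=header, index=False)
    summary = {
        "funnel": report.funnel,
        "candidates": report.candidates,
        "confirmed": report.confirmed,
        "final": report.final,
        "provenance": report.provenance,
    }
    if null_cmp is not None:
        summary["permutation_null"] = {
            "real": null_cmp.real.n_bonferroni_sig,
            "null_median": null_cmp.null_median,
            "null_iqr": list(null_cmp.null_iqr),
            "percentile": null_cmp.percentile,
            "n_replicates": null_cmp.n_replicates,
        }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
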