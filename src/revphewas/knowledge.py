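"""Concordance of screened diagnoses with gene-level phenotype annotation.

Candidate filtering emulates an expert review step: a variant's screened
diagnoses are compared with the OMIM / knock-out-mouse phenotype terms
annotated to its gene, each term carrying a set of mapped diagnosis
groups.  Set overlap stands in for human judgement (the original review
criteria — shared pathophysiological mechanism and organ-system
distribution — are not algorithmic), so this is an emulation with a
tunable match-fraction threshold, not a reproduction of clinician review.
Direction of effect is deliberately ignored: an apparent gain-of-function
pattern opposite to the annotated loss-of-function phenotype still counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .screen import ScreenResult

__all__ = ["KnowledgeBase", "ConcordanceResult", "concordance_score", "select_candidates"]

log = logging.getLogger(__name__)

_SOURCES = {"OMIM", "KO-mouse"}


class KnowledgeBase:
    """Gene-level phenotype annotation table.

    Entries have columns gene, source ('OMIM' | 'KO-mouse'), term (free
    text) and mapped_groups (a frozenset of diagnosis group ids; may be
    empty for unmappable molecular phenotypes).
    """

    def __init__(self, entries: pd.DataFrame) -> None:
        required = {"gene", "source", "term", "mapped_groups"}
        missing = required - set(entries.columns)
        if missing:
            raise ValueError(f"knowledge base lacks columns {sorted(missing)}")
        bad = set(entries["source"].unique()) - _SOURCES
        if bad:
            raise ValueError(f"unknown annotation sources: {bad}")
        if (entries["gene"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene names in knowledge base")
        self.entries = entries.reset_index(drop=True)
        self._by_gene: dict[str, set[str]] = {}
        for gene, sub in self.entries.groupby("gene"):
            groups: set[str] = set()
            for mg in sub["mapped_groups"]:
                groups |= set(mg)
            self._by_gene[str(gene)] = groups

    @property
    def genes(self) -> set[str]:
        return set(self._by_gene)

    def groups_for_gene(self, gene: str) -> set[str]:
        return set(self._by_gene.get(gene, set()))

    def terms_for_group(self, gene: str, group: str) -> list[str]:
        sub = self.entries[self.entries["gene"] == gene]
        return [str(t) for t, mg in zip(sub["term"], sub["mapped_groups"]) if group in mg]


@dataclass(frozen=True)
class ConcordanceResult:
    """Overlap between a variant's screened diagnoses and its gene's
    annotated phenotypes."""

    variant: str
    gene: str
    matched: tuple[tuple[str, str], ...]  # (group, annotation term)
    score: float  # fraction of screened diagnoses matched
    passed: bool
    annotated: bool  # gene present in the knowledge base at all


def concordance_score(
    result: ScreenResult, gene: str, kb: KnowledgeBase, threshold: float = 0.0
) -> ConcordanceResult:
    """Score one variant's screened diagnoses against its gene annotation.

    A screened diagnosis matches when its group appears among the mapped
    groups of any of the gene's terms.  The variant passes when at least
    one diagnosis matches and the matched fraction reaches ``threshold``
    (default 0: any match suffices, the inclusive organ-system reading).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    screened = list(result.rows["group"]) if len(result.rows) else []
    if gene not in kb.genes:
        return ConcordanceResult(result.variant, gene, (), 0.0, False, False)
    mapped = kb.groups_for_gene(gene)
    matched = tuple(
        (grp, kb.terms_for_group(gene, grp)[0]) for grp in screened if grp in mapped
    )
    score = len(matched) / len(screened) if screened else 0.0
    passed = bool(matched) and score >= threshold
    return ConcordanceResult(result.variant, gene, matched, score, passed, True)


def select_candidates(
    results: list[ScreenResult],
    gene_of: dict[str, str],
    kb: KnowledgeBase,
    threshold: float = 0.0,
) -> list[ConcordanceResult]:
    """Variants whose gene is annotated and whose screened diagnoses are
    concordant with the annotation.

    Restricting to annotated genes first mirrors the analysis design:
    only variants with in-vivo functional data can be judged at all.
    """
    out = []
    n_annotated = 0
    for res in results:
        gene = gene_of[res.variant]
        conc = concordance_score(res, gene, kb, threshold)
        if conc.annotated:
            n_annotated += 1
        if conc.passed:
            out.append(conc)
    log.info(
        "knowledge filter: %d screened variants, %d in annotated genes, %d concordant",
        len(results), n_annotated, len(out),
    )
    return out
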