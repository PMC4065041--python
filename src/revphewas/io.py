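"""Reading and writing the pipeline's table formats.

All tables are plain TSV; genotypes may alternatively come from a VCF
(dosages re-polarized so 2 always counts copies of the cohort-wide minor
allele).  Phenotype definitions are YAML or JSON lists of
``{name, groups, age_min}``.  Files written by the pipeline carry a
comment header embedding the run seed and configuration hash.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .phenome import CodeGroupMap, PhenotypeDef

__all__ = [
    "read_genotypes",
    "read_diagnoses",
    "read_demographics",
    "read_code_group_map",
    "read_phenotype_defs",
    "read_knowledge_base",
    "write_knowledge_base",
    "write_cohort",
    "read_cohort",
    "write_table",
]

log = logging.getLogger(__name__)


def read_genotypes(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Genotype matrix (subjects x variants), minor-allele dosage with NaN
    for missing.

    TSV dialect: header ``subject_id`` plus one variant id per column,
    cells in {0, 1, 2, NA}.  VCF: biallelic sites only (others skipped
    with a warning); ALT dosages are re-polarized to minor-allele counts
    using cohort-wide allele frequencies.
    """
    path = Path(path)
    if format == "tsv":
        if path.stat().st_size == 0:
            warnings.warn(f"empty genotype file {path}")
            return pd.DataFrame()
        frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, comment="#")
        frame = frame.set_index("subject_id")
        if frame.index.has_duplicates:
            raise ValueError(f"duplicate subject ids in {path}")
        return frame.astype(float)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping non-biallelic site {var.ID or var.POS}")
            continue
        gts = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        called = ~np.isnan(dosage)
        if called.sum() and np.nanmean(dosage) / 2.0 > 0.5:
            dosage = 2.0 - dosage  # ALT is the major allele: flip
        cols[var.ID or f"{var.CHROM}:{var.POS}"] = dosage
    frame = pd.DataFrame(cols, index=pd.Index(samples, name="subject_id"))
    if frame.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return frame


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    """Long-format diagnosis table: columns subject_id, code."""
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def read_demographics(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str}, comment="#")
    frame = frame.set_index("subject_id")
    frame["age"] = frame["age"].astype(float)
    return frame


def read_code_group_map(path: str | Path) -> CodeGroupMap:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return CodeGroupMap.from_frame(frame)


def read_phenotype_defs(path: str | Path) -> list[PhenotypeDef]:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    defs = []
    for item in raw:
        defs.append(
            PhenotypeDef(
                name=str(item["name"]),
                groups=frozenset(str(g) for g in item["groups"]),
                age_min=item.get("age_min"),
            )
        )
    return defs


def read_knowledge_base(path: str | Path) -> pd.DataFrame:
    """Knowledge base TSV: gene, source, term, mapped_group_ids
    (semicolon-separated; may be empty)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna({"mapped_group_ids": ""})
    frame["mapped_groups"] = [
        frozenset(g for g in str(s).split(";") if g) for s in frame["mapped_group_ids"]
    ]
    return frame[["gene", "source", "term", "mapped_groups"]]


def write_knowledge_base(entries: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    out = entries[["gene", "source", "term"]].copy()
    out["mapped_group_ids"] = [";".join(sorted(mg)) for mg in entries["mapped_groups"]]
    write_table(out, path, header=header, index=False)


def write_table(
    frame: pd.DataFrame, path: str | Path, header: str | None = None, index: bool = True
) -> None:
    """Write a TSV, optionally prefixed with '#'-comment provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


def write_cohort(cohort: Cohort, outdir: str | Path, header: str | None = None) -> dict[str, Path]:
    """Emit a cohort as the same TSV set the pipeline reads back."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "demographics": outdir / "demographics.tsv",
        "diagnosis_groups": outdir / "diagnosis_groups.tsv",
        "variants": outdir / "variants.tsv",
    }
    paths["groups"] = outdir / "groups.tsv"
    write_table(cohort.genotypes, paths["genotypes"], header=header)
    write_table(cohort.demographics, paths["demographics"], header=header)
    long = cohort.diagnoses.stack()
    long = long[long]
    diag = long.reset_index()[["subject_id", "level_1"]].rename(columns={"level_1": "group_id"})
    write_table(diag, paths["diagnosis_groups"], header=header, index=False)
    write_table(
        pd.DataFrame({"group_id": list(cohort.diagnoses.columns)}),
        paths["groups"], header=header, index=False,
    )
    write_table(cohort.variants, paths["variants"], header=header)
    if cohort.pcs is not None:
        paths["pcs"] = outdir / "pcs.tsv"
        write_table(cohort.pcs, paths["pcs"], header=header)
    return paths


def read_cohort(indir: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort` (round-trip)."""
    indir = Path(indir)
    demographics = read_demographics(indir / "demographics.tsv")
    genotypes = read_genotypes(indir / "genotypes.tsv")
    genotypes = genotypes.reindex(demographics.index)
    variants = pd.read_csv(indir / "variants.tsv", sep="\t", dtype=str, comment="#").set_index("rsid")
    diag_long = pd.read_csv(indir / "diagnosis_groups.tsv", sep="\t", dtype=str, comment="#")
    groups_path = indir / "groups.tsv"
    if groups_path.exists():
        groups = pd.read_csv(groups_path, sep="\t", dtype=str, comment="#")["group_id"].tolist()
    else:
        groups = sorted(diag_long["group_id"].unique())
    diagnoses = pd.DataFrame(False, index=demographics.index, columns=groups)
    for sid, sub in diag_long.groupby("subject_id"):
        diagnoses.loc[sid, sub["group_id"].tolist()] = True
    pcs_path = indir / "pcs.tsv"
    pcs = None
    if pcs_path.exists():
        pcs = pd.read_csv(pcs_path, sep="\t", comment="#").set_index("subject_id")
        pcs.index = pcs.index.astype(str)
        pcs = pcs.reindex(demographics.index)
    return Cohort(demographics, genotypes, diagnoses, variants, pcs)
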