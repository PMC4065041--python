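"""The in-memory cohort container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Cohort"]

ANCESTRIES = ("EA", "AA", "other")


@dataclass
class Cohort:
    """Subjects with demographics, mapped diagnosis groups and genotypes.

    Attributes
    ----------
    demographics : DataFrame indexed by subject id with columns
        ``sex`` ('M'/'F'), ``ancestry`` ('EA'/'AA'/'other'), ``dataset``
        (sub-cohort label) and ``age`` (years at last encounter).
    genotypes : DataFrame (subjects x variants) of minor-allele dosages
        0/1/2 as float, ``NaN`` for missing calls.
    diagnoses : boolean DataFrame (subjects x diagnosis groups); a cell is
        True when the subject carries at least one code in that group.
    variants : DataFrame indexed by variant id (rsid) with at least a
        ``gene`` column.
    pcs : optional DataFrame (subjects x principal components), present in
        replication cohorts.
    """

    demographics: pd.DataFrame
    genotypes: pd.DataFrame
    diagnoses: pd.DataFrame
    variants: pd.DataFrame
    pcs: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        idx = self.demographics.index
        if idx.has_duplicates:
            raise ValueError("duplicate subject ids")
        for name, frame in (("genotypes", self.genotypes), ("diagnoses", self.diagnoses)):
            if not frame.index.equals(idx):
                raise ValueError(f"{name} index does not match demographics")
        if self.pcs is not None and not self.pcs.index.equals(idx):
            raise ValueError("pcs index does not match demographics")
        missing = set(self.genotypes.columns) - set(self.variants.index)
        if missing:
            raise ValueError(f"variants table lacks {sorted(missing)[:5]}...")
        if (self.demographics["age"] < 0).any():
            raise ValueError("negative ages")
        bad = set(self.demographics["ancestry"].unique()) - set(ANCESTRIES)
        if bad:
            raise ValueError(f"unknown ancestry labels: {bad}")

    @property
    def subject_ids(self) -> pd.Index:
        return self.demographics.index

    @property
    def n_subjects(self) -> int:
        return len(self.demographics)

    def dosages(self, rsid: str) -> pd.Series:
        return self.genotypes[rsid]

    def minor_hz_mask(self, rsid: str) -> np.ndarray:
        return (self.genotypes[rsid] == 2).to_numpy()

    def common_hz_mask(self, rsid: str) -> np.ndarray:
        return (self.genotypes[rsid] == 0).to_numpy()

    def gene_of(self, rsid: str) -> str:
        return str(self.variants.loc[rsid, "gene"])
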