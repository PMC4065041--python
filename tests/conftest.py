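"""Shared fixtures: a small hand-constructed cohort and code tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from revphewas.cohort import Cohort
from revphewas.phenome import CodeGroupMap


@pytest.fixture
def code_map() -> CodeGroupMap:
    frame = pd.DataFrame(
        {
            "code": ["250.0", "250.1", "366.1", "366.2", "153.9"],
            "group_id": ["G_DM", "G_DM", "G_CAT", "G_CAT", "G_CA"],
            "label": ["diabetes", "diabetes", "cataract", "cataract", "colon cancer"],
            "is_cancer": ["0", "0", "0", "0", "1"],
        }
    )
    return CodeGroupMap.from_frame(frame)


def build_cohort(
    genotypes: dict[str, list[float]],
    groups: dict[str, list[bool]],
    ages: list[float] | None = None,
    sex: list[str] | None = None,
    ancestry: list[str] | None = None,
    dataset: list[str] | None = None,
    genes: dict[str, str] | None = None,
) -> Cohort:
    n = len(next(iter(genotypes.values())))
    ids = pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id")
    demo = pd.DataFrame(
        {
            "sex": sex or ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "ancestry": ancestry or ["EA"] * n,
            "dataset": dataset or ["A"] * n,
            "age": ages or [50.0] * n,
        },
        index=ids,
    )
    geno = pd.DataFrame(genotypes, index=ids, dtype=float)
    diag = pd.DataFrame(groups, index=ids, dtype=bool)
    variants = pd.DataFrame(
        {"gene": [(genes or {}).get(v, f"GENE_{v}") for v in geno.columns]},
        index=pd.Index(geno.columns, name="rsid"),
    )
    return Cohort(demo, geno, diag, variants)


@pytest.fixture
def ten_subject_cohort() -> Cohort:
    """10 subjects, 2 variants, 3 groups; counts easy to enumerate by hand."""
    return build_cohort(
        genotypes={
            "rs1": [2, 2, 2, 0, 0, 0, 0, 1, 1, np.nan],
            "rs2": [0, 0, 1, 1, 2, 2, 2, 2, 0, 0],
        },
        groups={
            "G_A": [True, True, False, True, False, False, False, True, False, False],
            "G_B": [False, True, True, False, False, True, True, False, False, True],
            "G_C": [False] * 10,
        },
        ages=[45.0, 55.0, 61.0, 30.0, 2.0, 10.0, 70.0, 50.0, 33.0, 8.0],
    )
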