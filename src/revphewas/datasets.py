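"""Small reference datasets bundled with the package.

``load_matched_assoc_tables`` returns the benchmark 2x2 homozygote
contingency tables from a published EMR-linked study of low-frequency
coding variants, with the odds ratios and p-values its matched-control
exact analysis reported.  They exercise the exact 2x2 machinery on real
table shapes, including zero cells in either homozygote class.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["load_matched_assoc_tables"]

_NA = math.nan

# columns: rsid, gene, phenotype, total minor HZ, affected minor HZ,
#          total common HZ, affected common HZ, reported OR, reported p
_ROWS = [
    ("rs17255978", "ADAM22", "Peripheral neuropathy", 28, 9, 1402, 143, 4.2, 0.0006),
    ("rs17255978", "ADAM22", "Demyelination disease", 28, 0, 1402, 7, _NA, _NA),
    ("rs17255978", "ADAM22", "Seizures", 28, 1, 1402, 55, 0.9, 0.92),
    ("rs33986943", "AOC3", "Gram negative sepsis", 35, 7, 1023, 56, 4.3, 0.001),
    ("rs33986943", "AOC3", "All sepsis", 35, 16, 1023, 307, 2.0, 0.051),
    ("rs33986943", "AOC3", "Gram positive sepsis", 35, 11, 1023, 190, 2.0, 0.06),
    ("rs33986943", "AOC3", "Decrease serum IgA", 35, 0, 1023, 4, _NA, _NA),
    ("rs16027", "CACNA1A", "Migraine", 54, 10, 1512, 114, 2.8, 0.004),
    ("rs16027", "CACNA1A", "Convulsions", 54, 10, 1512, 128, 2.5, 0.01),
    ("rs16027", "CACNA1A", "Seizures", 54, 4, 1512, 69, 1.7, 0.33),
    ("rs3735972", "CNGB3", "Cataract", 74, 18, 1554, 162, 2.6, 0.0007),
    ("rs3735972", "CNGB3", "Cataract (age>50)", 43, 15, 860, 124, 3.2, 0.0005),
    ("rs3735972", "CNGB3", "Macular degeneration", 74, 4, 1554, 19, 4.4, 0.008),
    ("rs3735972", "CNGB3", "Colorblindness", 74, 0, 1554, 0, _NA, _NA),
    ("rs3735972", "CNGB3", "Retinopathy (not hypertension or diabetes)", 74, 7, 1554, 76, 1.9, 0.11),
    ("rs1800067", "ERCC4", "Seborrheic keratosis", 42, 8, 1512, 124, 2.6, 0.016),
    ("rs6031", "F5", "Pregnancy loss", 13, 3, 715, 23, 9.0, 0.001),
    ("rs6031", "F5", "On anti-coagulant", 15, 4, 825, 74, 3.7, 0.028),
    ("rs6031", "F5", "Stroke", 15, 4, 825, 81, 3.3, 0.04),
    ("rs6031", "F5", "Venous thrombosis", 15, 3, 825, 52, 3.7, 0.047),
    ("rs6031", "F5", "Budd-Chiari syndrome", 15, 0, 825, 1, _NA, _NA),
    ("rs2291628", "FBN2", "Avascular necrosis", 62, 7, 1488, 29, 6.4, 0.0001),
    ("rs2291628", "FBN2", "Osteomyelitis", 62, 8, 1488, 76, 2.8, 0.01),
    ("rs2291628", "FBN2", "Bone fracture", 62, 20, 1488, 306, 1.8, 0.029),
    ("rs2291628", "FBN2", "Pathologic fracture", 62, 5, 1488, 43, 2.9, 0.027),
    ("rs2291628", "FBN2", "Osteoporosis", 62, 7, 1488, 206, 0.8, 0.56),
    ("rs2291628", "FBN2", "Joint disease", 62, 27, 1488, 663, 1.0, 0.87),
    ("rs2291628", "FBN2", "Polydactyly", 62, 0, 1488, 5, _NA, _NA),
    ("rs13157270", "GPR98", "Epilepsy", 48, 7, 1488, 77, 3.1, 0.007),
    ("rs13157270", "GPR98", "Febrile seizure", 48, 0, 1488, 4, _NA, _NA),
    ("rs13157270", "GPR98", "Convulsions", 48, 7, 1488, 140, 1.6, 0.23),
    ("rs16844401", "HGFAC", "GI bleed", 32, 6, 1503, 68, 4.9, 0.0007),
    ("rs16844401", "HGFAC", "GI infections (bacterial)", 32, 1, 1503, 109, 0.4, 0.38),
    ("rs17537869", "PLCG2", "Extrinsic asthma", 11, 2, 1279, 18, 15.6, 0.0008),
    ("rs17537869", "PLCG2", "Humoral immunity/Decreased IgA,IgM", 11, 1, 1279, 0, 9.7, 0.03),
    ("rs17537869", "PLCG2", "Allergic reactions", 11, 5, 1279, 251, 3.4, 0.04),
    ("rs17537869", "PLCG2", "Allergic rhinitis", 11, 2, 1279, 182, 1.3, 0.70),
    ("rs17537869", "PLCG2", "Cold induced urticaria", 11, 0, 1279, 1, _NA, _NA),
    ("rs5939", "PTAFR", "Bacterial meningitis", 17, 3, 964, 7, 29.3, 0.0001),
    ("rs5939", "PTAFR", "Acute upper respiratory infection", 17, 11, 964, 199, 7.0, 0.0001),
    ("rs5939", "PTAFR", "Chronic sinusitis", 17, 6, 964, 103, 4.6, 0.003),
    ("rs5939", "PTAFR", "Sinusitis", 17, 8, 964, 188, 3.7, 0.008),
    ("rs5939", "PTAFR", "Acute sinusitis", 17, 6, 964, 137, 3.3, 0.02),
    ("rs5939", "PTAFR", "All sepsis", 17, 3, 964, 84, 2.2, 0.21),
    ("rs5939", "PTAFR", "Gram positive sepsis", 17, 2, 964, 53, 2.3, 0.27),
    ("rs5939", "PTAFR", "Strep infections", 17, 1, 964, 41, 1.4, 0.74),
    ("rs5939", "PTAFR", "Gram negative sepsis", 17, 0, 964, 12, _NA, _NA),
    ("rs8192619", "TAAR1", "Anxiety", 17, 7, 725, 132, 4.6, 0.002),
    ("rs8192619", "TAAR1", "Depression", 17, 9, 725, 173, 3.6, 0.009),
    ("rs8192619", "TAAR1", "Schizophrenia", 17, 0, 725, 12, _NA, _NA),
]


def load_matched_assoc_tables() -> pd.DataFrame:
    """Benchmark matched-control homozygote tables with reported OR and p.

    Reported ORs are from an exact conditional (logistic) analysis, so on
    some rows they differ from the cross-product odds ratio; rows with no
    affected minor-allele homozygote were reported as not estimable
    (``reported_or`` is NaN).  '<0.0001'-style p-values are stored at
    their bound.
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "rsid", "gene", "phenotype", "total_minor_hz", "affected_minor_hz",
            "total_common_hz", "affected_common_hz", "reported_or", "reported_p",
        ],
    )
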