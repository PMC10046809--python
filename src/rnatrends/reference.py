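"""Published reference values for the GSE132040 mouse aging cohort analysis.

Per-age group summary statistics (mean RNA production with 95% CI for the
housekeeping and integrative gene groups, 17 tissues pooled, ages 1-27
months) and the named developmental gene blocks, as reported for that
cohort. These are inputs to desk-scale re-analysis: the trend, ratio and
segmented statistics of the study are all functions of this table.

The DNA-repair block is shipped as a curated default list of 56 mouse
repair-pathway genes (base-excision, nucleotide-excision, mismatch,
homologous-recombination and non-homologous end-joining repair); the
original study names its repair set only by citation, so this list is
editable and block-level results depend on it.
"""

from __future__ import annotations

from .aggregate import AgeSeries
from .ratio import DEFAULT_STAGES  # noqa: F401  (re-export: stages belong to the study design)

STUDY_AGES: tuple[float, ...] = (1, 3, 6, 9, 12, 15, 18, 21, 24, 27)

# 17 tissue types of the cohort (labels as deposited).
STUDY_TISSUES: tuple[str, ...] = (
    "Brain", "BAT", "Bone", "GAT", "Heart", "Kidney", "Lung", "Marrow",
    "MAT", "Pancreas", "SCAT", "Skin", "Small", "Spleen", "WBC", "Limb",
    "Liver",
)

# Reported per-age mean RNA production (normalized expression units).
HG_MEANS: tuple[float, ...] = (
    496.39, 486.62, 498.84, 465.32, 480.44, 485.38, 475.54, 462.22, 460.17, 450.0,
)
HG_CI: tuple[tuple[float, float], ...] = (
    (474.49, 518.29), (464.47, 508.78), (476.33, 521.35), (444.47, 486.18),
    (459.26, 501.62), (462.60, 508.16), (454.77, 496.30), (441.06, 483.38),
    (439.31, 481.02), (428.02, 471.95),
)
INTG_MEANS: tuple[float, ...] = (
    135.49, 130.96, 134.88, 125.83, 130.06, 130.53, 132.69, 125.45, 126.75, 123.14,
)
INTG_CI: tuple[tuple[float, float], ...] = (
    (130.06, 140.92), (125.71, 136.21), (129.34, 140.43), (120.84, 130.81),
    (124.95, 135.10), (125.17, 135.88), (127.45, 137.93), (120.34, 130.56),
    (121.61, 131.89), (118.02, 128.27),
)

# Reported cohort-scale gene counts (recomputable only from the deposited
# accession plus the resolved housekeeping list).
TOTAL_GENES = 35_630
N_HG = 5_101
N_INTG = 30_529

BREAKPOINT_MONTHS = 9.0  # a-priori physiological-peak age splitting 1-9 / 9-27

# HOXA developmental block (Block I) as reported.
BLOCK_I_GENES: tuple[str, ...] = (
    "HOXA1", "HOXA2", "HOXA3", "HOXA4", "HOXA5", "HOXA6", "HOXA7",
    "HOXA9", "HOXA10", "HOXA11", "HOXA13",
)

# Cardiovascular/metabolic developmental block (Block II) as reported
# ("GDF 10" normalized to "GDF10").
BLOCK_II_GENES: tuple[str, ...] = (
    "CDX", "CUX1", "GDF1", "GDF3", "GDF5", "GDF10", "GDF15", "GSX",
    "PAX3", "PAX6", "SRGAP2", "GDF11",
)

# Curated default DNA-repair block: 56 mouse genes across the major repair
# pathways. Editable; see module docstring.
DNA_REPAIR_GENES: tuple[str, ...] = (
    # base-excision repair
    "Apex1", "Apex2", "Ogg1", "Mutyh", "Nthl1", "Neil1", "Neil2", "Neil3",
    "Ung", "Smug1", "Mpg", "Tdg", "Mbd4", "Lig1", "Lig3", "Xrcc1",
    "Parp1", "Parp2", "Polb",
    # nucleotide-excision repair
    "Ercc1", "Ercc2", "Ercc3", "Ercc4", "Ercc5", "Ercc6", "Ercc8",
    "Xpa", "Xpc", "Ddb1", "Ddb2", "Rad23a", "Rad23b", "Pold1", "Pole",
    # mismatch repair
    "Msh2", "Msh3", "Msh6", "Mlh1", "Mlh3", "Pms2", "Exo1",
    # homologous recombination
    "Brca1", "Brca2", "Rad50", "Rad51", "Rad52", "Rad54l", "Mre11a",
    "Nbn", "Atm", "Atr",
    # non-homologous end joining
    "Prkdc", "Lig4", "Xrcc4", "Xrcc5", "Xrcc6",
)

assert len(DNA_REPAIR_GENES) == 56
assert len(BLOCK_I_GENES) == 11
assert len(BLOCK_II_GENES) == 12


def hg_reference_series() -> AgeSeries:
    """The housekeeping group's published per-age mean series."""
    return AgeSeries.from_means(STUDY_AGES, HG_MEANS, HG_CI)


def intg_reference_series() -> AgeSeries:
    """The integrative group's published per-age mean series."""
    return AgeSeries.from_means(STUDY_AGES, INTG_MEANS, INTG_CI)
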