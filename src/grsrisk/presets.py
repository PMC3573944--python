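"""Bundled reference inputs: a four-SNP lung-cancer candidate panel and the
summary tables of the case-control study it was reported in.

These constants are the package defaults for simulation and the fixtures for
the regression tests; counts are (cases, controls) per category.
"""

from __future__ import annotations

from .types import SimConfig, SnpDef

# Candidate panel: id, risk allele, control risk-allele frequency, per-allele OR.
DEFAULT_PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs2736100", "C", 0.41, 1.18),
    SnpDef("rs402710", "C", 0.68, 1.10),
    SnpDef("rs4083914", "G", 0.14, 1.15),
    SnpDef("rs4488809", "T", 0.47, 1.21),
)

# The fifth genotyped locus, excluded from the panel (not associated; MAF 0.02).
EXCLUDED_SNP = SnpDef("rs1051730", "T", 0.02, 1.09)

STUDY_N_CASES = 2283
STUDY_N_CONTROLS = 2785

# Control-group smoking distribution (never/light/heavy) and per-level OR.
SMOKING_CONTROL_DIST = (0.5447, 0.1946, 0.2607)
SMOKING_OR = 1.67

# Printed category counts: (label, n cases, n controls).
SMOKING_COUNTS = [
    ("never", 801, 1517),
    ("light", 416, 542),
    ("heavy", 1066, 726),
]

CGRS_BAND_COUNTS = [
    ("0-1", 125, 226),
    ("2", 337, 465),
    ("3", 589, 733),
    ("4", 600, 740),
    ("5", 435, 453),
    (">=6", 197, 168),
]

WGRS_DECILE_COUNTS = [
    ("0", 222, 400),
    ("1", 192, 241),
    ("2", 211, 272),
    ("3", 215, 299),
    ("4", 423, 512),
    ("5", 102, 115),
    ("6", 140, 173),
    ("7", 185, 195),
    ("8", 309, 323),
    ("9", 284, 255),
]

# Published combined-model coefficients: intercept, per-decile wGRS, per-level smoking.
PUBLISHED_COEFFICIENTS = (-0.9372, 0.0610, 0.5142)


def default_sim_config(seed: int, n_cases: int = STUDY_N_CASES,
                       n_controls: int = STUDY_N_CONTROLS, **kwargs) -> SimConfig:
    """SimConfig matching the reference study's panel, sizes and smoking mix."""
    return SimConfig(
        snps=DEFAULT_PANEL,
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        smoking_dist=SMOKING_CONTROL_DIST,
        smoking_or=SMOKING_OR,
        **kwargs,
    )
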