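"""Genetic risk scores.

Two scores per subject: the count score (cGRS) is the plain sum of
risk-allele dosages; the weighted score (wGRS) is a product over loci of
genotype-specific relative risks scaled by the population-average relative
risk ``u = (1-p)^2 + 2p(1-p)OR + p^2 OR^2``.

Two weighting modes are provided.  ``"normalized"`` (default) uses genotype
values (1/u, OR/u, OR^2/u), whose HWE-weighted population mean is exactly 1.
``"literal"`` uses (1/u, OR/u, OR^2/u^2), reproducing a published variant of
the weighting in which the homozygote value is divided by u twice; its
population mean is not 1.  A missing genotype always contributes a factor of
exactly 1 to the wGRS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .types import Cohort, GrsError, SnpDef

GrsMode = Literal["normalized", "literal"]

CGRS_BANDS = ("0-1", "2", "3", "4", "5", ">=6")


@dataclass(frozen=True)
class SnpWeight:
    """Per-locus weighting: population-average relative risk ``u`` and the
    adjusted risk value for dosage 0, 1, 2."""

    snp_id: str
    u: float
    genotype_scores: tuple[float, float, float]

    def score_for(self, dosage: float) -> float:
        """Genotype score for one dosage; missing (NaN) contributes 1."""
        if np.isnan(dosage):
            return 1.0
        if dosage not in (0.0, 1.0, 2.0):
            raise GrsError(f"{self.snp_id}: dosage must be 0/1/2/missing, got {dosage}")
        return self.genotype_scores[int(dosage)]


@dataclass
class ScoreSet:
    """Per-subject risk scores plus the banded/decile categorizations."""

    subject_id: list[str]
    status: np.ndarray
    cgrs: np.ndarray
    cgrs_band: np.ndarray
    wgrs: np.ndarray
    wgrs_decile: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "status": self.status,
                "cgrs": self.cgrs,
                "cgrs_band": self.cgrs_band,
                "wgrs": self.wgrs,
                "wgrs_decile": self.wgrs_decile,
            }
        )


def average_relative_risk(p: float, oratio: float) -> float:
    """Population-average relative risk at a locus in HWE.

    ``u = (1-p)^2 + 2 p (1-p) OR + p^2 OR^2`` — the mean of the genotype
    relative risks (1, OR, OR^2) under HWE genotype frequencies.
    """
    if not 0.0 <= p <= 1.0:
        raise GrsError(f"allele frequency must be in [0, 1], got {p}")
    if oratio <= 0:
        raise GrsError(f"odds ratio must be positive, got {oratio}")
    q = 1.0 - p
    return q * q + 2.0 * p * q * oratio + p * p * oratio * oratio


def snp_genotype_scores(
    p: float, oratio: float, mode: GrsMode = "normalized", snp_id: str = ""
) -> SnpWeight:
    """Adjusted genotype risk values for dosages 0, 1, 2.

    ``normalized``: (1/u, OR/u, OR^2/u), HWE-weighted mean exactly 1.
    ``literal``:    (1/u, OR/u, OR^2/u^2).
    """
    u = average_relative_risk(p, oratio)
    if mode == "normalized":
        scores = (1.0 / u, oratio / u, oratio * oratio / u)
    elif mode == "literal":
        scores = (1.0 / u, oratio / u, oratio * oratio / (u * u))
    else:
        raise GrsError(f"unknown GRS mode {mode!r}; use 'normalized' or 'literal'")
    return SnpWeight(snp_id=snp_id, u=u, genotype_scores=scores)


def weights_for_panel(
    snps: Iterable[SnpDef], mode: GrsMode = "normalized"
) -> list[SnpWeight]:
    return [snp_genotype_scores(s.p, s.oratio, mode=mode, snp_id=s.snp_id) for s in snps]


def cgrs_band(count: float) -> str:
    """Risk-allele-count band used for reporting: 0-1, 2, 3, 4, 5, >=6."""
    c = int(count)
    if c <= 1:
        return "0-1"
    if c >= 6:
        return ">=6"
    return str(c)


def compute_cgrs(cohort: Cohort, missing: str = "zero") -> np.ndarray:
    """Count score: sum of risk-allele dosages over non-missing loci.

    ``missing="zero"`` treats a missing genotype as 0 risk alleles;
    ``missing="expected"`` imputes 2p from the cohort's observed dosage mean.
    """
    dos = cohort.dosages.to_numpy(dtype=float)
    if missing == "zero":
        filled = np.nan_to_num(dos, nan=0.0)
    elif missing == "expected":
        col_mean = np.nanmean(dos, axis=0) if dos.size else np.zeros(dos.shape[1])
        filled = np.where(np.isnan(dos), col_mean, dos)
    else:
        raise GrsError(f"unknown cGRS missing policy {missing!r}")
    return filled.sum(axis=1)


def compute_wgrs(cohort: Cohort, weights: Sequence[SnpWeight]) -> np.ndarray:
    """Weighted score: product over loci of genotype scores.

    Missing genotypes contribute a factor of exactly 1.
    """
    by_id = {w.snp_id: w for w in weights}
    missing_cols = [c for c in cohort.snp_ids if c not in by_id]
    if missing_cols:
        raise GrsError(f"no weights supplied for SNP column(s): {missing_cols}")
    wgrs = np.ones(len(cohort), dtype=float)
    for col in cohort.snp_ids:
        w = by_id[col]
        dos = cohort.dosages[col].to_numpy(dtype=float)
        bad = ~(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0)))
        if bad.any():
            i = int(np.argmax(bad))
            raise GrsError(
                f"dosage outside 0/1/2/missing for subject "
                f"{cohort.subject_id[i]!r}, SNP {col!r}: {dos[i]!r}"
            )
        table = np.array(w.genotype_scores, dtype=float)
        factor = np.where(np.isnan(dos), 1.0, table[np.nan_to_num(dos, nan=0.0).astype(int)])
        wgrs *= factor
    return wgrs


def decile_categories(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Decile rank 0-9 of each score against a reference distribution.

    Cut points are the 10th-90th percentiles of ``reference``; a score equal
    to a cut point goes to the upper category, so category 9 always means
    ">= Q90".  With discrete scores the categories can be very uneven.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise GrsError("decile reference distribution is empty")
    cuts = np.percentile(reference, np.arange(10, 100, 10))
    return np.searchsorted(cuts, np.asarray(scores, dtype=float), side="right")


def score_cohort(
    cohort: Cohort,
    snps: Iterable[SnpDef],
    mode: GrsMode = "normalized",
    decile_reference: str = "controls",
    cgrs_missing: str = "zero",
) -> ScoreSet:
    """Compute cGRS, wGRS and wGRS decile ranks for every subject.

    ``decile_reference`` selects the distribution defining the decile cut
    points: ``"controls"`` (default) or ``"pooled"``.
    """
    weights = weights_for_panel(snps, mode=mode)
    wgrs = compute_wgrs(cohort, weights)
    cgrs = compute_cgrs(cohort, missing=cgrs_missing)
    if decile_reference == "controls":
        ref = wgrs[cohort.status == 0]
    elif decile_reference == "pooled":
        ref = wgrs
    else:
        raise GrsError(f"unknown decile reference policy {decile_reference!r}")
    deciles = decile_categories(wgrs, ref)
    bands = np.array([cgrs_band(c) for c in cgrs])
    return ScoreSet(
        subject_id=list(cohort.subject_id),
        status=cohort.status.copy(),
        cgrs=cgrs,
        cgrs_band=bands,
        wgrs=wgrs,
        wgrs_decile=deciles,
    )
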