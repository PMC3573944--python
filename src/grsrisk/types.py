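"""Core domain types shared across the pipeline.

A :class:`Cohort` is an individual-level case-control table: binary disease
status, a 3-level ordinal smoking exposure, and per-SNP risk-allele dosages
(0/1/2, possibly missing).  :class:`SnpDef` describes one candidate risk
locus; :class:`SimConfig` parameterizes the cohort simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class GrsError(ValueError):
    """Base class for all validation errors raised by this package."""


class SimulationError(GrsError):
    """Raised when a simulated cohort cannot be assembled within budget."""


class SchemaError(GrsError):
    """Raised when an input file or table violates the cohort schema."""


SMOKING_LEVELS = ("never", "light", "heavy")


@dataclass(frozen=True)
class SnpDef:
    """A candidate risk locus.

    Parameters
    ----------
    snp_id : str
        Locus identifier (column name in cohort files).
    risk_allele : str
        Label of the risk-increasing allele; dosage counts this allele.
    p : float
        Risk-allele frequency, in [0, 1].
    oratio : float
        Per-allele odds ratio, > 0.
    """

    snp_id: str
    risk_allele: str
    p: float
    oratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise GrsError(
                f"{self.snp_id}: risk-allele frequency must be in [0, 1], got {self.p}"
            )
        if not self.oratio > 0:
            raise GrsError(
                f"{self.snp_id}: odds ratio must be positive, got {self.oratio}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the case-control cohort simulator.

    ``smoking_dist`` gives the control-population probabilities of the
    never/light/heavy categories; ``smoking_or`` is the per-level odds
    ratio of the ordinal smoking effect.  ``prevalence`` anchors the
    logistic intercept in the source population before case-control
    ascertainment.
    """

    snps: tuple[SnpDef, ...]
    n_cases: int
    n_controls: int
    seed: int
    smoking_dist: tuple[float, float, float] = (0.5447, 0.1946, 0.2607)
    smoking_or: float = 1.67
    prevalence: float = 0.01
    missing_rate: float = 0.005
    max_draws: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(self, "smoking_dist", tuple(self.smoking_dist))
        if len(self.smoking_dist) != 3:
            raise GrsError("smoking_dist must have exactly 3 categories")
        if abs(sum(self.smoking_dist) - 1.0) > 1e-9:
            raise GrsError(f"smoking_dist must sum to 1, got {sum(self.smoking_dist)}")
        if min(self.smoking_dist) < 0:
            raise GrsError("smoking_dist probabilities must be non-negative")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise GrsError("n_cases and n_controls must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise GrsError("prevalence must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise GrsError("missing_rate must be in [0, 1)")
        if self.smoking_or <= 0:
            raise GrsError("smoking_or must be positive")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass
class Cohort:
    """Individual-level case-control records.

    ``dosages`` is a float DataFrame (one column per SNP) holding
    risk-allele counts 0/1/2 with NaN marking a missing genotype.
    """

    subject_id: list[str]
    status: np.ndarray
    smoking: np.ndarray
    dosages: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int64)
        self.smoking = np.asarray(self.smoking, dtype=np.int64)
        n = len(self.subject_id)
        if self.dosages is None or self.dosages.shape[1] == 0:
            self.dosages = pd.DataFrame(index=range(n))
        if len(self.status) != n or len(self.smoking) != n or len(self.dosages) != n:
            raise SchemaError("subject_id, status, smoking and dosages must align")
        if len(set(self.subject_id)) != n:
            raise SchemaError("duplicate subject ids")
        if not np.isin(self.status, (0, 1)).all():
            raise SchemaError("status must be 0 (control) or 1 (case)")
        if not np.isin(self.smoking, (0, 1, 2)).all():
            raise SchemaError("smoking must be ordinal 0/1/2")
        self.dosages = self.dosages.astype(float).reset_index(drop=True)
        values = self.dosages.to_numpy()
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"dosage must be 0, 1, 2 or missing: subject "
                f"{self.subject_id[i]!r}, SNP {self.dosages.columns[j]!r}, "
                f"value {values[i, j]!r}"
            )

    def __len__(self) -> int:
        return len(self.subject_id)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk tabular layout (dosages still float/NaN)."""
        df = pd.DataFrame(
            {"subject_id": self.subject_id, "status": self.status, "smoking": self.smoking}
        )
        return pd.concat([df, self.dosages.reset_index(drop=True)], axis=1)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.subject_id == other.subject_id
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.smoking, other.smoking)
            and self.snp_ids == other.snp_ids
            and np.array_equal(
                self.dosages.to_numpy(), other.dosages.to_numpy(), equal_nan=True
            )
        )


def genotype_counts(dosages: Sequence[float]) -> tuple[int, int, int]:
    """Collapse a dosage vector to (n_AA, n_AB, n_BB) counts, ignoring NaN."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    return (int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum()))
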