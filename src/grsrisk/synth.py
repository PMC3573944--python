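"""Synthetic case-control cohorts.

``simulate_cohort`` draws individuals from a source population — independent
HWE genotypes, smoking independent of genotype — assigns disease by a
log-additive logistic model whose intercept is solved so the marginal
disease probability matches the configured prevalence, and keeps sampling
until the case and control quotas are filled (case-control ascertainment by
rejection).  ``expand_counts`` materializes printed category/count rows as
individual records for reanalysis of published tables.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import optimize, special

from .types import Cohort, GrsError, SimConfig, SimulationError

_BATCH = 100_000


def solve_intercept(config: SimConfig) -> float:
    """Logistic intercept giving the configured marginal disease probability.

    The population expectation is computed exactly by enumerating all
    genotype x smoking combinations (3^K x 3 cells).
    """
    betas = np.array([math.log(s.oratio) for s in config.snps])
    beta_smoke = math.log(config.smoking_or)
    cells = []
    for dosages in itertools.product((0, 1, 2), repeat=len(config.snps)):
        prob_g = 1.0
        for snp, d in zip(config.snps, dosages):
            hwe = ((1 - snp.p) ** 2, 2 * snp.p * (1 - snp.p), snp.p**2)
            prob_g *= hwe[d]
        lin_g = float(np.dot(betas, dosages))
        for smoke, prob_s in enumerate(config.smoking_dist):
            cells.append((prob_g * prob_s, lin_g + beta_smoke * smoke))
    probs = np.array([c[0] for c in cells])
    lins = np.array([c[1] for c in cells])

    def marginal(alpha: float) -> float:
        return float(np.dot(probs, special.expit(alpha + lins))) - config.prevalence

    return optimize.brentq(marginal, -40.0, 20.0, xtol=1e-12)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a case-control cohort; deterministic given ``config.seed``.

    Raises :class:`SimulationError` naming the shortfall if the case or
    control quota cannot be filled within the draw budget (default budget:
    50x the expected number of draws needed).
    """
    rng = np.random.default_rng(config.seed)
    alpha = solve_intercept(config)
    betas = np.array([math.log(s.oratio) for s in config.snps])
    beta_smoke = math.log(config.smoking_or)
    freqs = np.array([s.p for s in config.snps])
    smoking_probs = np.array(config.smoking_dist)

    need_draws = max(
        config.n_cases / config.prevalence,
        config.n_controls / (1.0 - config.prevalence),
    )
    budget = config.max_draws if config.max_draws is not None else int(50 * need_draws) + 1000

    case_parts: list[tuple[np.ndarray, np.ndarray]] = []
    ctrl_parts: list[tuple[np.ndarray, np.ndarray]] = []
    n_case = n_ctrl = drawn = 0
    while (n_case < config.n_cases or n_ctrl < config.n_controls) and drawn < budget:
        m = min(_BATCH, budget - drawn)
        drawn += m
        dosages = rng.binomial(2, freqs, size=(m, len(freqs))).astype(float)
        smoking = rng.choice(3, size=m, p=smoking_probs)
        lin = alpha + dosages @ betas + beta_smoke * smoking
        disease = rng.random(m) < special.expit(lin)
        if n_case < config.n_cases:
            take = min(int(disease.sum()), config.n_cases - n_case)
            idx = np.flatnonzero(disease)[:take]
            case_parts.append((dosages[idx], smoking[idx]))
            n_case += take
        if n_ctrl < config.n_controls:
            take = min(int((~disease).sum()), config.n_controls - n_ctrl)
            idx = np.flatnonzero(~disease)[:take]
            ctrl_parts.append((dosages[idx], smoking[idx]))
            n_ctrl += take
    if n_case < config.n_cases or n_ctrl < config.n_controls:
        raise SimulationError(
            f"draw budget {budget} exhausted with {n_case}/{config.n_cases} cases "
            f"and {n_ctrl}/{config.n_controls} controls collected "
            f"(prevalence {config.prevalence})"
        )

    dos = np.vstack([p[0] for p in case_parts] + [p[0] for p in ctrl_parts])
    smoke = np.concatenate([p[1] for p in case_parts] + [p[1] for p in ctrl_parts])
    status = np.concatenate(
        [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    )
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan
    n = len(status)
    width = len(str(n))
    subject_id = [f"S{i:0{width}d}" for i in range(n)]
    return Cohort(
        subject_id=subject_id,
        status=status,
        smoking=smoke.astype(int),
        dosages=pd.DataFrame(dos, columns=[s.snp_id for s in config.snps]),
    )


def expand_counts(table: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Expand (category, case count, control count) rows to subject records.

    Returns a DataFrame with columns ``subject_id``, ``status``,
    ``category`` holding exactly the stated number of cases and controls per
    category, in deterministic order (cases first within each row).
    """
    ids: list[str] = []
    status: list[int] = []
    category: list[str] = []
    for label, n_case, n_ctrl in table:
        if n_case < 0 or n_ctrl < 0 or n_case != int(n_case) or n_ctrl != int(n_ctrl):
            raise GrsError(f"counts must be non-negative integers: {(label, n_case, n_ctrl)}")
        for st, count in ((1, int(n_case)), (0, int(n_ctrl))):
            start = len(ids)
            ids.extend(f"E{start + i:06d}" for i in range(count))
            status.extend([st] * count)
            category.extend([str(label)] * count)
    return pd.DataFrame({"subject_id": ids, "status": status, "category": category})


def expanded_scores(table: list[tuple[str, int, int]], score_map: dict[str, float]):
    """Expand count rows to paired (scores, status) arrays via a label map."""
    df = expand_counts(table)
    scores = df["category"].map(score_map)
    if scores.isna().any():
        missing = sorted(set(df["category"]) - set(score_map))
        raise GrsError(f"no score mapping for categories: {missing}")
    return scores.to_numpy(dtype=float), df["status"].to_numpy()
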