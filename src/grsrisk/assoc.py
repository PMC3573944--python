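"""Per-SNP quality control and association.

Hardy-Weinberg goodness of fit, allelic odds ratios with Woolf (log-normal)
confidence intervals, pairwise linkage disequilibrium (D') via EM haplotype
frequency estimation from unphased genotypes, and the liability-threshold
variance explained by a locus, ``2 p (1-p) (ln OR)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import Cohort, GrsError, SnpDef, genotype_counts

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class OrResult:
    """A 2x2 odds ratio with Woolf CI and z-test p-value."""

    oratio: float
    ci95: tuple[float, float]
    p: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    hwe_p: float
    allele_freq: float
    oratio: float
    ci95: tuple[float, float]
    p_assoc: float
    var_explained: float


def hwe_test(counts: tuple[int, int, int], method: str = "chisq") -> float:
    """Hardy-Weinberg goodness-of-fit p-value from (n_AA, n_AB, n_BB).

    Default is the 1-df asymptotic chi-square against expected counts from
    the observed allele frequency; ``method="exact"`` uses the conditional
    exact test (sum of heterozygote-count probabilities no larger than the
    observed one).  Monomorphic samples return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0:
        raise GrsError(f"genotype counts must be non-negative: {counts}")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise GrsError("cannot test HWE with zero subjects")
    p_hat = (n_ab + 2 * n_bb) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    if method == "chisq":
        q_hat = 1.0 - p_hat
        expected = np.array([n * q_hat**2, 2 * n * p_hat * q_hat, n * p_hat**2])
        observed = np.array([n_aa, n_ab, n_bb], dtype=float)
        statistic = ((observed - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(statistic, df=1))
    if method == "exact":
        return _hwe_exact(n_aa, n_ab, n_bb)
    raise GrsError(f"unknown HWE test method {method!r}")


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    # Conditional exact test: enumerate heterozygote counts at fixed allele
    # totals; p = sum of genotype-table probabilities <= observed probability.
    n = n_aa + n_ab + n_bb
    n_b = n_ab + 2 * n_bb  # minor-side allele total (either side works)
    n_b = min(n_b, 2 * n - n_b)
    obs_ab = n_ab
    het_values = range(n_b % 2, n_b + 1, 2)
    logprobs = {}
    for het in het_values:
        hom_rare = (n_b - het) // 2
        hom_common = n - het - hom_rare
        lp = (
            het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_common + 1)
            + math.lgamma(n_b + 1)
            + math.lgamma(2 * n - n_b + 1)
            - math.lgamma(2 * n + 1)
        )
        logprobs[het] = lp
    obs_lp = logprobs[obs_ab]
    total = sum(math.exp(lp) for lp in logprobs.values())
    p = sum(math.exp(lp) for lp in logprobs.values() if lp <= obs_lp + 1e-12)
    return min(1.0, p / total)


def two_by_two_or(a: float, b: float, c: float, d: float) -> OrResult:
    """Cross-product odds ratio ``(a*d)/(b*c)`` with Woolf 95% CI.

    Layout: a = exposed cases, b = exposed controls, c = reference cases,
    d = reference controls.  A zero cell triggers the Haldane-Anscombe 0.5
    correction (flagged on the result).
    """
    cells = [a, b, c, d]
    if min(cells) < 0:
        raise GrsError(f"2x2 cells must be non-negative: {cells}")
    corrected = False
    if min(cells) == 0:
        cells = [x + 0.5 for x in cells]
        corrected = True
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_ / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = log_or / se
    return OrResult(
        oratio=math.exp(log_or),
        ci95=(math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)),
        p=float(2 * stats.norm.sf(abs(z))),
        corrected=corrected,
    )


def allelic_or(
    case_counts: tuple[int, int, int], control_counts: tuple[int, int, int]
) -> OrResult:
    """Per-allele odds ratio from genotype counts collapsed to allele counts.

    Risk alleles = 2*n_BB + n_AB; the 2x2 table is risk/non-risk alleles in
    cases vs controls, with Woolf CI and a two-sided z p-value.
    """
    for counts in (case_counts, control_counts):
        if min(counts) < 0:
            raise GrsError(f"genotype counts must be non-negative: {counts}")
        if sum(counts) == 0:
            raise GrsError("empty genotype table")
    risk_case = 2 * case_counts[2] + case_counts[1]
    nonrisk_case = 2 * case_counts[0] + case_counts[1]
    risk_ctrl = 2 * control_counts[2] + control_counts[1]
    nonrisk_ctrl = 2 * control_counts[0] + control_counts[1]
    return two_by_two_or(risk_case, risk_ctrl, nonrisk_case, nonrisk_ctrl)


def variance_explained(p: float, oratio: float) -> float:
    """Liability-scale variance fraction of one locus: ``2 p (1-p) (ln OR)^2``.

    Returned as a fraction of unit liability variance (multiply by 100 to
    report percent).  Monomorphic loci explain 0 by continuity.
    """
    if not 0.0 <= p <= 1.0:
        raise GrsError(f"allele frequency must be in [0, 1], got {p}")
    if oratio <= 0:
        raise GrsError(f"odds ratio must be positive, got {oratio}")
    if p in (0.0, 1.0):
        return 0.0
    beta = math.log(oratio)
    return 2.0 * p * (1.0 - p) * beta * beta


def ld_dprime(
    dosages_a: np.ndarray, dosages_b: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> float:
    """Pairwise D' between two loci from unphased dosage vectors.

    Haplotype frequencies are estimated by EM over the 3x3 genotype table
    (only double heterozygotes are phase-ambiguous); D = p_AB - p_A p_B and
    D' = |D| / D_max with the usual frequency bound.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise GrsError("dosage vectors must be paired (equal length)")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise GrsError("need at least 2 complete genotype pairs for LD")
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((a == i) & (b == j))
    return ld_dprime_from_table(table, tol=tol, max_iter=max_iter)


def ld_dprime_from_table(
    table: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> float:
    """D' from a 3x3 genotype count table (rows: dosage at locus A)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_a = (table[1, :].sum() + 2 * table[2, :].sum()) / (2 * n)
    p_b = (table[:, 1].sum() + 2 * table[:, 2].sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise GrsError("D' undefined for a monomorphic locus")

    # haplotypes: x[1][1]=AB, x[1][0]=Ab, x[0][1]=aB, x[0][0]=ab
    x11 = p_a * p_b
    x10 = p_a * (1 - p_b)
    x01 = (1 - p_a) * p_b
    x00 = (1 - p_a) * (1 - p_b)
    n_hap = 2 * n
    # fixed haplotype contributions from unambiguous genotypes
    c11 = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    c10 = 2 * table[2, 0] + table[2, 1] + table[1, 0]
    c01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    c00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    dh = table[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    for _ in range(max_iter):
        denom = x11 * x00 + x10 * x01
        frac = 0.5 if denom == 0 else x11 * x00 / denom
        n11 = c11 + dh * frac
        n00 = c00 + dh * frac
        n10 = c10 + dh * (1 - frac)
        n01 = c01 + dh * (1 - frac)
        new = (n11 / n_hap, n10 / n_hap, n01 / n_hap, n00 / n_hap)
        delta = max(abs(new[0] - x11), abs(new[1] - x10), abs(new[2] - x01), abs(new[3] - x00))
        x11, x10, x01, x00 = new
        if delta < tol:
            break
    d = x11 - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max == 0:
        return 0.0
    return abs(d) / d_max


def snp_logistic_or(dosages: np.ndarray, status: np.ndarray) -> OrResult:
    """Log-additive per-SNP logistic fit (cross-check for the allelic OR)."""
    keep = ~np.isnan(np.asarray(dosages, dtype=float))
    x = sm.add_constant(np.asarray(dosages, dtype=float)[keep])
    fit = sm.Logit(np.asarray(status)[keep], x).fit(disp=0)
    beta, se = fit.params[1], fit.bse[1]
    return OrResult(
        oratio=math.exp(beta),
        ci95=(math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)),
        p=float(fit.pvalues[1]),
    )


def assoc_table(cohort: Cohort, snps: list[SnpDef], hwe_method: str = "chisq"):
    """Per-SNP association summary over a cohort.

    HWE and allele frequency are computed in controls; the OR is the crude
    allelic odds ratio; variance explained uses the control frequency and
    the estimated OR.
    """
    import pandas as pd

    rows = []
    for snp in snps:
        if snp.snp_id not in cohort.snp_ids:
            raise GrsError(f"SNP column {snp.snp_id!r} not present in cohort")
        dos = cohort.dosages[snp.snp_id].to_numpy(dtype=float)
        ctrl = dos[cohort.status == 0]
        case = dos[cohort.status == 1]
        ctrl_counts = genotype_counts(ctrl)
        case_counts = genotype_counts(case)
        hwe_p = hwe_test(ctrl_counts, method=hwe_method)
        freq = (2 * ctrl_counts[2] + ctrl_counts[1]) / (2 * sum(ctrl_counts))
        orr = allelic_or(case_counts, control_counts=ctrl_counts)
        rows.append(
            AssocResult(
                snp_id=snp.snp_id,
                hwe_p=hwe_p,
                allele_freq=freq,
                oratio=orr.oratio,
                ci95=orr.ci95,
                p_assoc=orr.p,
                var_explained=variance_explained(freq, orr.oratio),
            )
        )
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in rows],
            "hwe_p": [r.hwe_p for r in rows],
            "risk_allele_freq": [r.allele_freq for r in rows],
            "oratio": [r.oratio for r in rows],
            "ci_low": [r.ci95[0] for r in rows],
            "ci_high": [r.ci95[1] for r in rows],
            "p_assoc": [r.p_assoc for r in rows],
            "var_explained_pct": [100 * r.var_explained for r in rows],
        }
    )
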