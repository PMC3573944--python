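"""File formats, pipeline configuration and end-to-end orchestration.

Cohorts travel as tab-separated text with header
``subject_id  status  smoking  <snp_id>...`` and ``NA`` marking a missing
dosage.  The pipeline configuration is YAML with keys matching
:class:`PipelineConfig` fields.  ``run_pipeline`` writes six artifacts in a
fixed order, each stamped with the configuration hash and seed so that a
rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import evaluate as eval_mod
from . import grs as grs_mod
from . import model as model_mod
from . import synth as synth_mod
from .types import Cohort, GrsError, SchemaError, SimConfig, SnpDef

log = logging.getLogger("grsrisk")

SMOKING_CODES = {"never": 0, "light": 1, "heavy": 2}


@dataclass(frozen=True)
class PipelineConfig:
    snps: tuple[SnpDef, ...]
    seed: int
    smoking_coding: dict = field(default_factory=lambda: dict(SMOKING_CODES))
    grs_mode: str = "normalized"
    decile_reference: str = "controls"
    bootstrap_b: int = 1000
    split_fraction: float = 0.75
    out_dir: str = "grsrisk_out"
    # simulation block (used when no cohort file is supplied)
    n_cases: int = 2283
    n_controls: int = 2785
    prevalence: float = 0.01
    smoking_dist: tuple[float, float, float] = (0.5447, 0.1946, 0.2607)
    smoking_or: float = 1.67
    missing_rate: float = 0.005

    def sim_config(self) -> SimConfig:
        return SimConfig(
            snps=self.snps,
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            seed=self.seed,
            smoking_dist=self.smoking_dist,
            smoking_or=self.smoking_or,
            prevalence=self.prevalence,
            missing_rate=self.missing_rate,
        )

    def to_dict(self) -> dict:
        return {
            "snps": [
                {"snp_id": s.snp_id, "risk_allele": s.risk_allele, "p": s.p, "oratio": s.oratio}
                for s in self.snps
            ],
            "seed": self.seed,
            "smoking_coding": dict(self.smoking_coding),
            "grs_mode": self.grs_mode,
            "decile_reference": self.decile_reference,
            "bootstrap_b": self.bootstrap_b,
            "split_fraction": self.split_fraction,
            "out_dir": self.out_dir,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "prevalence": self.prevalence,
            "smoking_dist": list(self.smoking_dist),
            "smoking_or": self.smoking_or,
            "missing_rate": self.missing_rate,
        }

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where artifacts land does not affect their content
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "snps" not in raw or "seed" not in raw:
        raise GrsError(f"{path}: config must define at least 'snps' and 'seed'")
    snps = tuple(SnpDef(**s) for s in raw.pop("snps"))
    if "smoking_dist" in raw:
        raw["smoking_dist"] = tuple(raw["smoking_dist"])
    return PipelineConfig(snps=snps, **raw)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    cols = ["subject_id", "status", "smoking", *cohort.snp_ids]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        dos = cohort.dosages.to_numpy()
        for i, sid in enumerate(cohort.subject_id):
            row = [sid, str(int(cohort.status[i])), str(int(cohort.smoking[i]))]
            row += ["NA" if np.isnan(v) else str(int(v)) for v in dos[i]]
            fh.write("\t".join(row) + "\n")


def read_cohort(path: str | Path) -> Cohort:
    """Parse a cohort TSV; schema violations name file, line and column."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["subject_id", "status", "smoking"]:
            raise SchemaError(
                f"{path}:1: header must start with 'subject_id\\tstatus\\tsmoking', got {header[:3]}"
            )
        snp_ids = header[3:]
        ids, status, smoking = [], [], []
        rows = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise SchemaError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
            sid = parts[0]
            if sid in seen:
                raise SchemaError(f"{path}:{lineno}: duplicate subject id {sid!r}")
            seen.add(sid)
            if parts[1] not in ("0", "1"):
                raise SchemaError(f"{path}:{lineno}: column 'status' must be 0 or 1, got {parts[1]!r}")
            if parts[2] not in ("0", "1", "2"):
                raise SchemaError(f"{path}:{lineno}: column 'smoking' must be 0/1/2, got {parts[2]!r}")
            dos = []
            for col, val in zip(snp_ids, parts[3:]):
                if val == "NA":
                    dos.append(np.nan)
                elif val in ("0", "1", "2"):
                    dos.append(float(val))
                else:
                    raise SchemaError(
                        f"{path}:{lineno}: column {col!r} dosage must be 0/1/2/NA, got {val!r}"
                    )
            ids.append(sid)
            status.append(int(parts[1]))
            smoking.append(int(parts[2]))
            rows.append(dos)
    dosages = pd.DataFrame(rows, columns=snp_ids, dtype=float) if snp_ids else pd.DataFrame(index=range(len(ids)))
    return Cohort(subject_id=ids, status=np.array(status), smoking=np.array(smoking), dosages=dosages)


def _fmt(v) -> str:
    if isinstance(v, float):
        return format(v, ".10g")
    return str(v)


def _write_table(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(stamp)
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _write_kv(items: list[tuple[str, object]], path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(stamp)
        for k, v in items:
            fh.write(f"{k}\t{_fmt(v)}\n")


def run_pipeline(config: PipelineConfig, cohort_path: str | Path | None = None) -> dict:
    """Run association -> GRS -> model -> evaluation, writing six artifacts.

    Returns a dict of artifact paths plus the in-memory results.  If
    ``cohort_path`` is None a cohort is simulated from the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_sha256={config.hash()}\tseed={config.seed}\n"

    if cohort_path is None:
        log.info("simulating cohort: %d cases / %d controls", config.n_cases, config.n_controls)
        cohort = synth_mod.simulate_cohort(config.sim_config())
    else:
        cohort = read_cohort(cohort_path)
    missing = [s.snp_id for s in config.snps if s.snp_id not in cohort.snp_ids]
    if missing:
        raise SchemaError(f"cohort lacks configured SNP column(s): {missing}")

    log.info("grs_mode=%s decile_reference=%s ci_method=woolf", config.grs_mode, config.decile_reference)

    # 1. association table
    assoc_df = assoc_mod.assoc_table(cohort, list(config.snps))
    _write_table(assoc_df, out / "assoc.tsv", stamp)

    # 2. SNP weights
    weights = grs_mod.weights_for_panel(config.snps, mode=config.grs_mode)
    wdf = pd.DataFrame(
        {
            "snp_id": [w.snp_id for w in weights],
            "u": [w.u for w in weights],
            "score_dos0": [w.genotype_scores[0] for w in weights],
            "score_dos1": [w.genotype_scores[1] for w in weights],
            "score_dos2": [w.genotype_scores[2] for w in weights],
        }
    )
    _write_table(wdf, out / "weights.tsv", stamp)

    # 3. scores
    scores = grs_mod.score_cohort(
        cohort, config.snps, mode=config.grs_mode, decile_reference=config.decile_reference
    )
    _write_table(scores.to_frame(), out / "scores.tsv", stamp)

    # 4. category OR tables
    tables = []
    for name, cats, order in (
        ("cgrs_band", scores.cgrs_band, list(grs_mod.CGRS_BANDS)),
        ("wgrs_decile", scores.wgrs_decile.astype(str), [str(i) for i in range(10)]),
        ("smoking", cohort.smoking.astype(str), ["0", "1", "2"]),
    ):
        order_present = [c for c in order if c in set(map(str, cats))]
        # lowest occupied category is the reference (discrete scores can
        # leave the nominal bottom decile empty under the ties-to-upper rule)
        t = model_mod.category_or_table(
            cohort.status, cats, order_present[0], order=order_present
        )
        t.insert(0, "variable", name)
        tables.append(t)
    _write_table(pd.concat(tables, ignore_index=True), out / "category_or.tsv", stamp)

    # 5. model fit
    fit = model_mod.fit_risk_model(cohort, scores)
    kv = [("converged", fit.converged)]
    for i, nm in enumerate(fit.names):
        kv += [
            (f"coef_{nm}", fit.coefficients[i]),
            (f"se_{nm}", fit.bse[i]),
            (f"or_{nm}", float(np.exp(fit.coefficients[i]))),
            (f"ci_low_{nm}", float(np.exp(fit.ci95[i][0]))),
            (f"ci_high_{nm}", float(np.exp(fit.ci95[i][1]))),
            (f"p_{nm}", fit.pvalues[i]),
        ]
    _write_kv(kv, out / "model.tsv", stamp)

    # 6. evaluation report
    y = cohort.status
    full_scores = fit.fitted_probabilities
    auc_wgrs = eval_mod.auc_rank(scores.wgrs, y, n_boot=config.bootstrap_b, seed=config.seed)
    auc_cgrs = eval_mod.auc_rank(scores.cgrs, y, n_boot=config.bootstrap_b, seed=config.seed)
    auc_smoke = eval_mod.auc_rank(cohort.smoking, y, n_boot=config.bootstrap_b, seed=config.seed)
    auc_full = eval_mod.auc_rank(full_scores, y, n_boot=config.bootstrap_b, seed=config.seed)
    X = np.column_stack([scores.wgrs_decile, cohort.smoking]).astype(float)
    proc = model_mod.logistic_procedure()
    boc = eval_mod.bootstrap_optimism(X, y, proc, n_boot=config.bootstrap_b, seed=config.seed)
    c_train, c_test = eval_mod.split_validate(
        X, y, proc, train_fraction=config.split_fraction, seed=config.seed
    )
    hl_stat, hl_p = eval_mod.hosmer_lemeshow(full_scores, y)
    cut = eval_mod.youden_cutoff_metrics(full_scores, y)
    delta, p_delta = eval_mod.compare_auc(
        scores.wgrs, scores.cgrs, y, n_boot=config.bootstrap_b, seed=config.seed
    )
    report = [
        ("auc_wgrs", auc_wgrs.auc), ("auc_wgrs_lo", auc_wgrs.ci95[0]), ("auc_wgrs_hi", auc_wgrs.ci95[1]),
        ("auc_cgrs", auc_cgrs.auc),
        ("auc_smoking", auc_smoke.auc),
        ("auc_full", auc_full.auc), ("auc_full_lo", auc_full.ci95[0]), ("auc_full_hi", auc_full.ci95[1]),
        ("auc_full_boc", boc.auc_corrected), ("optimism", boc.optimism),
        ("delta_auc_wgrs_cgrs", delta), ("p_delta_auc", p_delta),
        ("c_train", c_train), ("c_test", c_test),
        ("hl_stat", hl_stat), ("hl_p", hl_p),
        ("cutoff", cut.cutoff), ("sensitivity", cut.sensitivity), ("specificity", cut.specificity),
        ("accuracy", cut.accuracy), ("ppv", cut.ppv), ("npv", cut.npv),
    ]
    _write_kv(report, out / "evaluation.tsv", stamp)

    return {
        "out_dir": out,
        "artifacts": [out / f for f in (
            "assoc.tsv", "weights.tsv", "scores.tsv", "category_or.tsv", "model.tsv", "evaluation.tsv"
        )],
        "cohort": cohort,
        "scores": scores,
        "fit": fit,
        "report": dict(report),
    }
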