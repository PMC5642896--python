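"""End-to-end orchestration: simulate -> qc -> call-nat2 -> assoc -> validity -> roc.

Each stage writes plain TSV outputs into the run directory; a manifest
records the package version, the configuration hash, the seed, per-stage
timing and collected warnings, so a run is reproducible from its directory
alone.  When a manifest from a previous run with the same configuration
hash is present, completed stages whose outputs still exist are reused.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    default_candidate_panel,
    run_association,
    clinical_covariate_tests,
)
from .io import read_sample_sheet, read_vcf, write_sample_sheet, write_vcf
from .nat2 import (
    TAG_SNP,
    calls_to_frame,
    classify_by_tag,
    infer_acetylator,
    risk_allele_freq_by_grade,
    tag_concordance,
    tags_to_frame,
)
from .qc import run_qc
from .roc import compare_models
from .sim import default_config, generate_cohort
from .validity import validity_report

ALL_STAGES = ("simulate", "qc", "call-nat2", "assoc", "validity", "roc")


@dataclass
class RunConfig:
    """Pipeline configuration (defaults reproduce the packaged demo run)."""

    out_dir: str = "pgx_run"
    seed: int = 2017
    stages: tuple[str, ...] = ALL_STAGES
    vcf: str | None = None             # use an existing VCF instead of simulating
    sample_sheet: str | None = None
    sample_call_rate: float = 0.95
    variant_call_rate: float = 0.95
    hwe_stratum: str = "Chinese"
    hwe_alpha: float = 1e-6
    n_pcs: int = 2
    prevalence: float = 0.10
    sweep: tuple[float, float, float] = (0.05, 0.20, 0.01)
    models: tuple[str, ...] = ("additive", "dominant", "recessive")
    n_background_snps: int = 300
    missing_rate: float = 0.005

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .io import read_yaml

        raw = read_yaml(path) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "models", "sweep"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (the output path is excluded,
        so the same analysis into two directories shares one hash)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sweep_grid(spec: tuple[float, float, float]) -> list[float]:
    lo, hi, step = spec
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(n + 1)]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_hash") == chash:
                previous = old.get("stages", {})
        except (json.JSONDecodeError, OSError):
            previous = {}
    manifest = {
        "package": "pgxvalidity",
        "version": __version__,
        "seed": config.seed,
        "config_hash": chash,
        "config": asdict(config),
        "stages": {},
        "warnings": [],
    }

    bad = set(config.stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")

    def stage_done(name: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][name] = {
            "outputs": [str(p.relative_to(out)) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def reusable(name: str) -> bool:
        info = previous.get(name)
        if not info:
            return False
        ok = all((out / f).exists() for f in info.get("outputs", []))
        if ok:
            manifest["stages"][name] = dict(info, reused=True)
        return ok

    # -- simulate -----------------------------------------------------------
    vcf_path = Path(config.vcf) if config.vcf else out / "cohort.vcf"
    sheet_path = Path(config.sample_sheet) if config.sample_sheet else out / "samples.tsv"
    if "simulate" in config.stages and config.vcf is None:
        if not reusable("simulate"):
            t0 = time.perf_counter()
            sim_cfg = default_config(
                seed=config.seed,
                n_background_snps=config.n_background_snps,
                missing_rate=config.missing_rate,
            )
            cohort = generate_cohort(sim_cfg)
            write_vcf(cohort.genotypes, vcf_path)
            write_sample_sheet(cohort.samples, sheet_path)
            stage_done("simulate", [vcf_path, sheet_path], t0)
    if not vcf_path.exists():
        raise FileNotFoundError(f"stage qc: genotype VCF not found: {vcf_path}")
    if not sheet_path.exists():
        raise FileNotFoundError(f"stage qc: sample sheet not found: {sheet_path}")

    matrix = read_vcf(vcf_path)
    samples = read_sample_sheet(sheet_path)

    # -- qc -----------------------------------------------------------------
    retained_vcf = out / "retained.vcf"
    pca_path = out / "pca.tsv"
    if "qc" in config.stages:
        t0 = time.perf_counter()
        matrix, report, pca_res = run_qc(
            matrix,
            samples,
            sample_call_rate=config.sample_call_rate,
            variant_call_rate=config.variant_call_rate,
            hwe_stratum=config.hwe_stratum,
            hwe_alpha=config.hwe_alpha,
            n_pcs=max(config.n_pcs, 2),
        )
        write_vcf(matrix, retained_vcf)
        report.samples_frame().to_csv(out / "qc_removed_samples.tsv", sep="\t", index=False)
        report.variants_frame().to_csv(out / "qc_removed_variants.tsv", sep="\t", index=False)
        pca_res.coordinates.rename_axis("sample_id").to_csv(pca_path, sep="\t")
        stage_done(
            "qc",
            [retained_vcf, out / "qc_removed_samples.tsv", out / "qc_removed_variants.tsv", pca_path],
            t0,
        )
        kept = set(matrix.sample_ids)
        samples = [s for s in samples if s.sample_id in kept]
    pcs = (
        pd.read_csv(pca_path, sep="\t", index_col="sample_id")
        if pca_path.exists()
        else None
    )

    # -- call-nat2 ----------------------------------------------------------
    calls_path = out / "nat2_calls.tsv"
    if "call-nat2" in config.stages:
        t0 = time.perf_counter()
        calls = infer_acetylator(matrix)
        tags = classify_by_tag(matrix, TAG_SNP)
        cf = calls_to_frame(calls).merge(tags_to_frame(tags), on="sample_id")
        cf.to_csv(calls_path, sep="\t", index=False)
        frac, xtab = tag_concordance(calls, tags)
        xtab.to_csv(out / "tag_concordance.tsv", sep="\t")
        (out / "tag_concordance.txt").write_text(
            f"tag={TAG_SNP}\nconcordance={frac:.4f}\n"
        )
        exposure = {c.sample_id: c.exposure for c in calls}
        risk_allele_freq_by_grade(matrix, samples, exposure=exposure).to_csv(
            out / "risk_freq_by_grade.tsv", sep="\t", index=False
        )
        n_imputed = sum(1 for c in calls if c.imputed_snps)
        if n_imputed:
            manifest["warnings"].append(
                f"call-nat2: {n_imputed} samples with imputed panel SNPs"
            )
        stage_done(
            "call-nat2",
            [calls_path, out / "tag_concordance.tsv", out / "risk_freq_by_grade.tsv"],
            t0,
        )

    # -- assoc --------------------------------------------------------------
    if "assoc" in config.stages:
        t0 = time.perf_counter()
        assoc = run_association(
            matrix,
            samples,
            pcs=pcs,
            panel=default_candidate_panel(),
            models=config.models,
            n_pcs=config.n_pcs,
            seed=config.seed,
        )
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)
        clinical_covariate_tests(samples).to_csv(
            out / "covariate_tests.tsv", sep="\t", index=False
        )
        stage_done("assoc", [out / "association.tsv", out / "covariate_tests.tsv"], t0)

    # -- validity -----------------------------------------------------------
    if "validity" in config.stages:
        t0 = time.perf_counter()
        if not calls_path.exists():
            raise FileNotFoundError("stage validity: nat2_calls.tsv missing (run call-nat2)")
        cf = pd.read_csv(calls_path, sep="\t")
        exposures = {
            "SA": dict(zip(cf["sample_id"], cf["exposure"].map(_to_flag))),
            f"{TAG_SNP}_AA": dict(zip(cf["sample_id"], cf["predicted_sa"].map(_to_flag))),
        }
        if "rs1041983" in matrix.variant_ids:
            dos = matrix.dosages("rs1041983")
            exposures["rs1041983_hom"] = {
                s: (None if np.isnan(d) else bool(d == 2))
                for s, d in zip(matrix.sample_ids, dos)
            }
        rep = validity_report(
            exposures, samples, prevalence=config.prevalence,
            sweep_grid=_sweep_grid(config.sweep),
        )
        rep.to_csv(out / "validity.tsv", sep="\t", index=False)
        stage_done("validity", [out / "validity.tsv"], t0)

    # -- roc ----------------------------------------------------------------
    if "roc" in config.stages:
        t0 = time.perf_counter()
        cf = pd.read_csv(calls_path, sep="\t") if calls_path.exists() else None
        if cf is None:
            raise FileNotFoundError("stage roc: nat2_calls.tsv missing (run call-nat2)")
        genetic = {
            "SA": pd.Series(
                cf["exposure"].map(_to_flag).map(lambda v: np.nan if v is None else float(v)).to_numpy(),
                index=cf["sample_id"],
            )
        }
        for snp in ("rs1495741", "rs1041983"):
            if snp in matrix.variant_ids:
                genetic[snp] = pd.Series(matrix.dosages(snp), index=matrix.sample_ids)
        models, comparison = compare_models(samples, genetic)
        comparison.to_csv(out / "roc_comparison.tsv", sep="\t", index=False)
        scores = pd.concat(
            {name: m.scores for name, m in models.items()}, axis=1
        )
        scores.rename_axis("sample_id").to_csv(out / "roc_scores.tsv", sep="\t")
        for name, m in models.items():
            if m.separation:
                manifest["warnings"].append(f"roc: separation in model {name}")
        stage_done("roc", [out / "roc_comparison.tsv", out / "roc_scores.tsv"], t0)

    _write_summary(out, manifest)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _to_flag(v):
    if pd.isna(v):
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() == "true"


def _write_summary(out: Path, manifest: dict) -> None:
    lines = [
        f"pgxvalidity {manifest['version']} run summary",
        f"seed: {manifest['seed']}   config hash: {manifest['config_hash']}",
        "",
    ]
    assoc_path = out / "association.tsv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        est = assoc[assoc["estimable"] == True]  # noqa: E712
        lines.append(f"association: {len(assoc)} tests, {len(est)} estimable")
        if not est.empty:
            top = est.nsmallest(3, "p")
            for r in top.itertuples(index=False):
                lines.append(
                    f"  {r.snp} [{r.model}] OR={r.OR:.2f} "
                    f"({r.ci_low:.2f}-{r.ci_high:.2f}) p={r.p:.3g} adj={r.p_adjusted:.3g}"
                )
    val_path = out / "validity.tsv"
    if val_path.exists():
        val = pd.read_csv(val_path, sep="\t")
        at_main = val[val["prevalence"] == val["prevalence"].iloc[0]]
        lines.append("")
        lines.append("clinical validity (at the assumed prevalence):")
        for r in at_main.itertuples(index=False):
            nnt_s = f"{r.nnt:.2f}" if pd.notna(r.nnt) else "undefined"
            lines.append(
                f"  {r.exposure}: sens={r.sensitivity:.3f} spec={r.specificity:.3f} "
                f"PPV={r.ppv:.3f} NPV={r.npv:.3f} NNT={nnt_s}"
            )
    roc_path = out / "roc_comparison.tsv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path, sep="\t")
        lines.append("")
        lines.append("ROC comparisons vs clinical model:")
        for r in roc.itertuples(index=False):
            lines.append(
                f"  {r.model_a}: AUC={r.auc_a:.3f} vs {r.auc_b:.3f} p={r.p:.3f}"
            )
    if manifest["warnings"]:
        lines.append("")
        lines.append("warnings:")
        lines.extend(f"  - {w}" for w in manifest["warnings"])
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
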