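"""Configured, reproducible end-to-end runs.

A :class:`RunConfig` (YAML-serializable) names the tissues and phases to
analyse, the preprocessing settings per phase (exclusion intervals; UV
scaling for aqueous models, Pareto for lipophilic), the validation settings
and the master seed. :func:`run_pipeline` simulates (or loads) each
tissue × phase cohort, preprocesses it, fits and validates the PLS-DA,
computes the univariate table and the quantitative profiles, writes every
intermediate as delimited text/JSON under the output directory, and returns
a manifest with per-stage checksums; re-running with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    CohortDesign,
    QuantCalibration,
    align_rspa,
    analyze_windows,
    build_default_library,
    build_matrix,
    default_exclusions,
    default_windows,
    exclude_regions,
    fatty_acid_fractions,
    fit_plsda,
    fold_change_matrix,
    integrate_windows,
    methylamine_levels,
    normalize_total_area,
    reference_axis,
    scale_columns,
    simulate_cohort,
    total_fa_concentration,
    validate,
)
from .preprocess import ExclusionSet

__all__ = ["RunConfig", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)

SCALING_BY_PHASE = {"aqueous": "uv", "lipophilic": "pareto"}
VALID_SCALINGS = ("center", "pareto", "uv")


@dataclass
class RunConfig:
    """Everything a run needs; defaults mirror the standard workflow."""

    tissues: list[str] = field(default_factory=lambda: ["heart", "kidney", "muscle"])
    phases: list[str] = field(default_factory=lambda: ["aqueous", "lipophilic"])
    scaling: dict[str, str] = field(default_factory=lambda: dict(SCALING_BY_PHASE))
    exclusions: dict[str, list] | None = None   # per phase [(lo, hi), ...]
    n_SC: int = 12
    n_HF: int = 11
    n_points: int = 16384
    n_components: int = 2
    cv_folds: int = 7
    n_permutations: int = 500
    mccv_blocks: int = 7
    mccv_iterations: int = 500
    auroc_k: int = 5
    auroc_permutations: int = 100
    rf_estimators: int = 500
    seed: int = 0
    out_dir: str = "nmrmet_run"
    bucket_ppm: float | None = None
    tissue_weight_g: float = 0.15

    def validate_config(self) -> None:
        for phase in self.phases:
            if phase not in ("aqueous", "lipophilic"):
                raise ValueError(f"unknown phase {phase!r}")
            mode = self.scaling.get(phase)
            if mode not in VALID_SCALINGS:
                raise ValueError(f"unknown scaling mode {mode!r} for phase {phase}")
        for t in self.tissues:
            if t not in ("heart", "kidney", "muscle"):
                raise ValueError(f"unknown tissue {t!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    def exclusion_set(self, phase: str) -> ExclusionSet:
        if self.exclusions and phase in self.exclusions:
            return ExclusionSet(self.exclusions[phase])
        return default_exclusions(phase)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _analysis_seed(master_seed: int, tissue: str, phase: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{tissue}:{phase}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_one(config: RunConfig, tissue: str, phase: str, out: Path) -> dict:
    """Simulate, preprocess, model, test and quantify one tissue × phase."""
    t0 = time.time()
    seed = _analysis_seed(config.seed, tissue, phase)
    n_hf = config.n_HF - 1 if tissue == "heart" else config.n_HF
    design = CohortDesign(
        phase=phase, n_SC=config.n_SC, n_HF=n_hf, tissue=tissue,
        n_points=config.n_points, tissue_weight_g=config.tissue_weight_g, seed=seed,
    )
    library = build_default_library(phase)
    spectra, gt = simulate_cohort(design, library, seed=seed)

    referenced = [reference_axis(s) for s in spectra]
    m = build_matrix(referenced, axis=design.axis, bucket_ppm=config.bucket_ppm)
    m = exclude_regions(m, config.exclusion_set(phase))
    m = align_rspa(m)
    m = normalize_total_area(m)

    windows = [
        w for w in default_windows(phase)
        if not config.exclusion_set(phase).contains(
            np.array([(w.lo_ppm + w.hi_ppm) / 2])).any()
    ]
    integrals = integrate_windows(m, windows)
    uva = analyze_windows(integrals, m.groups)

    scaled = scale_columns(m, config.scaling[phase])
    model = fit_plsda(scaled, config.n_components)
    min_class = int(min((scaled.y == 0).sum(), (scaled.y == 1).sum()))
    auroc_k = min(config.auroc_k, min_class)
    if auroc_k < config.auroc_k:
        log.info("%s/%s: AUROC folds reduced to %d (smallest class size)",
                 tissue, phase, auroc_k)
    report = validate(
        scaled.data.to_numpy(), y=scaled.y, A=config.n_components,
        n_folds=config.cv_folds, n_perm=config.n_permutations,
        mccv_blocks=config.mccv_blocks, mccv_iter=config.mccv_iterations,
        auroc_k=auroc_k, auroc_perms=config.auroc_permutations,
        rf_estimators=config.rf_estimators, seed=seed,
    )

    quant_rows = []
    cal_cls = QuantCalibration.tsp if phase == "aqueous" else QuantCalibration.pyrazine
    cal = cal_cls(tissue_weight_g=config.tissue_weight_g)
    for s in spectra:
        sid = s.meta["sample_id"]
        if phase == "lipophilic":
            prof = fatty_acid_fractions(s, design.linewidth_ppm)
            total = total_fa_concentration(s, cal, design.linewidth_ppm)
            quant_rows.append({
                "sample_id": sid, "group": s.meta["group"],
                "pct_SFA": prof.pct_SFA, "pct_MUFA": prof.pct_MUFA,
                "pct_PUFA": prof.pct_PUFA, "pct_omega3": prof.pct_omega3,
                "total_FA_umol_g": total,
            })
        else:
            mp = methylamine_levels(s, cal, design.linewidth_ppm)
            quant_rows.append({
                "sample_id": sid, "group": s.meta["group"],
                "TMA_umol_g": mp.TMA_umol_g, "DMA_umol_g": mp.DMA_umol_g,
                "TMAO_umol_g": mp.TMAO_umol_g,
            })
    quant = pd.DataFrame(quant_rows).set_index("sample_id")

    tag = f"{tissue}_{phase}"
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    m.to_tsv(out / f"{tag}_matrix.tsv")
    files["matrix"] = f"{tag}_matrix.tsv"
    integrals.to_csv(out / f"{tag}_integrals.tsv", sep="\t")
    files["integrals"] = f"{tag}_integrals.tsv"
    uva.to_csv(out / f"{tag}_univariate.tsv", sep="\t")
    files["univariate"] = f"{tag}_univariate.tsv"
    quant.to_csv(out / f"{tag}_quant.tsv", sep="\t")
    files["quant"] = f"{tag}_quant.tsv"
    report.to_json(out / f"{tag}_validation.json")
    files["validation"] = f"{tag}_validation.json"
    lw = model.scaled_loading_weights()
    lw.to_csv(out / f"{tag}_loadings.tsv", sep="\t")
    files["loadings"] = f"{tag}_loadings.tsv"

    elapsed = time.time() - t0
    log.info("stage %s: seed=%d n=%d wall=%.1fs", tag, seed,
             len(spectra), elapsed)
    return {
        "tissue": tissue, "phase": phase, "seed": seed,
        "n_samples": len(spectra),
        "files": files,
        "checksums": {k: _checksum(out / v) for k, v in files.items()},
        "wall_s": round(elapsed, 2),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all tissue × phase analyses; write and return the manifest."""
    config.validate_config()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analyses = []
    for tissue in config.tissues:
        for phase in config.phases:
            try:
                analyses.append(run_one(config, tissue, phase, out))
            except Exception as exc:
                raise RuntimeError(f"stage {tissue}/{phase} failed: {exc}") from exc
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "analyses": analyses,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _format_table_one(uva: pd.DataFrame) -> pd.DataFrame:
    """Render a univariate table with ES(err), p and FDR columns.

    Non-significant FDR-adjusted p-values are shown as ``ns``.
    """
    def fmt_p(p):
        if not np.isfinite(p):
            return "nd"
        return "<0.001" if p < 0.001 else f"{p:.3f}"

    rows = []
    for name, r in uva.iterrows():
        mark = " ^n" if r["test_used"] == "mann_whitney" else ""
        fdr = r["p_fdr"]
        rows.append({
            "signal": name,
            "ES (ES Error)": f"{r['ES']:.2f} ({r['ES_err']:.2f})",
            "p-value": fmt_p(r["p_raw"]) + mark,
            "FDR adjusted p-value": fmt_p(fdr)
            if np.isfinite(fdr) and fdr < 0.05 else "ns",
        })
    return pd.DataFrame(rows).set_index("signal")


def make_report(manifest: dict, out_dir: str | Path | None = None) -> str:
    """Render the run's tables and validation summaries as one text document."""
    out = Path(out_dir if out_dir is not None else manifest["config"]["out_dir"])
    lines = ["# nmrmet run report", "",
             f"seed: {manifest['seed']}  version: {manifest['version']}", ""]
    results_by_tissue: dict[str, dict[str, pd.DataFrame]] = {}
    for a in manifest["analyses"]:
        tag = f"{a['tissue']} {a['phase']}"
        lines.append(f"## {tag}")
        uva_path = out / a["files"]["univariate"]
        if not uva_path.exists():
            lines.append("(missing univariate results)")
            continue
        uva = pd.read_csv(uva_path, sep="\t", index_col=0)
        if len(uva):
            lines.append(_format_table_one(uva).to_string())
        else:
            lines.append("(no integrated signals)")
        val_path = out / a["files"]["validation"]
        if val_path.exists():
            v = json.loads(val_path.read_text())
            mccv = v.get("mccv", {})
            auroc = v.get("auroc", {})
            lines.append(
                f"R2Y={v['r2y']:.2f} Q2={v['q2']:.2f} perm_p={v['perm_p']:.3g} "
                f"Q2_median={mccv.get('q2_median', float('nan')):.2f} "
                f"CR={mccv.get('classification_rate', float('nan')):.2f} "
                f"sens={mccv.get('sensitivity', float('nan')):.2f} "
                f"spec={mccv.get('specificity', float('nan')):.2f} "
                f"AUROC={auroc.get('mean_auroc', float('nan')):.2f}"
            )
        lines.append("")
        results_by_tissue.setdefault(a["phase"], {})[a["tissue"]] = uva
    for phase, per_tissue in results_by_tissue.items():
        lines.append(f"## fold-change heatmap table ({phase})")
        lines.append(fold_change_matrix(per_tissue).to_string())
        lines.append("")
    doc = "\n".join(lines)
    (out / "report.md").write_text(doc)
    return doc
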