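"""End-to-end orchestration: simulate -> overlay -> annotate -> statistics.

``run_pipeline`` drives the whole analysis from a single config and seed,
writing every stage output as TSV plus a JSON manifest (config hash,
version, per-stage row counts) into a run directory; ``report`` renders
plain-data summaries (vulnerability bars, regression tables, DE heatmap
tables) from a completed run. A single seed governs all stochastic stages
through per-stage child streams, so each stage is reproducible on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexp import deg_consensus, glm_vs_hsnca, nb_wald_de, pseudobulk_aggregate, \
    stratify_by_percentile, three_way_de
from .expression import lognormalize, mean_expression, scale_profiles, annotate_by_reference
from .io_formats import SampleBundle, write_bundle
from .pathology_overlay import call_psyn, calls_to_frame, map_centroids, threshold_inclusions
from .synthetic_data import GroundTruth, default_config, generate_tissue
from .vulnerability import anova_tukey, regress_vulnerability, vulnerability_table

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "n_per_group", "threshold", "min_area_px", "expand_um", "scale_factor",
    "min_cells", "fdr_alpha", "exn_types", "run_de", "run_glm", "group_by_sex",
    "noise_sd", "perturb_affine",
}


@dataclass
class RunConfig:
    """Validated pipeline parameters (unknown keys are rejected on load)."""

    seed: int = 0
    n_per_group: int = 1
    threshold: float = 100.0  # IF intensity threshold, fixed across samples
    min_area_px: int = 4
    expand_um: float = 5.0
    scale_factor: float = 1e4
    min_cells: int = 10
    fdr_alpha: float = 0.05
    exn_types: list[str] | None = None
    run_de: bool = True
    run_glm: bool = True
    group_by_sex: bool = False
    noise_sd: float = 5.0
    perturb_affine: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.threshold <= 0 or cfg.min_area_px < 0 or cfg.expand_um < 0:
            raise ValueError("threshold/min_area_px/expand_um out of range")
        if not (0 < cfg.fdr_alpha < 1):
            raise ValueError("fdr_alpha must be in (0, 1)")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunResult:
    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _reference_profiles(bundles, expr_by_sample, config: RunConfig) -> pd.DataFrame:
    """Scaled per-type profiles from ground-truth-typed non-tg cells.

    Stands in for an external reference atlas: per-type mean expression is
    computed from non-transgenic samples and scaled per gene across types.
    """
    frames = []
    for b in bundles:
        if b.genotype != "non_tg":
            continue
        expr = expr_by_sample[b.sample_id]
        frames.append(mean_expression(expr, b.cells["true_type"].to_numpy()))
    return scale_profiles(pd.concat(frames).groupby(level=0).mean())


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Run the full synthetic-data analysis and write a run directory."""
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}

    def record(stage: str, t0: float, n_rows: int) -> None:
        stages[stage] = {"seconds": round(time.time() - t0, 2), "rows": n_rows}
        log.info("stage %-14s %6.1fs %8d rows", stage, time.time() - t0, n_rows)

    # --- simulate -----------------------------------------------------
    t0 = time.time()
    sim = default_config(
        n_per_group=config.n_per_group,
        expand_um=config.expand_um,
        scale_factor=config.scale_factor,
    )
    if config.noise_sd != sim.imaging.noise_sd:
        from dataclasses import replace
        sim = replace(sim, imaging=replace(sim.imaging, noise_sd=config.noise_sd))
    bundles, truth = generate_tissue(
        sim, seed=config.seed, perturb_affine=config.perturb_affine
    )
    truth_by_cell = truth.cells.set_index("cell_id")
    record("simulate", t0, len(truth.cells))

    # --- overlay: threshold, map, assign ------------------------------
    t0 = time.time()
    all_calls = []
    for b in bundles:
        inc = threshold_inclusions(b.image, config.threshold, config.min_area_px)
        inc = map_centroids(inc, b.affine)
        calls = call_psyn(b.cells, b.polygons, inc)
        all_calls.append(calls_to_frame(calls))
    calls_df = pd.concat(all_calls, ignore_index=True)
    tables["psyn_calls"] = calls_df
    record("overlay", t0, len(calls_df))

    # --- normalize + annotate ----------------------------------------
    t0 = time.time()
    expr_by_sample = {}
    meta_frames = []
    for b in bundles:
        keep = b.counts.library_sizes() > 0
        if not keep.all():  # drop cells with no detected genes
            log.info("%s: %d zero-count cells filtered", b.sample_id, int((~keep).sum()))
        kept_ids = [cid for cid, k in zip(b.counts.cell_ids, keep) if k]
        from .io_formats import CountMatrix
        import scipy.sparse as sp
        cm = CountMatrix(
            counts=sp.csr_matrix(b.counts.counts[np.flatnonzero(keep)]),
            cell_ids=kept_ids, gene_names=b.counts.gene_names, panel=b.counts.panel,
        )
        b.counts = cm
        b.cells = b.cells[b.cells["cell_id"].isin(kept_ids)].reset_index(drop=True)
        b.cells["true_type"] = truth_by_cell.loc[b.cells["cell_id"], "cell_type"].to_numpy()
        expr_by_sample[b.sample_id] = lognormalize(cm, config.scale_factor)

    reference = _reference_profiles(bundles, expr_by_sample, config)
    marker_genes = [g for g, p in zip(bundles[0].counts.gene_names, bundles[0].counts.panel)
                    if p == "base"]
    for b in bundles:
        labels = annotate_by_reference(
            expr_by_sample[b.sample_id], reference, marker_genes
        )
        b.cells["cell_type"] = labels.loc[b.cells["cell_id"]].to_numpy()
        meta_frames.append(b.cells)
    cells_all = pd.concat(meta_frames, ignore_index=True)
    tables["cells"] = cells_all
    record("annotate", t0, len(cells_all))

    # --- vulnerability ------------------------------------------------
    t0 = time.time()
    tg_ids = set(cells_all.loc[cells_all["genotype"] == "tg", "cell_id"])
    vuln = vulnerability_table(
        calls_df[calls_df["cell_id"].isin(tg_ids)],
        cells_all.dropna(subset=["cell_type"]),
        group_by_sex=config.group_by_sex,
        min_cells=config.min_cells,
    )
    tables["vulnerability"] = vuln
    try:
        tk = anova_tukey(vuln[~vuln["low_n"]])
        tables["tukey"] = tk["tukey"]
        tables["anova"] = pd.DataFrame([tk["anova"]])
    except ValueError as err:
        log.warning("ANOVA skipped: %s", err)

    # regression of vulnerability on non-tg expression, all genes
    nontg = cells_all[(cells_all["genotype"] == "non_tg") & cells_all["cell_type"].notna()]
    frames = []
    for b in bundles:
        if b.genotype != "non_tg":
            continue
        sub = nontg[nontg["sample_id"] == b.sample_id]
        expr = expr_by_sample[b.sample_id]
        keep_idx = [expr.cell_ids.index(c) for c in sub["cell_id"]]
        from .expression import ExpressionMatrix
        em = ExpressionMatrix(
            expr.values[keep_idx], list(sub["cell_id"]), expr.gene_names,
            expr.transform, expr.scale_factor,
        )
        frames.append(mean_expression(em, sub["cell_type"].to_numpy()))
    mean_expr_nontg = pd.concat(frames).groupby(level=0).mean()
    try:
        reg = regress_vulnerability(vuln, mean_expr_nontg, min_cells=config.min_cells)
        tables["vulnerability_regression"] = reg.reset_index()
    except ValueError as err:
        log.warning("vulnerability regression skipped: %s", err)
    record("vulnerability", t0, len(vuln))

    # --- differential expression -------------------------------------
    status_by_cell = calls_df.set_index("cell_id")["status"]
    if config.run_de:
        t0 = time.time()
        merged, combined = _combine_counts(bundles, cells_all, status_by_cell)
        exn = config.exn_types or sorted(
            t for t in cells_all["cell_type"].dropna().unique() if "ExN" in t
        )
        try:
            de = three_way_de(
                combined, merged, exn_types=exn,
                min_cells=config.min_cells, fdr_alpha=config.fdr_alpha,
            )
            tables["de_results"] = de
            cons = []
            for label, grp in de.groupby("comparison"):
                c = deg_consensus(grp, fdr_alpha=config.fdr_alpha)
                c = c.reset_index()
                c.insert(0, "comparison", label)
                cons.append(c)
            tables["deg_consensus"] = pd.concat(cons, ignore_index=True)
        except ValueError as err:
            log.warning("three-way DE skipped: %s", err)
        record("diffexp", t0, len(tables.get("de_results", [])))

        if config.run_glm and "de_results" in tables:
            t0 = time.time()
            degs = sorted(set(tables["de_results"].loc[
                tables["de_results"]["fdr"] < config.fdr_alpha, "gene"]))
            glm_frames = []
            tg = merged[(merged["genotype"] == "tg") & merged["cell_type"].notna()]
            for ctype in exn:
                sub = tg[tg["cell_type"] == ctype]
                if len(sub) < 50 or not degs:
                    continue
                res = glm_vs_hsnca(
                    combined, sub, degs, scale_factor=config.scale_factor
                ).reset_index()
                res.insert(0, "cell_type", ctype)
                glm_frames.append(res)
            if glm_frames:
                tables["glm_results"] = pd.concat(glm_frames, ignore_index=True)
            record("glm", t0, len(tables.get("glm_results", [])))

    # --- write outputs ------------------------------------------------
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "config": config.__dict__,
        "config_hash": config.digest(),
        "version": __version__,
        "stages": stages,
        "total_seconds": round(time.time() - t_start, 2),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return RunResult(out_dir=out, tables=tables, manifest=manifest)


def _combine_counts(bundles: list[SampleBundle], cells_all: pd.DataFrame,
                    status_by_cell: pd.Series):
    """Stack per-sample count matrices; attach type/status metadata."""
    import scipy.sparse as sp
    from .io_formats import CountMatrix
    mats, ids = [], []
    for b in bundles:
        mats.append(b.counts.counts)
        ids.extend(b.counts.cell_ids)
    combined = CountMatrix(
        counts=sp.csr_matrix(sp.vstack(mats)),
        cell_ids=ids,
        gene_names=bundles[0].counts.gene_names,
        panel=bundles[0].counts.panel,
    )
    merged = cells_all.copy()
    merged["psyn"] = status_by_cell.loc[merged["cell_id"]].eq("pos").to_numpy()
    return merged, combined


def report(run_dir: str | Path) -> str:
    """Render a plain-text summary of a completed run (idempotent).

    Missing stage outputs yield warnings rather than failure, so partial
    runs still report what they produced.
    """
    run_dir = Path(run_dir)
    lines = ["# spatipath run report", ""]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"config hash: {manifest['config_hash']}  "
                     f"version: {manifest['version']}")
        lines.append("")

    def load(name: str) -> pd.DataFrame | None:
        p = run_dir / f"{name}.tsv"
        if not p.exists():
            lines.append(f"WARNING: missing stage output {name}.tsv")
            return None
        return pd.read_csv(p, sep="\t")

    vuln = load("vulnerability")
    lines.append("## Vulnerability (% pSyn+ per cell type, mean over samples)")
    if vuln is not None and len(vuln) and vuln["n_pos"].sum() > 0:
        summary = (
            vuln.groupby("cell_type")["pct_pos"].agg(["mean", "std", "count"]).round(2)
        )
        lines.append(summary.to_string())
        _vulnerability_figure(vuln, run_dir / "vulnerability.png")
    else:
        lines.append("(no transgenic pSyn+ cells in this run)")
    lines.append("")

    reg = load("vulnerability_regression")
    if reg is not None and len(reg):
        lines.append("## Top genes by vulnerability regression r2")
        top = reg.sort_values("r2", ascending=False).head(8)
        lines.append(
            top[["gene", "slope", "r2", "p", "p_adj"]].round(4).to_string(index=False)
        )
        lines.append("")

    cons = load("deg_consensus")
    if cons is not None:
        lines.append("## Consensus DEGs (same direction, >= 2 cell types)")
        if len(cons):
            lines.append(cons.to_string(index=False))
        else:
            lines.append("(none)")
        lines.append("")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text


def _vulnerability_figure(vuln: pd.DataFrame, path: Path) -> None:
    """Bar chart of mean % pSyn+ per type with per-sample dots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = (
        vuln.groupby("cell_type")["pct_pos"].mean().sort_values(ascending=False)
    )
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.bar(range(len(order)), order.values, color="#bbbbcc", edgecolor="black")
    for i, t in enumerate(order.index):
        pts = vuln.loc[vuln["cell_type"] == t, "pct_pos"]
        ax.plot([i] * len(pts), pts, "k.", ms=5)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order.index, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("% cells pSyn+")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_bundles(bundles, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write one directory per sample plus ground_truth.tsv and affines."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for b in bundles:
        write_bundle(out / b.sample_id, b)
    truth.cells.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if len(truth.spikes):
        truth.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False)
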