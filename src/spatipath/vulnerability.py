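"""Cell-type vulnerability to pSyn pathology and its expression correlates.

Vulnerability is the percent of cells of a type called pSyn+, computed per
sample (each sample contributes one replicate value per type). Types are
compared by one-way ANOVA with Tukey's HSD on the per-sample percentages,
and vulnerability is regressed gene-by-gene on per-type mean expression
(linear-scale expm1 units) with Benjamini-Hochberg correction across the
gene set. The regression is reported in the %pSyn+-on-expression
orientation; for simple OLS the r^2 and p-value are identical in either
direction, so this is presentation only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pathology_overlay import PSynCall, calls_to_frame

__all__ = ["vulnerability_table", "anova_tukey", "regress_vulnerability"]

log = logging.getLogger(__name__)


def vulnerability_table(
    calls: list[PSynCall] | pd.DataFrame,
    cells: pd.DataFrame,
    group_by_sex: bool = False,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per (sample, cell type) pathology frequency.

    ``cells`` must carry cell_id, sample_id, cell_type (and sex if
    ``group_by_sex``). Returns one row per group with n_cells, n_pos,
    pct_pos = 100*n_pos/n_cells, and a ``low_n`` flag for groups below
    ``min_cells``. Calls that do not join to a metadata row are an error.
    """
    calls_df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    merged = calls_df.merge(cells, on="cell_id", how="left", validate="one_to_one")
    if merged["sample_id"].isna().any():
        bad = merged.loc[merged["sample_id"].isna(), "cell_id"].tolist()[:10]
        raise ValueError(f"pSyn calls with no matching cell metadata: {bad}")
    keys = ["sample_id", "cell_type"] + (["sex"] if group_by_sex else [])
    grouped = merged.groupby(keys, dropna=False, observed=True)
    out = grouped.agg(
        n_cells=("cell_id", "size"),
        n_pos=("status", lambda s: int((s == "pos").sum())),
    ).reset_index()
    out["pct_pos"] = 100.0 * out["n_pos"] / out["n_cells"]
    out["low_n"] = out["n_cells"] < min_cells
    return out


def anova_tukey(vuln: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA across cell types with Tukey HSD on all pairs.

    Per-sample percentages are the replicates (one dot per sample). Types
    present in fewer than two samples are excluded (logged). Returns
    ``{"anova": {F, p}, "tukey": DataFrame[type_a, type_b, diff, p_adj]}``.
    """
    counts = vuln.groupby("cell_type", observed=True)["pct_pos"].count()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        log.info("types excluded from ANOVA (<2 samples): %s", dropped)
    if len(keep) < 2:
        raise ValueError("need >= 2 cell types with >= 2 samples each")
    groups = [
        vuln.loc[vuln["cell_type"] == t, "pct_pos"].to_numpy(dtype=float) for t in keep
    ]
    # guard the zero within-group variance corner (identical replicates)
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        if np.ptp(means) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat, p = stats.f_oneway(*groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        tukey = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            diff = float(np.mean(groups[i]) - np.mean(groups[j]))
            p_pair = float(tukey.pvalue[i, j])
            if not np.isfinite(p_pair):  # 0/0 from zero pooled variance
                p_pair = 0.0 if abs(diff) > 1e-12 else 1.0
            rows.append(
                {
                    "type_a": keep[i],
                    "type_b": keep[j],
                    "diff": diff,
                    "p_adj": p_pair,
                    "significant": bool(p_pair < alpha),
                }
            )
    return {"anova": {"F": float(f_stat), "p": float(p)}, "tukey": pd.DataFrame(rows)}


def regress_vulnerability(
    vuln: pd.DataFrame,
    mean_expr: pd.DataFrame,
    gene_set: list[str] | None = None,
    type_subset: list[str] | None = None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-gene OLS of mean %pSyn+ per type on mean expression per type.

    ``vuln`` rows are (sample, type) percentages from transgenic samples;
    they are averaged over samples per type. ``mean_expr`` is types x genes
    linear-scale (expm1) mean expression, typically computed from either
    non-transgenic or transgenic cells — both sources are supported by
    passing the corresponding matrix. Points are cell types. BH adjustment
    runs across the tested gene set. Results are recomputed from scratch
    for any ``type_subset`` (no caching).

    Degenerate genes (no expression variance across types) are reported
    with slope 0, r2 0 and p = 1 by convention.
    """
    use = vuln[~vuln["low_n"]] if "low_n" in vuln.columns else vuln
    pct = use.groupby("cell_type", observed=True)["pct_pos"].mean()
    types = pct.index.intersection(mean_expr.index)
    if type_subset is not None:
        types = types.intersection(type_subset)
    if len(types) < 3:
        raise ValueError(f"need >= 3 cell types for regression, got {len(types)}")
    genes = list(gene_set) if gene_set is not None else list(mean_expr.columns)
    y = pct.loc[types].to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = mean_expr.loc[types, g].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((g, 0.0, float(np.mean(y)), 0.0, 1.0, len(types)))
            continue
        res = stats.linregress(x, y)
        rows.append(
            (g, float(res.slope), float(res.intercept),
             float(res.rvalue**2), float(res.pvalue), len(types))
        )
    out = pd.DataFrame(
        rows, columns=["gene", "slope", "intercept", "r2", "p", "n_points"]
    ).set_index("gene")
    out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out
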