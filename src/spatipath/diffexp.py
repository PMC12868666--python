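"""Pseudo-bulk negative-binomial differential expression and per-cell GLMs.

Cells are aggregated into pseudo-bulk libraries over (cell type, sample,
pSyn status); each two-group contrast is tested per gene with a negative-
binomial GLM (log link, median-of-ratios size-factor offsets) and a Wald
test on the group coefficient, with Benjamini-Hochberg correction within
each cell type x comparison family. Dispersions are estimated per gene by
profile maximum likelihood with a floor — no empirical-Bayes shrinkage
toward a mean-dispersion trend, and no independent filtering or outlier
refitting: targeted panels of a few hundred genes do not need them.

The module also implements the percentile stratification used to decouple
pathology status from transgene dose (pSyn-/hSNCA-high vs pSyn+/hSNCA-low
within each cell type), the three-way genotype/pathology contrast design,
the >= 2-cell-type same-direction DEG consensus rule, and a per-cell NB
regression of gene expression on hSNCA expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix

__all__ = [
    "stratify_by_percentile",
    "pseudobulk_aggregate",
    "size_factors",
    "nb_wald_de",
    "three_way_de",
    "deg_consensus",
    "glm_vs_hsnca",
]

log = logging.getLogger(__name__)

_MIN_ALPHA = 1e-8  # dispersion floor
_MAX_ALPHA = 100.0


# ---------------------------------------------------------------------------
# NB GLM core (log link, offset)
# ---------------------------------------------------------------------------


def _nb_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fisher scoring for an NB GLM with log link and fixed dispersion.

    Var(y) = mu + alpha*mu^2 (alpha = 0 gives Poisson). Returns
    (beta, covariance, converged).
    """
    n, p = X.shape
    if beta0 is None:
        # start from WLS on log counts
        z0 = np.log(np.maximum(y, 0.5)) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    converged = False
    xtwx = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        xtwx = xtw @ X
        try:
            new_beta = np.linalg.solve(xtwx, xtw @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        beta = new_beta
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < _MIN_ALPHA:
        alpha = _MIN_ALPHA
    size = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - size * np.log1p(alpha * mu)
        )
    )


def _fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Profile-ML dispersion + NB GLM fit.

    Returns (beta, cov, alpha, converged). Dispersion is the maximizer of
    the profile likelihood over [1e-8, 100] with the GLM refit at each
    candidate; a floor of 1e-8 keeps the Poisson-like limit stable.
    """
    y = np.asarray(y, dtype=float)
    warm: dict[str, np.ndarray] = {}

    def profile_nll(log_alpha: float) -> float:
        a = float(np.exp(log_alpha))
        beta, _, _ = _nb_irls(y, X, offset, a, beta0=warm.get("beta"))
        warm["beta"] = beta
        mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
        return -_nb_loglik(y, mu, a)

    res = optimize.minimize_scalar(
        profile_nll,
        bounds=(np.log(_MIN_ALPHA), np.log(_MAX_ALPHA)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(res.x))
    beta, cov, converged = _nb_irls(y, X, offset, alpha, beta0=warm.get("beta"))
    return beta, cov, alpha, converged


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------


@dataclass
class Stratum:
    cell_type: str
    q25: float
    q75: float
    high: list[str]  # pSyn-, expression > q75
    low: list[str]  # pSyn+, expression < q25


def stratify_by_percentile(
    cells: pd.DataFrame,
    expr_values: pd.Series,
    min_cells_per_stratum: int = 10,
) -> dict[str, Stratum]:
    """Split each cell type into pSyn-/high and pSyn+/low transgene strata.

    ``cells`` holds transgenic cells only (cell_id, cell_type, psyn bool);
    ``expr_values`` is the per-cell linear-scale (expm1) transgene
    expression indexed by cell_id. Quantile thresholds use linear
    interpolation over all transgenic cells of the type. Types where
    either stratum is smaller than ``min_cells_per_stratum`` are skipped
    and logged. By construction mean(high) > mean(low); this is asserted.
    """
    out: dict[str, Stratum] = {}
    for ctype, grp in cells.groupby("cell_type", observed=True):
        vals = expr_values.loc[grp["cell_id"]].to_numpy(dtype=float)
        q25, q75 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
        psyn = grp["psyn"].to_numpy(dtype=bool)
        high = grp.loc[~psyn & (vals > q75), "cell_id"].tolist()
        low = grp.loc[psyn & (vals < q25), "cell_id"].tolist()
        if len(high) < min_cells_per_stratum or len(low) < min_cells_per_stratum:
            log.info(
                "type %s skipped: strata too small (high=%d, low=%d)",
                ctype, len(high), len(low),
            )
            continue
        assert expr_values.loc[high].mean() > expr_values.loc[low].mean()
        out[str(ctype)] = Stratum(str(ctype), float(q25), float(q75), high, low)
    return out


# ---------------------------------------------------------------------------
# Pseudo-bulk aggregation
# ---------------------------------------------------------------------------


def pseudobulk_aggregate(
    counts: CountMatrix,
    cells: pd.DataFrame,
    keys: tuple[str, ...] = ("cell_type", "sample_id", "psyn_status"),
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum raw counts over cells sharing the grouping keys.

    Returns (pseudo-samples x genes integer frame, group sizes). Groups
    with fewer than ``min_cells`` member cells are dropped (logged). The
    input must be raw counts — normalized values are rejected upstream by
    CountMatrix's integer invariant.
    """
    order = {cid: i for i, cid in enumerate(counts.cell_ids)}
    missing = [c for c in cells["cell_id"] if c not in order]
    if missing:
        raise ValueError(f"cells absent from count matrix: {missing[:5]}")
    groups = cells.groupby(list(keys), dropna=False, observed=True)
    rows, labels, sizes = [], [], []
    for name, grp in groups:
        if len(grp) < min_cells:
            log.info("pseudo-bulk group %s dropped (%d cells)", name, len(grp))
            continue
        sub = counts.counts[[order[c] for c in grp["cell_id"]]]
        rows.append(np.asarray(sub.sum(axis=0)).ravel().astype(np.int64))
        labels.append(name if isinstance(name, tuple) else (name,))
        sizes.append(len(grp))
    if not rows:
        raise ValueError("no pseudo-bulk group met the min_cells threshold")
    index = pd.MultiIndex.from_tuples(labels, names=list(keys))
    pb = pd.DataFrame(np.vstack(rows), index=index, columns=counts.gene_names)
    return pb, pd.Series(sizes, index=index, name="n_cells")


def size_factors(pseudobulk: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Only genes with nonzero counts in every pseudo-sample enter the
    reference; if none exist the factors fall back to library sizes
    (logged). Factors are normalized to geometric mean 1.
    """
    m = pseudobulk.to_numpy(dtype=float)
    all_nonzero = np.all(m > 0, axis=0)
    if not np.any(all_nonzero):
        log.warning("no all-nonzero genes; falling back to library-size factors")
        s = m.sum(axis=1)
    else:
        ref = np.exp(np.mean(np.log(m[:, all_nonzero]), axis=0))
        s = np.median(m[:, all_nonzero] / ref, axis=1)
    s = s / np.exp(np.mean(np.log(s)))
    return s


# ---------------------------------------------------------------------------
# NB Wald differential expression
# ---------------------------------------------------------------------------


def nb_wald_de(
    pseudobulk: pd.DataFrame,
    group: pd.Series | np.ndarray,
    comparison: str = "",
    genes: list[str] | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group NB Wald test per gene on pseudo-bulk counts.

    ``group`` is a two-level factor over pseudo-samples; the reported
    log2FC is second level over first (levels in sorted order). Genes with
    zero counts everywhere are excluded; BH runs across the genes actually
    tested (pass ``genes`` to restrict the family, e.g. to the custom
    panel). Requires >= 2 pseudo-samples per group.
    """
    g = np.asarray(group)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    n_per = [(g == lv).sum() for lv in levels]
    if min(n_per) < 2:
        raise ValueError(
            f"need >= 2 pseudo-samples per group (replicates), got {dict(zip(levels, n_per))}"
        )
    cols = list(genes) if genes is not None else list(pseudobulk.columns)
    m = pseudobulk[cols].to_numpy(dtype=float)
    s = size_factors(pseudobulk)
    offset = np.log(s)
    X = np.column_stack([np.ones_like(s), (g == levels[1]).astype(float)])

    rows = []
    for j, gene in enumerate(cols):
        y = m[:, j]
        if np.all(y == 0):
            continue
        beta, cov, alpha, converged = _fit_nb_glm(y, X, offset)
        se = float(np.sqrt(cov[1, 1]))
        lfc = float(beta[1] / np.log(2.0))
        wald = beta[1] / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(wald)))
        rows.append(
            {
                "gene": gene,
                "base_mean": float(np.mean(y / s)),
                "log2fc": lfc,
                "se": float(se / np.log(2.0)),
                "wald_stat": float(wald),
                "p": p,
                "dispersion": alpha,
                "converged": converged,
                "comparison": comparison,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_alpha
    return out


def three_way_de(
    counts: CountMatrix,
    cells: pd.DataFrame,
    exn_types: list[str] | None = None,
    genes: list[str] | None = None,
    min_cells: int = 10,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotype/pathology three-contrast pseudo-bulk DE per ExN type.

    Cells are split into non-tg, pSyn+ tg, and pSyn- tg categories; per
    cell type the contrasts nontg_vs_pos, nontg_vs_neg, and pos_vs_neg are
    each tested with :func:`nb_wald_de`. ``cells`` needs cell_id,
    sample_id, genotype, cell_type, psyn (bool). Inhibitory and
    non-neuronal types are excluded by restricting ``exn_types``. By
    default the tested gene family is the custom panel.
    """
    if genes is None:
        genes = [g for g, p in zip(counts.gene_names, counts.panel) if p == "custom"]
    cells = cells.copy()
    cat = np.where(
        cells["genotype"] != "tg", "nontg", np.where(cells["psyn"], "pos", "neg")
    )
    cells["category"] = cat
    if not (cat == "nontg").any() or not (cat != "nontg").any():
        raise ValueError("both genotypes must be present")
    types = exn_types if exn_types is not None else sorted(cells["cell_type"].unique())
    pb, _ = pseudobulk_aggregate(
        counts, cells, keys=("cell_type", "sample_id", "category"), min_cells=min_cells
    )
    contrasts = [
        ("nontg_vs_pos", "nontg", "pos"),
        ("nontg_vs_neg", "nontg", "neg"),
        ("pos_vs_neg", "neg", "pos"),  # log2FC: pos over neg
    ]
    results = []
    for ctype in types:
        if ctype not in pb.index.get_level_values("cell_type"):
            continue
        sub = pb.xs(ctype, level="cell_type")
        for label, ref, alt in contrasts:
            mask = sub.index.get_level_values("category").isin([ref, alt])
            block = sub[mask]
            grp = block.index.get_level_values("category")
            if min((grp == ref).sum(), (grp == alt).sum()) < 2:
                log.info("%s / %s skipped: insufficient replicates", ctype, label)
                continue
            # encode so sorted level order puts `alt` second (log2FC alt/ref)
            coded = np.where(grp == ref, f"0_{ref}", f"1_{alt}")
            res = nb_wald_de(block, coded, comparison=label, genes=genes, fdr_alpha=fdr_alpha)
            res.insert(0, "cell_type", ctype)
            results.append(res)
    if not results:
        raise ValueError("no (cell type, contrast) pair had enough replicates")
    return pd.concat(results, ignore_index=True)


def deg_consensus(
    results: pd.DataFrame, fdr_alpha: float = 0.05, min_types: int = 2
) -> pd.DataFrame:
    """Genes significant in the same direction in >= ``min_types`` cell types.

    ``results`` holds one comparison label (gene, cell_type, log2fc, fdr
    columns); returns a gene-indexed frame with direction and the
    supporting cell types.
    """
    empty = pd.DataFrame(columns=["direction", "n_types", "cell_types"]).rename_axis("gene")
    if results.empty:
        return empty
    sig = results[(results["fdr"] < fdr_alpha) & (results["log2fc"] != 0)]
    rows = []
    for gene, grp in sig.groupby("gene"):
        for sign, sgrp in grp.groupby(np.sign(grp["log2fc"])):
            if len(sgrp) >= min_types:
                rows.append(
                    {
                        "gene": gene,
                        "direction": "up" if sign > 0 else "down",
                        "n_types": len(sgrp),
                        "cell_types": ",".join(sorted(sgrp["cell_type"])),
                    }
                )
    if not rows:
        return empty
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Per-cell GLM against the transgene
# ---------------------------------------------------------------------------


def glm_vs_hsnca(
    counts: CountMatrix,
    cells: pd.DataFrame,
    gene_set: list[str],
    transgene: str = "hSNCA",
    scale_factor: float = 1e4,
    family: str = "nb",
) -> pd.DataFrame:
    """Per-cell regression of gene expression on transgene expression.

    For transgenic cells of one cell type (pSyn status deliberately
    ignored), each gene's raw count is modeled as NB with log link,
    log-library-size offset, and the cell's linear-scale (expm1) transgene
    expression as the single covariate; BH q-values run across
    ``gene_set``. Non-convergent fits fall back to a Poisson model with
    robust (HC0) standard errors and are flagged. ``family="gaussian"``
    instead fits OLS on log-normalized values (no offset).
    """
    order = {cid: i for i, cid in enumerate(counts.cell_ids)}
    idx = np.array([order[c] for c in cells["cell_id"]])
    sub = counts.counts[idx]
    lib = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    keep = lib > 0
    if not np.all(keep):
        log.info("%d zero-library cells dropped from GLM", int((~keep).sum()))
        sub, lib = sub[keep], lib[keep]
    tg_col = np.asarray(sub[:, counts.gene_index(transgene)].todense()).ravel()
    x = np.expm1(np.log1p(tg_col / lib * scale_factor))  # = tg/lib*scale, kept explicit
    X = np.column_stack([np.ones_like(x), x])
    offset = np.log(lib)

    rows = []
    for gene in gene_set:
        y = np.asarray(sub[:, counts.gene_index(gene)].todense()).ravel().astype(float)
        if family == "gaussian":
            v = np.log1p(y / lib * scale_factor)
            res = stats.linregress(x, v)
            rows.append(
                {"gene": gene, "beta": float(res.slope), "se": float(res.stderr),
                 "p": float(res.pvalue), "fallback": False}
            )
            continue
        beta, cov, alpha, converged = _fit_nb_glm(y, X, offset)
        if converged and np.isfinite(cov[1, 1]) and cov[1, 1] > 0:
            se = float(np.sqrt(cov[1, 1]))
            wald = beta[1] / se
            rows.append(
                {"gene": gene, "beta": float(beta[1]), "se": se,
                 "p": float(2.0 * stats.norm.sf(abs(wald))), "fallback": False}
            )
        else:
            beta, se, p = _poisson_robust(y, X, offset)
            rows.append({"gene": gene, "beta": beta, "se": se, "p": p, "fallback": True})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def _poisson_robust(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[float, float, float]:
    """Poisson fit with HC0 sandwich SE for the slope (GLM fallback)."""
    beta, _, _ = _nb_irls(y, X, offset, alpha=0.0)
    mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
    W = X.T * mu
    bread = np.linalg.pinv(W @ X)
    meat = (X * ((y - mu) ** 2)[:, None]).T @ X
    cov = bread @ meat @ bread
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    wald = beta[1] / se if se > 0 else 0.0
    return float(beta[1]), se, float(2.0 * stats.norm.sf(abs(wald)))
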