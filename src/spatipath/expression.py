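"""Normalization, cell-type annotation, and cross-platform comparison.

Counts are library-size normalized and natural-log transformed
(``v = ln(1 + count/lib * scale_factor)``, the standard single-cell
convention); linear-scale summaries use ``expm1(v)``, the unit used for all
per-type averages and vulnerability regressions. Cell types are annotated
by Pearson correlation against reference expression profiles (scaled
average expression per type), replacing upstream graph clustering; a hook
for externally computed labels is the ``cell_type`` metadata column itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "lognormalize",
    "mean_expression",
    "scale_profiles",
    "annotate_by_reference",
    "compare_platforms_genewise",
    "compare_platforms_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Cells x genes real-valued expression with its transform tag."""

    values: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    transform: str  # lognorm | scaled
    scale_factor: float | None = None

    def gene(self, name: str) -> np.ndarray:
        return self.values[:, self.gene_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_names)


def lognormalize(counts: CountMatrix, scale_factor: float = 1e4) -> ExpressionMatrix:
    """v[c, g] = ln(1 + counts[c, g] / lib_c * scale_factor).

    Cells with zero library size must be filtered upstream; they are
    reported by id here rather than silently producing NaN.
    """
    lib = counts.library_sizes().astype(float)
    if np.any(lib == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(lib == 0)[:10]]
        raise ValueError(f"cells with zero library size (filter first): {bad}")
    dense = np.asarray(counts.counts.todense(), dtype=float)
    values = np.log1p(dense / lib[:, None] * scale_factor)
    return ExpressionMatrix(
        values=values,
        cell_ids=list(counts.cell_ids),
        gene_names=list(counts.gene_names),
        transform="lognorm",
        scale_factor=scale_factor,
    )


def mean_expression(
    expr: ExpressionMatrix,
    groups: pd.Series | np.ndarray,
    mode: str = "expm1_mean",
) -> pd.DataFrame:
    """Per-group mean expression, groups x genes.

    ``expm1_mean`` (default): mean over the group's cells of expm1(v) —
    the linear-scale unit used for vulnerability regressions and per-type
    summaries. ``lognorm_mean``: plain mean of v.
    """
    if mode not in ("expm1_mean", "lognorm_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = np.expm1(expr.values) if mode == "expm1_mean" else expr.values
    df = pd.DataFrame(vals, columns=expr.gene_names)
    df["_group"] = np.asarray(groups)
    out = df.groupby("_group", sort=True).mean()
    out.index.name = "group"
    return out


def scale_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene (column) to mean 0, sd 1 across the profile rows.

    Zero-variance genes are left at 0. Idempotent up to floating point.
    """
    mu = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    sd = sd.replace(0.0, 1.0)
    return (profiles - mu) / sd


def annotate_by_reference(
    expr: ExpressionMatrix,
    reference: pd.DataFrame,
    marker_genes: list[str] | None = None,
) -> pd.Series:
    """Assign each cell the reference type with the highest Pearson r.

    ``reference`` is types x genes (scaled average expression). Cells with
    zero variance over the marker genes, or tied best correlations, are
    left unassigned (label ``None``) and counted in the log.
    """
    if len(reference) < 2:
        raise ValueError("need >= 2 reference types")
    markers = marker_genes or [g for g in reference.columns if g in expr.gene_names]
    missing = [g for g in markers if g not in expr.gene_names]
    if missing:
        raise ValueError(f"marker genes not in panel: {missing}")
    ref = reference[markers].to_numpy(dtype=float)
    cols = [expr.gene_names.index(g) for g in markers]
    x = expr.values[:, cols]

    # row-standardize both sides; Pearson r is then a scaled dot product
    def _std(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        return np.divide(a - mu, sd, out=np.zeros_like(a), where=sd > 0), sd.ravel()

    xs, xsd = _std(x)
    rs, rsd = _std(ref)
    r = xs @ rs.T / len(markers)

    labels: list[str | None] = []
    n_unassigned = 0
    types = list(reference.index)
    for i in range(r.shape[0]):
        if xsd[i] == 0:
            labels.append(None)
            n_unassigned += 1
            continue
        row = r[i]
        best = np.max(row)
        ties = np.flatnonzero(row >= best - 1e-12)
        if len(ties) > 1:
            labels.append(None)
            n_unassigned += 1
        else:
            labels.append(types[int(ties[0])])
    if n_unassigned:
        log.info("%d cells unassigned (zero variance or tied)", n_unassigned)
    return pd.Series(labels, index=expr.cell_ids, name="cell_type")


@dataclass(frozen=True)
class GeneRegression:
    gene: str
    slope: float
    intercept: float
    r2: float
    p: float
    n_points: int


def compare_platforms_genewise(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene OLS of platform A's scaled profile on platform B's.

    Both inputs are types x genes; they are aligned on shared types and
    genes and each scaled per gene across those types before regression.
    Returns a gene-indexed frame with slope, intercept, r2, p, n_points.
    """
    types = profiles_a.index.intersection(profiles_b.index)
    genes = profiles_a.columns.intersection(profiles_b.columns)
    if len(types) < 3:
        raise ValueError(f"need >= 3 shared cell types, got {len(types)}")
    a = scale_profiles(profiles_a.loc[types, genes])
    b = scale_profiles(profiles_b.loc[types, genes])
    rows = []
    for g in genes:
        x, y = b[g].to_numpy(), a[g].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(GeneRegression(g, 0.0, float(np.mean(y)), 0.0, 1.0, len(types)))
            continue
        res = stats.linregress(x, y)
        rows.append(
            GeneRegression(
                g, float(res.slope), float(res.intercept),
                float(res.rvalue**2), float(res.pvalue), len(types),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("gene")


def compare_platforms_profiles(
    profiles_a: pd.DataFrame, profiles_b: pd.DataFrame
) -> pd.DataFrame:
    """Full types_a x types_b Pearson matrix over the shared gene set.

    Zero-variance profiles yield NaN entries (reported missing rather than
    an arbitrary value).
    """
    genes = profiles_a.columns.intersection(profiles_b.columns)
    a = profiles_a[genes].to_numpy(dtype=float)
    b = profiles_b[genes].to_numpy(dtype=float)
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((am**2).sum(axis=1))
    bsd = np.sqrt((bm**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (am @ bm.T) / np.outer(asd, bsd)
    r[np.outer(asd == 0, np.ones_like(bsd, dtype=bool))] = np.nan
    r[np.outer(np.ones_like(asd, dtype=bool), bsd == 0)] = np.nan
    return pd.DataFrame(r, index=profiles_a.index, columns=profiles_b.index)
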