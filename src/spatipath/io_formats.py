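"""On-disk artifacts of a spatial-transcriptomics + pathology-IF experiment.

Every reader/writer here is lossless for the value types it handles and pins
down the coordinate conventions used throughout the package:

* image arrays are indexed ``[row, col]`` with ``x = col`` and ``y = row``
  (y increases downward); pixel ``(0, 0)`` has continuous coordinate
  ``(0.0, 0.0)`` at its center;
* spatial coordinates are in micrometres, also y-down, and are obtained from
  image pixel coordinates through an affine transform stored image -> spatial.

Formats: cell boundary polygons as GeoJSON, raw counts as MatrixMarket plus
two index tables (10x-style triplet), cell metadata / affines / reference
profiles as TSV, and the immunofluorescence image as a single-channel TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "AffineTransform",
    "CellPolygon",
    "CountMatrix",
    "SampleBundle",
    "read_polygons",
    "write_polygons",
    "read_counts",
    "write_counts",
    "read_affine",
    "write_affine",
    "read_image",
    "write_image",
    "read_cell_metadata",
    "write_cell_metadata",
    "read_bundle",
]


class ValidationError(ValueError):
    """An on-disk artifact violated a structural contract."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellPolygon:
    """A cell boundary: an ordered, closed, simple ring in micrometres."""

    cell_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        verts = [(float(x), float(y)) for x, y in self.vertices]
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValidationError(
                f"polygon {self.cell_id!r}: needs >=3 distinct vertices, got {len(verts)}"
            )
        shp = _ShapelyPolygon(verts)
        if not shp.is_valid:
            raise ValidationError(f"polygon {self.cell_id!r}: ring is not simple")
        if shp.area <= 0:
            raise ValidationError(f"polygon {self.cell_id!r}: non-positive area")
        object.__setattr__(self, "vertices", tuple(verts))

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return self.shapely.area


def read_polygons(path: str | Path) -> list[CellPolygon]:
    """Read cell polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon carrying a ``cell_id`` property; vertex
    order is preserved as stored. Coordinates are taken to be micrometres.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    polys: list[CellPolygon] = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise ValidationError(f"{path}: feature geometry is not Polygon")
        props = feat.get("properties") or {}
        cell_id = props.get("cell_id") or props.get("id")
        if cell_id is None:
            raise ValidationError(f"{path}: polygon feature without cell_id property")
        ring = geom["coordinates"][0]
        polys.append(CellPolygon(str(cell_id), tuple((p[0], p[1]) for p in ring)))
    return polys


def write_polygons(path: str | Path, polygons: Sequence[CellPolygon]) -> None:
    feats = []
    for poly in polygons:
        ring = [list(v) for v in poly.vertices] + [list(poly.vertices[0])]
        feats.append(
            {
                "type": "Feature",
                "properties": {"cell_id": poly.cell_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# Affine transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous 2D affine mapping image pixel coords to spatial um.

    ``matrix`` is 3x3 with last row (0, 0, 1). ``apply`` maps (x, y) points
    given as an (n, 2) array; ``inverse`` returns the spatial -> image map.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape == (2, 3):
            m = np.vstack([m, [0.0, 0.0, 1.0]])
        if m.shape != (3, 3):
            raise ValidationError(f"affine must be 2x3 or 3x3, got {m.shape}")
        if not np.allclose(m[2], [0.0, 0.0, 1.0]):
            raise ValidationError("affine last row must be (0, 0, 1)")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValidationError("affine linear block is singular")
        m = m.copy()
        m[2] = (0.0, 0.0, 1.0)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3))

    @classmethod
    def from_parts(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation about the origin, then isotropic scale, then translation."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        m = np.array(
            [
                [scale * c, -scale * s, translation[0]],
                [scale * s, scale * c, translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return AffineTransform(self.matrix @ other.matrix)


def read_affine(path: str | Path) -> AffineTransform:
    """Read a 2x3 or 3x3 affine from a TSV table (rows = matrix rows)."""
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    return AffineTransform(m)


def write_affine(path: str | Path, affine: AffineTransform) -> None:
    np.savetxt(path, affine.matrix, delimiter="\t", fmt="%.17g")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes, with gene panel labels.

    ``panel`` labels each gene as belonging to the instrument's ``base``
    panel or a ``custom`` add-on panel; downstream differential-expression
    families are restricted to the custom panel.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_names: list[str]
    panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValidationError(
                f"count matrix {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_names)} genes"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        if not self.panel:
            self.panel = ["base"] * len(self.gene_names)
        if len(self.panel) != len(self.gene_names):
            raise ValidationError("panel labels must match gene count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_names.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in panel") from None


def read_counts(
    matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> CountMatrix:
    """Read counts from MatrixMarket + gene/cell index tables.

    The .mtx matrix is stored genes x cells (10x convention) and transposed
    to cells x genes on load. The gene table has columns ``gene`` and
    optional ``panel``; the cell table has a ``cell_id`` column.
    """
    mat = scipy.io.mmread(str(matrix_path))
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    counts = sp.csr_matrix(mat.T)
    if counts.shape != (len(cells), len(genes)):
        raise ValidationError(
            f"matrix {mat.shape} (genes x cells) does not match index tables "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    panel = list(genes["panel"]) if "panel" in genes.columns else []
    return CountMatrix(
        counts=counts,
        cell_ids=[str(c) for c in cells["cell_id"]],
        gene_names=[str(g) for g in genes["gene"]],
        panel=panel,
    )


def write_counts(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    cm: CountMatrix,
) -> None:
    mat = sp.coo_matrix(cm.counts.T.astype(np.int64))
    scipy.io.mmwrite(str(matrix_path), mat)
    pd.DataFrame({"gene": cm.gene_names, "panel": cm.panel}).to_csv(
        genes_path, sep="\t", index=False
    )
    pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def read_image(path: str | Path, channel: int | None = None) -> np.ndarray:
    """Read a single-channel TIFF as a 2D array indexed [row=y, col=x].

    Multi-channel images require an explicit ``channel`` selector; integer
    intensities are preserved exactly.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if channel is None:
            raise ValidationError(
                f"{path}: multi-channel image (shape {arr.shape}) needs channel="
            )
        # accept both (c, h, w) and (h, w, c) layouts
        axis = 0 if arr.shape[0] <= 4 < arr.shape[-1] else 2
        arr = np.take(arr, channel, axis=axis)
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image))


# ---------------------------------------------------------------------------
# Cell metadata and bundles
# ---------------------------------------------------------------------------

CELL_META_COLUMNS = [
    "cell_id",
    "sample_id",
    "genotype",
    "sex",
    "region",
    "x_um",
    "y_um",
]


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    missing = [c for c in CELL_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()[:5]
        raise ValidationError(f"{path}: duplicate cell ids, e.g. {dupes}")
    return df


def write_cell_metadata(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SampleBundle:
    """All artifacts for one tissue section, loaded and cross-validated."""

    sample_id: str
    genotype: str  # non_tg | tg
    sex: str  # M | F
    polygons: list[CellPolygon]
    counts: CountMatrix
    cells: pd.DataFrame  # one row per cell, CELL_META_COLUMNS
    image: np.ndarray | None = None
    pixel_size_um: float | None = None
    affine: AffineTransform | None = None

    def __post_init__(self) -> None:
        if self.genotype not in ("non_tg", "tg"):
            raise ValidationError(f"genotype must be non_tg|tg, got {self.genotype!r}")
        meta_ids = set(self.cells["cell_id"])
        count_ids = set(self.counts.cell_ids)
        poly_ids = [p.cell_id for p in self.polygons]
        if len(set(poly_ids)) != len(poly_ids):
            raise ValidationError("duplicate polygon cell ids")
        if count_ids != meta_ids:
            raise ValidationError(
                f"count matrix / metadata cell id mismatch "
                f"({len(count_ids ^ meta_ids)} ids differ)"
            )
        if set(poly_ids) != meta_ids:
            raise ValidationError("every cell must have exactly one polygon")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


BUNDLE_LAYOUT = {
    "polygons": "cells.geojson",
    "matrix": "matrix.mtx",
    "genes": "genes.tsv",
    "cells_index": "barcodes.tsv",
    "metadata": "cell_metadata.tsv",
    "image": "if_image.tif",
    "affine": "affine.tsv",
    "info": "sample.json",
}


def read_bundle(directory: str | Path) -> SampleBundle:
    """Load a per-sample bundle directory written by the simulator/pipeline."""
    d = Path(directory)
    with open(d / BUNDLE_LAYOUT["info"]) as fh:
        info = json.load(fh)
    image = None
    affine = None
    if (d / BUNDLE_LAYOUT["image"]).exists():
        image = read_image(d / BUNDLE_LAYOUT["image"])
    if (d / BUNDLE_LAYOUT["affine"]).exists():
        affine = read_affine(d / BUNDLE_LAYOUT["affine"])
    return SampleBundle(
        sample_id=info["sample_id"],
        genotype=info["genotype"],
        sex=info["sex"],
        polygons=read_polygons(d / BUNDLE_LAYOUT["polygons"]),
        counts=read_counts(
            d / BUNDLE_LAYOUT["matrix"],
            d / BUNDLE_LAYOUT["genes"],
            d / BUNDLE_LAYOUT["cells_index"],
        ),
        cells=read_cell_metadata(d / BUNDLE_LAYOUT["metadata"]),
        image=image,
        pixel_size_um=info.get("pixel_size_um"),
        affine=affine,
    )


def write_bundle(directory: str | Path, bundle: SampleBundle) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_polygons(d / BUNDLE_LAYOUT["polygons"], bundle.polygons)
    write_counts(
        d / BUNDLE_LAYOUT["matrix"],
        d / BUNDLE_LAYOUT["genes"],
        d / BUNDLE_LAYOUT["cells_index"],
        bundle.counts,
    )
    write_cell_metadata(d / BUNDLE_LAYOUT["metadata"], bundle.cells)
    if bundle.image is not None:
        write_image(d / BUNDLE_LAYOUT["image"], bundle.image)
    if bundle.affine is not None:
        write_affine(d / BUNDLE_LAYOUT["affine"], bundle.affine)
    with open(d / BUNDLE_LAYOUT["info"], "w") as fh:
        json.dump(
            {
                "sample_id": bundle.sample_id,
                "genotype": bundle.genotype,
                "sex": bundle.sex,
                "pixel_size_um": bundle.pixel_size_um,
            },
            fh,
            indent=1,
        )
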