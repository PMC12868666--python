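"""Assign phospho-synuclein pathology to segmented cells.

The central bespoke step of the pipeline: the immunofluorescence image of
pSyn staining (acquired on the same section as the transcriptomic run) is
thresholded into inclusion objects; inclusion centroids are mapped into
spatial micrometre coordinates through the stored image->spatial affine;
and each cell is called pSyn+ if at least one inclusion centroid falls
within its boundary polygon (boundary points count as inside).

Conventions fixed here: components are 8-connected, an inclusion's centroid
is the unweighted mean of its pixel coordinates, objects below ``min_area_px``
are discarded as noise, and an inclusion whose centroid lies in no cell is
counted as an orphan, logged, and excluded from every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point
from shapely.strtree import STRtree

from .io_formats import AffineTransform, CellPolygon

__all__ = [
    "Inclusion",
    "InclusionSet",
    "PSynCall",
    "threshold_inclusions",
    "map_centroids",
    "point_in_polygon",
    "call_psyn",
]

log = logging.getLogger(__name__)


@dataclass
class Inclusion:
    """One thresholded pathology object."""

    inclusion_id: int
    area_px: int
    centroid_image: tuple[float, float]  # (x px, y px)
    centroid_spatial: tuple[float, float] | None = None  # (x um, y um)
    cell_id: str | None = None


@dataclass
class InclusionSet:
    inclusions: list[Inclusion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.inclusions)

    def __iter__(self):
        return iter(self.inclusions)

    def centroids_image(self) -> np.ndarray:
        return np.array([i.centroid_image for i in self.inclusions]).reshape(-1, 2)

    def centroids_spatial(self) -> np.ndarray:
        return np.array(
            [i.centroid_spatial for i in self.inclusions if i.centroid_spatial is not None]
        ).reshape(-1, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inclusion_id": [i.inclusion_id for i in self.inclusions],
                "area_px": [i.area_px for i in self.inclusions],
                "x_px": [i.centroid_image[0] for i in self.inclusions],
                "y_px": [i.centroid_image[1] for i in self.inclusions],
                "x_um": [
                    i.centroid_spatial[0] if i.centroid_spatial else np.nan
                    for i in self.inclusions
                ],
                "y_um": [
                    i.centroid_spatial[1] if i.centroid_spatial else np.nan
                    for i in self.inclusions
                ],
                "cell_id": [i.cell_id for i in self.inclusions],
            }
        )


@dataclass(frozen=True)
class PSynCall:
    """Per-cell pathology status; pos iff at least one assigned inclusion."""

    cell_id: str
    status: str  # pos | neg
    n_inclusions: int

    def __post_init__(self) -> None:
        assert (self.status == "pos") == (self.n_inclusions >= 1)


def threshold_inclusions(
    image: np.ndarray, threshold: float, min_area_px: int = 4
) -> InclusionSet:
    """Detect inclusions as 8-connected components of ``image >= threshold``.

    The same fixed threshold is meant to be applied to every sample of an
    experiment. Components smaller than ``min_area_px`` are dropped;
    centroids are unweighted pixel-coordinate means in (x, y) pixel units.
    """
    image = np.asarray(image)
    binary = image >= threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    out = InclusionSet()
    if n == 0:
        return out
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    k = 0
    for lab in range(1, n + 1):
        area = int(areas[lab - 1])
        if area < min_area_px:
            continue
        cy, cx = centroids[lab - 1]  # center_of_mass returns (row, col)
        k += 1
        out.inclusions.append(Inclusion(k, area, (float(cx), float(cy))))
    return out


def map_centroids(inclusions: InclusionSet, affine: AffineTransform) -> InclusionSet:
    """Set each inclusion's spatial centroid = affine(image centroid)."""
    for inc in inclusions:
        x, y = affine.apply(np.array(inc.centroid_image))
        inc.centroid_spatial = (float(x), float(y))
    return inclusions


def point_in_polygon(point: tuple[float, float], polygon: CellPolygon) -> bool:
    """Even-odd containment; points exactly on the boundary count as inside."""
    return polygon.shapely.covers(Point(point))


def call_psyn(
    cells: pd.DataFrame,
    polygons: list[CellPolygon],
    inclusions: InclusionSet,
) -> list[PSynCall]:
    """Call each cell pSyn+/- from mapped inclusion centroids.

    Every inclusion is assigned to the polygon covering its spatial
    centroid (smallest area on the rare overlap, which segmentation
    invariants should preclude); orphan inclusions are logged and ignored.
    ``cells`` needs a cell_id column; every polygon id must appear there.
    """
    cell_ids = list(cells["cell_id"])
    known = set(cell_ids)
    for poly in polygons:
        if poly.cell_id not in known:
            raise ValueError(f"polygon {poly.cell_id!r} has no cell metadata row")

    shapes = [p.shapely for p in polygons]
    tree = STRtree(shapes)
    n_incl: dict[str, int] = {cid: 0 for cid in cell_ids}
    orphans = 0
    for inc in inclusions:
        if inc.centroid_spatial is None:
            raise ValueError("inclusion centroids must be mapped to spatial um first")
        pt = Point(inc.centroid_spatial)
        hits = [i for i in tree.query(pt) if shapes[i].covers(pt)]
        if not hits:
            orphans += 1
            inc.cell_id = None
            continue
        if len(hits) > 1:
            areas = [shapes[i].area for i in hits]
            log.warning(
                "inclusion %d centroid inside %d overlapping polygons; "
                "assigning smallest", inc.inclusion_id, len(hits),
            )
            hits = [hits[int(np.argmin(areas))]]
        cid = polygons[hits[0]].cell_id
        inc.cell_id = cid
        n_incl[cid] += 1
    if orphans:
        log.info("%d orphan inclusions (centroid in no cell) excluded", orphans)
    return [
        PSynCall(cid, "pos" if n_incl[cid] >= 1 else "neg", n_incl[cid])
        for cid in cell_ids
    ]


def calls_to_frame(calls: list[PSynCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "status": [c.status for c in calls],
            "n_inclusions": [c.n_inclusions for c in calls],
        }
    )
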