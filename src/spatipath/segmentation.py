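"""Cell boundary generation by bounded nuclear expansion.

Imaging spatial transcriptomics platforms segment nuclei from a DAPI stain
and then grow each nucleus outward by a fixed distance (here 5 um by
default) to approximate the cell body, stopping early where two expansions
would collide. This module reproduces that contract on label masks:

* every output pixel is assigned the label of the nucleus whose pixel set is
  nearest in Euclidean distance, iff that distance is within the expansion
  radius; ties go to the smaller label;
* nucleus pixels always keep their own label.

``mask_to_polygons`` then traces each territory's outer contour so the
downstream overlay can test inclusion centroids against cell boundaries.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure

from .io_formats import CellPolygon

__all__ = ["expand_nuclei", "mask_to_polygons"]

log = logging.getLogger(__name__)


def expand_nuclei(
    mask: np.ndarray, distance_um: float, pixel_size_um: float = 1.0
) -> np.ndarray:
    """Expand each labelled nucleus by ``distance_um``, truncating at collisions.

    Parameters
    ----------
    mask:
        2D integer label mask; 0 is background, k>0 a nucleus.
    distance_um:
        Maximum Euclidean distance (um) from the nucleus pixel set.
    pixel_size_um:
        Physical size of one pixel.

    Returns
    -------
    A new label mask in which every pixel within ``distance_um`` of some
    nucleus carries the label of the nearest nucleus (ties toward the
    smaller label); all input nucleus pixels keep their labels.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be a 2D integer label array")
    if distance_um < 0:
        raise ValueError("distance_um must be >= 0")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no labels")

    dist_px2 = (distance_um / pixel_size_um) ** 2
    pad = int(np.ceil(np.sqrt(dist_px2)))
    out = np.zeros_like(mask)
    best = np.full(mask.shape, np.inf)

    # Per-label exact EDT inside a padded bounding box. Squared distances
    # between integer pixel centers are integers, so rounding d**2 makes
    # every comparison (threshold and tie-break) exact. Processing labels in
    # ascending order with strict improvement gives the smaller label on ties.
    objects = ndimage.find_objects(mask)
    for lab in labels:
        sl = objects[lab - 1]
        if sl is None:
            continue
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, mask.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, mask.shape[1])
        box = mask[r0:r1, c0:c1]
        d2 = np.rint(ndimage.distance_transform_edt(box != lab) ** 2)
        win_out = out[r0:r1, c0:c1]
        win_best = best[r0:r1, c0:c1]
        take = (d2 <= dist_px2 + 1e-6) & (d2 < win_best)
        win_out[take] = lab
        win_best[take] = d2[take]

    # nucleus pixels always keep their own label (d == 0 guarantees it, but
    # make the invariant explicit against any floating-point edge)
    nuc = mask > 0
    out[nuc] = mask[nuc]
    return out


def mask_to_polygons(
    mask: np.ndarray, pixel_size_um: float = 1.0, id_prefix: str = "cell_"
) -> list[CellPolygon]:
    """Trace each label's outer contour into a boundary polygon in um.

    Holes are ignored (outer contour only) and labels too small to form a
    ring (<3 boundary pixels) are dropped; both events are logged. Polygon
    area tracks the label's pixel count times the pixel area to within a
    couple of pixel-areas (the contour passes midway between foreground and
    background pixel centers).
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    polys: list[CellPolygon] = []
    objects = ndimage.find_objects(mask)
    for lab in labels:
        sl = objects[lab - 1]
        r0, c0 = sl[0].start, sl[1].start
        if (mask[sl] == lab).sum() < 3:
            log.warning("label %d: <3 boundary pixels, dropped", lab)
            continue
        box = np.pad((mask[sl] == lab).astype(float), 1)
        contours = measure.find_contours(box, 0.5)
        if not contours:
            log.warning("label %d: no traceable contour, dropped", lab)
            continue
        contour = max(contours, key=len)  # outer ring; holes ignored
        if len(contours) > 1:
            log.warning("label %d: %d holes ignored", lab, len(contours) - 1)
        # contour is (row, col) in the padded box frame; shift back and
        # convert to (x, y) um. Drop the duplicated closing vertex.
        rows = contour[:-1, 0] + (r0 - 1)
        cols = contour[:-1, 1] + (c0 - 1)
        verts = np.column_stack([cols, rows]) * pixel_size_um
        # collapse collinear runs to keep polygons small
        verts = _simplify_collinear(verts)
        if len(verts) < 3:
            log.warning("label %d: degenerate contour (<3 vertices), dropped", lab)
            continue
        try:
            polys.append(CellPolygon(f"{id_prefix}{lab}", tuple(map(tuple, verts))))
        except ValueError:
            log.warning("label %d: invalid ring, dropped", lab)
    return polys


def _simplify_collinear(verts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Remove vertices lying on the segment between their neighbours."""
    n = len(verts)
    if n < 4:
        return verts
    keep = np.ones(n, dtype=bool)
    prev = np.roll(verts, 1, axis=0)
    nxt = np.roll(verts, -1, axis=0)
    cross = (verts[:, 0] - prev[:, 0]) * (nxt[:, 1] - prev[:, 1]) - (
        verts[:, 1] - prev[:, 1]
    ) * (nxt[:, 0] - prev[:, 0])
    keep = np.abs(cross) > tol
    if keep.sum() < 3:
        return verts
    return verts[keep]
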