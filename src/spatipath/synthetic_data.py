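"""Synthetic Xenium-like tissue sections with known ground truth.

The generator emulates the study design this package analyses: a 2x2x2
layout of mouse cortical sections (transgenic for human alpha-synuclein or
non-transgenic, male or female, several samples per group), each carrying

* layered tissue geometry — excitatory-neuron subtypes restricted to
  cortical-depth bands, inhibitory neurons and glia scattered throughout;
* per-cell-type negative-binomial expression over a small targeted gene
  panel that includes the human transgene (hSNCA, transgenic samples only),
  the endogenous mouse gene (mSnca), the kinase Plk2 with a planted
  across-type gradient, cell-type marker genes, and filler genes;
* a planted pathology mechanism — each cell's probability of carrying a
  phospho-synuclein (pSyn) inclusion follows a logistic model in its own
  hSNCA and Plk2 expression plus a cell-class offset;
* a rendered immunofluorescence image in a perturbed (rotated/translated)
  pixel frame, together with the true image->spatial affine.

Every planted quantity (cell types, pSyn states, inclusion centroids,
expression fold changes, the affine) is recorded in :class:`GroundTruth`,
so each downstream module can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import AffineTransform, CountMatrix, SampleBundle
from .segmentation import expand_nuclei, mask_to_polygons

__all__ = [
    "CellTypeSpec",
    "GeneSpec",
    "PathologyParams",
    "ImagingParams",
    "SimulationConfig",
    "GroundTruth",
    "default_config",
    "generate_tissue",
    "sample_counts",
    "assign_pathology",
    "render_if_image",
]


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type: where it lives and how it expresses."""

    name: str
    cell_class: str  # ExN | InN | NonNeuronal
    layer: tuple[float, float] | None  # depth band as fractions, None = scattered
    density_per_mm2: float
    nucleus_radius_um: float = 3.0
    mean_library_size: float = 250.0
    psyn_offset: float = 0.0  # additive logit offset for the pathology model


@dataclass(frozen=True)
class GeneSpec:
    """One panel gene: relative expression rate per cell type."""

    name: str
    panel: str  # base | custom
    rates: dict[str, float]
    dispersion: float = 0.3  # NB dispersion alpha, Var = mu + alpha*mu^2; 0 = Poisson


@dataclass(frozen=True)
class PathologyParams:
    """Logistic inclusion model: logit P(pSyn+) = b0 + b_snca*x + b_plk2*x + b_type.

    Covariates are the cell's log-normalized hSNCA and Plk2 values;
    non-transgenic cells are always pSyn-negative.
    """

    beta0: float = -7.6
    beta_snca: float = 0.3
    beta_plk2: float = 0.8


@dataclass(frozen=True)
class ImagingParams:
    """IF image rendering and registration perturbation."""

    pixel_size_um: float = 1.0
    inclusion_radius_um: float = 1.5
    inclusion_intensity: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 5.0
    rotation_max_deg: float = 5.0
    translation_max_um: float = 30.0
    margin_um: float = 60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment.

    ``n_per_group`` samples are generated for each genotype x sex cell of
    the 2x2 design. ``spike_genotype`` / ``spike_psyn`` multiply a gene's
    rate by 2**log2fc in transgenic cells / pSyn+ cells respectively and
    are recorded as ground truth for differential-expression recovery.
    """

    n_per_group: int = 1
    width_um: float = 600.0
    height_um: float = 450.0
    mask_pixel_um: float = 0.5
    expand_um: float = 5.0
    scale_factor: float = 1e4
    library_size_cv: float = 0.25
    cell_types: tuple[CellTypeSpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    pathology: PathologyParams = field(default_factory=PathologyParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    spike_genotype: dict[str, float] = field(default_factory=dict)
    spike_psyn: dict[str, float] = field(default_factory=dict)
    sex_snca_multiplier: dict[str, float] = field(
        default_factory=lambda: {"M": 1.25, "F": 1.0}
    )
    transgene: str = "hSNCA"
    kinase: str = "Plk2"
    region: str = "cortex"

    def __post_init__(self) -> None:
        if not self.cell_types or not self.genes:
            return
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        for t in self.cell_types:
            if t.layer is not None:
                lo, hi = t.layer
                if not (0.0 <= lo < hi <= 1.0):
                    raise ValueError(f"{t.name}: layer band must satisfy 0<=lo<hi<=1")
            if t.density_per_mm2 < 0 or t.nucleus_radius_um <= 0:
                raise ValueError(f"{t.name}: invalid density or radius")
        for g in self.genes:
            if g.dispersion < 0:
                raise ValueError(f"{g.name}: dispersion must be >= 0")
            if any(r < 0 for r in g.rates.values()):
                raise ValueError(f"{g.name}: rates must be >= 0")
            if g.panel not in ("base", "custom"):
                raise ValueError(f"{g.name}: panel must be base|custom")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def rate_matrix(self) -> pd.DataFrame:
        """Types x genes relative expression rates."""
        return pd.DataFrame(
            {g.name: [g.rates.get(t.name, 0.0) for t in self.cell_types] for g in self.genes},
            index=[t.name for t in self.cell_types],
        )


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery testing.

    ``cells`` has one row per cell: cell_id, sample_id, cell_type, psyn
    (bool), and the planted inclusion centroid in spatial um (NaN for
    pSyn- cells). ``affines`` maps sample_id to the true image->spatial
    transform; ``spikes`` records planted log2 fold changes.
    """

    cells: pd.DataFrame
    affines: dict[str, AffineTransform]
    spikes: pd.DataFrame


# ---------------------------------------------------------------------------
# Default experiment
# ---------------------------------------------------------------------------

_EXN = "ExN"
_INN = "InN"
_NON = "NonNeuronal"

_TYPES = (
    CellTypeSpec("L2/3 IT ExN", _EXN, (0.00, 0.30), 2000.0),
    CellTypeSpec("L4/5 IT ExN", _EXN, (0.30, 0.45), 2000.0),
    CellTypeSpec("L5 ET ExN", _EXN, (0.45, 0.65), 1200.0),
    CellTypeSpec("L5 IT ExN", _EXN, (0.45, 0.65), 1200.0),
    CellTypeSpec("L6 ExN", _EXN, (0.65, 1.00), 1800.0),
    CellTypeSpec("InN", _INN, None, 600.0, mean_library_size=220.0, psyn_offset=-1.5),
    CellTypeSpec(
        "Astro", _NON, None, 400.0, nucleus_radius_um=2.5,
        mean_library_size=120.0, psyn_offset=-2.0,
    ),
    CellTypeSpec(
        "Micro", _NON, None, 250.0, nucleus_radius_um=2.5,
        mean_library_size=120.0, psyn_offset=-2.0,
    ),
)

_TYPE_NAMES = [t.name for t in _TYPES]


def _rates(values: list[float]) -> dict[str, float]:
    return dict(zip(_TYPE_NAMES, values))


def _default_genes(n_filler: int = 24) -> tuple[GeneSpec, ...]:
    #                 L2/3  L4/5  L5ET  L5IT   L6   InN   Ast   Mic
    base = [
        GeneSpec("Slc17a7", "base", _rates([20, 20, 20, 20, 20, 0.2, 0.1, 0.1])),
        GeneSpec("Gad1", "base", _rates([0.2, 0.2, 0.2, 0.2, 0.2, 25, 0.1, 0.1])),
        GeneSpec("Aqp4", "base", _rates([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 30, 0.2])),
        GeneSpec("Cx3cr1", "base", _rates([0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2, 30])),
        GeneSpec("Cux2", "base", _rates([15, 2, 0.5, 0.5, 0.5, 3, 0.5, 0.5])),
        GeneSpec("Rorb", "base", _rates([2, 15, 1, 1, 0.5, 0.5, 0.5, 0.5])),
        GeneSpec("Fezf2", "base", _rates([0.5, 1, 15, 2, 3, 0.5, 0.2, 0.2])),
        GeneSpec("Etv1", "base", _rates([0.5, 1, 2, 12, 2, 0.5, 0.2, 0.2])),
        GeneSpec("Foxp2", "base", _rates([0.3, 0.5, 1, 1, 14, 1, 0.2, 0.2])),
        GeneSpec("mSnca", "base", _rates([5, 5, 5, 5, 5, 4, 1, 1])),
    ]
    custom = [
        GeneSpec("hSNCA", "custom", _rates([30, 30, 32, 28, 30, 12, 4, 4])),
        GeneSpec("Plk2", "custom", _rates([6, 6, 12, 3, 8, 1, 0.5, 0.5])),
    ]
    # type-independent filler genes: fixed rates so they carry no
    # vulnerability signal; frozen RNG keeps the panel stable across runs
    frng = np.random.default_rng(20240612)
    for i in range(n_filler):
        rate = float(np.round(frng.lognormal(np.log(2.0), 0.6), 3))
        custom.append(
            GeneSpec(f"Filler{i + 1:02d}", "custom", _rates([rate] * len(_TYPE_NAMES)), 0.3)
        )
    return tuple(base + custom)


def default_config(**overrides) -> SimulationConfig:
    """The default simulated experiment (cortical section, full panel)."""
    cfg = SimulationConfig(cell_types=_TYPES, genes=_default_genes())
    return replace(cfg, **overrides) if overrides else cfg


def mechanism_config(
    n_types: int = 8,
    beta_plk2: float = 1.0,
    beta_snca: float = 0.0,
    n_filler: int = 24,
) -> SimulationConfig:
    """A rate-balanced benchmark where only the kinase drives vulnerability.

    Cell types differ solely in their Plk2 rate (log-spaced 1..12); a
    padding gene absorbs the difference so every type has the same total
    rate. Library-size normalization therefore leaves filler genes with
    identical expected expression in every type — they are genuinely null
    for the vulnerability regression, unlike in :func:`default_config`
    where compositional closure couples them to the marker/kinase gradient.
    """
    plk2_rates = np.round(np.geomspace(1.0, 12.0, n_types), 3)
    types = tuple(
        CellTypeSpec(f"T{i + 1:02d}", _EXN, None, 400.0) for i in range(n_types)
    )
    names = [t.name for t in types]
    genes = [
        GeneSpec("hSNCA", "custom", {n: 20.0 for n in names}),
        GeneSpec("mSnca", "base", {n: 5.0 for n in names}),
        GeneSpec("Plk2", "custom", dict(zip(names, map(float, plk2_rates)))),
        GeneSpec(
            "Pad", "base",
            dict(zip(names, (float(plk2_rates.max() - r + 2.0) for r in plk2_rates))),
        ),
    ]
    for i in range(n_filler):
        genes.append(GeneSpec(f"Filler{i + 1:02d}", "custom", {n: 2.0 for n in names}))
    # beta0 centers the most kinase-rich type near 50% pathology
    x_top = float(np.log1p(250.0 * plk2_rates.max() / 87.0 / 250.0 * 1e4))
    pathology = PathologyParams(
        beta0=-beta_plk2 * x_top, beta_snca=beta_snca, beta_plk2=beta_plk2
    )
    return SimulationConfig(cell_types=types, genes=tuple(genes), pathology=pathology)


# ---------------------------------------------------------------------------
# Cell placement
# ---------------------------------------------------------------------------


def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Poisson placement per type with hard-core nucleus separation.

    Candidate centers are drawn uniformly in the type's depth band and
    rejected if closer than the sum of nucleus radii (plus one mask pixel)
    to any accepted cell; bounded retries guard against infeasible density.
    """
    w, h = config.width_um, config.height_um
    rows: list[tuple[float, float, str, float, float]] = []
    accepted = np.empty((0, 2))
    radii = np.empty(0)
    for spec in config.cell_types:
        lo, hi = spec.layer if spec.layer is not None else (0.0, 1.0)
        band_area_mm2 = w * (hi - lo) * h / 1e6
        n = rng.poisson(spec.density_per_mm2 * band_area_mm2)
        placed = 0
        attempts = 0
        max_attempts = 200 * max(n, 1)
        r = spec.nucleus_radius_um
        while placed < n:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {n} cells of {spec.name!r} after "
                    f"{max_attempts} attempts; lower density_per_mm2"
                )
            x = rng.uniform(r, w - r)
            y = rng.uniform(max(lo * h, r), min(hi * h, h - r))
            if accepted.shape[0]:
                d2 = np.sum((accepted - (x, y)) ** 2, axis=1)
                min_sep = radii + r + config.mask_pixel_um
                if np.any(d2 < min_sep**2):
                    continue
            accepted = np.vstack([accepted, (x, y)])
            radii = np.append(radii, r)
            rows.append((x, y, spec.name, r, spec.mean_library_size))
            placed += 1
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "cell_type", "radius_um", "mean_lib"])
    # spatially shuffle so cell index carries no layer information
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB draws with Var = mu + alpha*mu^2; alpha = 0 is the Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def sample_counts(
    cells: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    genotype: str = "tg",
    sex: str = "F",
    psyn: np.ndarray | None = None,
) -> CountMatrix:
    """Draw the cells x genes count matrix.

    counts[c, g] ~ NB(mean = lib_c * rate[type_c, g] / sum_g rate[type_c, :],
    dispersion alpha_g). Non-transgenic samples have the transgene rate
    forced to zero; genotype/pSyn spike-ins multiply rates by 2**log2fc.
    """
    n = len(cells)
    rate = config.rate_matrix().loc[cells["cell_type"].to_numpy()].to_numpy(dtype=float)
    gene_names = config.gene_names
    gidx = {g: i for i, g in enumerate(gene_names)}

    if config.transgene in gidx:
        j = gidx[config.transgene]
        if genotype != "tg":
            rate[:, j] = 0.0
        else:
            rate[:, j] *= config.sex_snca_multiplier.get(sex, 1.0)
    if genotype == "tg":
        for gene, lfc in config.spike_genotype.items():
            rate[:, gidx[gene]] *= 2.0**lfc
    if psyn is not None:
        for gene, lfc in config.spike_psyn.items():
            rate[np.asarray(psyn, bool), gidx[gene]] *= 2.0**lfc

    totals = rate.sum(axis=1)
    totals[totals == 0] = 1.0
    mean_lib = cells["mean_lib"].to_numpy(dtype=float)
    cv = config.library_size_cv
    if cv > 0:
        lib = rng.gamma(shape=1.0 / cv**2, scale=mean_lib * cv**2)
    else:
        lib = mean_lib
    mu = lib[:, None] * rate / totals[:, None]

    cols = np.empty((n, len(gene_names)), dtype=np.int64)
    for j, gene in enumerate(gene_names):
        cols[:, j] = _nb_draw(rng, mu[:, j], config.genes[j].dispersion)
    counts = sp.csr_matrix(cols)
    return CountMatrix(
        counts=counts,
        cell_ids=list(cells["cell_id"]) if "cell_id" in cells else [str(i) for i in range(n)],
        gene_names=list(gene_names),
        panel=[g.panel for g in config.genes],
    )


def _resample_psyn_spikes(
    cm: CountMatrix,
    cells: pd.DataFrame,
    psyn: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Redraw spiked genes for pSyn+ cells after pathology assignment.

    Pathology depends on expression, so baseline counts must be drawn
    first; only the spiked columns of pSyn+ cells are then resampled with
    the multiplied rate.
    """
    if not config.spike_psyn or not np.any(psyn):
        return cm
    dense = cm.counts.toarray()
    rate = config.rate_matrix().loc[cells["cell_type"].to_numpy()].to_numpy(dtype=float)
    gidx = {g: i for i, g in enumerate(cm.gene_names)}
    totals = rate.sum(axis=1)
    totals[totals == 0] = 1.0
    lib = dense.sum(axis=1).astype(float)  # realized library as the size proxy
    pos = np.asarray(psyn, bool)
    for gene, lfc in config.spike_psyn.items():
        j = gidx[gene]
        mu = lib[pos] * rate[pos, j] * 2.0**lfc / totals[pos]
        dense[pos, j] = _nb_draw(rng, mu, config.genes[j].dispersion)
    return CountMatrix(
        counts=sp.csr_matrix(dense),
        cell_ids=cm.cell_ids,
        gene_names=cm.gene_names,
        panel=cm.panel,
    )


# ---------------------------------------------------------------------------
# Pathology
# ---------------------------------------------------------------------------


def assign_pathology(
    cells: pd.DataFrame,
    x_snca: np.ndarray,
    x_plk2: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    genotype: str = "tg",
) -> np.ndarray:
    """Draw per-cell pSyn states from the planted logistic mechanism.

    logit P = beta0 + beta_snca * x_snca + beta_plk2 * x_plk2 + offset(type),
    with x the cell's log-normalized transgene / kinase values. Cells of
    non-transgenic samples are always negative.
    """
    n = len(cells)
    if genotype != "tg":
        return np.zeros(n, dtype=bool)
    p = config.pathology
    offsets = {t.name: t.psyn_offset for t in config.cell_types}
    off = cells["cell_type"].map(offsets).to_numpy(dtype=float)
    eta = p.beta0 + p.beta_snca * np.asarray(x_snca) + p.beta_plk2 * np.asarray(x_plk2) + off
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return rng.uniform(size=n) < prob


# ---------------------------------------------------------------------------
# IF image rendering
# ---------------------------------------------------------------------------


def _sample_affine(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[AffineTransform, tuple[int, int]]:
    """Sample the true image->spatial affine and size the canvas to fit.

    The image frame is the tissue frame rotated about the tissue center and
    translated, at the configured pixel size; the canvas covers the tissue
    bounding box plus a margin in that frame.
    """
    im = config.imaging
    theta = rng.uniform(-im.rotation_max_deg, im.rotation_max_deg)
    tx = rng.uniform(-im.translation_max_um, im.translation_max_um)
    ty = rng.uniform(-im.translation_max_um, im.translation_max_um)

    th = np.deg2rad(theta)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    center = np.array([config.width_um / 2.0, config.height_um / 2.0])

    # spatial -> image um: rotate back about center, then shift
    corners = np.array(
        [[0, 0], [config.width_um, 0], [0, config.height_um], [config.width_um, config.height_um]]
    )
    img_um = (corners - center) @ rot + center - (tx, ty)
    origin = img_um.min(axis=0) - im.margin_um
    extent = img_um.max(axis=0) + im.margin_um - origin
    shape = (
        int(np.ceil(extent[1] / im.pixel_size_um)),  # rows
        int(np.ceil(extent[0] / im.pixel_size_um)),  # cols
    )

    # image px -> spatial um: px -> image um -> undo shift -> rotate forward
    # spatial = R @ (px*s + origin + t - center) + center
    lin = rot.T * im.pixel_size_um  # note: forward rotation is rot.T here
    shift = rot.T @ (origin + (tx, ty) - center) + center
    m = np.array(
        [[lin[0, 0], lin[0, 1], shift[0]], [lin[1, 0], lin[1, 1], shift[1]], [0, 0, 1]]
    )
    return AffineTransform(m), shape


def render_if_image(
    cells: pd.DataFrame,
    psyn: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    perturb_affine: bool = True,
) -> tuple[np.ndarray, AffineTransform, np.ndarray]:
    """Render the pSyn immunofluorescence image.

    One disk inclusion is drawn at each pSyn+ cell's nucleus center (a
    deep-interior point of its boundary polygon, so clipping never detaches
    the centroid from the owning cell), in image coordinates obtained via
    the inverse of the sampled true affine. Gaussian background noise is
    added. Returns (image, true_affine, planted spatial centroids).
    """
    im = config.imaging
    if perturb_affine:
        affine, shape = _sample_affine(config, rng)
    else:
        affine = AffineTransform.from_parts(scale=im.pixel_size_um)
        shape = (
            int(np.ceil(config.height_um / im.pixel_size_um)),
            int(np.ceil(config.width_um / im.pixel_size_um)),
        )
    img = np.full(shape, im.background_level, dtype=float)
    if im.noise_sd > 0:
        img += rng.normal(0.0, im.noise_sd, size=shape)

    pos = np.asarray(psyn, bool)
    planted = cells.loc[pos, ["x_um", "y_um"]].to_numpy(dtype=float)
    inv = affine.inverse()
    r_px = im.inclusion_radius_um / im.pixel_size_um
    rr = int(np.ceil(r_px))
    for pt in planted:
        cx, cy = inv.apply(pt)
        x0, x1 = int(np.floor(cx - rr)), int(np.ceil(cx + rr)) + 1
        y0, y1 = int(np.floor(cy - rr)), int(np.ceil(cy + rr)) + 1
        x0, x1 = max(x0, 0), min(x1, shape[1])
        y0, y1 = max(y0, 0), min(y1, shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        img[y0:y1, x0:x1][disk] = im.inclusion_intensity
    img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    return img, affine, planted


# ---------------------------------------------------------------------------
# Whole-experiment generation
# ---------------------------------------------------------------------------


def _lognorm_gene(
    cm: CountMatrix, gene: str, scale_factor: float
) -> np.ndarray:
    lib = cm.library_sizes().astype(float)
    lib[lib == 0] = 1.0
    col = np.asarray(cm.counts[:, cm.gene_index(gene)].todense()).ravel()
    return np.log1p(col / lib * scale_factor)


def generate_sample(
    config: SimulationConfig,
    sample_id: str,
    genotype: str,
    sex: str,
    rng: np.random.Generator,
    render_image: bool = True,
    perturb_affine: bool = True,
) -> tuple[SampleBundle, pd.DataFrame, AffineTransform | None]:
    """Generate one tissue section; returns (bundle, truth rows, true affine)."""
    cells = _place_cells(config, rng)
    cells["cell_id"] = [f"{sample_id}_c{i + 1}" for i in range(len(cells))]

    # rasterize nuclei and run the segmentation contract to get boundaries
    px = config.mask_pixel_um
    h_px = int(np.ceil(config.height_um / px))
    w_px = int(np.ceil(config.width_um / px))
    mask = np.zeros((h_px, w_px), dtype=np.int32)
    yy, xx = np.mgrid[0:h_px, 0:w_px]
    for i, row in enumerate(cells.itertuples()):
        cx, cy, r = row.x_um / px, row.y_um / px, row.radius_um / px
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h_px)
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w_px)
        disk = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2 <= r**2
        mask[y0:y1, x0:x1][disk] = i + 1
    expanded = expand_nuclei(mask, config.expand_um, pixel_size_um=px)
    polys = mask_to_polygons(expanded, pixel_size_um=px, id_prefix=f"{sample_id}_c")

    counts = sample_counts(cells, config, rng, genotype=genotype, sex=sex)
    x_snca = _lognorm_gene(counts, config.transgene, config.scale_factor)
    x_plk2 = _lognorm_gene(counts, config.kinase, config.scale_factor)
    psyn = assign_pathology(cells, x_snca, x_plk2, config, rng, genotype=genotype)
    counts = _resample_psyn_spikes(counts, cells, psyn, config, rng)

    image = None
    affine = None
    planted = np.empty((0, 2))
    if render_image:
        image, affine, planted = render_if_image(
            cells, psyn, config, rng, perturb_affine=perturb_affine
        )

    meta = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "sample_id": sample_id,
            "genotype": genotype,
            "sex": sex,
            "region": config.region,
            "x_um": cells["x_um"],
            "y_um": cells["y_um"],
        }
    )
    bundle = SampleBundle(
        sample_id=sample_id,
        genotype=genotype,
        sex=sex,
        polygons=polys,
        counts=counts,
        cells=meta,
        image=image,
        pixel_size_um=config.imaging.pixel_size_um,
        affine=affine,
    )
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "sample_id": sample_id,
            "cell_type": cells["cell_type"],
            "psyn": psyn,
            "incl_x_um": np.where(psyn, cells["x_um"], np.nan),
            "incl_y_um": np.where(psyn, cells["y_um"], np.nan),
        }
    )
    return bundle, truth, affine


def generate_tissue(
    config: SimulationConfig,
    seed: int,
    render_images: bool = True,
    perturb_affine: bool = True,
) -> tuple[list[SampleBundle], GroundTruth]:
    """Generate the full 2 (genotype) x 2 (sex) x n_per_group experiment.

    Deterministic for a fixed seed: each sample draws from its own child
    stream of ``SeedSequence(seed)``, so bundles are byte-stable and
    independent of generation order.
    """
    ss = np.random.SeedSequence(seed)
    bundles: list[SampleBundle] = []
    truths: list[pd.DataFrame] = []
    affines: dict[str, AffineTransform] = {}
    groups = [
        (genotype, sex)
        for genotype in ("non_tg", "tg")
        for sex in ("M", "F")
    ]
    children = ss.spawn(len(groups) * config.n_per_group)
    k = 0
    for genotype, sex in groups:
        for i in range(config.n_per_group):
            sample_id = f"{genotype}_{sex}{i + 1}"
            rng = np.random.default_rng(children[k])
            k += 1
            bundle, truth, affine = generate_sample(
                config, sample_id, genotype, sex, rng,
                render_image=render_images, perturb_affine=perturb_affine,
            )
            bundles.append(bundle)
            truths.append(truth)
            if affine is not None:
                affines[sample_id] = affine
    spikes = pd.DataFrame(
        [("genotype", g, l) for g, l in config.spike_genotype.items()]
        + [("psyn", g, l) for g, l in config.spike_psyn.items()],
        columns=["scope", "gene", "log2fc"],
    )
    return bundles, GroundTruth(
        cells=pd.concat(truths, ignore_index=True), affines=affines, spikes=spikes
    )
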