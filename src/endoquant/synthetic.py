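"""Ground-truthed synthetic microscopy fields and cytometry event tables.

No raw microscopy or cytometry data accompany the published summaries, so
every downstream stage is exercised on simulated data with known truth:

* adherent-cell mimics drawn as star-convex radial perturbations of an
  ellipse, placed without overlap by dart throwing;
* a receptor channel with a bright membrane rim plus a dimmer cytoplasmic
  haze, and a QD channel of point-source puncta split between the membrane
  band and a deep-interior (endosomal) region according to a log-logistic
  internalization time course;
* Poisson shot noise on signal + background and Gaussian read noise;
* bivariate log-normal cytometry populations (transfected / untransfected
  x labeled / unlabeled) with a per-event acid-strip flag: stripped
  surface-bound label falls back to the unlabeled QD distribution, so only
  internalized label keeps a high QD intensity.

Everything is deterministic for a fixed seed (independent child generators
are spawned per field / per sample from the master seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as sk_polygon
from skimage.morphology import disk

from .fov import FieldOfView

__all__ = [
    "KineticsSpec",
    "ImagingNoiseSpec",
    "CellGeometryParams",
    "CellGroundTruth",
    "ImagingSimConfig",
    "EventSimConfig",
    "interior_fraction_timecourse",
    "generate_cell",
    "render_field",
    "generate_image_dataset",
    "generate_event_dataset",
]


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class KineticsSpec:
    """Truth parameters of the log-logistic internalization time course.

    f(t) = a2 + (a1 - a2) / (1 + (t/x0)^p), f(0) = a1, with baseline
    fraction ``a1``, plateau ``a2`` (0 <= a1 < a2 <= 1), center time ``x0``
    (min > 0) and power ``p`` (> 0).
    """

    a1: float
    a2: float
    x0: float
    p: float

    def __post_init__(self):
        if not (0 <= self.a1 < self.a2 <= 1):
            raise ValueError("require 0 <= a1 < a2 <= 1")
        if self.x0 <= 0 or self.p <= 0:
            raise ValueError("require x0 > 0 and p > 0")


@dataclass(frozen=True)
class ImagingNoiseSpec:
    """Camera/optics model: scalar background, shot + read noise, Gaussian PSF.

    Defaults give a signal-to-noise ratio around 10 at punctum peaks.
    """

    background_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    psf_sigma: float = 1.5

    def __post_init__(self):
        if self.background_level < 0 or self.read_noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class CellGeometryParams:
    """Ranges for the star-convex cell geometry.

    ``interior_margin_px`` is the erosion depth of the punctum placement
    region for internalized label (endosomes sit in the deep cytoplasm,
    away from the cortex); ``None`` means membrane_band_width + 8.
    It is intentionally decoupled from the analysis erosion setting.
    """

    radius_range: tuple[float, float] = (18.0, 28.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.15)
    irregularity_range: tuple[float, float] = (0.0, 0.10)
    membrane_band_width: int = 4
    expression_range: tuple[float, float] = (800.0, 1600.0)
    n_puncta_range: tuple[int, int] = (30, 50)
    interior_margin_px: int | None = None
    n_boundary_points: int = 128

    @property
    def margin(self) -> int:
        if self.interior_margin_px is not None:
            return self.interior_margin_px
        return self.membrane_band_width + 8


@dataclass
class CellGroundTruth:
    """One simulated cell: geometry, expression and punctum budget."""

    cell_id: str
    center: tuple[float, float]  # (row, col) pixels
    angles: np.ndarray  # boundary parameterization, radians
    radii: np.ndarray  # boundary radius at each angle, pixels
    membrane_band_width: int
    expression_level: float
    n_puncta: int
    seed: int
    true_interior_fraction: float = math.nan
    border_touching: bool = False

    def mask(self, field_shape) -> np.ndarray:
        """Rasterize the boundary as a filled polygon mask."""
        rr = self.center[0] + self.radii * np.sin(self.angles)
        cc = self.center[1] + self.radii * np.cos(self.angles)
        out = np.zeros(field_shape, dtype=bool)
        pr, pc = sk_polygon(rr, cc, shape=field_shape)
        out[pr, pc] = True
        return out


@dataclass(frozen=True)
class ImagingSimConfig:
    """A simulated imaging experiment: ligands x times x fields."""

    ligands: dict  # ligand name -> KineticsSpec
    times: tuple = (0.0, 10.0, 20.0, 150.0)
    fields_per_timepoint: int = 3
    cells_per_field: int = 5
    field_shape: tuple[int, int] = (256, 256)
    geometry: CellGeometryParams = field(default_factory=CellGeometryParams)
    noise: ImagingNoiseSpec = field(default_factory=ImagingNoiseSpec)
    punctum_flux: float = 2500.0
    punctum_flux_cv: float = 0.2

    def __post_init__(self):
        if len(self.times) == 0:
            raise ValueError("times must be non-empty")
        if not self.ligands:
            raise ValueError("at least one ligand is required")


# ---------------------------------------------------------------------------
# time course

def interior_fraction_timecourse(spec: KineticsSpec, times):
    """True interior fraction f(t) at the requested times (minutes >= 0)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    with np.errstate(divide="ignore"):
        u = np.where(t > 0, t / spec.x0, 0.0)
        f = spec.a2 + (spec.a1 - spec.a2) / (1.0 + u**spec.p)
    f = np.where(t == 0, spec.a1, f)
    return float(f) if f.ndim == 0 else f


# ---------------------------------------------------------------------------
# cell geometry

def generate_cell(
    params: CellGeometryParams,
    seed: int,
    field_shape=(256, 256),
    center=None,
    cell_id: str = "cell",
) -> CellGroundTruth:
    """Draw one star-convex cell; deterministic for a fixed seed.

    The boundary is r(theta) = r0 * (1 + e cos 2(theta-phi)) modulated by
    low-order cosine modes scaled by the irregularity; with irregularity 0
    and eccentricity 0 the boundary is a circle.  The cell must fit inside
    the field (with a 1-px margin) unless a center is forced on it.
    """
    rng = np.random.default_rng(seed)
    r_lo, r_hi = params.radius_range
    if r_hi * 2 + 2 > min(field_shape):
        raise ValueError("requested radius does not fit in the field")
    r0 = rng.uniform(r_lo, r_hi)
    ecc = rng.uniform(*params.eccentricity_range)
    irr = rng.uniform(*params.irregularity_range)
    phi = rng.uniform(0, 2 * math.pi)
    theta = np.linspace(0, 2 * math.pi, params.n_boundary_points, endpoint=False)
    profile = 1.0 + ecc * np.cos(2 * (theta - phi))
    for m in (3, 4, 5):
        profile += irr * rng.uniform(-1, 1) * np.cos(m * theta + rng.uniform(0, 2 * math.pi))
    radii = r0 * profile / profile.max() * (1 + ecc)  # keep max radius ~ r0*(1+ecc)
    radii = np.clip(radii, 1.0, None)
    r_max = float(radii.max())

    border_touching = False
    if center is None:
        # 3-px clearance keeps cells off the border even after label growth
        lo, hi_r = r_max + 3, field_shape[0] - r_max - 3
        lo_c, hi_c = r_max + 3, field_shape[1] - r_max - 3
        center = (rng.uniform(lo, hi_r), rng.uniform(lo_c, hi_c))
    else:
        border_touching = (
            center[0] - r_max < 0 or center[0] + r_max >= field_shape[0]
            or center[1] - r_max < 0 or center[1] + r_max >= field_shape[1]
        )
    expression = rng.uniform(*params.expression_range)
    n_puncta = int(rng.integers(params.n_puncta_range[0], params.n_puncta_range[1] + 1))
    return CellGroundTruth(
        cell_id=cell_id,
        center=(float(center[0]), float(center[1])),
        angles=theta,
        radii=radii,
        membrane_band_width=params.membrane_band_width,
        expression_level=float(expression),
        n_puncta=n_puncta,
        seed=int(seed),
        border_touching=border_touching,
    )


def _place_cells(params, n_cells, field_shape, rng, max_attempts=500):
    """Non-overlapping dart-throwing placement; cells keep a 3-px gap."""
    cells, centers, radii = [], [], []
    for i in range(n_cells):
        for attempt in range(max_attempts):
            seed = int(rng.integers(0, 2**31 - 1))
            cell = generate_cell(params, seed=seed, field_shape=field_shape, cell_id=f"c{i:02d}")
            r = float(cell.radii.max())
            ok = all(
                math.hypot(cell.center[0] - c[0], cell.center[1] - c[1]) > r + rr + 3
                for c, rr in zip(centers, radii)
            )
            if ok:
                cells.append(cell)
                centers.append(cell.center)
                radii.append(r)
                break
        else:
            raise ValueError("field too small: could not place all cells without overlap")
    return cells


# ---------------------------------------------------------------------------
# rendering

def render_field(
    cells,
    fractions,
    noise: ImagingNoiseSpec,
    field_shape=(256, 256),
    seed: int | np.random.Generator = 0,
    punctum_flux: float = 2500.0,
    punctum_flux_cv: float = 0.2,
    haze_fraction: float = 0.25,
    metadata=None,
):
    """Render one two-channel field from ground-truth cells.

    Receptor channel: membrane band at the cell's expression level plus a
    ``haze_fraction`` cytoplasmic haze, blurred by the PSF.  QD channel:
    each cell's ``n_puncta`` point sources are assigned to the interior
    with probability f (its requested interior fraction) and to the
    membrane band otherwise, given a log-normal flux around
    ``punctum_flux``, blurred by the PSF.  Both channels then get the
    scalar background, optional Poisson shot noise and Gaussian read noise.

    Returns ``(FieldOfView, truth)`` where ``truth`` is a per-cell frame
    recording the requested fraction, the realized flux split and the
    realized flux-weighted interior fraction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(cells):
        raise ValueError("one interior fraction per cell is required")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")

    receptor = np.zeros(field_shape, dtype=float)
    qd_deltas = np.zeros(field_shape, dtype=float)
    rows = []
    for cell, f in zip(cells, fractions):
        cell_mask = cell.mask(field_shape)
        if not cell_mask.any():
            raise ValueError(f"cell {cell.cell_id} rasterized to an empty mask")
        band = cell_mask & ~ndi.binary_erosion(cell_mask, structure=disk(cell.membrane_band_width))
        margin = cell.membrane_band_width + 8
        deep = ndi.binary_erosion(cell_mask, structure=disk(margin))
        while not deep.any() and margin > 1:
            margin -= 2  # very small/irregular cell: relax the placement depth
            deep = ndi.binary_erosion(cell_mask, structure=disk(max(margin, 1)))
        if not deep.any():
            deep = cell_mask & ~band

        receptor += band * cell.expression_level
        receptor += cell_mask * (haze_fraction * cell.expression_level)

        n_int = int(rng.binomial(cell.n_puncta, f))
        n_mem = cell.n_puncta - n_int
        flux_int = flux_mem = 0.0
        for region, n_pts in ((deep, n_int), (band, n_mem)):
            if n_pts == 0:
                continue
            rr, cc = np.nonzero(region)
            idx = rng.integers(0, len(rr), size=n_pts)
            sigma_ln = math.sqrt(math.log(1 + punctum_flux_cv**2))
            fluxes = punctum_flux * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, size=n_pts)
            np.add.at(qd_deltas, (rr[idx], cc[idx]), fluxes)
            if region is deep:
                flux_int = float(fluxes.sum())
            else:
                flux_mem = float(fluxes.sum())
        total = flux_int + flux_mem
        rows.append(
            {
                "cell_id": cell.cell_id,
                "true_interior_fraction": float(f),
                "realized_interior_fraction": flux_int / total if total > 0 else math.nan,
                "flux_interior": flux_int,
                "flux_membrane": flux_mem,
                "n_puncta": cell.n_puncta,
                "n_puncta_interior": n_int,
                "expression_level": cell.expression_level,
                "cell_px": int(cell_mask.sum()),
                "seed": cell.seed,
            }
        )

    if noise.psf_sigma > 0:
        receptor = ndi.gaussian_filter(receptor, noise.psf_sigma)
        qd = ndi.gaussian_filter(qd_deltas, noise.psf_sigma)
    else:
        qd = qd_deltas

    out = []
    for chan in (receptor, qd):
        img = chan + noise.background_level
        if noise.shot_noise:
            img = rng.poisson(img).astype(float)
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0, noise.read_noise_sd, size=img.shape)
        out.append(np.maximum(img, 0.0))

    fov = FieldOfView(receptor=out[0], qd=out[1], metadata=dict(metadata or {}))
    return fov, pd.DataFrame(rows)


def generate_image_dataset(config: ImagingSimConfig, master_seed: int = 0):
    """Simulate the full imaging experiment: ligands x times x fields.

    Every cell at (ligand, time) carries the interior fraction prescribed
    by that ligand's time course.  Returns ``(fields, manifest)`` where
    ``fields`` is a list of (FieldOfView, per-cell truth) and ``manifest``
    one row per cell across the experiment.  Bit-identical for a fixed
    master seed.
    """
    ss = np.random.SeedSequence(master_seed)
    manifest_rows = []
    fields = []
    n_jobs = len(config.ligands) * len(config.times) * config.fields_per_timepoint
    children = ss.spawn(n_jobs)
    job = 0
    for ligand in sorted(config.ligands):
        spec = config.ligands[ligand]
        for t in config.times:
            f_true = float(interior_fraction_timecourse(spec, t))
            for k in range(config.fields_per_timepoint):
                rng = np.random.default_rng(children[job])
                job += 1
                field_id = f"{ligand}_t{t:g}_f{k:02d}"
                cells = _place_cells(config.geometry, config.cells_per_field, config.field_shape, rng)
                fov, truth = render_field(
                    cells,
                    fractions=[f_true] * len(cells),
                    noise=config.noise,
                    field_shape=config.field_shape,
                    seed=rng,
                    punctum_flux=config.punctum_flux,
                    punctum_flux_cv=config.punctum_flux_cv,
                    metadata={"ligand": ligand, "time_min": float(t), "field_id": field_id},
                )
                truth.insert(0, "field_id", field_id)
                truth.insert(1, "ligand", ligand)
                truth.insert(2, "time_min", float(t))
                fields.append((fov, truth))
                manifest_rows.append(truth)
    manifest = pd.concat(manifest_rows, ignore_index=True)
    return fields, manifest


# ---------------------------------------------------------------------------
# cytometry events

@dataclass(frozen=True)
class EventSimConfig:
    """Bivariate log-normal event populations for one simulated experiment.

    Channel locations/scales are (mu, sigma) of ln intensity.  Transfected
    events draw SYFP from the positive distribution; labeled transfected
    events carry full QD label unless acid treatment strips the
    surface-bound portion, in which case only events internalized by time t
    (Bernoulli with probability f(t) from ``kinetics``) keep the labeled QD
    distribution and the rest fall back to the unlabeled one.
    """

    n_events: int = 10_000
    transfected_fraction: float = 0.4
    labeled_fraction: float = 0.9
    syfp_neg: tuple[float, float] = (math.log(100.0), 0.5)
    syfp_pos: tuple[float, float] = (math.log(3000.0), 0.6)
    qd_neg: tuple[float, float] = (math.log(50.0), 0.5)
    qd_pos: tuple[float, float] = (math.log(2000.0), 0.6)
    times: tuple = (0.0, 20.0, 40.0, 90.0)
    kinetics: KineticsSpec = field(default_factory=lambda: KineticsSpec(0.15, 0.95, 35.0, 2.0))
    acid_treated: bool = True
    ligand: str = "IGF-II"
    n_control: int = 10_000

    def __post_init__(self):
        for name in ("transfected_fraction", "labeled_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.times) == 0 or 0.0 not in tuple(float(t) for t in self.times):
            raise ValueError("times must include 0")


def _lognormal(rng, mu_sigma, n):
    mu, sigma = mu_sigma
    return rng.lognormal(mu, sigma, size=n)


def generate_event_dataset(config: EventSimConfig, seed: int = 0):
    """Simulate per-time event tables plus an untransfected control table.

    Returns ``(tables_by_time, control, truth)``.  Tables carry ``syfp``
    and ``qd`` intensities (strictly positive) plus ground-truth boolean
    columns ``transfected``, ``labeled`` and ``internalized``; ``truth``
    summarizes realized subpopulation fractions per time.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.times) + 1)
    tables = {}
    truth_rows = []
    for child, t in zip(children, config.times):
        rng = np.random.default_rng(child)
        n = config.n_events
        transfected = rng.random(n) < config.transfected_fraction
        labeled = transfected & (rng.random(n) < config.labeled_fraction)
        f_t = float(interior_fraction_timecourse(config.kinetics, t))
        internalized = labeled & (rng.random(n) < f_t)

        syfp = _lognormal(rng, config.syfp_neg, n)
        syfp[transfected] = _lognormal(rng, config.syfp_pos, int(transfected.sum()))
        qd = _lognormal(rng, config.qd_neg, n)
        if config.acid_treated:
            keep = internalized  # surface-bound label stripped at low pH
        else:
            keep = labeled
        qd[keep] = _lognormal(rng, config.qd_pos, int(keep.sum()))

        tables[float(t)] = pd.DataFrame(
            {
                "event_id": np.arange(n),
                "syfp": syfp,
                "qd": qd,
                "time_min": float(t),
                "ligand": config.ligand,
                "acid_treated": config.acid_treated,
                "transfected": transfected,
                "labeled": labeled,
                "internalized": internalized,
            }
        )
        truth_rows.append(
            {
                "time_min": float(t),
                "true_interior_fraction": f_t,
                "realized_transfected_fraction": float(transfected.mean()),
                "realized_internalized_fraction": float(internalized[labeled].mean())
                if labeled.any()
                else math.nan,
            }
        )

    rng = np.random.default_rng(children[-1])
    control = pd.DataFrame(
        {
            "event_id": np.arange(config.n_control),
            "syfp": _lognormal(rng, config.syfp_neg, config.n_control),
            "qd": _lognormal(rng, config.qd_neg, config.n_control),
            "time_min": 0.0,
            "ligand": "none",
            "acid_treated": False,
            "transfected": False,
            "labeled": False,
            "internalized": False,
        }
    )
    return tables, control, pd.DataFrame(truth_rows)
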