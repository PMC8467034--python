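"""Parametric 2D neck phantom with stenosed carotid artery and jugular vein.

The phantom replaces a patient-specific neck cross-section with simple
parametric shapes: an elliptical neck with annular skin and fat layers, a
muscle background, and disc-shaped organs (cervical spine, trachea,
esophagus, two glands) and vessels (artery, vein).  Each grid cell carries
exactly one tissue label and the corresponding electrical conductivity.
Twelve point electrodes sit on the skin surface at equally spaced angles;
electrode 0 is the grounded reference.

Axis conventions: x increases rightward, y upward, blood flows along +z
(out of plane) in the artery and -z in the vein; the static magnetic field
is applied along +x.  Grids are cell-centered, 0-based, row-major with the
y index as the leading (row) axis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUES",
    "TISSUE_CONDUCTIVITY",
    "GridSpec",
    "VesselSpec",
    "PhantomConfig",
    "Phantom",
    "StenosisConfig",
    "FlowConfig",
    "VelocityField",
    "build_phantom",
    "default_config",
    "stenosis_mask",
    "pulsatile_waveform",
    "stenosis_velocity_coefficient",
    "velocity_field",
    "save_phantom",
    "load_phantom",
]

#: Tissue categories, in label-integer order.  "background" is the
#: non-conducting exterior of the neck ellipse.
TISSUES = (
    "background",
    "skin",
    "fat",
    "muscle",
    "esophagus",
    "cervical_spine",
    "glands",
    "trachea",
    "artery",
    "vein",
)

#: Default electrical conductivity per tissue in S/m.  Trachea and
#: esophagus are air-filled lumina and modelled as perfect insulators.
TISSUE_CONDUCTIVITY = {
    "background": 0.0,
    "skin": 0.005,
    "fat": 0.1,
    "muscle": 0.2,
    "esophagus": 0.0,
    "cervical_spine": 0.001,
    "glands": 0.6,
    "trachea": 0.0,
    "artery": 1.12,
    "vein": 1.12,
}

LABEL_INDEX = {name: i for i, name in enumerate(TISSUES)}


@dataclass(frozen=True)
class GridSpec:
    """Cell-centered rectangular grid.

    ``origin`` is the physical coordinate (m) of the center of cell
    (ix=0, iy=0); cell (ix, iy) is centered at origin + (ix*dx, iy*dy).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3 cells")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate arrays X, Y of shape (ny, nx)."""
        x = self.origin[0] + self.dx * np.arange(self.nx)
        y = self.origin[1] + self.dy * np.arange(self.ny)
        return np.meshgrid(x, y)

    def flat_index(self, ix: int, iy: int) -> int:
        return iy * self.nx + ix


@dataclass(frozen=True)
class VesselSpec:
    """Disc-shaped vessel: center (m) and radius (m)."""

    center: tuple[float, float]
    radius: float


@dataclass
class PhantomConfig:
    """Geometry and material configuration of the neck phantom.

    All lengths are meters.  Defaults approximate an adult neck: a
    120 x 100 mm elliptical cross-section, 2 mm skin and 4 mm fat layers,
    a 4 mm-radius common carotid artery and a 5 mm-radius internal jugular
    vein lying anterolaterally, so the combined blood area is well below
    10% of the cross-section.
    """

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            nx=130, ny=110, dx=0.001, dy=0.001, origin=(-0.0645, -0.0545)
        )
    )
    neck_semi_axes: tuple[float, float] = (0.060, 0.050)
    neck_center: tuple[float, float] = (0.0, 0.0)
    skin_thickness: float = 0.002
    fat_thickness: float = 0.004
    organs: dict = field(
        default_factory=lambda: {
            "cervical_spine": VesselSpec((0.0, -0.022), 0.013),
            "trachea": VesselSpec((0.0, 0.024), 0.008),
            "esophagus": VesselSpec((0.0, 0.010), 0.005),
            "glands": [
                VesselSpec((0.028, 0.026), 0.006),
                VesselSpec((-0.028, 0.026), 0.006),
            ],
        }
    )
    artery: VesselSpec = field(default_factory=lambda: VesselSpec((0.020, 0.014), 0.004))
    vein: VesselSpec = field(default_factory=lambda: VesselSpec((0.030, 0.016), 0.005))
    n_electrodes: int = 12
    e0_angle_deg: float = 90.0
    roi_shape: tuple[int, int] = (51, 51)
    roi_center: tuple[float, float] = (0.025, 0.015)
    conductivity_overrides: dict = field(default_factory=dict)

    def conductivity_table(self) -> dict:
        table = dict(TISSUE_CONDUCTIVITY)
        for name, value in self.conductivity_overrides.items():
            if name not in table:
                raise ValueError(f"unknown tissue {name!r}")
            if value < 0:
                raise ValueError("conductivity must be nonnegative")
            table[name] = float(value)
        return table


def default_config(scale: str = "small") -> PhantomConfig:
    """Stock configurations.

    ``"full"`` uses the 51x51 reconstruction window (n = 2601 units);
    ``"small"`` a 21x21 window and ``"coarse"`` an 11x11 window for quick
    runs.  Geometry in physical units is identical; only the grid pitch
    changes so the reconstruction window always covers both vessels.
    """
    if scale == "full":
        grid = GridSpec(nx=246, ny=206, dx=0.0005, dy=0.0005, origin=(-0.06125, -0.05125))
        roi = (51, 51)
    elif scale == "small":
        grid = GridSpec(nx=104, ny=88, dx=0.0012, dy=0.0012, origin=(-0.0618, -0.0522))
        roi = (21, 21)
    elif scale == "coarse":
        grid = GridSpec(nx=52, ny=44, dx=0.0024, dy=0.0024, origin=(-0.0612, -0.0516))
        roi = (11, 11)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return PhantomConfig(grid=grid, roi_shape=roi)


@dataclass
class Phantom:
    """Discretized neck phantom.

    ``labels`` and ``sigma`` have shape (ny, nx); ``electrodes`` holds the
    12 flat cell indices (e0 first) on the skin boundary; ``roi`` is the
    (iy0, ix0, h, w) cell-index window containing both vessels.
    """

    grid: GridSpec
    labels: np.ndarray
    sigma: np.ndarray
    electrodes: np.ndarray
    roi: tuple[int, int, int, int]
    config: PhantomConfig

    @property
    def n_measuring(self) -> int:
        return len(self.electrodes) - 1

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABEL_INDEX[tissue]

    @property
    def artery_mask(self) -> np.ndarray:
        return self.mask("artery")

    @property
    def vein_mask(self) -> np.ndarray:
        return self.mask("vein")

    @property
    def roi_slices(self) -> tuple[slice, slice]:
        iy0, ix0, h, w = self.roi
        return slice(iy0, iy0 + h), slice(ix0, ix0 + w)

    @property
    def n_units(self) -> int:
        return self.roi[2] * self.roi[3]

    def roi_flat_indices(self) -> np.ndarray:
        """Flat grid indices of the ROI cells in row-major ROI order."""
        iy0, ix0, h, w = self.roi
        iy, ix = np.mgrid[iy0 : iy0 + h, ix0 : ix0 + w]
        return (iy * self.grid.nx + ix).ravel()

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(self.labels.tobytes())
        h.update(self.sigma.tobytes())
        h.update(self.electrodes.tobytes())
        h.update(np.asarray(self.roi).tobytes())
        return h.hexdigest()[:16]


def _disc_mask(X: np.ndarray, Y: np.ndarray, spec: VesselSpec) -> np.ndarray:
    return (X - spec.center[0]) ** 2 + (Y - spec.center[1]) ** 2 <= spec.radius**2


def build_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Rasterize the parametric phantom onto its grid.

    Raises ``ValueError`` for overlapping vessel discs, a wrong electrode
    count, a grid too coarse to separate the electrodes, or a
    reconstruction window that does not contain both vessels.
    """
    cfg = config if config is not None else PhantomConfig()
    grid = cfg.grid
    if grid.nx < 32 or grid.ny < 32:
        raise ValueError("grid must be at least 32x32 cells")
    if cfg.n_electrodes != 12:
        raise ValueError("phantom requires exactly 12 electrodes (e0 + e1..e11)")
    if cfg.artery.radius <= 0 or cfg.vein.radius <= 0:
        raise ValueError("vessel radii must be positive")
    d = np.hypot(
        cfg.artery.center[0] - cfg.vein.center[0],
        cfg.artery.center[1] - cfg.vein.center[1],
    )
    if d < cfg.artery.radius + cfg.vein.radius:
        raise ValueError(
            "artery and vein discs overlap: centers are "
            f"{d * 1000:.1f} mm apart but radii sum to "
            f"{(cfg.artery.radius + cfg.vein.radius) * 1000:.1f} mm"
        )

    X, Y = grid.coords()
    a, b = cfg.neck_semi_axes
    cx, cy = cfg.neck_center

    def ellipse_mask(sa: float, sb: float) -> np.ndarray:
        if sa <= 0 or sb <= 0:
            return np.zeros_like(X, dtype=bool)
        return ((X - cx) / sa) ** 2 + ((Y - cy) / sb) ** 2 <= 1.0

    neck = ellipse_mask(a, b)
    inner_skin = ellipse_mask(a - cfg.skin_thickness, b - cfg.skin_thickness)
    inner_fat = ellipse_mask(
        a - cfg.skin_thickness - cfg.fat_thickness,
        b - cfg.skin_thickness - cfg.fat_thickness,
    )

    labels = np.zeros(X.shape, dtype=np.int8)  # background
    labels[neck] = LABEL_INDEX["skin"]
    labels[inner_skin] = LABEL_INDEX["fat"]
    labels[inner_fat] = LABEL_INDEX["muscle"]

    for name, spec in cfg.organs.items():
        specs = spec if isinstance(spec, (list, tuple)) else [spec]
        for s in specs:
            labels[_disc_mask(X, Y, s)] = LABEL_INDEX[name]
    labels[_disc_mask(X, Y, cfg.artery)] = LABEL_INDEX["artery"]
    labels[_disc_mask(X, Y, cfg.vein)] = LABEL_INDEX["vein"]

    table = cfg.conductivity_table()
    sigma = np.zeros_like(X)
    for name, idx in LABEL_INDEX.items():
        sigma[labels == idx] = table[name]

    electrodes = _place_electrodes(grid, neck, cfg)

    roi = _roi_window(grid, cfg)
    iy0, ix0, h, w = roi
    vessel = (labels == LABEL_INDEX["artery"]) | (labels == LABEL_INDEX["vein"])
    outside = vessel.copy()
    outside[iy0 : iy0 + h, ix0 : ix0 + w] = False
    if outside.any():
        raise ValueError("reconstruction window does not contain all vessel cells")
    if not vessel.any():
        raise ValueError("grid too coarse: no artery/vein cells rasterized")

    return Phantom(grid=grid, labels=labels, sigma=sigma, electrodes=electrodes, roi=roi, config=cfg)


def _place_electrodes(grid: GridSpec, neck: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Outermost in-neck cell along each of 12 equally spaced rays."""
    a, b = cfg.neck_semi_axes
    cx, cy = cfg.neck_center
    ids = []
    for j in range(cfg.n_electrodes):
        theta = np.deg2rad(cfg.e0_angle_deg + 360.0 * j / cfg.n_electrodes)
        # march inward from just outside the ellipse until a neck cell is hit
        found = None
        for s in np.linspace(1.02, 0.5, 400):
            x = cx + s * a * np.cos(theta)
            y = cy + s * b * np.sin(theta)
            ix = int(round((x - grid.origin[0]) / grid.dx))
            iy = int(round((y - grid.origin[1]) / grid.dy))
            if 0 <= ix < grid.nx and 0 <= iy < grid.ny and neck[iy, ix]:
                found = grid.flat_index(ix, iy)
                break
        if found is None:
            raise ValueError(f"could not place electrode {j} on the neck surface")
        ids.append(found)
    arr = np.asarray(ids, dtype=np.int64)
    if len(np.unique(arr)) != len(arr):
        raise ValueError("grid too coarse: electrode positions collide")
    return arr


def _roi_window(grid: GridSpec, cfg: PhantomConfig) -> tuple[int, int, int, int]:
    h, w = cfg.roi_shape
    icx = (cfg.roi_center[0] - grid.origin[0]) / grid.dx
    icy = (cfg.roi_center[1] - grid.origin[1]) / grid.dy
    ix0 = int(round(icx - (w - 1) / 2))
    iy0 = int(round(icy - (h - 1) / 2))
    if ix0 < 0 or iy0 < 0 or ix0 + w > grid.nx or iy0 + h > grid.ny:
        raise ValueError("reconstruction window falls outside the grid")
    return (iy0, ix0, h, w)


# ---------------------------------------------------------------------------
# stenosis and flow


@dataclass(frozen=True)
class StenosisConfig:
    """Degree and growth direction of the arterial occlusion.

    ``rate`` is the occluded fraction of the artery cross-section, on the
    ten-step ladder 0.0, 0.1, ..., 0.9.  The occluded region grows as a
    half-plane sweep from one artery edge: direction ``"+x"`` sweeps
    rightward, ``"-y"`` sweeps downward.
    """

    rate: float = 0.0
    direction: str = "+x"

    def __post_init__(self) -> None:
        steps = np.arange(10) / 10.0
        if not np.any(np.isclose(self.rate, steps, atol=1e-9)):
            raise ValueError("stenosis rate must be one of 0.0, 0.1, ..., 0.9")
        if self.direction not in ("+x", "-y"):
            raise ValueError("direction must be '+x' or '-y'")


@dataclass(frozen=True)
class FlowConfig:
    """Pulsatile artery / steady vein flow parameters.

    The artery carries a two-harmonic systolic waveform with period
    ``period`` (s) sampled every ``dt``; the vein carries a constant
    counter-flow of ``vein_speed`` m/s.
    """

    period: float = 0.85
    dt: float = 0.01
    vein_speed: float = 0.08
    peak_speed: float = 1.0
    waveform_params: tuple[float, float, float, float] = (0.45, 0.45, 0.3, 0.3)

    def __post_init__(self) -> None:
        if self.period <= 0 or self.dt <= 0:
            raise ValueError("period and dt must be positive")
        if self.dt > self.period:
            raise ValueError("dt must not exceed the period")
        if self.vein_speed < 0:
            raise ValueError("vein speed must be nonnegative")

    def sample_times(self) -> np.ndarray:
        """Inclusive-endpoint sampling grid over one period."""
        n = int(np.floor(self.period / self.dt + 1e-9)) + 1
        return self.dt * np.arange(n)


@dataclass
class VelocityField:
    """Axial (z) velocity per cell at one instant, plus the stenosis mask."""

    vz: np.ndarray
    stenosis_mask: np.ndarray
    time: float


def stenosis_mask(phantom: Phantom, cfg: StenosisConfig) -> np.ndarray:
    """Occluded-cell mask: a half-plane sweep accreting artery cells.

    The mask contains ``round(rate * |artery|)`` cells, taken in ascending
    x (direction ``"+x"``) or descending y (``"-y"``); ties at equal sweep
    coordinate are broken by ascending flat cell index.  Masks at lower
    rates are nested inside masks at higher rates for a fixed direction.
    """
    artery = phantom.artery_mask
    if not artery.any():
        raise ValueError("phantom has no artery cells")
    iy, ix = np.nonzero(artery)
    flat = iy * phantom.grid.nx + ix
    if cfg.direction == "+x":
        sweep = ix
    else:
        sweep = -iy
    order = np.lexsort((flat, sweep))
    k = int(round(cfg.rate * len(flat)))
    mask = np.zeros_like(artery)
    sel = flat[order[:k]]
    mask.ravel()[sel] = True
    return mask


def pulsatile_waveform(t: float | np.ndarray, flow: FlowConfig | None = None) -> np.ndarray:
    """Pulsatile carotid speed (m/s) at time ``t``.

    w(t) = peak_speed * max(0, a0 + a1 sin(2πt/T) + a2 sin(4πt/T + φ)) / M,
    where M normalizes the clipped two-harmonic pulse so its maximum over
    one period equals ``peak_speed``.  The default parameters place the
    systolic peak near t = 0.15 T with a short zero-flow segment in late
    diastole.
    """
    flow = flow if flow is not None else FlowConfig()
    a0, a1, a2, phi = flow.waveform_params
    T = flow.period

    def raw(tt: np.ndarray) -> np.ndarray:
        th = 2 * np.pi * (np.asarray(tt, dtype=float) % T) / T
        return np.maximum(0.0, a0 + a1 * np.sin(th) + a2 * np.sin(2 * th + phi))

    tfine = np.linspace(0.0, T, 2048, endpoint=False)
    peak = raw(tfine).max()
    if peak <= 0:
        raise ValueError("waveform parameters yield a non-positive pulse")
    out = flow.peak_speed * raw(t) / peak
    return out if np.ndim(t) else float(out)


def stenosis_velocity_coefficient(
    rate: float, table: dict[float, float] | None = None, cap: float = 4.0
) -> float:
    """Speed-up multiplier for the residual lumen at a given stenosis rate.

    Default model is flux continuity through the narrowed segment,
    c = 1 / (1 - rate), capped at ``cap`` (stenotic jets in practice do
    not reach the inviscid continuity limit at severe occlusion).  A
    user-supplied ``table`` mapping rate -> coefficient overrides the
    default, with linear interpolation between tabulated rates.
    """
    if not 0 <= rate < 1:
        raise ValueError("stenosis rate must lie in [0, 1): a fully occluded vessel has no throughflow")
    if table:
        rates = np.array(sorted(table))
        vals = np.array([table[r] for r in rates])
        return float(np.interp(rate, rates, vals))
    return float(min(1.0 / (1.0 - rate), cap))


def velocity_field(
    phantom: Phantom,
    cfg: StenosisConfig,
    t: float,
    flow: FlowConfig | None = None,
    coefficient_table: dict[float, float] | None = None,
    coefficient_cap: float = 4.0,
) -> VelocityField:
    """Axial velocity field at time ``t`` under one stenosis configuration.

    Non-occluded artery cells carry +w(t)*c(rate); occluded cells carry
    exactly 0; vein cells carry -vein_speed; everything else is 0.
    """
    flow = flow if flow is not None else FlowConfig()
    mask = stenosis_mask(phantom, cfg)
    c = stenosis_velocity_coefficient(cfg.rate, coefficient_table, coefficient_cap)
    speed = pulsatile_waveform(t, flow) * c
    vz = np.zeros_like(phantom.sigma)
    vz[phantom.artery_mask] = speed
    vz[mask] = 0.0
    vz[phantom.vein_mask] = -flow.vein_speed
    return VelocityField(vz=vz, stenosis_mask=mask, time=float(t))


# ---------------------------------------------------------------------------
# serialization


def save_phantom(phantom: Phantom, path) -> None:
    """Write labels, conductivity, electrodes, ROI and config to an NPZ."""
    cfg = phantom.config
    meta = {
        "format": "emflowtomo-phantom-v1",
        "config": _config_to_jsonable(cfg),
    }
    np.savez(
        path,
        labels=phantom.labels,
        sigma=phantom.sigma,
        electrodes=phantom.electrodes,
        roi=np.asarray(phantom.roi, dtype=np.int64),
        grid=np.asarray(
            [phantom.grid.nx, phantom.grid.ny, phantom.grid.dx, phantom.grid.dy,
             phantom.grid.origin[0], phantom.grid.origin[1]]
        ),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_phantom(path) -> Phantom:
    with np.load(path) as z:
        g = z["grid"]
        grid = GridSpec(int(g[0]), int(g[1]), float(g[2]), float(g[3]), (float(g[4]), float(g[5])))
        meta = json.loads(bytes(z["meta"]).decode())
        cfg = _config_from_jsonable(meta["config"], grid)
        return Phantom(
            grid=grid,
            labels=z["labels"],
            sigma=z["sigma"],
            electrodes=z["electrodes"],
            roi=tuple(int(v) for v in z["roi"]),
            config=cfg,
        )


def _config_to_jsonable(cfg: PhantomConfig) -> dict:
    def enc(obj):
        if isinstance(obj, VesselSpec):
            return {"center": list(obj.center), "radius": obj.radius}
        if isinstance(obj, GridSpec):
            return None  # stored separately
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    d = dataclasses.asdict(cfg)
    d.pop("grid")
    out = {}
    for k in ("organs",):
        out[k] = {}
        for name, spec in cfg.organs.items():
            if isinstance(spec, (list, tuple)):
                out[k][name] = [enc(s) for s in spec]
            else:
                out[k][name] = enc(spec)
    for k, v in d.items():
        if k in ("organs",):
            continue
        out[k] = enc(getattr(cfg, k))
    out["artery"] = enc(cfg.artery)
    out["vein"] = enc(cfg.vein)
    return out


def _config_from_jsonable(d: dict, grid: GridSpec) -> PhantomConfig:
    def dec_vessel(obj):
        return VesselSpec(tuple(obj["center"]), obj["radius"])

    organs = {}
    for name, spec in d.get("organs", {}).items():
        if isinstance(spec, list):
            organs[name] = [dec_vessel(s) for s in spec]
        else:
            organs[name] = dec_vessel(spec)
    return PhantomConfig(
        grid=grid,
        neck_semi_axes=tuple(d["neck_semi_axes"]),
        neck_center=tuple(d["neck_center"]),
        skin_thickness=d["skin_thickness"],
        fat_thickness=d["fat_thickness"],
        organs=organs,
        artery=dec_vessel(d["artery"]),
        vein=dec_vessel(d["vein"]),
        n_electrodes=d["n_electrodes"],
        e0_angle_deg=d["e0_angle_deg"],
        roi_shape=tuple(d["roi_shape"]),
        roi_center=tuple(d["roi_center"]),
        conductivity_overrides=d.get("conductivity_overrides", {}),
    )
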