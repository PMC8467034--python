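"""Flow-induced potential forward model and weight-matrix assembly.

Physics: conductive blood moving with axial velocity v (along z) through a
static magnetic field B (along +x) experiences a motional EMF v x B (along
+y).  The resulting quasi-static potential u on the heterogeneous neck
cross-section obeys

    div(sigma grad u) = div(sigma (v x B)),

with zero-flux (insulating) outer boundary and u = 0 at the grounded
reference electrode e0.  The linear sensitivity of each electrode voltage
to each cell's velocity -- the weight matrix W with U = W v -- follows
from the Rayleigh-Carson reciprocity theorem: inject unit current through
(e_k, e0), record the reciprocal current density J_A, and weight each cell
by the z-component of the reciprocal Lorentz force (J_A x B) times the
cell area.

Discretization is a cell-centered 5-point finite-difference scheme with
harmonic face averaging of sigma.  Cells with sigma = 0 (trachea,
esophagus, exterior) drop out of the conduction problem naturally: every
face they touch carries zero conductance, which is exactly an internal
Neumann (insulating) condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import (
    FlowConfig,
    Phantom,
    StenosisConfig,
    VelocityField,
    stenosis_mask,
    velocity_field,
)

__all__ = [
    "SimulationConfig",
    "PotentialMap",
    "ReciprocalField",
    "WeightMatrix",
    "MeasurementVector",
    "SampleSet",
    "ConductionSolver",
    "solve_flow_potential",
    "electrode_voltages",
    "reciprocal_field",
    "assemble_weight_matrix",
    "add_noise",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass
class SimulationConfig:
    """Sweep definition for dataset generation.

    Defaults follow the full factorial: five field strengths 0.02-0.10 T,
    ten stenosis rates expanded separately along +x and -y (rate 0 counted
    once, so 19 configurations), and the FlowConfig time grid.  The weight
    matrix is always computed from the stenosis-free phantom at
    ``weight_B`` tesla.
    """

    B_values: tuple = (0.02, 0.04, 0.06, 0.08, 0.10)
    stenosis_rates: tuple = tuple(np.round(np.arange(10) / 10.0, 1))
    directions: tuple = ("+x", "-y")
    weight_B: float = 0.10
    train_fraction: float = 0.8
    seed: int = 0
    #: whether the occluded cells are also removed from the conduction
    #: model (sigma = 0 there) rather than only carrying zero velocity;
    #: both readings of "removing a portion of the artery" are defensible
    stenosis_removes_conductivity: bool = False

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.B_values):
            raise ValueError("field strengths must be positive")

    def stenosis_configs(self) -> list[StenosisConfig]:
        out = []
        for rate in self.stenosis_rates:
            if np.isclose(rate, 0.0):
                out.append(StenosisConfig(0.0, self.directions[0]))
            else:
                for d in self.directions:
                    out.append(StenosisConfig(rate, d))
        return out


@dataclass
class PotentialMap:
    """Scalar potential per cell (V), gauged to 0 at e0."""

    u: np.ndarray


@dataclass
class ReciprocalField:
    """Cell-centered reciprocal current density for one measuring electrode.

    ``J`` has shape (ny, nx, 2) holding (Jx, Jy) in A/m^2 per unit injected
    current (per meter of depth).
    """

    J: np.ndarray
    electrode: int


@dataclass
class WeightMatrix:
    """Linear map W (V per m/s) from ROI cell velocities to voltages."""

    W: np.ndarray
    cell_area: float
    weight_B: float
    phantom_hash: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape


@dataclass
class MeasurementVector:
    """Electrode potential differences U_k = u(e_k) - u(e0), k = 1..m."""

    U: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class SampleSet:
    """Dataset of (U, v) pairs with the shared weight matrix and split."""

    U: np.ndarray          # (N, m)
    V: np.ndarray          # (N, n)
    W: WeightMatrix
    meta: list             # per-sample dicts: B, rate, direction, t
    train_idx: np.ndarray
    test_idx: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.U.shape[0]


class ConductionSolver:
    """Sparse 5-point solver for div(sigma grad u) = rhs on a phantom.

    The system matrix depends only on the conductivity map, so one
    factorization serves every velocity field, field strength and
    injection pattern.  The grounded reference electrode is pinned to 0 by
    an identity row/column (symmetry-preserving); sigma = 0 cells are
    likewise pinned since they carry no current.
    """

    def __init__(self, phantom: Phantom):
        self.phantom = phantom
        g = phantom.grid
        sigma = phantom.sigma
        if not (sigma > 0).any():
            raise ValueError("all-zero conductivity: system is singular")
        nx, ny, dx, dy = g.nx, g.ny, g.dx, g.dy

        def harmonic(s1, s2):
            num = 2.0 * s1 * s2
            den = s1 + s2
            out = np.zeros_like(num)
            nz = den > 0
            out[nz] = num[nz] / den[nz]
            return out

        # face conductances (flux per unit potential difference, unit depth)
        self.cx = harmonic(sigma[:, :-1], sigma[:, 1:]) * dy / dx  # (ny, nx-1)
        self.cy = harmonic(sigma[:-1, :], sigma[1:, :]) * dx / dy  # (ny-1, nx)
        # face harmonic sigma alone, for source terms
        self.sy = harmonic(sigma[:-1, :], sigma[1:, :])            # (ny-1, nx)

        N = nx * ny
        idx = np.arange(N).reshape(ny, nx)
        diag = np.zeros(N)

        # assemble -L so the operator is positive semidefinite:
        # (-L u)_i = sum_f c_f (u_i - u_j)
        rows2, cols2, vals2 = [], [], []
        ax, bx = idx[:, :-1], idx[:, 1:]
        ay, by = idx[:-1, :], idx[1:, :]
        for c, a, b in ((self.cx, ax, bx), (self.cy, ay, by)):
            cf, af, bf = c.ravel(), a.ravel(), b.ravel()
            rows2.append(af); cols2.append(bf); vals2.append(-cf)
            rows2.append(bf); cols2.append(af); vals2.append(-cf)
            np.add.at(diag, af, cf)
            np.add.at(diag, bf, cf)

        rows2.append(np.arange(N)); cols2.append(np.arange(N)); vals2.append(diag)
        A = sp.csr_matrix(
            (np.concatenate(vals2), (np.concatenate(rows2), np.concatenate(cols2))),
            shape=(N, N),
        )

        # pin decoupled (sigma-isolated) nodes and the reference electrode
        self.e0 = int(phantom.electrodes[0])
        pinned = np.asarray(A.sum(axis=1)).ravel() == 0.0
        pinned &= A.diagonal() == 0.0
        pin_idx = np.nonzero(pinned)[0].tolist()
        pin_idx.append(self.e0)
        A = A.tolil()
        for i in pin_idx:
            A.rows[i] = [i]
            A.data[i] = [1.0]
        A = A.tocsr()
        # zero the pinned columns (u there is 0, keeps symmetry)
        mask = np.ones(N, dtype=bool)
        mask[pin_idx] = False
        keep = sp.diags(mask.astype(float))
        A = keep @ A @ keep + sp.diags((~mask).astype(float))
        self._pinned = np.asarray(pin_idx)
        self.A = A.tocsc()
        self._lu = None

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.A)
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Solve -L u = rhs (rhs flat or (N, k)); pinned entries forced to 0."""
        b = np.array(rhs, dtype=float, copy=True)
        flat = b.ndim == 1
        if flat:
            b = b[:, None]
        b[self._pinned, :] = 0.0
        u = self.lu.solve(b)
        if not np.all(np.isfinite(u)):
            raise RuntimeError("conduction solve produced non-finite potentials")
        return u[:, 0] if flat else u

    # -- right-hand sides ---------------------------------------------------

    def face_divergence(self, u: np.ndarray) -> np.ndarray:
        """Net outgoing current per cell, sum_f c_f (u_i - u_j), shape (ny, nx).

        This is the discrete Kirchhoff balance: zero away from current
        injection nodes, +I at a source node.
        """
        g = self.phantom.grid
        U = u.reshape(g.ny, g.nx)
        div = np.zeros((g.ny, g.nx))
        fx = self.cx * (U[:, :-1] - U[:, 1:])
        fy = self.cy * (U[:-1, :] - U[1:, :])
        div[:, :-1] += fx
        div[:, 1:] -= fx
        div[:-1, :] += fy
        div[1:, :] -= fy
        return div

    def rhs_from_velocity(self, vz: np.ndarray, B: float) -> np.ndarray:
        """Divergence of the motional-EMF flux sigma * (v x B).

        With B along +x and v along +z the EMF field is q = v*B along +y,
        so only y-faces carry source flux: F = sigma_f * mean(q) * dx.
        Sign convention matches -L: rhs_i = -(div flux)_i.
        """
        g = self.phantom.grid
        q = vz * B
        qf = 0.5 * (q[:-1, :] + q[1:, :])
        F = self.sy * qf * g.dx  # (ny-1, nx): flux through each y-face, +y direction
        rhs = np.zeros((g.ny, g.nx))
        # (-L u)_i = rhs_i with rhs_i = sum over faces of outgoing EMF flux
        rhs[:-1, :] -= F   # top face of lower cell
        rhs[1:, :] += F    # bottom face of upper cell
        return -rhs.ravel()

    def rhs_injection(self, k: int) -> np.ndarray:
        """Unit current injected at measuring electrode e_k, returned at e0."""
        if k == 0:
            raise ValueError("electrode 0 is the grounded reference, not a measuring electrode")
        if not 1 <= k < len(self.phantom.electrodes):
            raise ValueError(f"electrode index {k} out of range")
        rhs = np.zeros(self.phantom.grid.n_cells)
        rhs[int(self.phantom.electrodes[k])] = 1.0
        # the matching -1 A at e0 is absorbed by the pinned ground node
        return rhs

    def current_density(self, u: np.ndarray) -> np.ndarray:
        """Cell-centered J = -sigma grad u from face fluxes (A/m^2).

        Face current densities use the harmonic sigma; cell values average
        the two adjacent faces per direction (one-sided at boundaries),
        which makes the weight matrix consistent with the discrete adjoint.
        """
        g = self.phantom.grid
        U = u.reshape(g.ny, g.nx)
        # face current densities (positive along +axis)
        jx_face = -(self.cx * (U[:, 1:] - U[:, :-1])) / g.dy  # (ny, nx-1)
        jy_face = -(self.cy * (U[1:, :] - U[:-1, :])) / g.dx  # (ny-1, nx)

        def center(face, axis):
            acc = np.zeros((g.ny, g.nx))
            cnt = np.zeros((g.ny, g.nx))
            nz = np.zeros(face.shape)
            nz[face != 0.0] = 1.0
            if axis == 1:
                acc[:, 1:] += face
                acc[:, :-1] += face
                cnt[:, 1:] += nz
                cnt[:, :-1] += nz
            else:
                acc[1:, :] += face
                acc[:-1, :] += face
                cnt[1:, :] += nz
                cnt[:-1, :] += nz
            out = np.zeros((g.ny, g.nx))
            np.divide(acc, cnt, out=out, where=cnt > 0)
            return out

        Jx = center(jx_face, 1)
        Jy = center(jy_face, 0)
        return np.stack([Jx, Jy], axis=-1)


def solve_flow_potential(
    phantom: Phantom,
    vel: VelocityField,
    B: float,
    solver: ConductionSolver | None = None,
) -> PotentialMap:
    """Potential map induced by a velocity field in field strength B (T).

    Negative B means a field along -x and antisymmetrically flips every
    potential.
    """
    if vel.vz.shape != phantom.sigma.shape:
        raise ValueError("velocity field and phantom grids differ")
    s = solver if solver is not None else ConductionSolver(phantom)
    u = s.solve(s.rhs_from_velocity(vel.vz, B))
    return PotentialMap(u=u)


def electrode_voltages(u: PotentialMap, phantom: Phantom) -> MeasurementVector:
    """U_k = u(e_k) - u(e0) for the 11 measuring electrodes."""
    pot = u.u.ravel()
    e = phantom.electrodes
    U = pot[e[1:]] - pot[e[0]]
    return MeasurementVector(U=U, meta={})


def reciprocal_field(
    phantom: Phantom, k: int, solver: ConductionSolver | None = None
) -> ReciprocalField:
    """Current-density field for unit current driven through (e_k, e0)."""
    s = solver if solver is not None else ConductionSolver(phantom)
    uA = s.solve(s.rhs_injection(k))
    return ReciprocalField(J=s.current_density(uA), electrode=k)


def assemble_weight_matrix(
    phantom: Phantom,
    cfg: SimulationConfig | None = None,
    solver: ConductionSolver | None = None,
) -> WeightMatrix:
    """Weight matrix W[k-1, i] = (J_A^(k) x B)_z * S_i over ROI cells.

    Row k comes from electrode k's reciprocal field; with B along +x the
    z-component of the reciprocal Lorentz force is -J_Ay * B.  The overall
    sign is fixed so that W v agrees with the full PDE voltages (validated
    by the reciprocity consistency test): with the solver's convention of
    current injected at e_k and returned at ground, W = +J_Ay * B * S.
    """
    cfg = cfg if cfg is not None else SimulationConfig()
    s = solver if solver is not None else ConductionSolver(phantom)
    roi_flat = phantom.roi_flat_indices()
    m = phantom.n_measuring
    W = np.empty((m, len(roi_flat)))
    Si = phantom.grid.cell_area
    for k in range(1, m + 1):
        rf = reciprocal_field(phantom, k, solver=s)
        Jy = rf.J[:, :, 1].ravel()
        W[k - 1, :] = Jy[roi_flat] * cfg.weight_B * Si
    if not np.all(np.isfinite(W)):
        raise RuntimeError("weight matrix contains non-finite entries")
    return WeightMatrix(
        W=W, cell_area=Si, weight_B=cfg.weight_B, phantom_hash=phantom.content_hash()
    )


def add_noise(U: MeasurementVector, snr_db: float, rng_seed: int) -> MeasurementVector:
    """White Gaussian noise at the requested SNR (dB).

    SNR = 20 log10(U_rms / noise_rms), so the noise standard deviation is
    RMS(U) * 10^(-snr_db/20).  An infinite SNR returns U unchanged.
    """
    if np.isinf(snr_db):
        return MeasurementVector(U=U.U.copy(), meta={**U.meta, "snr_db": None})
    rms = float(np.sqrt(np.mean(U.U**2)))
    if rms == 0.0:
        raise ValueError("cannot set a finite SNR on an all-zero measurement")
    sd = rms * 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(rng_seed)
    noisy = U.U + rng.normal(0.0, sd, size=U.U.shape)
    return MeasurementVector(U=noisy, meta={**U.meta, "snr_db": snr_db, "noise_seed": rng_seed})


def generate_dataset(
    phantom: Phantom,
    cfg: SimulationConfig | None = None,
    flow: FlowConfig | None = None,
    coefficient_cap: float = 4.0,
) -> SampleSet:
    """Full factorial sweep: B values x stenosis configs x time samples.

    Every sample's voltage vector comes from the full heterogeneous PDE on
    the stenosed phantom, while the shared weight matrix comes from the
    stenosis-free phantom at ``weight_B`` -- the deliberate model mismatch
    that keeps reconstruction honest.  Velocities enter the PDE linearly,
    so the solver factors the conduction operator once and back-substitutes
    per (stenosis, time) right-hand side; scaling over the B sweep uses
    the exact linearity of the source in B.  The 80/20 train/test split is
    drawn from the recorded seed.
    """
    cfg = cfg if cfg is not None else SimulationConfig()
    flow = flow if flow is not None else FlowConfig()
    solver = ConductionSolver(phantom)
    W = assemble_weight_matrix(phantom, cfg, solver=solver)
    times = flow.sample_times()
    sten_cfgs = cfg.stenosis_configs()
    roi_flat = phantom.roi_flat_indices()
    e = phantom.electrodes
    m = phantom.n_measuring

    U_rows, V_rows, meta = [], [], []
    for sc in sten_cfgs:
        cfg_solver = solver
        if cfg.stenosis_removes_conductivity and sc.rate > 0:
            import dataclasses as _dc

            sten = stenosis_mask(phantom, sc)
            sigma2 = phantom.sigma.copy()
            sigma2[sten] = 0.0
            cfg_solver = ConductionSolver(_dc.replace(phantom, sigma=sigma2))
        rhs = np.empty((phantom.grid.n_cells, len(times)))
        labels = np.empty((len(times), len(roi_flat)))
        for j, t in enumerate(times):
            try:
                vf = velocity_field(phantom, sc, t, flow, coefficient_cap=coefficient_cap)
                rhs[:, j] = cfg_solver.rhs_from_velocity(vf.vz, 1.0)
            except Exception as err:
                raise RuntimeError(
                    f"velocity/source assembly failed at rate={sc.rate}, "
                    f"direction={sc.direction}, t={t:.3f}s: {err}"
                ) from err
            labels[j] = vf.vz.ravel()[roi_flat]
        try:
            u = cfg_solver.solve(rhs)  # (N, T) at B = 1 T
        except Exception as err:
            raise RuntimeError(
                f"PDE solve failed for rate={sc.rate}, direction={sc.direction}: {err}"
            ) from err
        Ue = (u[e[1:], :] - u[e[0], :]).T  # (T, m), B = 1 T
        for B in cfg.B_values:
            U_rows.append(Ue * B)
            V_rows.append(labels)
            meta.extend(
                {"B": float(B), "rate": float(sc.rate), "direction": sc.direction, "t": float(t)}
                for t in times
            )

    U = np.concatenate(U_rows, axis=0)
    V = np.concatenate(V_rows, axis=0)
    N = U.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5B117]))
    perm = rng.permutation(N)
    n_train = int(round(cfg.train_fraction * N))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])

    snapshot = {
        "B_values": [float(b) for b in cfg.B_values],
        "stenosis_rates": [float(r) for r in cfg.stenosis_rates],
        "directions": list(cfg.directions),
        "weight_B": float(cfg.weight_B),
        "train_fraction": float(cfg.train_fraction),
        "seed": int(cfg.seed),
        "flow": {
            "period": flow.period,
            "dt": flow.dt,
            "vein_speed": flow.vein_speed,
            "peak_speed": flow.peak_speed,
            "waveform_params": list(flow.waveform_params),
        },
        "coefficient_cap": float(coefficient_cap),
        "n_units": int(len(roi_flat)),
        "m": int(m),
        "phantom_hash": phantom.content_hash(),
    }
    return SampleSet(
        U=U, V=V, W=W, meta=meta, train_idx=train_idx, test_idx=test_idx, config=snapshot
    )


def save_dataset(ds: SampleSet, path) -> None:
    """Write the dataset container (arrays + JSON metadata) as NPZ."""
    meta = {
        "format": "emflowtomo-dataset-v1",
        "config": ds.config,
        "samples": ds.meta,
        "weight": {
            "cell_area": ds.W.cell_area,
            "weight_B": ds.W.weight_B,
            "phantom_hash": ds.W.phantom_hash,
        },
    }
    np.savez_compressed(
        path,
        U=ds.U,
        V=ds.V,
        W=ds.W.W,
        train_idx=ds.train_idx,
        test_idx=ds.test_idx,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_dataset(path) -> SampleSet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        wmeta = meta["weight"]
        W = WeightMatrix(
            W=z["W"],
            cell_area=wmeta["cell_area"],
            weight_B=wmeta["weight_B"],
            phantom_hash=wmeta["phantom_hash"],
        )
        return SampleSet(
            U=z["U"],
            V=z["V"],
            W=W,
            meta=meta["samples"],
            train_idx=z["train_idx"],
            test_idx=z["test_idx"],
            config=meta["config"],
        )


def export_csv(ds: SampleSet, path_prefix: str, max_samples: int = 100) -> None:
    """Plain-text export of a small subset (U and V as CSV)."""
    k = min(max_samples, ds.n_samples)
    np.savetxt(f"{path_prefix}_U.csv", ds.U[:k], delimiter=",")
    np.savetxt(f"{path_prefix}_V.csv", ds.V[:k], delimiter=",")
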