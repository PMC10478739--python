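"""Transient Pennes bioheat solver on the voxel domain.

Solves   rho c_v dT/dt = q + div(k_m grad T) + rho_b w_b c_b (T_b - T)
with the Monte Carlo absorbed-power field as q, over the 600 s irradiation.

Discretization: conservative finite volumes with harmonic-mean face
conductivities (flux continuity across tissue interfaces).  Time stepping is
explicit FTCS with an automatic step at 0.9x the stability limit, or backward
Euler ("implicit", conjugate-gradient per step) for coarse-step runs.

Boundary conditions: adiabatic at the skin surface (z = 0); the deep face,
the box faces, and every voxel outside the tissue cylinder are clamped to
the boundary temperature (default 37 C = arterial blood).  With those
defaults the whole problem is linear in the heat source, so the temperature
*rise* scales exactly with beam power.

Temperatures are handled in deg C throughout (the perfusion term uses only
differences from T_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import cg

from . import constants as C
from .domain import TissueDomain, TissueLayer, EXTERIOR, hazard_shell

__all__ = [
    "ThermalScenario",
    "TemperatureField",
    "perfusion_source",
    "step_heat",
    "run_transient",
]

DEFAULT_PROBES_MM = ((0.0, 0.0, 0.0), (0.0, 0.0, 2.0))  # surface, 2 mm depth


@dataclass(frozen=True)
class ThermalScenario:
    """Blood constants, initial/boundary conditions, and time stepping.

    The blood constants are standard literature values (they do not follow
    from the tissue table) and are configurable.
    """

    initial_temperature: float = C.INITIAL_TEMPERATURE_C
    boundary_temperature: float = C.ARTERIAL_TEMPERATURE_C
    rho_b: float = C.BLOOD_DENSITY
    c_b: float = C.BLOOD_SPECIFIC_HEAT
    T_b: float = C.ARTERIAL_TEMPERATURE_C
    duration: float = C.IRRADIATION_TIME_S
    dt: float | None = None            # None = auto (0.9x explicit limit)
    snapshot_interval: float = 10.0    # s
    perfusion_enabled: bool = True
    scheme: str = "explicit"           # "explicit" | "implicit"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.scheme not in ("explicit", "implicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class TemperatureField:
    """Transient solution: masked snapshot history plus probe time series."""

    times: np.ndarray                  # (n_snap,) s
    tumor_temps: np.ndarray            # (n_snap, n_tumor) deg C
    shell_temps: np.ndarray            # (n_snap, n_shell) deg C
    probe_temps: np.ndarray            # (n_snap, n_probes) deg C
    probes_mm: tuple
    final_field: np.ndarray            # (nx, ny, nz) at t = duration
    dt: float
    scheme: str
    diagnostics: dict = field(default_factory=dict)

    def rescaled(self, factor: float, T_ref: float) -> "TemperatureField":
        """Temperature history with the rise above T_ref scaled by ``factor``.

        Valid because the bioheat problem is linear in the source when the
        initial and boundary temperatures equal T_b.
        """
        scale = lambda a: T_ref + factor * (a - T_ref)  # noqa: E731
        return TemperatureField(
            times=self.times,
            tumor_temps=scale(self.tumor_temps),
            shell_temps=scale(self.shell_temps),
            probe_temps=scale(self.probe_temps),
            probes_mm=self.probes_mm,
            final_field=scale(self.final_field),
            dt=self.dt,
            scheme=self.scheme,
            diagnostics=dict(self.diagnostics),
        )


def perfusion_source(
    T: float | np.ndarray, layer: TissueLayer, scenario: ThermalScenario
) -> float | np.ndarray:
    """Pennes perfusion source q_perf = rho_b w_b c_b (T_b - T), W/m^3."""
    return scenario.rho_b * layer.w_b * scenario.c_b * (scenario.T_b - T)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _face_conductance(k3: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean conductivity on interior faces along one axis."""
    a = np.swapaxes(k3, 0, axis)
    g = 2.0 * a[:-1] * a[1:] / (a[:-1] + a[1:])
    return np.ascontiguousarray(np.swapaxes(g, 0, axis))


def _clamp_mask(domain: TissueDomain) -> np.ndarray:
    """Voxels held at the boundary temperature: cylinder wall + deep face."""
    m = domain.tissue_id == EXTERIOR
    m[:, :, -1] = True
    m[0, :, :] = True
    m[-1, :, :] = True
    m[:, 0, :] = True
    m[:, -1, :] = True
    return m


@njit(cache=True, fastmath=True)
def _ftcs_steps(T, Gx, Gy, Gz, coef, decay, src, clamp_idx, clamp_val, n_steps):
    """n_steps explicit updates in place.

    coef  = dt / (rho c dx^2)  per voxel
    decay = dt * rho_b w_b c_b / (rho c)  per voxel
    src   = dt (q + rho_b w_b c_b T_b) / (rho c)  per voxel

    The x/y box faces and the deep z face are clamped (Dirichlet), so only
    the interior and the adiabatic surface row (k = 0) need the stencil;
    clamped voxels are rewritten afterwards.
    """
    nx, ny, nz = T.shape
    Tn = np.empty_like(T)
    for _ in range(n_steps):
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                # adiabatic surface voxel (k = 0): no z- neighbor flux
                t = T[i, j, 0]
                acc = Gx[i - 1, j, 0] * (T[i - 1, j, 0] - t)
                acc += Gx[i, j, 0] * (T[i + 1, j, 0] - t)
                acc += Gy[i, j - 1, 0] * (T[i, j - 1, 0] - t)
                acc += Gy[i, j, 0] * (T[i, j + 1, 0] - t)
                acc += Gz[i, j, 0] * (T[i, j, 1] - t)
                Tn[i, j, 0] = t + coef[i, j, 0] * acc + src[i, j, 0] - decay[i, j, 0] * t
                for k in range(1, nz - 1):
                    t = T[i, j, k]
                    acc = Gx[i - 1, j, k] * (T[i - 1, j, k] - t)
                    acc += Gx[i, j, k] * (T[i + 1, j, k] - t)
                    acc += Gy[i, j - 1, k] * (T[i, j - 1, k] - t)
                    acc += Gy[i, j, k] * (T[i, j + 1, k] - t)
                    acc += Gz[i, j, k - 1] * (T[i, j, k - 1] - t)
                    acc += Gz[i, j, k] * (T[i, j, k + 1] - t)
                    Tn[i, j, k] = t + coef[i, j, k] * acc + src[i, j, k] - decay[i, j, k] * t
        for n in range(clamp_idx.shape[0]):
            Tn.flat[clamp_idx[n]] = clamp_val
        # clamped box faces (x/y faces, deep z face) keep their values
        for j in range(ny):
            for k in range(nz):
                Tn[0, j, k] = T[0, j, k]
                Tn[nx - 1, j, k] = T[nx - 1, j, k]
        for i in range(nx):
            for k in range(nz):
                Tn[i, 0, k] = T[i, 0, k]
                Tn[i, ny - 1, k] = T[i, ny - 1, k]
        for i in range(nx):
            for j in range(ny):
                Tn[i, j, nz - 1] = T[i, j, nz - 1]
        T[:, :, :] = Tn
    return T


class _HeatSystem:
    """Prepared arrays for one (domain, q, scenario) heat problem."""

    def __init__(self, domain, q_w_m3, scenario, clamp=None):
        self.domain = domain
        self.scenario = scenario
        k3, rc3, wb3 = domain.thermal_volumes()
        self.k3, self.rc3 = k3, rc3
        dx_m = domain.voxel_size * 1e-3
        self.Gx = _face_conductance(k3, 0)
        self.Gy = _face_conductance(k3, 1)
        self.Gz = _face_conductance(k3, 2)
        perf = scenario.rho_b * scenario.c_b * wb3 if scenario.perfusion_enabled \
            else np.zeros_like(wb3)
        self.perf = perf
        self.q = q_w_m3
        self.dx_m = dx_m
        self.clamp = _clamp_mask(domain) if clamp is None else clamp
        self.clamp_idx = np.flatnonzero(self.clamp)
        # Explicit stability: dt <= rho c dx^2 / (sum G + perf dx^2), minimized.
        gsum = np.zeros(domain.shape)
        gsum[:-1] += self.Gx
        gsum[1:] += self.Gx
        gsum[:, :-1] += self.Gy
        gsum[:, 1:] += self.Gy
        gsum[:, :, :-1] += self.Gz
        gsum[:, :, 1:] += self.Gz
        self.dt_stable = float(np.min(rc3 * dx_m**2 / (gsum + perf * dx_m**2)))

    def coefficients(self, dt):
        coef = dt / (self.rc3 * self.dx_m**2)
        decay = dt * self.perf / self.rc3
        src = dt * (self.q + self.perf * self.scenario.T_b) / self.rc3
        return coef, decay, src


def _reference_step(T, Gx, Gy, Gz, coef, decay, src, clamp_idx, clamp_val):
    """Vectorized single explicit update; box faces without neighbors are
    naturally adiabatic (missing-flux convention).  Reference path for the
    production kernel and the unit-level verification entry point."""
    acc = np.zeros_like(T)
    dfx = Gx * (T[1:] - T[:-1])
    acc[:-1] += dfx
    acc[1:] -= dfx
    dfy = Gy * (T[:, 1:] - T[:, :-1])
    acc[:, :-1] += dfy
    acc[:, 1:] -= dfy
    dfz = Gz * (T[:, :, 1:] - T[:, :, :-1])
    acc[:, :, :-1] += dfz
    acc[:, :, 1:] -= dfz
    Tn = T + coef * acc + src - decay * T
    Tn.flat[clamp_idx] = clamp_val
    return Tn


def step_heat(
    T: np.ndarray,
    q_w_m3: np.ndarray,
    domain: TissueDomain,
    scenario: ThermalScenario,
    dt: float | None = None,
    clamp: np.ndarray | None = None,
) -> np.ndarray:
    """One explicit conservative update; returns the field at t + dt.

    Exposed for unit-level verification (energy balance, analytic slabs,
    scheme cross-checks); accepts a custom clamp mask so tests can impose
    their own boundary conditions (unclamped faces are adiabatic).
    """
    sys_ = _HeatSystem(domain, q_w_m3, scenario, clamp=clamp)
    dt = sys_.dt_stable * 0.9 if dt is None else dt
    if dt > sys_.dt_stable * (1 + 1e-12):
        raise ValueError(
            f"dt = {dt:g} s exceeds the explicit stability limit {sys_.dt_stable:g} s"
        )
    coef, decay, src = sys_.coefficients(dt)
    Tn = _reference_step(
        T, sys_.Gx, sys_.Gy, sys_.Gz, coef, decay, src,
        sys_.clamp_idx, scenario.boundary_temperature,
    )
    if not np.all(np.isfinite(Tn)):
        raise FloatingPointError("temperature field overflowed (NaN/Inf)")
    return Tn


def _implicit_matrix(sys_: _HeatSystem, dt: float) -> sparse.csr_matrix:
    """Backward-Euler system matrix (I + dt*decay - dt*L), clamp rows = I."""
    dom = sys_.domain
    nx, ny, nz = dom.shape
    n = nx * ny * nz
    coef, decay, _ = sys_.coefficients(dt)
    diag = 1.0 + decay.ravel().copy()
    rows, cols, vals = [], [], []
    strides = (ny * nz, nz, 1)
    G = {0: sys_.Gx, 1: sys_.Gy, 2: sys_.Gz}
    clamped = np.zeros(n, bool)
    clamped[sys_.clamp_idx] = True
    idx = np.arange(n).reshape(nx, ny, nz)
    for axis in range(3):
        g = G[axis]
        lo = np.swapaxes(idx, 0, axis)[:-1].ravel()
        hi = np.swapaxes(idx, 0, axis)[1:].ravel()
        gv = np.swapaxes(g, 0, axis).ravel()
        w_lo = coef.ravel()[lo] * gv   # weight in lo's row toward hi
        w_hi = coef.ravel()[hi] * gv   # weight in hi's row toward lo
        keep_lo = ~clamped[lo]
        keep_hi = ~clamped[hi]
        rows.append(lo[keep_lo]); cols.append(hi[keep_lo]); vals.append(-w_lo[keep_lo])
        rows.append(hi[keep_hi]); cols.append(lo[keep_hi]); vals.append(-w_hi[keep_hi])
        np.add.at(diag, lo[keep_lo], w_lo[keep_lo])
        np.add.at(diag, hi[keep_hi], w_hi[keep_hi])
    diag[clamped] = 1.0
    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    # drop off-diagonal entries in clamped rows
    r = np.concatenate(rows); c_ = np.concatenate(cols); v = np.concatenate(vals)
    A = sparse.csr_matrix((v, (r, c_)), shape=(n, n))
    return A


def run_transient(
    domain: TissueDomain,
    q_w_m3: np.ndarray,
    scenario: ThermalScenario | None = None,
    probes_mm: tuple = DEFAULT_PROBES_MM,
    tumor_mask: np.ndarray | None = None,
    shell_mask: np.ndarray | None = None,
) -> TemperatureField:
    """Integrate the bioheat equation over the treatment and record history.

    Snapshots (masked tumor/shell temperatures and probe values) are stored
    every ``snapshot_interval`` seconds including t = 0 and t = duration.
    Deterministic.
    """
    sc = scenario or ThermalScenario()
    sys_ = _HeatSystem(domain, q_w_m3, sc)
    if sc.scheme == "explicit":
        dt0 = sc.dt if sc.dt is not None else sys_.dt_stable * 0.9
        if dt0 > sys_.dt_stable:
            raise ValueError("explicit dt exceeds the stability limit")
    else:
        dt0 = sc.dt if sc.dt is not None else 1.0
    n_sub = max(1, int(np.ceil(sc.snapshot_interval / dt0 - 1e-12)))
    dt = sc.snapshot_interval / n_sub
    n_snap = int(round(sc.duration / sc.snapshot_interval)) + 1
    times = np.arange(n_snap) * sc.snapshot_interval

    if tumor_mask is None:
        tumor_mask = domain.tumor_mask
    if shell_mask is None:
        shell_mask = hazard_shell(domain)
    tumor_idx = np.flatnonzero(tumor_mask)
    shell_idx = np.flatnonzero(shell_mask)
    probe_idx = np.array(
        [np.ravel_multi_index(_probe_voxel(domain, p), domain.shape) for p in probes_mm]
    )

    T = np.full(domain.shape, float(sc.initial_temperature))
    T.flat[sys_.clamp_idx] = sc.boundary_temperature
    tumor_out = np.empty((n_snap, tumor_idx.size))
    shell_out = np.empty((n_snap, shell_idx.size))
    probe_out = np.empty((n_snap, probe_idx.size))

    def record(i):
        tumor_out[i] = T.flat[tumor_idx]
        shell_out[i] = T.flat[shell_idx]
        probe_out[i] = T.flat[probe_idx]

    record(0)
    if sc.scheme == "explicit":
        coef, decay, src = sys_.coefficients(dt)
        for i in range(1, n_snap):
            _ftcs_steps(
                T, sys_.Gx, sys_.Gy, sys_.Gz, coef, decay, src,
                sys_.clamp_idx, sc.boundary_temperature, n_sub,
            )
            record(i)
    else:
        A = _implicit_matrix(sys_, dt)
        _, _, src = sys_.coefficients(dt)
        clamped = np.zeros(T.size, bool)
        clamped[sys_.clamp_idx] = True
        for i in range(1, n_snap):
            for _ in range(n_sub):
                rhs = T.ravel() + src.ravel()
                rhs[clamped] = sc.boundary_temperature
                x, info = cg(A, rhs, x0=T.ravel(), rtol=1e-9, maxiter=2000)
                if info != 0:
                    raise RuntimeError(f"implicit solve failed (cg info={info})")
                T = x.reshape(domain.shape)
            record(i)
    if not np.all(np.isfinite(T)):
        raise FloatingPointError("temperature field overflowed (NaN/Inf)")

    return TemperatureField(
        times=times,
        tumor_temps=tumor_out,
        shell_temps=shell_out,
        probe_temps=probe_out,
        probes_mm=tuple(probes_mm),
        final_field=T,
        dt=dt,
        scheme=sc.scheme,
        diagnostics={"dt_stable": sys_.dt_stable, "n_substeps": n_sub},
    )


def _probe_voxel(domain: TissueDomain, p_mm) -> tuple[int, int, int]:
    x, y, z = p_mm
    nx, ny, nz = domain.shape
    ix, iy, iz = domain.voxel_index(x, y, min(z, (nz - 0.5) * domain.voxel_size))
    return (min(max(ix, 0), nx - 1), min(max(iy, 0), ny - 1), min(max(iz, 0), nz - 1))
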