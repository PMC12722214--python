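"""Numerical Bloch-McConnell engine for multi-pool saturation transfer.

The coupled magnetization dynamics of water + mobile solute pools (full
transverse and longitudinal components) + an optional longitudinal-only
semisolid pool are propagated with piecewise-constant generator matrices.
For a continuous-wave saturation block the system is linear,

    dM/dt = A M + b,

and is advanced exactly via the eigendecomposition of ``A`` (equivalent to a
matrix exponential):  M(t) = M_ss + exp(A t) (M(0) - M_ss)  with
M_ss = -A^{-1} b the driven steady state.  Exchange topology is star-shaped
(each solute pool exchanges with water only) and mass balance
``f_s * k_ws = k_sw`` fixes the reverse rate.  The semisolid pool couples
longitudinally and is saturated at the rate ``pi * w1^2 * g(dw)`` with ``g``
its absorption lineshape (super-Lorentzian by default, with the on-resonance
singularity bridged by polynomial interpolation over +-1 ppm).

A batched code path (:func:`simulate_batch`) propagates many tissue
parameter combinations that share a pool structure through the same
schedule at once; it is the workhorse behind dictionary generation and
digital phantoms and is bit-identical to the per-tissue path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pools import Pool, SemisolidPool, TissueModel
from .schedules import AcquisitionSchedule, SaturationEvent, ScheduleEntry

__all__ = [
    "GAMMA_HZ_PER_T",
    "ppm_to_angular_frequency",
    "absorption_lineshape",
    "MagnetizationState",
    "evolve_state",
    "simulate_trajectory",
    "simulate_zspectrum",
    "simulate_batch",
    "SignalTrajectory",
]

GAMMA_HZ_PER_T = 42.5764e6  # proton gyromagnetic ratio / 2 pi, Hz/T

_CHUNK = 4096  # rows per batched linear-algebra block (fixed for determinism)


def ppm_to_angular_frequency(offset_ppm: float, b0_field: float) -> float:
    """Convert a chemical-shift offset (ppm) to rad/s at the given field."""
    if b0_field <= 0:
        raise ValueError("b0_field must be > 0")
    return 2.0 * np.pi * GAMMA_HZ_PER_T * b0_field * offset_ppm * 1e-6


def _b1_to_omega1(b1_uT: float) -> float:
    """CW saturation amplitude in rad/s from B1 in microtesla."""
    return 2.0 * np.pi * GAMMA_HZ_PER_T * 1e-6 * b1_uT


# ---------------------------------------------------------------------------
# Semisolid absorption lineshapes


def _super_lorentzian_raw(delta: np.ndarray, t2: float) -> np.ndarray:
    """Super-Lorentzian absorption lineshape, valid away from resonance.

    g(d) = sqrt(2/pi) * T2 * int_0^1 du / |3u^2-1| * exp(-2 (d T2 / (3u^2-1))^2)
    """
    # Gauss-Legendre quadrature over u = cos(theta) in [0, 1].
    u, w = np.polynomial.legendre.leggauss(64)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    denom = 3.0 * u**2 - 1.0
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    arg = delta[..., None] * t2 / denom
    integrand = np.exp(-2.0 * arg**2) / np.abs(denom)
    return np.sqrt(2.0 / np.pi) * t2 * (integrand * w).sum(axis=-1)


def absorption_lineshape(delta_rad_s, t2: float, kind: str = "super_lorentzian",
                         b0_field: float = 7.0) -> np.ndarray:
    """Absorption lineshape g (units of seconds) at offset ``delta_rad_s``.

    For the super-Lorentzian the on-resonance singularity is bridged by
    fitting a cubic through samples at +-(1, 1.5, 2) ppm and evaluating it
    inside |delta| < 1 ppm.
    """
    delta = np.atleast_1d(np.asarray(delta_rad_s, dtype=float))
    if kind == "lorentzian":
        g = (t2 / np.pi) / (1.0 + (delta * t2) ** 2)
    elif kind == "super_lorentzian":
        cut = abs(ppm_to_angular_frequency(1.0, b0_field))
        g = _super_lorentzian_raw(delta, t2)
        inner = np.abs(delta) < cut
        if np.any(inner):
            # g is even in delta: interpolate a quadratic in delta^2 through
            # the samples at 1, 1.5 and 2 ppm (exact at the 1 ppm boundary,
            # so the bridged region joins continuously).
            nodes = np.array([1.0, 1.5, 2.0]) * cut
            coeffs = np.polyfit(nodes**2, _super_lorentzian_raw(nodes, t2), 2)
            g = np.where(inner, np.polyval(coeffs, delta**2), g)
    else:
        raise ValueError(f"unknown lineshape {kind!r}")
    return g if np.ndim(delta_rad_s) else float(g[0])


# ---------------------------------------------------------------------------
# State container


@dataclass
class MagnetizationState:
    """Transverse (x, y) and longitudinal (z) components per free pool plus
    the semisolid longitudinal component.  Row 0 of ``free`` is water."""

    free: np.ndarray  # (n_free, 3) -> columns x, y, z
    z_semisolid: Optional[float]
    pool_names: tuple[str, ...]  # free-pool names, water first

    @classmethod
    def equilibrium(cls, tissue: TissueModel) -> "MagnetizationState":
        n_free = 1 + len(tissue.solute_pools)
        free = np.zeros((n_free, 3))
        free[0, 2] = 1.0
        for i, pool in enumerate(tissue.solute_pools):
            free[i + 1, 2] = pool.volume_fraction
        zss = tissue.semisolid.volume_fraction if tissue.semisolid is not None else None
        names = ("water",) + tuple(p.name for p in tissue.solute_pools)
        return cls(free=free, z_semisolid=zss, pool_names=names)

    @property
    def water_z(self) -> float:
        return float(self.free[0, 2])

    def copy(self) -> "MagnetizationState":
        zss = None if self.z_semisolid is None else float(self.z_semisolid)
        return MagnetizationState(self.free.copy(), zss, self.pool_names)


@dataclass
class SignalTrajectory:
    """Per-pixel MRF signal: one intensity per schedule entry (entry 0 = M0)."""

    values: np.ndarray
    schedule_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Batched generator-matrix construction
#
# State vector layout: [x_0, y_0, z_0, x_1, y_1, z_1, ..., z_ss] with pool 0
# the water pool; the semisolid contributes a single trailing z component.


class _BatchModel:
    """Pre-assembled saturation-independent parts of the generator matrix for
    a batch of tissues sharing one pool structure."""

    def __init__(self, template: TissueModel, params: dict[str, np.ndarray]):
        template.validate()
        self.template = template
        arrays = {k: np.asarray(v, dtype=float) for k, v in params.items()}
        n = max((a.size for a in arrays.values()), default=1)
        for k, a in arrays.items():
            if a.size not in (1, n):
                raise ValueError(f"parameter {k!r} has incompatible length {a.size}")
            arrays[k] = np.broadcast_to(a.ravel(), (n,)).astype(float)
        self.n = n
        self.solutes = list(template.solute_pools)
        self.ss = template.semisolid
        self.n_free = 1 + len(self.solutes)
        self.dim = 3 * self.n_free + (1 if self.ss is not None else 0)

        def get(key: str, default: float) -> np.ndarray:
            return arrays.get(key, np.full(n, default))

        self.water_t1 = get("water_t1", template.water_t1)
        self.water_t2 = get("water_t2", template.water_t2)
        self.f = [get(f"f_{p.name}", p.volume_fraction) for p in self.solutes]
        self.k = [get(f"k_{p.name}", p.exchange_rate) for p in self.solutes]
        if self.ss is not None:
            self.f_ss = get(f"f_{self.ss.name}", self.ss.volume_fraction)
            self.k_ss = get(f"k_{self.ss.name}", self.ss.exchange_rate)

        self._assemble_base()

    def _assemble_base(self) -> None:
        n, d = self.n, self.dim
        A = np.zeros((n, d, d))
        b = np.zeros((n, d))
        r1w, r2w = 1.0 / self.water_t1, 1.0 / self.water_t2
        # Water relaxation.
        A[:, 0, 0] -= r2w
        A[:, 1, 1] -= r2w
        A[:, 2, 2] -= r1w
        b[:, 2] = r1w
        for i, pool in enumerate(self.solutes):
            base = 3 * (i + 1)
            r1, r2 = 1.0 / pool.t1, 1.0 / pool.t2
            k, f = self.k[i], self.f[i]
            A[:, base + 0, base + 0] -= r2
            A[:, base + 1, base + 1] -= r2
            A[:, base + 2, base + 2] -= r1
            b[:, base + 2] = r1 * f
            # Star-shaped exchange with water, all three components.
            for c in range(3):
                A[:, c, c] -= f * k
                A[:, c, base + c] += k
                A[:, base + c, base + c] -= k
                A[:, base + c, c] += f * k
        if self.ss is not None:
            zi = d - 1
            r1ss = 1.0 / self.ss.t1
            A[:, zi, zi] -= r1ss + self.k_ss
            A[:, zi, 2] += self.f_ss * self.k_ss
            A[:, 2, 2] -= self.f_ss * self.k_ss
            A[:, 2, zi] += self.k_ss
            b[:, zi] = r1ss * self.f_ss
        self.A_base, self.b = A, b
        # Longitudinal-only subsystem (used for relaxation with spoiled
        # transverse magnetization): indices of all z components.
        self.z_idx = np.array([3 * p + 2 for p in range(self.n_free)]
                              + ([d - 1] if self.ss is not None else []))
        self.Az = A[np.ix_(np.arange(n), self.z_idx, self.z_idx)].copy()
        self.bz = b[:, self.z_idx].copy()
        self._z_eig = None

    def equilibrium(self) -> np.ndarray:
        M = np.zeros((self.n, self.dim))
        M[:, 2] = 1.0
        for i in range(len(self.solutes)):
            M[:, 3 * (i + 1) + 2] = self.f[i]
        if self.ss is not None:
            M[:, -1] = self.f_ss
        return M

    def saturation_matrix(self, event: SaturationEvent, b0_field: float,
                          b0_shift: float) -> np.ndarray:
        """Full generator for one CW block (adds off-resonance + B1 terms)."""
        A = self.A_base.copy()
        w1 = _b1_to_omega1(event.b1_amplitude)
        shifts = [0.0] + [p.chemical_shift for p in self.solutes]
        for p, shift in enumerate(shifts):
            dw = ppm_to_angular_frequency(
                shift + b0_shift - event.frequency_offset, b0_field)
            base = 3 * p
            A[:, base + 0, base + 1] += dw
            A[:, base + 1, base + 0] -= dw
            A[:, base + 1, base + 2] += w1
            A[:, base + 2, base + 1] -= w1
        if self.ss is not None:
            dw_ss = ppm_to_angular_frequency(
                self.ss.chemical_shift + b0_shift - event.frequency_offset, b0_field)
            g = absorption_lineshape(dw_ss, self.ss.t2, self.ss.lineshape, b0_field)
            A[:, -1, -1] -= np.pi * w1**2 * g
        return A

    # -- propagation -------------------------------------------------------

    @staticmethod
    def _propagate(A: np.ndarray, b: np.ndarray, M: np.ndarray,
                   t: float) -> np.ndarray:
        """Exact linear-system step M(t) = Mss + V exp(w t) V^-1 (M - Mss)."""
        Mss = np.linalg.solve(A, -b[..., None])[..., 0]
        w, V = np.linalg.eig(A)
        c = np.linalg.solve(V, (M - Mss)[..., None].astype(complex))[..., 0]
        out = Mss + (V @ (np.exp(w * t) * c)[..., None])[..., 0].real
        return out

    def evolve_saturation(self, M: np.ndarray, event: SaturationEvent,
                          b0_field: float, b0_shift: float) -> np.ndarray:
        A = self.saturation_matrix(event, b0_field, b0_shift)
        return self._propagate(A, self.b, M, event.duration)

    def relax_z(self, z: np.ndarray, t: float) -> np.ndarray:
        """Free relaxation of the longitudinal subsystem (transverse spoiled)."""
        if self._z_eig is None:
            zss = np.linalg.solve(self.Az, -self.bz[..., None])[..., 0]
            w, V = np.linalg.eig(self.Az)
            Vinv = np.linalg.inv(V)
            self._z_eig = (zss, w, V, Vinv)
        zss, w, V, Vinv = self._z_eig
        c = (Vinv @ (z - zss)[..., None].astype(complex))[..., 0]
        return zss + (V @ (np.exp(w * t) * c)[..., None])[..., 0].real


def _run_schedule(model: _BatchModel, schedule: AcquisitionSchedule,
                  b0_shift: float) -> np.ndarray:
    """Propagate a batch through a schedule; returns (n_rows, n_entries)."""
    M = model.equilibrium()
    n_entries = len(schedule.entries)
    signals = np.zeros((model.n, n_entries))
    te_decay_cache: dict[float, np.ndarray] = {}
    for j, entry in enumerate(schedule.entries):
        if entry.saturation is not None:
            M = model.evolve_saturation(M, entry.saturation, schedule.b0_field,
                                        b0_shift)
        if entry.te not in te_decay_cache:
            te_decay_cache[entry.te] = np.exp(-entry.te / model.water_t2)
        signals[:, j] = M[:, 2] * te_decay_cache[entry.te]
        # Ideal 90-degree excitation + spoiling: all free-pool components are
        # consumed by the readout; the (unexcited) semisolid z carries over.
        z = M[:, model.z_idx].copy()
        z[:, : model.n_free] = 0.0
        t_rec = entry.tr - entry.saturation_duration - entry.te
        z = model.relax_z(z, t_rec)
        M = np.zeros_like(M)
        M[:, model.z_idx] = z
    return signals


def simulate_batch(template: TissueModel, params: dict[str, np.ndarray],
                   schedule: AcquisitionSchedule, chunk: int = _CHUNK) -> np.ndarray:
    """Simulate signal trajectories for many tissues sharing a pool layout.

    ``params`` maps parameter names (``water_t1``, ``water_t2``, ``f_<pool>``,
    ``k_<pool>``) to per-row value arrays; parameters not listed take the
    template's value.  Rows are processed in fixed-size chunks so results are
    bitwise independent of any outer parallelization.
    """
    schedule.validate()
    arrays = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in params.items()}
    n = max((a.size for a in arrays.values()), default=1)
    out = np.zeros((n, len(schedule.entries)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        sub = {k: (a if a.size == 1 else a[start:stop]) for k, a in arrays.items()}
        model = _BatchModel(template, sub)
        out[start:stop] = _run_schedule(model, schedule, template.b0_shift)
    return out


# ---------------------------------------------------------------------------
# Single-tissue convenience API


def _state_to_vector(state: MagnetizationState, model: _BatchModel) -> np.ndarray:
    M = np.zeros((1, model.dim))
    M[0, : 3 * model.n_free] = state.free.ravel()
    if model.ss is not None:
        M[0, -1] = state.z_semisolid
    return M


def _vector_to_state(M: np.ndarray, model: _BatchModel,
                     names: tuple[str, ...]) -> MagnetizationState:
    free = M[0, : 3 * model.n_free].reshape(model.n_free, 3).copy()
    zss = float(M[0, -1]) if model.ss is not None else None
    return MagnetizationState(free=free, z_semisolid=zss, pool_names=names)


def evolve_state(state: MagnetizationState, tissue: TissueModel,
                 event: SaturationEvent, b0_field: float = 7.0) -> MagnetizationState:
    """Evolve the coupled Bloch-McConnell system through one CW block."""
    event.validate()
    tissue.validate()
    model = _BatchModel(tissue, {})
    M = _state_to_vector(state, model)
    M = model.evolve_saturation(M, event, b0_field, tissue.b0_shift)
    return _vector_to_state(M, model, state.pool_names)


def simulate_trajectory(tissue: TissueModel,
                        schedule: AcquisitionSchedule) -> SignalTrajectory:
    """Non-steady-state signal trajectory for one tissue through a schedule."""
    tissue.validate()
    values = simulate_batch(tissue, {}, schedule)[0]
    return SignalTrajectory(values=values, schedule_id=schedule.name)


def simulate_zspectrum(tissue: TissueModel, protocol: AcquisitionSchedule):
    """Z-spectrum (offsets, S_sat/S0) from a sweep protocol with an M0 entry.

    Returns a :class:`cestmrf.zspec.ZSpectrum`.
    """
    from .zspec import ZSpectrum  # local import to avoid a cycle

    m0_entries = [j for j, e in enumerate(protocol.entries) if e.is_m0]
    if not m0_entries:
        raise ValueError("protocol has no unsaturated M0 entry")
    traj = simulate_trajectory(tissue, protocol)
    s0 = traj.values[m0_entries[0]]
    offsets, z = [], []
    to_discard = protocol.dummy_entries
    for j, entry in enumerate(protocol.entries):
        if entry.saturation is None:
            continue
        if to_discard > 0:
            to_discard -= 1
            continue
        offsets.append(entry.saturation.frequency_offset)
        z.append(traj.values[j] / s0)
    sat = next(e.saturation for e in protocol.entries if e.saturation is not None)
    return ZSpectrum(
        offsets=np.array(offsets), z_values=np.array(z),
        saturation_power=sat.b1_amplitude, saturation_duration=sat.duration,
    )
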