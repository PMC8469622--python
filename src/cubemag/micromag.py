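"""Effective-field evaluation and LLG time integration.

The magnetization dynamics follow the Landau-Lifshitz-Gilbert equation

    dM/dt = -gamma/(1+alpha^2) M x [H_eff + (alpha/Ms) M x H_eff],

with H_eff = H_a + H_m + H_ex + H_an (+ H_th).  Time stepping uses the
Cayley-transform geometric integrator: each cell's unit magnetization is
rotated about its instantaneous angular velocity, which preserves |m| = 1 to
round-off.  A time-adaptive controller bounds the local truncation error.

Quasi-static equilibria can alternatively be reached with a projected
Barzilai-Borwein energy descent ("minimize"), the standard accelerator for
static hysteresis computations; both modes stop on the same reduced-torque
criterion.

Unit conventions: magnetization is stored as the unit vector field m on the
full grid (zero outside the mask); fields are A/m, energies J/m^3, time s.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .demag import DemagKernel
from .geometry import DiscretizedGeometry
from .materials import K_B, MU0, MagneticMaterial

__all__ = [
    "MagnetizationState",
    "ThermalFieldParams",
    "LLGSolver",
    "ConvergenceError",
    "uniform_state",
    "demag_field",
    "exchange_field",
    "anisotropy_field",
    "thermal_field",
    "llg_step",
    "relax",
]


class ConvergenceError(RuntimeError):
    """Relaxation did not reach the torque criterion within the step budget."""

    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


@dataclass
class MagnetizationState:
    """Unit magnetization per cell (zero outside the mask) and simulated time."""

    m: np.ndarray  # (nx, ny, nz, 3)
    t: float = 0.0

    def copy(self) -> "MagnetizationState":
        return MagnetizationState(self.m.copy(), self.t)


@dataclass
class ThermalFieldParams:
    """Stochastic (Langevin) field parameters: temperature and time step."""

    T: float  # K
    dt: float  # s

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if self.dt <= 0:
            raise ValueError("time step must be > 0")


def uniform_state(geom: DiscretizedGeometry, direction) -> MagnetizationState:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    m = np.zeros(geom.grid_shape + (3,))
    m[geom.mask] = d
    return MagnetizationState(m=m)


def _normalize(m, mask):
    n = np.linalg.norm(m, axis=-1, keepdims=True)
    n[~mask] = 1.0
    return m / n


# 18/26-neighbour stencil weights chosen so the quadratic term of the Taylor
# expansion reproduces the Laplacian: w_face + 4 w_edge + 4 w_corner = 1.
_STENCILS = {
    "6": [(s, 1.0) for s in
          [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]],
    "26": (
        [(s, 1.0 / 3.0) for s in
         [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]]
        + [((sx, sy, sz), 1.0 / 12.0)
           for sx in (-1, 0, 1) for sy in (-1, 0, 1) for sz in (-1, 0, 1)
           if (sx, sy, sz) != (0, 0, 0) and abs(sx) + abs(sy) + abs(sz) >= 2]
    ),
}


class LLGSolver:
    """Field evaluator + integrator bound to one geometry and material.

    Parameters
    ----------
    geom : the discretized particle/assembly.
    material : magnetic constants.
    demag : include the magnetostatic field (default True).
    exchange_stencil : "6" (default) or "26" neighbour Laplacian.
    demag_dtype : precision of the FFT workspace.
    """

    def __init__(self, geom: DiscretizedGeometry, material: MagneticMaterial,
                 demag: bool = True, exchange_stencil: str = "6",
                 demag_dtype=np.float64):
        self.geom = geom
        self.material = material
        self.mask = geom.mask
        self.nmag = int(self.mask.sum())
        self.use_demag = demag
        self.kernel = DemagKernel(geom.grid_shape, dtype=demag_dtype) if demag else None
        self.stencil = _STENCILS[exchange_stencil]
        ds_m = geom.ds * 1e-9
        self.cex = 2.0 * material.k_ex / (MU0 * material.Ms * ds_m**2)
        self.ds_m = ds_m
        # padded mask for boundary-aware neighbour sums
        self._maskp = np.pad(self.mask, 1)
        nx, ny, nz = self.mask.shape
        self._mpad = np.zeros((nx + 2, ny + 2, nz + 2, 3))
        self._nb = []  # (slice, weighted neighbour-mask float array)
        for (sx, sy, sz), w in self.stencil:
            sl = (slice(1 + sx, 1 + sx + nx), slice(1 + sy, 1 + sy + ny),
                  slice(1 + sz, 1 + sz + nz))
            self._nb.append((sl, (w * self._maskp[sl].astype(float))[..., None]))
        self._wsum = sum(wm for _, wm in self._nb)  # per-cell neighbour weight
        self._maskf = self.mask.astype(float)[..., None]
        self.stats = {"field_evals": 0, "relax_iters": 0}

    # ------------------------------------------------------------------ fields
    def demag_field(self, m: np.ndarray) -> np.ndarray:
        M = self.material.Ms * m
        return self.kernel.field(M)

    def exchange_field(self, m: np.ndarray) -> np.ndarray:
        """Neighbour-difference Laplacian with free (Neumann) boundaries."""
        self._mpad[1:-1, 1:-1, 1:-1] = m
        h = -self._wsum * m
        for sl, wm in self._nb:
            h += wm * self._mpad[sl]
        h *= self.cex * self._maskf
        return h

    def anisotropy_field(self, m: np.ndarray) -> np.ndarray:
        mat = self.material
        mx2, my2, mz2 = m[..., 0] ** 2, m[..., 1] ** 2, m[..., 2] ** 2
        pref = -2.0 / (MU0 * mat.Ms)
        h = np.empty_like(m)
        h[..., 0] = pref * (mat.K1 * (my2 + mz2) + mat.K2 * my2 * mz2) * m[..., 0]
        h[..., 1] = pref * (mat.K1 * (mx2 + mz2) + mat.K2 * mx2 * mz2) * m[..., 1]
        h[..., 2] = pref * (mat.K1 * (mx2 + my2) + mat.K2 * mx2 * my2) * m[..., 2]
        if mat.Ku != 0.0:
            u = np.asarray(mat.easy_axis, dtype=float)
            u = u / np.linalg.norm(u)
            proj = m @ u
            h += (2.0 * mat.Ku / (MU0 * mat.Ms)) * proj[..., None] * u
        h[~self.mask] = 0.0
        return h

    def thermal_field(self, params: ThermalFieldParams, seed: int,
                      step: int = 0) -> np.ndarray:
        """Langevin field: iid N(0,1) triples scaled by the
        fluctuation-dissipation amplitude sqrt(2 a kB T / (g mu0 Ms ds^3 dt))."""
        mat = self.material
        if params.T == 0.0:
            return np.zeros(self.mask.shape + (3,))
        amp = np.sqrt(
            2.0 * mat.alpha * K_B * params.T
            / (mat.gamma * MU0 * mat.Ms * self.ds_m**3 * params.dt)
        )
        rng = np.random.Generator(
            np.random.Philox(key=np.uint64(seed), counter=[0, 0, 0, np.uint64(step)])
        )
        eta = rng.standard_normal(self.mask.shape + (3,))
        eta[~self.mask] = 0.0
        return amp * eta

    def effective_field(self, m: np.ndarray, H_a: np.ndarray,
                        components: bool = False):
        """H_eff = H_a + H_m + H_ex + H_an (thermal handled by the caller)."""
        self.stats["field_evals"] += 1
        if components:
            parts = {"H_a": np.broadcast_to(np.asarray(H_a, float), m.shape)}
            if self.use_demag:
                parts["H_m"] = self.demag_field(m)
            parts["H_ex"] = self.exchange_field(m)
            parts["H_an"] = self.anisotropy_field(m)
            h = sum(parts.values())
            h = np.where(self.mask[..., None], h, 0.0)
            return h, parts
        h = self.exchange_field(m)
        h += self.anisotropy_field(m)
        if self.use_demag:
            h += self.demag_field(m)
        h += np.asarray(H_a, float)
        h *= self._maskf
        return h

    # ---------------------------------------------------------------- energies
    def energies(self, m: np.ndarray, H_a) -> dict[str, float]:
        """Volume-averaged energy densities (J/m^3) over the magnetic region."""
        mat = self.material
        mask = self.mask
        mm = m[mask]
        Ha = np.broadcast_to(np.asarray(H_a, float), m.shape)[mask]
        out = {"E_Z": float(-MU0 * mat.Ms * np.mean(np.sum(mm * Ha, axis=-1)))}
        hex_ = self.exchange_field(m)[mask]
        out["E_ex"] = float(-0.5 * MU0 * mat.Ms * np.mean(np.sum(mm * hex_, axis=-1)))
        if self.use_demag:
            hm = self.demag_field(m)[mask]
            out["E_m"] = float(-0.5 * MU0 * mat.Ms * np.mean(np.sum(mm * hm, axis=-1)))
        else:
            out["E_m"] = 0.0
        mx2, my2, mz2 = mm[:, 0] ** 2, mm[:, 1] ** 2, mm[:, 2] ** 2
        ean = mat.K1 * (mx2 * my2 + my2 * mz2 + mz2 * mx2) + mat.K2 * mx2 * my2 * mz2
        if mat.Ku != 0.0:
            u = np.asarray(mat.easy_axis, float)
            u = u / np.linalg.norm(u)
            ean = ean + mat.Ku * (1.0 - (mm @ u) ** 2)
        out["E_an"] = float(np.mean(ean))
        out["E_total"] = out["E_Z"] + out["E_ex"] + out["E_m"] + out["E_an"]
        return out

    # -------------------------------------------------------------- integrator
    def _omega(self, m, h):
        """Angular velocity of the LLG rotation, per cell."""
        mat = self.material
        gp = mat.gamma / (1.0 + mat.alpha**2)
        return gp * (h + mat.alpha * np.cross(m, h))

    @staticmethod
    def _cayley_rotate(m, omega, dt):
        """Rotate m about omega by the Cayley angle 2*atan(|w| dt / 2)."""
        wnorm = np.linalg.norm(omega, axis=-1, keepdims=True)
        axis = omega / np.where(wnorm > 0, wnorm, 1.0)
        theta = 2.0 * np.arctan(0.5 * wnorm * dt)
        c, s = np.cos(theta), np.sin(theta)
        adotm = np.sum(axis * m, axis=-1, keepdims=True)
        return c * m + s * np.cross(axis, m) + (1.0 - c) * adotm * axis

    def llg_step(self, state: MagnetizationState, h_eff: np.ndarray,
                 dt: float) -> MagnetizationState:
        """Advance one explicit Cayley step with the given effective field."""
        omega = self._omega(state.m, h_eff)
        m_new = self._cayley_rotate(state.m, omega, dt)
        m_new[~self.mask] = 0.0
        return MagnetizationState(m=m_new, t=state.t + dt)

    def reduced_torque(self, m, h):
        """max over cells of |m x h| / |h| (dimensionless).

        The per-cell normalization is floored at 1% of the largest cell field:
        in cells where the field terms nearly cancel (|h| -> 0, e.g. corner
        cells at strong applied fields) the ratio is ill-conditioned while the
        physical torque is negligible.
        """
        mask = self.mask
        tq = np.linalg.norm(np.cross(m[mask], h[mask]), axis=-1)
        hn = np.linalg.norm(h[mask], axis=-1)
        if not len(tq):
            return 0.0
        hn = np.maximum(hn, max(0.01 * float(hn.max()), 1.0))
        return float(np.max(tq / hn))

    # ------------------------------------------------------------- relaxation
    def relax(self, state: MagnetizationState, H_a, torque_tol: float = 1e-4,
              method: str = "llg", max_steps: int = 500_000,
              trunc_tol: float = 1e-5, dt0: float = 1e-13,
              thermal: ThermalFieldParams | None = None, seed: int = 0
              ) -> MagnetizationState:
        """Integrate to equilibrium at fixed applied field.

        "llg": damped LLG with adaptive Cayley stepping (local truncation
        error kept near ``trunc_tol``).  "minimize": Barzilai-Borwein descent
        along the damping torque.  Raises :class:`ConvergenceError` carrying
        the torque residual on failure.
        """
        if method == "minimize":
            return self._relax_bb(state, H_a, torque_tol, max_steps)
        m = state.m.copy()
        t = state.t
        dt = dt0
        omega_prev = None
        for it in range(max_steps):
            h = self.effective_field(m, H_a)
            if thermal is not None:
                h = h + self.thermal_field(thermal, seed, step=it)
            tau = self.reduced_torque(m, h)
            if tau < torque_tol:
                return MagnetizationState(m=m, t=t)
            omega = self._omega(m, h)
            if omega_prev is not None:
                # local angle error ~ 0.5 |domega/dt| dt^2 (radians)
                dw = float(np.max(np.linalg.norm(omega - omega_prev, axis=-1)))
                err = 0.5 * dw / max(dt_prev, 1e-30) * dt * dt
                if err > 4.0 * trunc_tol:
                    dt = max(dt * 0.5, 1e-16)
                elif err > 0:
                    dt = min(dt * min((trunc_tol / err) ** 0.5, 1.25), 5e-11)
            m = self._cayley_rotate(m, omega, dt)
            m[~self.mask] = 0.0
            t += dt
            omega_prev = omega
            dt_prev = dt
        raise ConvergenceError(
            f"relax: torque {tau:.3e} above {torque_tol:.1e} after {max_steps} steps",
            residual=tau,
        )

    def _relax_bb(self, state, H_a, torque_tol, max_steps):
        mask3 = self.mask[..., None]
        m = state.m.copy()
        h = self.effective_field(m, H_a)
        g = np.cross(m, np.cross(m, h))
        hmax = float(np.max(np.linalg.norm(h[self.mask], axis=-1), initial=1.0))
        tau_step = 0.05 / max(hmax, 1.0)
        for it in range(max_steps):
            if self.reduced_torque(m, h) < torque_tol:
                return MagnetizationState(m=m, t=state.t)
            m_new = _normalize(m - tau_step * g, self.mask)
            m_new = np.where(mask3, m_new, 0.0)
            h = self.effective_field(m_new, H_a)
            g_new = np.cross(m_new, np.cross(m_new, h))
            s = (m_new - m).ravel()
            y = (g_new - g).ravel()
            sy = float(s @ y)
            if sy > 1e-300:
                # alternate the two Barzilai-Borwein step lengths
                tau_step = (float(s @ s) / sy if it % 2 == 0
                            else sy / float(y @ y))
                tau_step = min(max(tau_step, 1e-4 / hmax), 1e4 / hmax)
            else:
                tau_step = 0.05 / hmax
            m, g = m_new, g_new
        raise ConvergenceError(
            f"minimize: torque above {torque_tol:.1e} after {max_steps} steps",
            residual=self.reduced_torque(m, h),
        )

    # --------------------------------------------------- stochastic trajectory
    def run_thermal(self, state: MagnetizationState, H_a, T: float, dt: float,
                    n_steps: int, seed: int = 0, record_every: int = 0):
        """Fixed-step stochastic LLG (Heun-style midpoint Cayley rotation).

        Returns the final state and, if ``record_every`` > 0, the recorded
        magnetization snapshots (list of arrays).
        """
        params = ThermalFieldParams(T=T, dt=dt)
        m = state.m.copy()
        rec = []
        for step in range(n_steps):
            hth = self.thermal_field(params, seed, step=step)
            h1 = self.effective_field(m, H_a) + hth
            w1 = self._omega(m, h1)
            m_mid = self._cayley_rotate(m, w1, 0.5 * dt)
            m_mid[~self.mask] = 0.0
            h2 = self.effective_field(m_mid, H_a) + hth
            w2 = self._omega(m_mid, h2)
            m = self._cayley_rotate(m, w2, dt)
            m[~self.mask] = 0.0
            if record_every and (step + 1) % record_every == 0:
                rec.append(m.copy())
        return MagnetizationState(m=m, t=state.t + n_steps * dt), rec


# ------------------------------------------------------------- module-level ops
def _solver_for(geom, material, **kw) -> LLGSolver:
    return LLGSolver(geom, material, **kw)


def demag_field(state: MagnetizationState, geom: DiscretizedGeometry,
                material: MagneticMaterial) -> np.ndarray:
    return _solver_for(geom, material).demag_field(state.m)


def exchange_field(state: MagnetizationState, geom: DiscretizedGeometry,
                   material: MagneticMaterial, stencil: str = "6") -> np.ndarray:
    return _solver_for(geom, material, demag=False,
                       exchange_stencil=stencil).exchange_field(state.m)


def anisotropy_field(state: MagnetizationState, geom: DiscretizedGeometry,
                     material: MagneticMaterial) -> np.ndarray:
    return _solver_for(geom, material, demag=False).anisotropy_field(state.m)


def thermal_field(params: ThermalFieldParams, geom: DiscretizedGeometry,
                  material: MagneticMaterial, rng_seed: int,
                  step: int = 0) -> np.ndarray:
    return _solver_for(geom, material, demag=False).thermal_field(
        params, rng_seed, step)


def llg_step(state: MagnetizationState, h_eff: np.ndarray,
             material: MagneticMaterial, geom: DiscretizedGeometry,
             dt: float) -> MagnetizationState:
    return _solver_for(geom, material, demag=False).llg_step(state, h_eff, dt)


def relax(state: MagnetizationState, H_a, material: MagneticMaterial,
          geom: DiscretizedGeometry, **kw) -> MagnetizationState:
    return _solver_for(geom, material).relax(state, H_a, **kw)
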