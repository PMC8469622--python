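"""Quasi-static hysteresis loops and their properties.

A field sweep drives the particle through a sequence of equilibria
(descending branch from +H_max to -H_max, then ascending back), warm-starting
each relaxation from the previous equilibrium.  Coarse field steps are
refined on the fly wherever the magnetization jumps, so switching fields are
resolved at the fine step.  From the closed loop the remanence M_r, the
coercivity H_c (linear interpolation of the M = 0 crossing, branch-averaged)
and the specific energy losses

    E = mu0 * contour-integral of H_a dM        (J/m^3)

are extracted.  A high-field law-of-approach fit M = Ms (1 - d/H - l/H^2) + chi H
estimates the saturation magnetization; ensembles over size and orientation
are handled by weighted loop averaging.

Applied-field directions are tilted by a small fixed angle (default 1
degree) toward a fixed generic direction: with the field exactly on a
crystal symmetry axis a deterministic simulation would sit forever on an
unstable saddle at switching.

All public numeric interfaces are SI (A/m, J/m^3); kA/m and kJ/m^3 appear
only in files and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.interpolate import make_interp_spline

from .geometry import DiscretizedGeometry
from .materials import MU0, MagneticMaterial
from .micromag import LLGSolver, MagnetizationState, uniform_state

__all__ = [
    "FieldSweepProtocol",
    "HysteresisLoop",
    "LoopProperties",
    "SaturationFit",
    "LawOfApproachModel",
    "DomainClassification",
    "IncompleteLoopError",
    "ProtocolError",
    "tilted_direction",
    "run_loop",
    "loop_properties",
    "fit_law_of_approach",
    "classify_domain_state",
    "size_sweep",
    "ensemble_average",
    "orientation_set",
]


class IncompleteLoopError(ValueError):
    """Loop property extraction needs both branches."""


class ProtocolError(RuntimeError):
    """Sweep protocol failure, e.g. branches not closing at +-H_max."""


# fixed generic tie-break direction for the symmetry-breaking tilt
_TILT_REF = np.array([0.7, 0.5, 0.9]) / np.linalg.norm([0.7, 0.5, 0.9])


def tilted_direction(direction, tilt_deg: float = 1.0) -> np.ndarray:
    """Unit vector ``direction`` rotated by ``tilt_deg`` toward a fixed
    generic transverse direction (deterministic symmetry breaking)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if tilt_deg == 0.0:
        return d
    p = _TILT_REF - (_TILT_REF @ d) * d
    if np.linalg.norm(p) < 1e-8:
        alt = np.array([1.0, 0.0, 0.0])
        p = alt - (alt @ d) * d
    p = p / np.linalg.norm(p)
    a = np.radians(tilt_deg)
    return d * np.cos(a) + p * np.sin(a)


@dataclass(frozen=True)
class FieldSweepProtocol:
    """Quasi-static field sweep along ``direction`` (SI units, A/m).

    ``coarse_step`` is used everywhere except across magnetization jumps
    (|dM| > refine_trigger * Ms between consecutive equilibria), which are
    re-walked at ``fine_step``.  ``tilt_deg`` breaks crystal-symmetry
    degeneracy; ``method`` selects the relaxation mode ("llg" damped dynamics
    or "minimize" energy descent).
    """

    direction: tuple = (1.0, 0.0, 0.0)
    H_max: float = 200e3
    coarse_step: float = 4e3
    fine_step: float = 0.5e3
    refine_trigger: float = 0.25
    tilt_deg: float = 1.0
    method: str = "minimize"
    torque_tol: float = 1e-4
    half_loop: bool = False
    closure_tol: float = 0.02

    def __post_init__(self):
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise ValueError("field steps must be positive")
        if self.H_max <= 0:
            raise ValueError("H_max must be positive")


@dataclass
class LoopProperties:
    """Remanence (A/m), coercivity (A/m) and loop energy losses (J/m^3)."""

    Mr: float
    Hc: float
    E: float

    def as_dict_pretty(self) -> dict:
        return {
            "Mr_kA_per_m": self.Mr / 1e3,
            "Hc_kA_per_m": self.Hc / 1e3,
            "E_kJ_per_m3": self.E / 1e3,
        }


@dataclass
class HysteresisLoop:
    """Branch data (H_a, M-parallel samples in A/m) plus metadata.

    ``branches`` maps "descending"/"ascending" to (H, M) arrays ordered along
    the sweep.  ``energy_trace`` holds the per-equilibrium energy
    decomposition; ``snapshots`` the magnetization at remanence/coercivity.
    """

    branches: dict
    meta: dict = dfield(default_factory=dict)
    energy_trace: pd.DataFrame | None = None
    snapshots: dict = dfield(default_factory=dict)

    @property
    def properties(self) -> LoopProperties:
        return loop_properties(self)

    def to_csv(self, path_or_buf=None):
        """Loop CSV: columns branch, H_a_kA_per_m, M_kA_per_m."""
        rows = []
        for br, (H, M) in self.branches.items():
            rows.append(pd.DataFrame(
                {"branch": br, "H_a_kA_per_m": H / 1e3, "M_kA_per_m": M / 1e3}))
        return pd.concat(rows, ignore_index=True).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, meta=None) -> "HysteresisLoop":
        df = pd.read_csv(path_or_buf)
        branches = {}
        for br, g in df.groupby("branch", sort=False):
            branches[br] = (g["H_a_kA_per_m"].to_numpy() * 1e3,
                            g["M_kA_per_m"].to_numpy() * 1e3)
        return cls(branches=branches, meta=meta or {})

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for br, (H, M) in self.branches.items():
            ax.plot(H / 1e3, M / 1e3, label=br, **kw)
        ax.set_xlabel("$H_a$ (kA/m)")
        ax.set_ylabel("$M$ (kA/m)")
        ax.legend()
        return ax


def _branch_points(H_start, H_end, coarse):
    n = int(round(abs(H_end - H_start) / coarse))
    return np.linspace(H_start, H_end, n + 1)[1:]


def _sweep_branch(sol: LLGSolver, state, proto: FieldSweepProtocol, H_start,
                  H_end, d_tilt, d_nominal, record):
    """Walk one branch, refining across jumps; mutates and returns state."""
    Ms = sol.material.Ms
    mask3 = sol.mask[..., None]
    last = {"m": None}  # previous equilibrium, for extrapolated warm starts

    def equil(st, H, extrapolate=True):
        m0 = st.m
        if extrapolate and last["m"] is not None:
            m0 = 2.0 * st.m - last["m"]
            n = np.linalg.norm(m0, axis=-1, keepdims=True)
            n[~sol.mask] = 1.0
            m0 = np.where(mask3, m0 / n, 0.0)
        last["m"] = st.m.copy()
        return sol.relax(MagnetizationState(m0.copy(), st.t), H * d_tilt,
                         torque_tol=proto.torque_tol, method=proto.method)

    def mpar(st):
        return Ms * float(np.mean(st.m[sol.mask] @ d_nominal))

    H_prev = H_start
    M_prev = mpar(state)
    for H in _branch_points(H_start, H_end, proto.coarse_step):
        prev_state = state
        prev_last = last["m"]
        state = equil(state, H)
        M = mpar(state)
        if (abs(M - M_prev) > proto.refine_trigger * Ms
                and proto.coarse_step > proto.fine_step):
            # jump detected: re-walk this interval at the fine step
            state = prev_state
            last["m"] = prev_last
            n_f = int(round(abs(H - H_prev) / proto.fine_step))
            for Hf in np.linspace(H_prev, H, n_f + 1)[1:]:
                state = equil(state, Hf)
                record(Hf, mpar(state), state)
        else:
            record(H, M, state)
        H_prev, M_prev = H, mpar(state)
    return state


def run_loop(geom: DiscretizedGeometry, material: MagneticMaterial,
             protocol: FieldSweepProtocol | None = None,
             solver_kwargs: dict | None = None) -> HysteresisLoop:
    """Compute a static major hysteresis loop.

    Saturates along the (tilted) sweep direction at +H_max, walks the
    descending branch to -H_max and the ascending branch back (or mirrors the
    descending branch when ``protocol.half_loop`` — valid for
    centro-symmetric geometries).  Records the energy decomposition at every
    equilibrium and snapshots at remanence and just past coercivity.
    """
    proto = protocol or FieldSweepProtocol()
    sol = LLGSolver(geom, material, **(solver_kwargs or {}))
    if geom.shape_spec is not None:
        # crystal->lab orientation applied to the field, not the mask
        R = geom.shape_spec.orientation
        d_nom_lab = np.asarray(proto.direction, float)
        d_nom_lab = d_nom_lab / np.linalg.norm(d_nom_lab)
        d_nominal = R.T @ d_nom_lab
    else:
        d_nominal = np.asarray(proto.direction, float)
        d_nominal = d_nominal / np.linalg.norm(d_nominal)
    d_tilt = tilted_direction(d_nominal, proto.tilt_deg)

    Hs, Ms_, energies = [], [], []
    snapshots = {}
    prev_rec = {}

    def record(H, M, state):
        Hs.append(H)
        Ms_.append(M)
        energies.append(sol.energies(state.m, H * d_tilt))
        if abs(H) < 0.5 * proto.fine_step and "remanence" not in snapshots:
            snapshots["remanence"] = state.m.copy()
        if prev_rec and "coercivity" not in snapshots:
            if np.sign(M) != np.sign(prev_rec["M"]) and prev_rec["M"] != 0:
                snapshots["coercivity"] = state.m.copy()
        prev_rec.update(H=H, M=M)

    state = uniform_state(geom, d_tilt)
    state = sol.relax(state, proto.H_max * d_tilt, torque_tol=proto.torque_tol,
                      method=proto.method)
    record(proto.H_max, material.Ms * float(np.mean(state.m[sol.mask] @ d_nominal)),
           state)
    state = _sweep_branch(sol, state, proto, proto.H_max, -proto.H_max,
                          d_tilt, d_nominal, record)
    n_desc = len(Hs)
    H_desc, M_desc = np.array(Hs), np.array(Ms_)

    if proto.half_loop:
        # exact mirror: M_asc(H) = -M_desc(-H); H_desc descends, so -H_desc
        # is already ordered along the ascending sweep
        H_asc, M_asc = -H_desc, -M_desc
        # mirrored energies (all terms even under m -> -m, H -> -H)
        energies = energies + energies
    else:
        state = _sweep_branch(sol, state, proto, -proto.H_max, proto.H_max,
                              d_tilt, d_nominal, record)
        H_asc, M_asc = np.array(Hs[n_desc:]), np.array(Ms_[n_desc:])

    # closure: ascending branch must return to the starting magnetization
    gap = abs(M_asc[-1] - M_desc[0]) / material.Ms
    if gap > proto.closure_tol:
        raise ProtocolError(
            f"loop does not close at +H_max (|dM|/Ms = {gap:.3f}); increase H_max"
        )

    trace = pd.DataFrame(energies)
    trace.insert(0, "H_a", np.concatenate([H_desc, H_asc]))
    meta = dict(geom.meta())
    meta.update(direction=list(np.round(d_nominal, 6)), tilt_deg=proto.tilt_deg,
                H_max=proto.H_max, coarse_step=proto.coarse_step,
                fine_step=proto.fine_step, method=proto.method,
                half_loop=proto.half_loop)
    return HysteresisLoop(
        branches={"descending": (H_desc, M_desc), "ascending": (H_asc, M_asc)},
        meta=meta, energy_trace=trace, snapshots=snapshots)


# ------------------------------------------------------------------ properties
def _zero_crossings(H, M, target="M"):
    """Linearly interpolated zero crossings of M(H) (or H where M crosses)."""
    out = []
    for i in range(len(H) - 1):
        a, b = M[i], M[i + 1]
        if a == 0.0:
            out.append(H[i])
        elif a * b < 0:
            out.append(H[i] - a * (H[i + 1] - H[i]) / (b - a))
    if len(H) and M[-1] == 0.0:
        out.append(H[-1])
    return out


def _interp_at_zero_field(H, M):
    idx = np.argsort(H)
    return float(np.interp(0.0, H[idx], M[idx]))


def loop_properties(loop: HysteresisLoop) -> LoopProperties:
    """(M_r, H_c, E) from a closed two-branch loop.

    M_r: branch-averaged |M(H=0)|.  H_c: branch-averaged |H| at the
    interpolated M = 0 crossing.  E: mu0 times the shoelace contour integral
    of H dM around the closed loop (J/m^3, >= 0 for a passive cycle).
    """
    if set(loop.branches) < {"descending", "ascending"}:
        raise IncompleteLoopError("both descending and ascending branches needed")
    Hd, Md = loop.branches["descending"]
    Ha, Ma = loop.branches["ascending"]
    Mr = 0.5 * (abs(_interp_at_zero_field(Hd, Md)) + abs(_interp_at_zero_field(Ha, Ma)))
    cr_d = _zero_crossings(Hd, Md)
    cr_a = _zero_crossings(Ha, Ma)
    if cr_d and cr_a:
        Hc = 0.5 * (abs(cr_d[0]) + abs(cr_a[0]))
    else:
        Hc = 0.0
    # closed polygon in the (H, M) plane; E = mu0 * oint H dM = mu0 * area
    H = np.concatenate([Hd, Ha])
    M = np.concatenate([Md, Ma])
    E = MU0 * 0.5 * float(np.sum(H * np.roll(M, -1) - np.roll(H, -1) * M))
    # orientation of traversal decides the sign; losses are the magnitude
    return LoopProperties(Mr=Mr, Hc=Hc, E=abs(E))


# -------------------------------------------------------- law of approach fit
@dataclass
class SaturationFit:
    """Law-of-approach parameters: M = Ms (1 - delta/H - lam/H^2) + chi H."""

    Ms: float
    delta: float
    lam: float
    chi: float
    cov: np.ndarray
    resid: np.ndarray
    window: tuple

    @property
    def Ms_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))


class LawOfApproachModel:
    """High-field saturation-approach model, linear-least-squares fit.

    The model is linear in (Ms, a = Ms*delta, b = Ms*lam, chi), so the fit is
    exact on noiseless data.  ``chi`` is fixed to zero by default (no
    paramagnetic background).
    """

    def __init__(self, H, M, window=None, fit_chi: bool = False):
        H = np.asarray(H, float)
        M = np.asarray(M, float)
        if window is not None:
            keep = (H >= window[0]) & (H <= window[1])
            H, M = H[keep], M[keep]
        else:
            window = (float(H.min()), float(H.max()))
        if len(H) < 4:
            raise ValueError("need >= 4 samples in the fit window")
        if np.any(H <= 0):
            raise ValueError("law-of-approach window must be at positive fields")
        self.H, self.M, self.window, self.fit_chi = H, M, tuple(window), fit_chi

    def fit(self) -> SaturationFit:
        H, M = self.H, self.M
        cols = [np.ones_like(H), -1.0 / H, -1.0 / H**2]
        if self.fit_chi:
            cols.append(H)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, M, rcond=None)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design: widen the window")
        resid = M - X @ beta
        dof = max(len(H) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov_lin = sigma2 * np.linalg.inv(X.T @ X)
        Ms, a, b = beta[0], beta[1], beta[2]
        chi = beta[3] if self.fit_chi else 0.0
        # delta = a/Ms, lam = b/Ms via the delta method
        J = np.zeros((4, X.shape[1]))
        J[0, 0] = 1.0
        J[1, 0], J[1, 1] = -a / Ms**2, 1.0 / Ms
        J[2, 0], J[2, 2] = -b / Ms**2, 1.0 / Ms
        if self.fit_chi:
            J[3, 3] = 1.0
        cov = J @ cov_lin @ J.T
        return SaturationFit(Ms=float(Ms), delta=float(a / Ms), lam=float(b / Ms),
                             chi=float(chi), cov=cov, resid=resid,
                             window=self.window)


def fit_law_of_approach(H, M, window=None, fit_chi=False) -> SaturationFit:
    return LawOfApproachModel(H, M, window=window, fit_chi=fit_chi).fit()


# ------------------------------------------------------- domain classification
@dataclass
class DomainClassification:
    state: str  # "single_domain" | "vortex_multidomain"
    mean_magnetization: float  # |<m>|
    circulation: float  # mean azimuthal component about the field axis


class StaleStateError(ValueError):
    """Classification asked for on a non-equilibrium state."""


def classify_domain_state(state_m: np.ndarray, geom: DiscretizedGeometry,
                          axis=(1.0, 0.0, 0.0), threshold: float = 0.8,
                          solver: LLGSolver | None = None,
                          check_equilibrium: bool = False,
                          torque_tol: float = 1e-3) -> DomainClassification:
    """Single-domain vs vortex/multidomain at remanence.

    single_domain iff |<m>| > threshold; the circulation order parameter is
    the mean magnetization component along the azimuthal direction about
    ``axis`` through the particle centroid (~1 for an ideal vortex).
    """
    mask = geom.mask
    mm = state_m[mask]
    if check_equilibrium:
        if solver is None:
            raise ValueError("equilibrium check needs the solver")
        h = solver.effective_field(state_m, np.zeros(3))
        if solver.reduced_torque(state_m, h) > torque_tol:
            raise StaleStateError("state is not relaxed at remanence")
    mean_m = float(np.linalg.norm(mm.mean(axis=0)))
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    pos = geom.cell_centers()
    pos = pos - pos.mean(axis=0)
    rho = pos - np.outer(pos @ a, a)
    rho_n = np.linalg.norm(rho, axis=1)
    good = rho_n > 1e-9
    phi_hat = np.cross(a, rho[good]) / rho_n[good, None]
    circulation = float(np.mean(np.sum(mm[good] * phi_hat, axis=1)))
    state = "single_domain" if mean_m > threshold else "vortex_multidomain"
    return DomainClassification(state=state, mean_magnetization=mean_m,
                                circulation=circulation)


# --------------------------------------------------------------- sweeps & avg
def size_sweep(sizes, direction, material: MagneticMaterial,
               protocol: FieldSweepProtocol | None = None,
               ds=None, solver_kwargs=None, return_loops: bool = False):
    """Loop properties vs particle size, with a cubic-spline interpolant.

    Returns a DataFrame with columns l_nm, Mr, Hc, E (SI units) and, when
    >= 4 sizes are given, attrs "Hc_argmax_nm" / "E_argmax_nm" located on a
    dense evaluation of a cubic basis spline through the sweep points.
    """
    from .geometry import build_truncated_cube, ds_for_size

    sizes = list(sizes)
    if len(sizes) < 1:
        raise ValueError("need at least one size")
    base = protocol or FieldSweepProtocol()
    rows, loops, errors = [], {}, {}
    for l in sizes:
        geom = build_truncated_cube(l, ds if ds is not None else ds_for_size(l))
        proto = FieldSweepProtocol(**{**base.__dict__, "direction": tuple(
            np.atleast_1d(direction))})
        try:
            loop = run_loop(geom, material, proto, solver_kwargs=solver_kwargs)
        except Exception as exc:  # propagate per-size, annotated
            errors[l] = exc
            continue
        p = loop.properties
        rows.append({"l_nm": l, "Mr": p.Mr, "Hc": p.Hc, "E": p.E})
        loops[l] = loop
    df = pd.DataFrame(rows)
    df.attrs["errors"] = errors
    if len(df) >= 4:
        ls = df["l_nm"].to_numpy()
        dense = np.linspace(ls.min(), ls.max(), 512)
        for col in ("Hc", "E"):
            spl = make_interp_spline(ls, df[col].to_numpy(), k=3)
            df.attrs[f"{col}_argmax_nm"] = float(dense[np.argmax(spl(dense))])
    return (df, loops) if return_loops else df


def ensemble_average(loops, weights=None) -> HysteresisLoop:
    """Weight-average M(H) over loops, resampled to a common field grid.

    Mimics a polydisperse, orientation-distributed ensemble: each loop enters
    with its probability weight; properties are recomputed on the averaged
    loop.
    """
    loops = list(loops)
    if not loops:
        raise ValueError("no loops to average")
    if weights is None:
        weights = np.ones(len(loops))
    w = np.asarray(weights, float)
    w = w / w.sum()
    branches = {}
    for br in ("descending", "ascending"):
        grids = [np.sort(lp.branches[br][0]) for lp in loops]
        lo = max(g[0] for g in grids)
        hi = min(g[-1] for g in grids)
        H = np.unique(np.concatenate(
            [g[(g >= lo) & (g <= hi)] for g in grids]))
        Mavg = np.zeros_like(H)
        for wi, lp in zip(w, loops):
            Hb, Mb = lp.branches[br]
            idx = np.argsort(Hb)
            Mavg += wi * np.interp(H, Hb[idx], Mb[idx])
        if br == "descending":
            H, Mavg = H[::-1], Mavg[::-1]
        branches[br] = (H, Mavg)
    return HysteresisLoop(branches=branches,
                          meta={"ensemble_of": len(loops)})


def orientation_set(n_fibonacci: int = 8, include_crystallographic: bool = True
                    ) -> np.ndarray:
    """Deterministic field-direction set: spherical-Fibonacci points plus the
    <100>, <110>, <111> crystallographic directions, for orientation averages."""
    k = np.arange(n_fibonacci) + 0.5
    golden = (1 + 5**0.5) / 2
    theta = np.arccos(1 - 2 * k / n_fibonacci)
    phi = 2 * np.pi * k / golden
    pts = np.column_stack([np.sin(theta) * np.cos(phi),
                           np.sin(theta) * np.sin(phi),
                           np.cos(theta)])
    if include_crystallographic:
        extra = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]], float)
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        pts = np.vstack([pts, extra])
    return pts
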