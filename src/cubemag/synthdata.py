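"""Synthetic inputs standing in for the study's instruments.

Three generators, all pure functions of (parameters, seed):

* particle-size draws from the truncated Gaussians fitted to the four
  samples' TEM size histograms (#1: 18.3/9.5 nm, #2: 14.9/8.5 nm,
  #3: 22.1/15.7 nm, #4: 162/95 nm on 50-275 nm);
* stratified (size, orientation) ensembles with truncated-normal
  probability weights, for polydispersity/orientation averaging of loops;
* fiber-optic-thermometer stand-ins: heating-cooling temperature traces of
  a suspension with known ground-truth SLP, ambient drift and additive
  Gaussian sensor noise, produced by the full conduction solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import stats

from .hysteresis import orientation_set
from .thermal import (AmbientLaw, HeatSources, ThermalScene, ThermometryTrace,
                      q_mnps, solve_heat)

__all__ = [
    "SizeDistribution",
    "SAMPLE_DISTRIBUTIONS",
    "GroundTruth",
    "sample_sizes",
    "make_trace",
    "make_ensemble_inputs",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated Gaussian over particle side length l (nm)."""

    mu: float
    sigma: float
    lo: float = 0.0
    hi: float = np.inf
    label: str = ""

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lo < 0 or self.hi <= self.lo:
            raise ValueError("invalid truncation range")

    def _frozen(self):
        a = (self.lo - self.mu) / self.sigma
        b = (self.hi - self.mu) / self.sigma
        if stats.truncnorm.sf(a, a, b) <= 0 or a >= b:
            raise ValueError("empty truncation mass")
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def pdf(self, x):
        return self._frozen().pdf(x)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def median(self):
        return float(self._frozen().median())


#: Gaussian fits to the four samples' size histograms (nm).
SAMPLE_DISTRIBUTIONS = {
    "#1": SizeDistribution(18.3, 9.5, lo=0.0, label="#1"),
    "#2": SizeDistribution(14.9, 8.5, lo=0.0, label="#2"),
    "#3": SizeDistribution(22.1, 15.7, lo=0.0, label="#3"),
    "#4": SizeDistribution(162.0, 95.0, lo=50.0, hi=275.0, label="#4"),
}


@dataclass
class GroundTruth:
    """True generating parameters recorded with every synthetic trace."""

    slp: float  # W/g
    ambient: AmbientLaw
    noise_sigma: float = 0.1  # degC
    seed: int = 0
    extras: dict = dfield(default_factory=dict)

    def as_dict(self) -> dict:
        return {"slp_W_per_g": self.slp, "noise_sigma_C": self.noise_sigma,
                "seed": self.seed,
                "ambient": {k: float(v) for k, v in vars(self.ambient).items()},
                **self.extras}


def sample_sizes(dist: SizeDistribution, n: int, seed: int) -> np.ndarray:
    """Deterministic truncated-normal size draws (nm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if dist.sigma < 1e-12:
        return np.full(n, dist.mu)
    rng = np.random.default_rng(seed)
    return dist._frozen().rvs(size=n, random_state=rng)


def make_trace(gt: GroundTruth, scene: ThermalScene | None = None,
               m_mnps_mg: float = 5.43, v_water_ml: float | None = None,
               Q_ext: float = 45e3, t_heat: float = 3900.0,
               t_cool: float = 3600.0, dt: float = 5.0,
               probe: str = "P4") -> ThermometryTrace:
    """Synthetic thermometry trace with known ground truth.

    Runs the conduction solver with Q_MNPs from the ground-truth SLP, samples
    the probe, adds iid Gaussian sensor noise and attaches the generating
    parameters for recovery scoring.  ``v_water_ml`` defaults to the scene's
    discretized suspension volume so the power bookkeeping is consistent.
    """
    if scene is None:
        scene = ThermalScene()
    if v_water_ml is None:
        v_water_ml = scene.suspension_volume_ml
    Q = q_mnps(gt.slp, m_mnps_mg, v_water_ml) * 1e3  # kW/m^3 -> W/m^3
    sources = HeatSources(Q_mnps=Q, Q_ext=Q_ext, t_off=t_heat)
    t = np.arange(0.0, t_heat + t_cool + dt / 2, dt)
    tr = solve_heat(scene, sources, t, T_ext=gt.ambient, probes=[probe])[probe]
    rng = np.random.default_rng(gt.seed)
    noisy = tr.T + rng.normal(0.0, gt.noise_sigma, size=tr.T.shape)
    return ThermometryTrace(
        t=tr.t, T=noisy, t_off=t_heat, probe=probe,
        ground_truth=gt.as_dict() | {"m_mnps_mg": m_mnps_mg,
                                     "v_water_ml": v_water_ml,
                                     "Q_ext_W_per_m3": Q_ext})


def make_ensemble_inputs(dist: SizeDistribution, n_sizes: int,
                         orientations: np.ndarray | str = "default",
                         seed: int = 0):
    """Stratified (size, orientation, weight) list for ensemble averaging.

    Sizes are the midpoints of ``n_sizes`` equal-width bins spanning the
    distribution's central mass (0.1th-99.9th percentile intersected with the
    truncation range); weights are the truncated-normal bin probabilities,
    renormalized, times equal orientation weights.  For ``n_sizes == 1`` the
    single size is the distribution median.

    Returns a list of (l_nm, direction, weight) with weights summing to 1.
    """
    if n_sizes < 1:
        raise ValueError("n_sizes must be >= 1")
    if isinstance(orientations, str):
        orientations = orientation_set()
    orientations = np.atleast_2d(np.asarray(orientations, float))
    if n_sizes == 1:
        sizes = np.array([dist.median()])
        wsize = np.array([1.0])
    else:
        fr = dist._frozen()
        lo = max(dist.lo, float(fr.ppf(0.001)))
        hi = min(dist.hi, float(fr.ppf(0.999)))
        edges = np.linspace(lo, hi, n_sizes + 1)
        sizes = 0.5 * (edges[:-1] + edges[1:])
        wsize = np.diff(fr.cdf(edges))
        wsize = wsize / wsize.sum()
    w_or = np.full(len(orientations), 1.0 / len(orientations))
    out = []
    for l, wl in zip(sizes, wsize):
        for d, wo in zip(orientations, w_or):
            out.append((float(l), d.copy(), float(wl * wo)))
    return out
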