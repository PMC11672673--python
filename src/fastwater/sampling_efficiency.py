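"""Autocorrelation and equilibrium statistics of collective-variable series.

The sampling efficiency of an MD run is governed by the integrated
autocorrelation time tau_int of the observables of interest: the
statistical error of a time average decays as
``sd * sqrt(2 tau_int / T)`` with simulation length T.  A solvent of
lower viscosity decorrelates solute collective variables faster, so
tau_int shrinks, while every equilibrium (configuration-space) statistic
is untouched because such averages are independent of particle masses.

Implemented here:

- linear and circular (dihedral) autocorrelation functions; the circular
  ACF is ``C(t) = <cos(theta(t0 + t) - theta(t0))>``, which decays to the
  squared circular resultant of the stationary distribution;
- tau_int with the Sokal automatic window and tau_exp from a log-linear
  fit of the slow ACF tail;
- the dihedral order parameter ``S_D^2 = <cos>^2 + <sin>^2``;
- block-average standard errors of the mean;
- histogram free-energy profiles ``G_i = -kB T ln p_i`` (1D and 2D);
- replica-resolved two-sample Kolmogorov-Smirnov comparisons, which
  sidestep the correlation problem of a naive KS test by building the
  null distribution of the statistic from within-group replica pairs;
- a weighted straight-line fit ``tau = a + b sqrt(m)`` whose intercept
  quantifies internal (solvent-independent) friction;
- an overdamped Langevin generator for dihedral dynamics on a periodic
  multi-well potential, with exactly known stationary density and a
  friction that scales as sqrt(mass scale) -- the synthetic embodiment
  of the mass-invariance/mass-scaling pair of properties the analyses
  are meant to detect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .constants import KB
from .errors import (
    DegenerateSeriesError,
    EmptyHistogramError,
    InsufficientDataError,
    IntegrationError,
    InvalidArgumentError,
    InvalidRangeError,
    TruncationWarning,
)

__all__ = [
    "CVSeries",
    "SeriesACF",
    "ACTEstimate",
    "FreeEnergyProfile",
    "FreeEnergySurface",
    "InternalFrictionFit",
    "KSComparison",
    "PeriodicPotential",
    "autocorrelation",
    "vdsb_dihedral_acf",
    "dihedral_order_parameter",
    "integrated_act",
    "exponential_act",
    "block_sem",
    "free_energy_profile",
    "free_energy_surface",
    "ks_replica_comparison",
    "internal_friction_fit",
    "generate_dihedral_series",
]


def wrap_degrees(angles: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angles, dtype=float), 360.0)


@dataclass(frozen=True)
class CVSeries:
    """A collective-variable time series.

    ``values`` are angles in degrees (``circular=True``, stored wrapped
    into (-180, 180]) or distances/other scalars; ``frame_dt`` is the
    sampling interval in ps.
    """

    values: np.ndarray
    frame_dt: float
    circular: bool = False
    replica_id: int | str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).ravel()
        if vals.size < 2:
            raise InvalidArgumentError("need at least 2 samples")
        if not self.frame_dt > 0:
            raise InvalidArgumentError("frame_dt must be > 0")
        if self.circular:
            vals = wrap_degrees(vals)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SeriesACF:
    """Normalized autocorrelation function over lags 0..max_lag."""

    lags: np.ndarray        # ps
    values: np.ndarray      # rho_0 = 1
    frame_dt: float
    n_samples: int
    kind: str = "linear"    # "linear" or "circular"


@dataclass(frozen=True)
class ACTEstimate:
    """Autocorrelation-time estimate (ps) with replica-based SE."""

    tau_int: float | None = None
    se_int: float | None = None
    tau_exp: float | None = None
    se_exp: float | None = None
    window_used: int | None = None
    fit_range: tuple[float, float] | None = None
    n_replicas: int = 1


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Binned free energies G_i = -kB T ln p_i over a collective variable."""

    centers: np.ndarray
    edges: np.ndarray
    probabilities: np.ndarray
    free_energies: np.ndarray   # kJ/mol, min = 0, empty bins NaN
    counts: np.ndarray
    temperature: float


@dataclass(frozen=True)
class FreeEnergySurface:
    """2D histogram free-energy map (e.g. over a Ramachandran grid)."""

    centers_x: np.ndarray
    centers_y: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray
    probabilities: np.ndarray
    free_energies: np.ndarray
    counts: np.ndarray
    temperature: float

    def difference(self, other: "FreeEnergySurface") -> np.ndarray:
        """G_self - G_other on shared bins (NaN where either is empty)."""
        if (self.edges_x.shape != other.edges_x.shape
                or not np.allclose(self.edges_x, other.edges_x)
                or not np.allclose(self.edges_y, other.edges_y)):
            raise InvalidArgumentError("surfaces must share bin edges")
        return self.free_energies - other.free_energies


@dataclass(frozen=True)
class InternalFrictionFit:
    """Fit tau = a + b sqrt(m_tot): intercept a = internal-friction floor."""

    a: float                 # ns (or the tau unit of the input)
    b: float                 # tau unit per sqrt(g/mol)
    se_a: float
    se_b: float
    cov: np.ndarray


@dataclass(frozen=True)
class KSComparison:
    """Replica-pair KS statistics within and between two groups."""

    within_a: np.ndarray
    within_b: np.ndarray
    between: np.ndarray
    locations_between: np.ndarray
    overlap_summary: float

    def as_dict(self) -> dict:
        return {
            "within_a_ks": self.within_a.tolist(),
            "within_b_ks": self.within_b.tolist(),
            "between_ks": self.between.tolist(),
            "between_max_distance_locations": self.locations_between.tolist(),
            "overlap_summary": self.overlap_summary,
        }


# ---------------------------------------------------------------------------
# autocorrelation


def _fft_autocovariance(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased per-lag autocovariance sum_k x_k x_{k+n} / (n_samples - n)."""
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    return acov / (n - np.arange(max_lag + 1))


def _resolve_max_lag(n: int, frame_dt: float, max_lag: float | None) -> int:
    if max_lag is None:
        return max(1, n // 4)
    steps = int(round(max_lag / frame_dt))
    if steps < 1 or steps >= n:
        raise InvalidArgumentError(
            f"max_lag must be within (0, series length); got {max_lag} ps")
    return steps


def autocorrelation(series: CVSeries, max_lag: float | None = None) -> SeriesACF:
    """Mean-subtracted, variance-normalized ACF of a linear series.

    Computed by FFT with unbiased per-lag normalization (divide by the
    number of contributing pairs).  ``max_lag`` in ps; default a quarter
    of the series.
    """
    if series.circular:
        raise InvalidArgumentError(
            "autocorrelation() is for linear series; use vdsb_dihedral_acf "
            "for circular ones")
    x = series.values - series.values.mean()
    var = np.mean(x**2)
    if var <= 0:
        raise DegenerateSeriesError("series has zero variance")
    steps = _resolve_max_lag(series.n, series.frame_dt, max_lag)
    acov = _fft_autocovariance(x, steps)
    rho = acov / acov[0]
    rho[0] = 1.0
    return SeriesACF(lags=np.arange(steps + 1) * series.frame_dt,
                     values=rho, frame_dt=series.frame_dt,
                     n_samples=series.n, kind="linear")


def vdsb_dihedral_acf(series: CVSeries, max_lag: float | None = None,
                      normalize: str = "none") -> SeriesACF:
    """Dihedral autocorrelation ``C(t) = <cos(theta(t0+t) - theta(t0))>``.

    Evaluated over all origins via FFT correlations of cos(theta) and
    sin(theta); C(0) = 1 identically.  With ``normalize="fluctuation"``
    the long-time plateau (the squared circular resultant) is subtracted
    and the ACF rescaled to decay from 1 toward 0, which makes it
    directly usable for integrated-time windows on series whose
    stationary distribution is anisotropic.
    """
    if not series.circular:
        raise InvalidArgumentError("vdsb_dihedral_acf requires a circular series")
    theta = np.radians(series.values)
    steps = _resolve_max_lag(series.n, series.frame_dt, max_lag)
    c_part = _fft_autocovariance(np.cos(theta), steps)
    s_part = _fft_autocovariance(np.sin(theta), steps)
    acf = c_part + s_part
    acf[0] = 1.0
    if normalize == "fluctuation":
        plateau = float(np.cos(theta).mean() ** 2 + np.sin(theta).mean() ** 2)
        if plateau >= 1.0 - 1e-12:
            raise DegenerateSeriesError("constant angle: no fluctuation to normalize")
        acf = (acf - plateau) / (1.0 - plateau)
    elif normalize != "none":
        raise InvalidArgumentError(f"unknown normalization {normalize!r}")
    return SeriesACF(lags=np.arange(steps + 1) * series.frame_dt,
                     values=acf, frame_dt=series.frame_dt,
                     n_samples=series.n, kind="circular")


def dihedral_order_parameter(series: CVSeries | np.ndarray) -> float:
    """Squared circular resultant ``S_D^2 = <cos theta>^2 + <sin theta>^2``.

    1 for a delta-like (fully ordered) dihedral distribution, 0 for a
    uniform or perfectly antipodal one.
    """
    if isinstance(series, CVSeries):
        if not series.circular:
            raise InvalidArgumentError("S_D^2 requires a circular series")
        values = series.values
    else:
        values = np.asarray(series, dtype=float).ravel()
        if values.size == 0:
            raise InvalidArgumentError("empty series")
    theta = np.radians(values)
    return float(np.cos(theta).mean() ** 2 + np.sin(theta).mean() ** 2)


# ---------------------------------------------------------------------------
# autocorrelation times


def _tau_int_single(rho: np.ndarray, frame_dt: float, window_rule: str,
                    c: float) -> tuple[float, int]:
    """Integrated time tau = dt*(1/2 + sum_{1..W} rho_k) with automatic W."""
    partial = 0.5 + np.cumsum(rho[1:])
    w_grid = np.arange(1, rho.size)
    if window_rule == "sokal":
        ok = w_grid >= c * np.maximum(partial, 1e-12)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            warnings.warn("Sokal window exceeds available lags; using all lags",
                          TruncationWarning, stacklevel=3)
            w = int(w_grid[-1])
        else:
            w = int(w_grid[idx[0]])
    elif window_rule == "first_negative":
        neg = np.flatnonzero(rho[1:] < 0)
        w = int(neg[0]) if neg.size else int(w_grid[-1])
        if neg.size == 0:
            warnings.warn("no negative ACF value within available lags",
                          TruncationWarning, stacklevel=3)
        w = max(w, 1)
    else:
        raise InvalidArgumentError(f"unknown window rule {window_rule!r}")
    tau = frame_dt * float(partial[w - 1])
    return tau, w


def integrated_act(acf: SeriesACF | Sequence[SeriesACF],
                   window_rule: str = "sokal", c: float = 5.0) -> ACTEstimate:
    """Integrated autocorrelation time with replica-based standard error.

    For a single ACF the Sokal rule picks the smallest window W with
    ``W >= c * tau_int(W)/dt`` (default c = 5).  For a sequence of
    replica ACFs, tau_int is the mean of per-replica estimates and the
    SE their standard deviation over sqrt(n_replicas).
    """
    acfs = [acf] if isinstance(acf, SeriesACF) else list(acf)
    if not acfs:
        raise InsufficientDataError("need at least one ACF")
    dts = {a.frame_dt for a in acfs}
    if len(dts) != 1:
        raise InvalidArgumentError("replicas must share frame_dt")
    taus, windows = zip(*(_tau_int_single(a.values, a.frame_dt, window_rule, c)
                          for a in acfs))
    tau = float(np.mean(taus))
    se = (float(np.std(taus, ddof=1) / math.sqrt(len(taus)))
          if len(taus) > 1 else None)
    return ACTEstimate(tau_int=tau, se_int=se,
                       window_used=int(max(windows)), n_replicas=len(acfs))


def exponential_act(acf: SeriesACF,
                    fit_range: tuple[float, float] | None = None) -> ACTEstimate:
    """Exponential relaxation time from a log-linear fit of the ACF tail.

    Fits ``ln C(t) = const - t/tau_exp`` over ``fit_range`` (ps).  The
    default range covers the lags where C lies in [0.05, 0.5], a regime
    that is reasonably linear in log space for the slowest process.
    """
    lags, vals = acf.lags, acf.values
    if fit_range is None:
        in_band = (vals <= 0.5) & (vals >= 0.05)
        idx = np.flatnonzero(in_band)
        if idx.size < 3:
            raise InsufficientDataError(
                "no usable auto range: fewer than 3 lags with C in [0.05, 0.5]")
        sel = np.arange(idx[0], idx[-1] + 1)
        if np.any(vals[sel] <= 0):
            sel = sel[: np.flatnonzero(vals[sel] <= 0)[0]]
        fit_range = (float(lags[sel[0]]), float(lags[sel[-1]]))
    else:
        sel = np.flatnonzero((lags >= fit_range[0]) & (lags <= fit_range[1]))
    if sel.size < 2:
        raise InsufficientDataError("fit range contains fewer than 2 lags")
    if np.any(vals[sel] <= 0):
        raise InvalidRangeError("ACF must be positive over the fit range")
    res = stats.linregress(lags[sel], np.log(vals[sel]))
    if res.slope >= 0:
        raise InvalidRangeError("ACF does not decay over the fit range")
    tau = -1.0 / res.slope
    se = res.stderr * tau**2 if res.stderr is not None else math.nan
    return ACTEstimate(tau_exp=float(tau), se_exp=float(se),
                       fit_range=fit_range)


def block_sem(series: CVSeries | np.ndarray,
              min_blocks: int = 32) -> float:
    """Standard error of the mean by block averaging.

    Block sizes grow geometrically (powers of two) while at least
    ``min_blocks`` blocks remain; the SEM curve rises from the naive
    iid value to a plateau once blocks exceed the correlation time.
    The estimate is the mean SEM over the detected plateau (consecutive
    block sizes whose SEM changed by < 5%), or the largest-block value
    if no plateau is detected.
    """
    values = series.values if isinstance(series, CVSeries) else (
        np.asarray(series, dtype=float).ravel())
    n = values.size
    if n < 16:
        raise InsufficientDataError("need at least 16 samples for block SEM")
    if np.ptp(values) == 0:
        return 0.0
    sems = []
    size = 1
    while n // size >= max(min_blocks, 2):
        nb = n // size
        means = values[: nb * size].reshape(nb, size).mean(axis=1)
        sems.append(float(np.std(means, ddof=1) / math.sqrt(nb)))
        size *= 2
    sems_arr = np.array(sems)
    if sems_arr.size == 1:
        return float(sems_arr[0])
    growth = np.diff(sems_arr) / sems_arr[:-1]
    flat = np.flatnonzero(growth < 0.05)
    if flat.size == 0:
        return float(sems_arr[-1])
    start = int(flat[0])
    return float(sems_arr[start:].mean())


# ---------------------------------------------------------------------------
# equilibrium distributions


def _default_edges(values: np.ndarray, circular: bool) -> np.ndarray:
    if circular:
        return np.linspace(-180.0, 180.0, 73)  # 5 degree bins
    return np.histogram_bin_edges(values, bins="fd")


def free_energy_profile(series: CVSeries | np.ndarray,
                        bin_edges: np.ndarray | None = None,
                        temperature: float = 310.0) -> FreeEnergyProfile:
    """Histogram free energies ``G_i = -kB T ln p_i``, minimum shifted to 0.

    Empty bins are masked with NaN rather than assigned infinite or zero
    free energy.  Default bins: 72 x 5-degree bins for circular series,
    Freedman-Diaconis for distances.
    """
    if isinstance(series, CVSeries):
        values, circular = series.values, series.circular
    else:
        values = np.asarray(series, dtype=float).ravel()
        circular = False
    if not temperature > 0:
        raise InvalidArgumentError("temperature must be > 0")
    edges = (_default_edges(values, circular) if bin_edges is None
             else np.asarray(bin_edges, dtype=float))
    counts, edges = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        raise EmptyHistogramError("all samples fall outside the bins")
    p = counts / total
    with np.errstate(divide="ignore"):
        g = -KB * temperature * np.log(p)
    g[counts == 0] = np.nan
    g -= np.nanmin(g)
    return FreeEnergyProfile(
        centers=0.5 * (edges[:-1] + edges[1:]), edges=edges,
        probabilities=p, free_energies=g, counts=counts,
        temperature=temperature)


def free_energy_surface(x: np.ndarray, y: np.ndarray,
                        bin_edges_x: np.ndarray, bin_edges_y: np.ndarray,
                        temperature: float = 310.0) -> FreeEnergySurface:
    """2D histogram free-energy map over two collective variables."""
    if not temperature > 0:
        raise InvalidArgumentError("temperature must be > 0")
    counts, ex, ey = np.histogram2d(np.ravel(x), np.ravel(y),
                                    bins=[bin_edges_x, bin_edges_y])
    total = counts.sum()
    if total == 0:
        raise EmptyHistogramError("all samples fall outside the bins")
    p = counts / total
    with np.errstate(divide="ignore"):
        g = -KB * temperature * np.log(p)
    g[counts == 0] = np.nan
    g -= np.nanmin(g)
    return FreeEnergySurface(
        centers_x=0.5 * (ex[:-1] + ex[1:]), centers_y=0.5 * (ey[:-1] + ey[1:]),
        edges_x=ex, edges_y=ey, probabilities=p, free_energies=g,
        counts=counts, temperature=temperature)


# ---------------------------------------------------------------------------
# replica comparison


def _series_values(obj: CVSeries | np.ndarray) -> np.ndarray:
    return obj.values if isinstance(obj, CVSeries) else (
        np.asarray(obj, dtype=float).ravel())


def ks_replica_comparison(group_a: Sequence[CVSeries | np.ndarray],
                          group_b: Sequence[CVSeries | np.ndarray],
                          ) -> KSComparison:
    """Two-sample KS statistics across and within two groups of replicas.

    Correlated MD samples invalidate the KS test's nominal p-values, so
    instead of testing any single pair, the distribution of the statistic
    itself is assembled: every unordered within-group pair and every
    cross-group pair.  If the two groups sample the same equilibrium
    distribution, the between-group values are statistically exchangeable
    with the within-group ones.  ``overlap_summary`` is the fraction of
    between-group statistics below the 95th percentile of the pooled
    within-group values (near 1 under the null, near 0 under a clear
    shift).
    """
    a_vals = [_series_values(s) for s in group_a]
    b_vals = [_series_values(s) for s in group_b]
    if len(a_vals) < 2 or len(b_vals) < 2:
        raise InsufficientDataError("need >= 2 replicas per group")

    def pair_stats(pairs: Iterable[tuple[np.ndarray, np.ndarray]]
                   ) -> tuple[np.ndarray, np.ndarray]:
        ks, loc = [], []
        for u, v in pairs:
            res = stats.ks_2samp(u, v)
            ks.append(res.statistic)
            loc.append(res.statistic_location)
        return np.array(ks), np.array(loc)

    within_a, _ = pair_stats(combinations(a_vals, 2))
    within_b, _ = pair_stats(combinations(b_vals, 2))
    between, loc_between = pair_stats(product(a_vals, b_vals))
    within_pool = np.concatenate([within_a, within_b])
    threshold = np.quantile(within_pool, 0.95)
    overlap = float(np.mean(between <= threshold))
    return KSComparison(within_a=within_a, within_b=within_b,
                        between=between, locations_between=loc_between,
                        overlap_summary=overlap)


# ---------------------------------------------------------------------------
# internal friction


def internal_friction_fit(points: Sequence[tuple[float, float, float | None]],
                          ) -> InternalFrictionFit:
    """Weighted straight-line fit ``tau = a + b sqrt(m_tot)``.

    ``points`` are (m_tot, tau, se) triples; the intercept ``a`` is the
    relaxation-time floor surviving extrapolation to zero solvent mass
    (internal plus thermostat friction), ``b`` measures solvent friction.
    With stated SEs the parameter covariance is the unscaled
    inverse-information matrix; without, residual-scaled OLS errors.
    """
    if len(points) < 2:
        raise InsufficientDataError("need >= 2 points")
    m = np.array([p[0] for p in points], dtype=float)
    tau = np.array([p[1] for p in points], dtype=float)
    if np.unique(m).size < 2:
        raise InsufficientDataError("need >= 2 distinct masses")
    ses = [p[2] for p in points]
    have_se = all(s is not None and s > 0 for s in ses)
    w = (np.array([1.0 / s**2 for s in ses]) if have_se
         else np.ones_like(m))
    x_mat = np.column_stack([np.ones_like(m), np.sqrt(m)])
    xtw = x_mat.T * w
    cov = np.linalg.inv(xtw @ x_mat)
    beta = cov @ (xtw @ tau)
    if not have_se:
        resid = tau - x_mat @ beta
        dof = max(len(m) - 2, 1)
        cov = cov * float(resid @ (w * resid)) / dof
    return InternalFrictionFit(a=float(beta[0]), b=float(beta[1]),
                               se_a=float(np.sqrt(cov[0, 0])),
                               se_b=float(np.sqrt(cov[1, 1])), cov=cov)


# ---------------------------------------------------------------------------
# Langevin dihedral generator


@dataclass(frozen=True)
class PeriodicPotential:
    """Periodic multi-well potential ``U(theta) = sum_j k_j cos(j theta - d_j)``.

    ``terms`` are (amplitude kJ/mol, integer multiplicity, phase degrees).
    The default is a symmetric double well with minima at +-90 degrees
    and a barrier of twice the amplitude.
    """

    terms: tuple[tuple[float, int, float], ...] = ((2.0, 2, 0.0),)

    def energy(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        u = np.zeros_like(theta)
        for amp, mult, phase in self.terms:
            u += amp * np.cos(mult * theta - math.radians(phase))
        return u

    def force(self, theta: np.ndarray) -> np.ndarray:
        """-dU/dtheta (kJ/mol per rad)."""
        theta = np.asarray(theta, dtype=float)
        f = np.zeros_like(theta)
        for amp, mult, phase in self.terms:
            f += amp * mult * np.sin(mult * theta - math.radians(phase))
        return f

    @property
    def max_curvature(self) -> float:
        return sum(abs(amp) * mult**2 for amp, mult, _ in self.terms)

    def stationary_cdf(self, temperature: float,
                       n_grid: int = 20001) -> tuple[np.ndarray, np.ndarray]:
        """Grid (theta_deg, CDF) of the Boltzmann density exp(-U/kB T)."""
        theta = np.linspace(-math.pi, math.pi, n_grid)
        dens = np.exp(-self.energy(theta) / (KB * temperature))
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(theta))])
        cdf /= cdf[-1]
        return np.degrees(theta), cdf


def _sample_stationary(potential: PeriodicPotential, temperature: float,
                       size: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample theta (rad) from the Boltzmann density."""
    beta = 1.0 / (KB * temperature)
    u_min = potential.energy(np.linspace(-math.pi, math.pi, 4096)).min()
    out = np.empty(size)
    filled = 0
    while filled < size:
        n_try = 2 * (size - filled) + 16
        theta = rng.uniform(-math.pi, math.pi, n_try)
        accept = rng.uniform(size=n_try) < np.exp(
            -beta * (potential.energy(theta) - u_min))
        take = theta[accept][: size - filled]
        out[filled: filled + take.size] = take
        filled += take.size
    return out


def generate_dihedral_series(potential: PeriodicPotential | None = None,
                             friction: float = 2.0,
                             mass_scale: float = 1.0,
                             temperature: float = 310.0,
                             dt: float = 0.01,
                             n_steps: int = 100_000,
                             seed: int | np.random.Generator | None = None,
                             n_replicas: int = 1,
                             floor_friction: float = 0.0,
                             ) -> list[CVSeries]:
    """Overdamped Langevin dynamics of a dihedral on a periodic potential.

    Integrates ``gamma_eff dtheta = -U'(theta) dt + sqrt(2 kB T gamma_eff) dW``
    with effective friction ``gamma_eff = floor_friction +
    friction * sqrt(mass_scale)`` (kJ/mol ps rad^-2), using the
    Leimkuhler-Matthews discretization (the Gaussian increment is the
    average of two consecutive unit normals), whose invariant measure is
    accurate to second order in dt -- so runs at different frictions but
    a common dt sample statistically indistinguishable stationary
    distributions.  The stationary density is the Boltzmann density of U
    regardless of friction -- the discrete-time embodiment of
    mass-independence of configuration-space averages -- while all
    relaxation times are proportional to gamma_eff, i.e. scale as
    sqrt(mass) when ``floor_friction = 0``.  Initial angles are
    rejection-sampled from the exact stationary density, so the output is
    stationary from the first frame.

    ``dt`` is in ps; stability requires ``dt <= 0.1 gamma_eff / max|U''|``
    (enforced).  Returns ``n_replicas`` independent :class:`CVSeries` in
    degrees with ``frame_dt = dt``.
    """
    potential = potential or PeriodicPotential()
    if friction <= 0 or floor_friction < 0:
        raise InvalidArgumentError("friction must be > 0, floor_friction >= 0")
    if mass_scale <= 0 or temperature <= 0 or n_steps < 2 or n_replicas < 1:
        raise InvalidArgumentError("invalid generator parameters")
    gamma = floor_friction + friction * math.sqrt(mass_scale)
    max_curv = potential.max_curvature
    if max_curv > 0 and dt > 0.1 * gamma / max_curv:
        raise IntegrationError(
            f"dt = {dt} ps exceeds the stability bound "
            f"0.1 * gamma_eff / max|U''| = {0.1 * gamma / max_curv:.4g} ps")
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    noise_amp = math.sqrt(2.0 * kt * dt / gamma)
    theta = _sample_stationary(potential, temperature, n_replicas, rng)
    out = np.empty((n_steps, n_replicas))
    out[0] = theta
    xi_prev = rng.standard_normal(n_replicas)
    for k in range(1, n_steps):
        xi = rng.standard_normal(n_replicas)
        theta = theta + (potential.force(theta) / gamma) * dt \
            + noise_amp * 0.5 * (xi_prev + xi)
        xi_prev = xi
        out[k] = theta
    out_deg = wrap_degrees(np.degrees(out))
    return [CVSeries(values=out_deg[:, r], frame_dt=dt, circular=True,
                     replica_id=r) for r in range(n_replicas)]
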