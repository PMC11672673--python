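"""Poisson crash-rate estimation and its mass dependence.

Catastrophic integration failures ("crashes") in MD are modelled as a
Poisson process: waiting times to a crash are exponential with rate
``k_crash``.  A batch of replicas therefore yields a censored-exponential
sample: each replica either crashed at time ``t_i`` or ended intact at
``t_i``.  The maximum-likelihood rate is ``k = n_crash / sum(t_i)`` (the
sum running over crashed *and* censored replicas), with Cramer-Rao
standard error ``k / sqrt(n_crash)``.

At fixed repartitioning and time step, the crash rate decreases
approximately exponentially with the total molecular mass,
``ln k = ln A - c * m_tot``.  Fitting this in log space over a grid of
masses and inverting at a target rate gives the iso-stability contour
``m_tot(m_r)`` used to select the fastest-diffusing stable model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, NoSolutionError

__all__ = [
    "CrashRecord",
    "CrashRateEstimate",
    "ExpMassModel",
    "estimate_crash_rate",
    "simulate_crash_records",
    "fit_exp_mass_model",
    "iso_crash_mass",
]

#: -ln(0.05): 95% upper bound on k when no crash was observed.
_UPPER95_FACTOR = math.log(20.0)


@dataclass(frozen=True)
class CrashRecord:
    """Outcome of one replica: end time (ns) and whether it crashed there."""

    t: float
    crashed: bool

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise InvalidArgumentError(f"record time must be > 0, got {self.t!r}")


@dataclass(frozen=True)
class CrashRateEstimate:
    """ML crash-rate estimate.

    Rates are per ns, or per (ns x 1000 molecules) when ``n_molecules``
    was supplied.  ``se`` is None when no crash was observed; then
    ``upper95`` carries the one-sided 95% bound instead.
    """

    k_hat: float
    se: float | None
    n: int
    n_crash: int
    total_time: float
    n_molecules: int | None = None
    upper95: float | None = None

    @property
    def normalized(self) -> bool:
        return self.n_molecules is not None

    def as_dict(self) -> dict:
        unit = ("per_ns_per_1000_molecules" if self.normalized else "per_ns")
        return {
            f"k_hat_{unit}": self.k_hat,
            f"se_{unit}": self.se,
            f"upper95_{unit}": self.upper95,
            "n_replicas": self.n,
            "n_crash": self.n_crash,
            "total_time_ns": self.total_time,
            "n_molecules": self.n_molecules,
        }


@dataclass(frozen=True)
class ExpMassModel:
    """Exponential mass dependence ``ln k = ln_A - c * m_tot`` at fixed m_r."""

    ln_A: float
    c: float
    m_r: float
    cov: np.ndarray  # 2x2 covariance of (ln_A, c)

    def predict_ln_k(self, m_tot: float) -> float:
        return self.ln_A - self.c * m_tot


def estimate_crash_rate(records: Iterable[CrashRecord],
                        n_molecules: int | None = None) -> CrashRateEstimate:
    """ML crash rate from censored replica outcomes.

    ``k = n_crash / sum(t_i)``; the censored end times enter the
    denominator exactly like crash times.  With ``n_molecules`` given,
    rate and error are normalised to per (ns x 1000 molecules).
    """
    records = list(records)
    if not records:
        raise InvalidArgumentError("need at least one crash record")
    total_time = sum(r.t for r in records)
    n_crash = sum(r.crashed for r in records)
    scale = 1.0 if n_molecules is None else 1000.0 / n_molecules
    k_hat = n_crash / total_time
    if n_crash > 0:
        se = k_hat / math.sqrt(n_crash)
        upper95 = None
    else:
        se = None
        upper95 = _UPPER95_FACTOR / total_time * scale
    return CrashRateEstimate(
        k_hat=k_hat * scale,
        se=None if se is None else se * scale,
        n=len(records),
        n_crash=n_crash,
        total_time=total_time,
        n_molecules=n_molecules,
        upper95=upper95,
    )


def simulate_crash_records(k_true: float, n: int, t_end: float,
                           seed: int | np.random.Generator | None = None,
                           ) -> list[CrashRecord]:
    """Draw ``n`` censored exponential waiting times at rate ``k_true`` (per ns).

    Each replica crashes at its exponential waiting time if that falls
    before ``t_end``, otherwise it is censored at ``t_end``.
    """
    if k_true < 0:
        raise InvalidArgumentError("k_true must be >= 0")
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not t_end > 0:
        raise InvalidArgumentError("t_end must be > 0")
    rng = np.random.default_rng(seed)
    if k_true == 0.0:
        return [CrashRecord(t_end, False) for _ in range(n)]
    waits = rng.exponential(1.0 / k_true, size=n)
    return [CrashRecord(float(w), True) if w < t_end
            else CrashRecord(t_end, False) for w in waits]


def fit_exp_mass_model(points: Sequence[tuple[float, CrashRateEstimate]],
                       m_r: float = math.nan) -> ExpMassModel:
    """Weighted least-squares fit of ``ln k`` versus total mass.

    Weights follow from error propagation of the rate SE into log space,
    ``sigma_ln_k = se / k_hat`` (equal to ``1/sqrt(n_crash)``).  Points
    with ``k_hat = 0`` carry no log-space information and are dropped
    with a warning.
    """
    usable = [(m, est) for m, est in points if est.k_hat > 0]
    dropped = len(points) - len(usable)
    if dropped:
        warnings.warn(f"excluded {dropped} zero-rate point(s) from the "
                      "exponential mass fit", stacklevel=2)
    if len(usable) < 2:
        raise InsufficientDataError(
            "need at least 2 points with k_hat > 0 to fit the mass model")
    m = np.array([p[0] for p in usable])
    y = np.log([p[1].k_hat for p in usable])
    sigma = np.array([
        (est.se / est.k_hat) if est.se else 1.0 for _, est in usable])
    w = 1.0 / sigma**2
    # design: ln k = ln_A + (-c) * m
    x_mat = np.column_stack([np.ones_like(m), m])
    xtw = x_mat.T * w
    normal = xtw @ x_mat
    try:
        cov = np.linalg.inv(normal)
    except np.linalg.LinAlgError as exc:
        raise InsufficientDataError("singular design (identical masses?)") from exc
    beta = cov @ (xtw @ y)
    ln_a, slope = float(beta[0]), float(beta[1])
    # reorder covariance for (ln_A, c) with c = -slope
    cov_out = np.array([[cov[0, 0], -cov[0, 1]],
                        [-cov[1, 0], cov[1, 1]]])
    return ExpMassModel(ln_A=ln_a, c=-slope, m_r=m_r, cov=cov_out)


def iso_crash_mass(model: ExpMassModel, k_target: float) -> float:
    """Total mass at which the fitted model reaches ``k_target``.

    Inverts ``ln k = ln_A - c m`` to ``m = (ln_A - ln k_target)/c``.
    A family of these over several repartitionings traces an
    iso-stability contour in the (m_r, m_tot) plane.
    """
    if not k_target > 0:
        raise InvalidArgumentError("k_target must be > 0")
    # numerically flat fits leave c at float-residue level; treat as c = 0
    if abs(model.c) < 1e-12:
        raise NoSolutionError("flat mass dependence (c = 0): no iso-rate mass")
    return (model.ln_A - math.log(k_target)) / model.c
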