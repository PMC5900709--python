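"""Shared harmonic-regression primitives for 24-h rhythmicity analysis.

Two entry points are provided:

* :func:`fourier_coefficient` — the (optionally weighted) complex 24-h
  Fourier coefficient of a set of values at arbitrary timepoints.  For a
  pure cosine ``cos(2*pi*(t - t0)/period)`` sampled at equispaced
  timepoints covering one period, the returned amplitude is exactly 1
  and the returned phase is exactly ``t0``.
* :func:`cosinor_test` — ordinary least-squares harmonic regression
  (intercept + cosine + sine) with an F-test against the flat model,
  used for unweighted track/expression rhythmicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "HarmonicFit",
    "fourier_coefficient",
    "phase_of",
    "cosinor_test",
    "circular_phase_difference",
]

DEFAULT_PERIOD = 24.0


@dataclass(frozen=True)
class HarmonicFit:
    """Result of a harmonic regression at a fixed period."""

    amplitude: float
    phase: float  # hours in [0, period)
    pvalue: float
    mesor: float  # fitted mean level
    period: float = DEFAULT_PERIOD

    @property
    def coefficient(self) -> complex:
        """Complex Fourier coefficient; ``phase = -arg/omega mod period``."""
        omega = 2.0 * np.pi / self.period
        return self.amplitude * np.exp(-1j * omega * self.phase)


def fourier_coefficient(
    times: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray | None = None,
    period: float = DEFAULT_PERIOD,
) -> complex:
    """Weighted complex Fourier coefficient at ``period``.

    Computes ``F = (2 / sum(u)) * sum_j u_j * y_j * exp(-i*omega*t_j)``
    with ``u_j`` the weights (uniform by default).  ``|F|`` is the
    cosine amplitude and ``phase_of(F)`` the peak time of the fitted
    cosine for equispaced full-period sampling.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if weights is None:
        u = np.ones_like(times)
    else:
        u = np.asarray(weights, dtype=float)
        if np.any(u < 0):
            raise ValueError("weights must be non-negative")
    usum = u.sum()
    if usum <= 0:
        raise ValueError("at least one positive weight required")
    omega = 2.0 * np.pi / period
    return complex(2.0 / usum * np.sum(u * values * np.exp(-1j * omega * times)))


def phase_of(coefficient: complex, period: float = DEFAULT_PERIOD) -> float:
    """Peak time (hours in ``[0, period)``) encoded by a Fourier coefficient."""
    omega = 2.0 * np.pi / period
    return float((-np.angle(coefficient) / omega) % period)


def cosinor_test(
    times: np.ndarray,
    values: np.ndarray,
    period: float = DEFAULT_PERIOD,
) -> HarmonicFit:
    """Unweighted harmonic regression with an F-test for rhythmicity.

    Fits ``y ~ m + bc*cos(omega*t) + bs*sin(omega*t)`` by OLS and tests
    ``bc = bs = 0`` with an F(2, n-3) statistic.  Replicated timepoints
    are supported (each observation enters individually).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = times.size
    if n < 4:
        raise ValueError("need at least 4 observations for a cosinor fit")
    omega = 2.0 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(omega * times), np.sin(omega * times)])
    beta, _, rank, _ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    rss = float(resid @ resid)
    flat = values - values.mean()
    tss = float(flat @ flat)
    dof = n - 3
    amplitude = float(np.hypot(beta[1], beta[2]))
    phase = float((np.arctan2(beta[2], beta[1]) / omega) % period)
    if dof <= 0 or rank < 3:
        pvalue = 1.0
    elif rss <= 0:
        # perfect fit: rhythmic iff any harmonic signal present
        pvalue = 0.0 if tss > rss + 1e-300 else 1.0
    else:
        fstat = ((tss - rss) / 2.0) / (rss / dof)
        pvalue = float(stats.f.sf(fstat, 2, dof))
    if amplitude == 0.0:
        pvalue = 1.0
    return HarmonicFit(
        amplitude=amplitude,
        phase=phase,
        pvalue=pvalue,
        mesor=float(beta[0]),
        period=period,
    )


def circular_phase_difference(
    phase_a: float | np.ndarray,
    phase_b: float | np.ndarray,
    period: float = DEFAULT_PERIOD,
) -> float | np.ndarray:
    """Signed circular difference ``a - b`` mapped to ``(-period/2, period/2]``.

    Antisymmetric: ``diff(a, b) == -diff(b, a)`` (mod period) except at
    the branch point ``period/2``.
    """
    d = (np.asarray(phase_a, dtype=float) - np.asarray(phase_b, dtype=float)) % period
    d = np.where(d > period / 2.0, d - period, d)
    if np.ndim(d) == 0:
        return float(d)
    return d
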