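"""FRAP recovery kinetics: exponential-association fits and diffusion coefficients.

The recovery of fluorescence into a bleached region is modeled as an
exponential association

    I(t) = f0 + (plateau - f0) * (1 - exp(-k t)),

with the post-bleach floor f0, the asymptote, and the rate k (1/s) all
fitted; the recovery half-time is t_half = ln 2 / k. The half-time converts
to an effective diffusion coefficient after Axelrod et al. (1976) for a
uniform circular beam,

    D = gamma * w^2 / (4 * t_half),

with beam factor gamma = 0.88 and effective radius w. A square bleach
region of side L maps to the equal-area circle, w = L / sqrt(pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, ParameterError

GAMMA_UNIFORM_CIRCLE = 0.88


@dataclass
class FRAPTrace:
    """A post-bleach time-intensity series; t = 0 at the first sample."""

    t: np.ndarray          # seconds, strictly increasing
    intensity: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.t.shape != self.intensity.shape:
            raise ParameterError("t and intensity lengths differ")
        if len(self.t) < 4:
            raise ParameterError("a trace needs >= 4 samples")
        if not (np.diff(self.t) > 0).all():
            raise ParameterError("t must be strictly increasing")


@dataclass
class FRAPFit:
    """Fitted recovery parameters; ``half_time`` = ln2/k when converged."""

    f0: float
    plateau: float
    k: float
    half_time: float
    covariance: np.ndarray | None
    converged: bool
    message: str = ""


@dataclass
class BleachGeometry:
    """Bleach-spot geometry for the diffusion-coefficient conversion.

    ``size`` is the radius (circle) or side length (square) in µm; squares
    map to the equal-area circle, w = size / sqrt(pi).
    """

    shape: Literal["circle", "square"] = "square"
    size: float = 5.0
    gamma: float = GAMMA_UNIFORM_CIRCLE

    def __post_init__(self) -> None:
        if self.size <= 0 or self.gamma <= 0:
            raise ParameterError("size and gamma must be positive")
        if self.shape not in ("circle", "square"):
            raise ParameterError(f"unknown bleach shape {self.shape!r}")

    @property
    def effective_radius(self) -> float:
        return self.size if self.shape == "circle" else self.size / math.sqrt(math.pi)


def recovery_model(t: np.ndarray, f0: float, plateau: float, k: float) -> np.ndarray:
    return f0 + (plateau - f0) * (1.0 - np.exp(-k * np.asarray(t, float)))


def _initial_guess(trace: FRAPTrace) -> tuple[float, float, float]:
    f0 = float(trace.intensity[0])
    plateau = float(trace.intensity[-1])
    half = f0 + 0.5 * (plateau - f0)
    crossing = np.flatnonzero(trace.intensity >= half) if plateau > f0 else np.array([])
    t_half = (
        float(trace.t[crossing[0]])
        if len(crossing) and trace.t[crossing[0]] > 0
        else float(trace.t[len(trace.t) // 2])
    )
    k0 = 1.0 / t_half if t_half > 0 else 1.0
    return f0, plateau, k0


def fit_recovery(trace: FRAPTrace) -> FRAPFit:
    """Least-squares fit of the exponential association to one trace.

    A flat trace (no recovery span) leaves the rate unidentifiable and is
    reported as a non-converged fit rather than a silent default; the same
    holds for a non-positive fitted rate or a solver failure.
    """
    span = float(trace.intensity.max() - trace.intensity.min())
    if span == 0.0:
        return FRAPFit(
            f0=float(trace.intensity[0]),
            plateau=float(trace.intensity[0]),
            k=float("nan"),
            half_time=float("nan"),
            covariance=None,
            converged=False,
            message="flat trace: recovery rate unidentifiable",
        )
    p0 = _initial_guess(trace)
    try:
        popt, pcov = curve_fit(
            recovery_model,
            trace.t,
            trace.intensity,
            p0=p0,
            xtol=1e-8,
            maxfev=500 * 4,
        )
    except RuntimeError as exc:
        return FRAPFit(*p0, float("nan"), None, False, f"solver failure: {exc}")
    f0, plateau, k = map(float, popt)
    if k <= 0 or not np.isfinite(k):
        return FRAPFit(
            f0, plateau, k, float("nan"), pcov, False, f"non-positive rate k={k:g}"
        )
    return FRAPFit(f0, plateau, k, math.log(2.0) / k, pcov, True)


def diffusion_coefficient(fit: FRAPFit, geom: BleachGeometry) -> float:
    """Effective D (µm²/s) from a converged fit: gamma * w² / (4 * t_half)."""
    if not fit.converged:
        raise DomainError("cannot derive D from a non-converged fit")
    if not (fit.half_time > 0):
        raise DomainError("half_time must be positive")
    w = geom.effective_radius
    return geom.gamma * w * w / (4.0 * fit.half_time)


def normalize_trace(raw: FRAPTrace, prebleach: float) -> FRAPTrace:
    """Divide intensities by the mean pre-bleach level; re-zero time."""
    if prebleach <= 0:
        raise DomainError("prebleach intensity must be positive")
    return FRAPTrace(raw.t - raw.t[0], raw.intensity / prebleach)


def k_confidence_interval(fit: FRAPFit, level: float = 0.95) -> tuple[float, float]:
    """Wald CI for the rate from the fit covariance."""
    from scipy.stats import norm

    if not fit.converged or fit.covariance is None:
        raise DomainError("no covariance available")
    se = math.sqrt(float(fit.covariance[2, 2]))
    z = norm.ppf(0.5 + level / 2.0)
    return fit.k - z * se, fit.k + z * se
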