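"""CDF area metric validation of moment-rotation response distributions.

Experimental specimens and probabilistic model runs each yield a rotation
(degrees) at every applied moment level (Nm).  At each level the two
samples are summarized by empirical CDFs and their disagreement is the
area between the CDFs — the exact integral of |F_exp − F_model| over the
real line, which for step functions is a finite sum over merged
breakpoints and equals the 1-Wasserstein distance between the empirical
distributions.  The raw area has units of degrees; dividing by the mean
experimental rotation at that level gives a dimensionless value
comparable across load levels.  The metric is zero iff the CDFs coincide
and grows without bound as agreement worsens; no universal "acceptable"
threshold is asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MomentRotationResponse",
    "EmpiricalCDF",
    "AreaMetricResult",
    "LOADING_MODES",
    "MOMENT_LEVELS_NM",
    "response_at_moment",
    "ecdf",
    "area_metric",
    "normalized_area_metric",
    "envelope",
]

LOADING_MODES = ("flexion_extension", "axial_rotation", "lateral_bending")

#: applied moment magnitudes (Nm) at which responses are evaluated
MOMENT_LEVELS_NM = (0.33, 0.5, 1.0, 1.5, 2.0)


@dataclass
class MomentRotationResponse:
    """One loading sweep: signed applied moments (Nm) vs rotations (degrees).

    Flexion / left-direction rotations are positive, extension / right
    negative.  Moments must be strictly monotone so interpolation is
    well defined.
    """

    moments: np.ndarray
    rotations: np.ndarray
    mode: str = "flexion_extension"
    source: str = "model_sample"

    def __post_init__(self) -> None:
        self.moments = np.asarray(self.moments, float)
        self.rotations = np.asarray(self.rotations, float)
        if self.moments.shape != self.rotations.shape or self.moments.ndim != 1:
            raise ValueError("moments and rotations must be equal-length 1D arrays")
        if len(self.moments) < 2:
            raise ValueError("need at least two recorded points")
        d = np.diff(self.moments)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("moments must be strictly monotone")
        if self.mode not in LOADING_MODES:
            raise ValueError(f"unknown loading mode {self.mode!r}")
        if self.source not in ("experiment", "model_sample"):
            raise ValueError(f"unknown source {self.source!r}")


def response_at_moment(response: MomentRotationResponse, moment: float) -> float:
    """Rotation at an applied moment, by linear interpolation (no extrapolation)."""
    m, r = response.moments, response.rotations
    if m[0] > m[-1]:
        m, r = m[::-1], r[::-1]
    if not m[0] <= moment <= m[-1]:
        raise ValueError(
            f"moment {moment} Nm outside recorded range [{m[0]}, {m[-1]}]"
        )
    return float(np.interp(moment, m, r))


@dataclass
class EmpiricalCDF:
    """Right-continuous empirical CDF: F(x) = (#values ≤ x) / n, ties stacked."""

    sorted_values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.sorted_values = np.asarray(self.sorted_values, float)
        if self.sorted_values.ndim != 1 or len(self.sorted_values) != self.n:
            raise ValueError("sorted_values must be 1D of length n")
        if self.n < 1:
            raise ValueError("empirical CDF needs at least one value")
        if np.any(np.diff(self.sorted_values) < 0):
            raise ValueError("values must be ascending")

    def __call__(self, x) -> np.ndarray | float:
        out = np.searchsorted(self.sorted_values, np.asarray(x, float), side="right") / self.n
        return float(out) if np.isscalar(x) else out


def ecdf(values) -> EmpiricalCDF:
    """Empirical CDF of a sample (jumps of 1/n at each sorted value)."""
    v = np.asarray(values, float).ravel()
    if len(v) == 0:
        raise ValueError("cannot build an empirical CDF from an empty sample")
    return EmpiricalCDF(sorted_values=np.sort(v), n=len(v))


def area_metric(experimental: EmpiricalCDF, model: EmpiricalCDF) -> float:
    """Exact area between two empirical CDFs (degrees).

    Both CDFs are step functions, so ∫|F_exp − F_model| dx reduces to a
    finite sum over the merged breakpoints.  Symmetric, nonnegative, and
    zero iff the two CDFs are identical functions; equals the
    1-Wasserstein distance between the empirical distributions.
    """
    breaks = np.union1d(experimental.sorted_values, model.sorted_values)
    if len(breaks) == 1:
        return 0.0
    # F is constant on [b_i, b_{i+1}); evaluate at the left endpoint
    fe = experimental(breaks[:-1])
    fm = model(breaks[:-1])
    return float(np.sum(np.abs(fe - fm) * np.diff(breaks)))


@dataclass
class AreaMetricResult:
    """Raw and normalized CDF area disagreement at one applied-moment level."""

    moment_level: float
    raw_area: float
    normalization: float
    normalized: float

    def __post_init__(self) -> None:
        if self.raw_area < 0:
            raise ValueError("raw_area must be >= 0")
        expected = self.raw_area / abs(self.normalization)
        if not np.isclose(self.normalized, expected, rtol=1e-12, atol=1e-12):
            raise ValueError("normalized must equal raw_area / |normalization|")


def normalized_area_metric(
    experimental_values, model_values, moment_level: float
) -> AreaMetricResult:
    """Area metric between two rotation samples, normalized by the mean
    experimental rotation at this load level (dimensionless)."""
    exp_v = np.asarray(experimental_values, float).ravel()
    mod_v = np.asarray(model_values, float).ravel()
    mean_exp = exp_v.mean()
    if mean_exp == 0:
        raise ValueError("undefined normalization: mean experimental rotation is zero")
    raw = area_metric(ecdf(exp_v), ecdf(mod_v))
    return AreaMetricResult(
        moment_level=float(moment_level),
        raw_area=raw,
        normalization=float(mean_exp),
        normalized=raw / abs(mean_exp),
    )


def envelope(
    samples: list[MomentRotationResponse], moments
) -> dict[str, np.ndarray]:
    """Mean and ±1 SD response envelope across samples at given moments.

    SD uses the population (1/n) convention used throughout the package.
    Returns arrays ``mean``, ``lower`` (mean − SD) and ``upper``
    (mean + SD), one entry per moment.
    """
    if len(samples) < 2:
        raise ValueError("envelope needs at least 2 samples")
    moments = np.asarray(moments, float).ravel()
    rot = np.array(
        [[response_at_moment(s, m) for m in moments] for s in samples]
    )
    mean = rot.mean(axis=0)
    sd = rot.std(axis=0)  # ddof=0: population convention
    return {"moments": moments, "mean": mean, "lower": mean - sd, "upper": mean + sd}
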