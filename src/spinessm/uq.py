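"""Random-variable definitions and Latin Hypercube designs.

The parametric spine model's inputs are fifteen random variables: four
shape-mode weighting factors (truncated standard normal, bounded at ±0.9),
the intervertebral-disk bulk modulus, and ten ligament load-curve scale
factors (all lognormal, given as arithmetic mean ± SD in native units).

Lognormal variables are parameterized by moment matching: the printed
arithmetic mean m and SD s give log-scale parameters
σ² = ln(1 + (s/m)²) and μ = ln m − σ²/2, so draws reproduce the printed
mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RandomVariableSpec",
    "SampleDesign",
    "table1_variables",
    "find_variable",
    "inverse_cdf",
    "lhs_design",
]


@dataclass
class RandomVariableSpec:
    """One input random variable: distribution family, moments and bounds.

    ``mean``/``sd`` are arithmetic moments in native units.  A truncated
    normal requires both bounds; a lognormal requires mean > 0.
    """

    name: str
    distribution: str
    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("truncated_normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.distribution == "truncated_normal" and (
            self.lower is None or self.upper is None
        ):
            raise ValueError("truncated_normal requires both bounds")
        if self.distribution == "lognormal" and not self.mean > 0:
            raise ValueError("lognormal requires mean > 0")

    def frozen(self):
        """The scipy frozen distribution for this spec."""
        if self.distribution == "truncated_normal":
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)
        sigma2 = np.log1p((self.sd / self.mean) ** 2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return stats.lognorm(np.sqrt(sigma2), scale=np.exp(mu))


def _pc(i: int) -> RandomVariableSpec:
    return RandomVariableSpec(
        name=f"Weighting factor for PC{i}",
        distribution="truncated_normal",
        mean=0.0,
        sd=1.0,
        lower=-0.9,
        upper=0.9,
    )


def _lognormal(name: str, mean: float, sd: float) -> RandomVariableSpec:
    return RandomVariableSpec(name=name, distribution="lognormal", mean=mean, sd=sd)


def table1_variables() -> list[RandomVariableSpec]:
    """The fifteen tabulated input random variables of the parametric model.

    Four shape-mode weights, the disk bulk modulus (MPa) and ten ligament
    load-curve scale factors (dimensionless), with their printed
    arithmetic means, SDs, bounds and distribution families.
    """
    rows = [
        _pc(1), _pc(2), _pc(3), _pc(4),
        _lognormal("Bulk modulus for intervertebral disks", 10.99, 8.47),
        _lognormal("Scale factor for ALL load curve (C3-C5)", 0.2500, 0.0422),
        _lognormal("Scale factor for ALL load curve (C5-T1)", 0.2500, 0.0480),
        _lognormal("Scale factor for PLL load curve (C3-C5)", 0.2500, 0.0709),
        _lognormal("Scale factor for PLL load curve (C5-T1)", 0.2500, 0.0260),
        _lognormal("Scale factor for ISL load curve (C3-C5)", 0.2500, 0.0520),
        _lognormal("Scale factor for ISL load curve (C5-T1)", 0.2000, 0.0211),
        _lognormal("Scale factor for LF load curve (C3-C5)", 0.1250, 0.0352),
        _lognormal("Scale factor for LF load curve (C5-T1)", 0.1250, 0.0211),
        _lognormal("Scale factor for JC load curve (C3-C5)", 0.1250, 0.0206),
        _lognormal("Scale factor for JC load curve (C5-T1)", 0.1250, 0.0205),
    ]
    return rows


def find_variable(specs: list[RandomVariableSpec], fragment: str) -> RandomVariableSpec:
    """Return the unique spec whose name contains ``fragment``."""
    hits = [s for s in specs if fragment in s.name]
    if len(hits) != 1:
        raise KeyError(f"{fragment!r} matched {len(hits)} variables")
    return hits[0]


def inverse_cdf(spec: RandomVariableSpec, u) -> np.ndarray | float:
    """Quantile of ``spec`` at probability u ∈ (0, 1) (scalar or array)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0) or np.any(u_arr >= 1):
        raise ValueError("u must lie strictly in (0, 1)")
    q = spec.frozen().ppf(u_arr)
    if spec.distribution == "truncated_normal":
        q = np.clip(q, spec.lower, spec.upper)
    return float(q) if np.isscalar(u) else q


@dataclass
class SampleDesign:
    """A Latin Hypercube design: unit-cube matrix and native-unit samples."""

    unit_matrix: np.ndarray
    samples: np.ndarray
    variable_names: list[str]
    seed: int
    specs: list[RandomVariableSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.unit_matrix = np.asarray(self.unit_matrix, float)
        self.samples = np.asarray(self.samples, float)
        n, d = self.unit_matrix.shape
        if self.samples.shape != (n, d) or len(self.variable_names) != d:
            raise ValueError("inconsistent design dimensions")
        # exactly one unit value per stratum [i/N, (i+1)/N) per column
        strata = np.floor(self.unit_matrix * n).astype(int)
        for j in range(d):
            if not np.array_equal(np.sort(strata[:, j]), np.arange(n)):
                raise ValueError(f"column {j} violates Latin Hypercube stratification")

    @property
    def n_samples(self) -> int:
        return self.unit_matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.variable_names)


def lhs_design(
    specs: list[RandomVariableSpec],
    n_samples: int,
    seed: int,
    midpoint: bool = False,
) -> SampleDesign:
    """Latin Hypercube design over ``specs``: one sample per stratum per column.

    For each variable the unit interval is split into ``n_samples`` equal
    strata; one value is placed uniformly at random inside each stratum
    (or at the stratum midpoint with ``midpoint=True``) and the strata are
    randomly permuted per column.  Native-unit samples follow through
    :func:`inverse_cdf`.  Reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    d = len(specs)
    unit = np.empty((n_samples, d))
    for j in range(d):
        perm = rng.permutation(n_samples)
        offs = np.full(n_samples, 0.5) if midpoint else rng.uniform(size=n_samples)
        unit[:, j] = (perm + offs) / n_samples
    # keep strictly inside (0, 1) for the quantile transform
    unit = np.clip(unit, 1e-12, 1.0 - 1e-12)
    samples = np.column_stack([inverse_cdf(spec, unit[:, j]) for j, spec in enumerate(specs)])
    return SampleDesign(
        unit_matrix=unit,
        samples=samples,
        variable_names=[s.name for s in specs],
        seed=seed,
        specs=list(specs),
    )
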