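"""Yearly stochastic realizations of demographic and control parameters.

Rates bounded in (0, 1) are drawn from beta distributions whose shapes are
recovered from the published mean and standard deviation by method of
moments; per-plant maximum fecundity is drawn from a normal distribution
truncated at zero by rejection. Seed-bank mortality (sm) and seed losses (sl)
are fixed at their means in every draw. One independent realization is drawn
per parameter per replicate-year, representing uncorrelated year-to-year
environmental variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateParam",
    "FecundityParam",
    "RealizedParams",
    "beta_shapes_from_moments",
    "sample_rate",
    "sample_fecundity",
    "sample_year_params",
    "mean_params",
]


@dataclass(frozen=True)
class RateParam:
    """A dimensionless rate in [0, 1] with mean, sd, and a stochastic flag."""

    mean: float
    sd: float = 0.0
    stochastic: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"{self.name or 'rate'}: mean {self.mean} outside [0, 1]")
        if self.sd < 0:
            raise ValueError(f"{self.name or 'rate'}: sd must be >= 0")
        if self.stochastic and self.sd > 0:
            # fail fast on infeasible moments rather than at sampling time
            beta_shapes_from_moments(self.mean, self.sd, name=self.name)

    def zeroed(self) -> "RateParam":
        return RateParam(self.mean, 0.0, False, self.name)


@dataclass(frozen=True)
class FecundityParam:
    """Maximum seed production of an isolated plant (seeds per plant)."""

    mean: float
    sd: float = 0.0
    name: str = "f"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("fecundity mean must be > 0")
        if self.sd < 0:
            raise ValueError("fecundity sd must be >= 0")

    def zeroed(self) -> "FecundityParam":
        return FecundityParam(self.mean, 0.0, self.name)


def beta_shapes_from_moments(mu: float, sigma: float, name: str = "") -> tuple[float, float]:
    """Beta shape parameters (a, b) with mean mu and standard deviation sigma.

    Method of moments: a = mu*nu, b = (1-mu)*nu with nu = mu(1-mu)/sigma^2 - 1.
    Requires 0 < mu < 1 and 0 < sigma^2 < mu(1-mu).
    """
    label = name or f"rate(mu={mu}, sd={sigma})"
    if not (0.0 < mu < 1.0):
        raise ValueError(f"{label}: beta mean must lie strictly in (0, 1)")
    var = sigma * sigma
    if var <= 0:
        raise ValueError(f"{label}: beta sd must be > 0 (use the degenerate sampler for sd=0)")
    if var >= mu * (1.0 - mu):
        raise ValueError(
            f"{label}: infeasible beta moments, sd^2={var:.6g} >= mu(1-mu)={mu * (1 - mu):.6g}"
        )
    nu = mu * (1.0 - mu) / var - 1.0
    return mu * nu, (1.0 - mu) * nu


def sample_rate(p: RateParam, rng: np.random.Generator, size=None):
    """Draw a rate: beta with matched moments, or exactly the mean if fixed."""
    if not p.stochastic or p.sd == 0.0:
        return p.mean if size is None else np.full(size, p.mean)
    a, b = beta_shapes_from_moments(p.mean, p.sd, name=p.name)
    return rng.beta(a, b, size=size)


def sample_fecundity(p: FecundityParam, rng: np.random.Generator, size=None):
    """Normal fecundity draw, rejection-resampled until non-negative.

    With realistic parameter sets (mean many sd above zero) rejection almost
    never triggers; it guards against pathological configurations.
    """
    if p.sd == 0.0:
        return p.mean if size is None else np.full(size, p.mean)
    if size is None:
        value = rng.normal(p.mean, p.sd)
        while value < 0:
            value = rng.normal(p.mean, p.sd)
        return value
    values = rng.normal(p.mean, p.sd, size=size)
    bad = values < 0
    while bad.any():
        values[bad] = rng.normal(p.mean, p.sd, size=int(bad.sum()))
        bad = values < 0
    return values


@dataclass(frozen=True)
class RealizedParams:
    """One year's realized (scalar) demographic and control parameters."""

    sm: float
    e: float
    sdls: tuple[float, float, float]
    fr: tuple[float, float, float]
    f: float
    b: float
    lp: float
    sl: float
    rc_post_early: float
    rc_post_late: float
    cr: dict[str, float]


def sample_year_params(pop, ctrl, rng: np.random.Generator) -> RealizedParams:
    """Draw one year's realization of every stochastic parameter.

    ``pop`` is a demography.PopulationParams and ``ctrl`` a
    management.ControlRates. Draw order is fixed (e, sdls 1-3, fr 1-3, lp,
    f, b, rc early, rc late, cr in declaration order) so that a given rng
    state always yields the same realization. sm and sl stay at their means.
    """
    return RealizedParams(
        sm=pop.sm.mean,
        e=float(sample_rate(pop.e, rng)),
        sdls=tuple(float(sample_rate(p, rng)) for p in pop.sdls),
        fr=tuple(float(sample_rate(p, rng)) for p in pop.fr),
        lp=float(sample_rate(pop.lp, rng)),
        f=float(sample_fecundity(pop.f, rng)),
        b=float(sample_rate(pop.b, rng)),
        sl=pop.sl.mean,
        rc_post_early=float(sample_rate(ctrl.rc_post_early, rng)),
        rc_post_late=float(sample_rate(ctrl.rc_post_late, rng)),
        cr={key: float(sample_rate(p, rng)) for key, p in ctrl.cr.items()},
    )


def mean_params(pop, ctrl) -> RealizedParams:
    """The deterministic (all-means) realization used by the analytic oracles."""
    return RealizedParams(
        sm=pop.sm.mean,
        e=pop.e.mean,
        sdls=tuple(p.mean for p in pop.sdls),
        fr=tuple(p.mean for p in pop.fr),
        lp=pop.lp.mean,
        f=pop.f.mean,
        b=pop.b.mean,
        sl=pop.sl.mean,
        rc_post_early=ctrl.rc_post_early.mean,
        rc_post_late=ctrl.rc_post_late.mean,
        cr={key: p.mean for key, p in ctrl.cr.items()},
    )
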