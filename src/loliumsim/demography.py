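"""Annual life-cycle equations of the three-cohort seed-bank model.

State variable: the seed bank SB (seeds m^-2). Each year:

    SDL   = SB * e                          emerged seedlings
    SDL_i = fraction_i * SDL                cohort allocation
    AP_i  = SDL_i * sdls_i * (1 - rc_i)     surviving adult plants
    SP_i  = f (1-fr_i)(1-lp)(1-rc_i) / (1 + b AP_i)   seeds per plant
    TSP_i = SP_i * AP_i * (1 - l)           cohort seed return
    TSP   = sum_i TSP_i
    SB'   = SB (1-e)(1-sm) + TSP (1-cr)     seed-bank recursion

Seed production per plant is density dependent (hyperbolic): half of the
isolated-plant output at density 1/b. The herbicide kill rate rc of the
cohort's action appears in both the survival and the per-plant fecundity
term, as printed in the source equations; because survivors of a late
application arguably still reproduce, the ``rc_applies`` switch can restrict
rc to one of the two places. Densities are continuous (no rounding); seed
banks below a small extinction floor are reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stochastics import FecundityParam, RateParam, RealizedParams

__all__ = [
    "PopulationParams",
    "AnnualState",
    "RC_APPLIES_MODES",
    "emerged_seedlings",
    "allocate_cohorts",
    "adult_plants",
    "seeds_per_plant",
    "cohort_seed_return",
    "total_seed_return",
    "update_seedbank",
    "annual_step",
]

#: Where a cohort's herbicide kill rate acts: in the survival term (Eq. for
#: adult plants), the per-plant fecundity term, or both (the printed default).
RC_APPLIES_MODES = ("both", "survival_only", "fecundity_only")

#: Seed banks below this density (seeds m^-2) are reported as extinct.
EXTINCTION_FLOOR = 1e-6


@dataclass(frozen=True)
class PopulationParams:
    """Demographic parameters of one population (susceptible or resistant).

    sm: seed-bank mortality; e: emergence rate; sdls: per-cohort seedling
    survival; fr: per-cohort fecundity-reduction factors; f: maximum seeds
    per isolated plant; b: area (m^2) a plant needs to produce f seeds
    (sampled with the beta machinery since 0 < b < 1, a modelling
    convention); lp: pollination-loss rate; sl: seed-loss rate.
    """

    sm: RateParam
    e: RateParam
    sdls: tuple[RateParam, RateParam, RateParam]
    fr: tuple[RateParam, RateParam, RateParam]
    f: FecundityParam
    b: RateParam
    lp: RateParam
    sl: RateParam
    label: str = ""

    @classmethod
    def susceptible(cls) -> "PopulationParams":
        return cls(
            sm=RateParam(0.49, 0.0, False, "sm"),
            e=RateParam(0.73, 0.04, True, "e"),
            sdls=(
                RateParam(0.02, 0.02, True, "sdls1"),
                RateParam(0.03, 0.02, True, "sdls2"),
                RateParam(0.11, 0.05, True, "sdls3"),
            ),
            fr=(
                RateParam(0.07, 0.07, True, "fr1"),
                RateParam(0.0, 0.0, False, "fr2"),
                RateParam(0.46, 0.10, True, "fr3"),
            ),
            f=FecundityParam(20300.0, 1212.0),
            b=RateParam(0.17, 0.03, True, "b"),
            lp=RateParam(0.88, 0.05, True, "lp"),
            sl=RateParam(0.19, 0.0, False, "sl"),
            label="susceptible",
        )

    @classmethod
    def resistant(cls) -> "PopulationParams":
        return cls(
            sm=RateParam(0.49, 0.0, False, "sm"),
            e=RateParam(0.73, 0.04, True, "e"),
            sdls=(
                RateParam(0.04, 0.03, True, "sdls1"),
                RateParam(0.05, 0.03, True, "sdls2"),
                RateParam(0.16, 0.07, True, "sdls3"),
            ),
            fr=(
                RateParam(0.02, 0.06, True, "fr1"),
                RateParam(0.0, 0.0, False, "fr2"),
                RateParam(0.34, 0.12, True, "fr3"),
            ),
            f=FecundityParam(13830.0, 1305.0),
            b=RateParam(0.12, 0.03, True, "b"),
            lp=RateParam(0.88, 0.05, True, "lp"),
            sl=RateParam(0.19, 0.0, False, "sl"),
            label="resistant",
        )

    @classmethod
    def by_label(cls, label: str) -> "PopulationParams":
        try:
            return {"susceptible": cls.susceptible, "resistant": cls.resistant}[label]()
        except KeyError:
            raise ValueError(f"unknown population {label!r}") from None

    def zero_spread(self) -> "PopulationParams":
        """Copy with every sd zeroed (deterministic parameter mode)."""
        return PopulationParams(
            sm=self.sm.zeroed(),
            e=self.e.zeroed(),
            sdls=tuple(p.zeroed() for p in self.sdls),
            fr=tuple(p.zeroed() for p in self.fr),
            f=self.f.zeroed(),
            b=self.b.zeroed(),
            lp=self.lp.zeroed(),
            sl=self.sl.zeroed(),
            label=self.label,
        )


@dataclass(frozen=True)
class AnnualState:
    """Every per-year quantity of one model year for one replicate."""

    year: int
    sb: float                      # seed bank at the start of the year
    sdl: float                     # emerged seedlings
    sdl_i: tuple[float, float, float]
    ap_i: tuple[float, float, float]
    sp_i: tuple[float, float, float]
    tsp_i: tuple[float, float, float]
    tsp: float
    sb_next: float                 # seed bank entering the next year

    def __post_init__(self) -> None:
        for name in ("sb", "sdl", "tsp", "sb_next"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.tsp - sum(self.tsp_i)) > 1e-9 * max(1.0, self.tsp):
            raise ValueError("TSP must equal the sum of cohort seed returns")


def _check_rate(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


def emerged_seedlings(sb: float, e: float) -> float:
    """Seedlings emerging from the seed bank this year: SB * e."""
    if sb < 0:
        raise ValueError("seed bank must be >= 0")
    _check_rate(e, "e")
    return sb * e


def allocate_cohorts(sdl: float, fractions) -> tuple[float, float, float]:
    """Split the season's seedlings across the three cohorts."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("cohort fractions must lie in [0, 1]")
    if fractions.sum() > 1.0 + 1e-9:
        raise ValueError(f"cohort fractions sum to {fractions.sum():.12f} > 1")
    return tuple(float(frac) * sdl for frac in fractions)


def adult_plants(sdl_i: float, sdls_i: float, rc_i: float) -> float:
    """Seedlings surviving to adulthood after herbicide: SDL_i sdls_i (1-rc)."""
    if sdl_i < 0:
        raise ValueError("seedling density must be >= 0")
    _check_rate(sdls_i, "sdls")
    _check_rate(rc_i, "rc")
    return sdl_i * sdls_i * (1.0 - rc_i)


def seeds_per_plant(
    f: float, fr_i: float, lp: float, rc_i: float, b: float, ap_i: float
) -> float:
    """Density-dependent per-plant seed output (hyperbolic model).

    f (1-fr_i)(1-lp)(1-rc_i) / (1 + b AP_i); halves at density AP_i = 1/b.
    """
    _check_rate(fr_i, "fr")
    _check_rate(lp, "lp")
    _check_rate(rc_i, "rc")
    if b <= 0:
        raise ValueError("b must be > 0")
    if ap_i < 0:
        raise ValueError("adult-plant density must be >= 0")
    return f * (1.0 - fr_i) * (1.0 - lp) * (1.0 - rc_i) / (1.0 + b * ap_i)


def cohort_seed_return(sp_i: float, ap_i: float, sl: float) -> float:
    """Seeds a cohort returns to the soil after losses: SP_i AP_i (1-l)."""
    if sp_i < 0 or ap_i < 0:
        raise ValueError("inputs must be >= 0")
    _check_rate(sl, "sl")
    return sp_i * ap_i * (1.0 - sl)


def total_seed_return(tsp_i) -> float:
    """Total seed return across the three cohorts."""
    tsp_i = np.asarray(tsp_i, dtype=float)
    if np.any(tsp_i < 0):
        raise ValueError("cohort seed returns must be >= 0")
    return float(tsp_i.sum())


def update_seedbank(sb_prev: float, e_prev: float, sm: float, tsp_prev: float, cr: float) -> float:
    """Annual seed-bank recursion: SB (1-e)(1-sm) + TSP (1-cr)."""
    if sb_prev < 0 or tsp_prev < 0:
        raise ValueError("seed densities must be >= 0")
    for value, name in ((e_prev, "e"), (sm, "sm"), (cr, "cr")):
        _check_rate(value, name)
    return sb_prev * (1.0 - e_prev) * (1.0 - sm) + tsp_prev * (1.0 - cr)


def annual_step(
    sb: float,
    fractions,
    params: RealizedParams,
    rc: tuple[float, float, float] = (0.0, 0.0, 0.0),
    cr: float = 0.0,
    year: int = 1,
    rc_applies: str = "both",
    extinction_floor: float = EXTINCTION_FLOOR,
) -> AnnualState:
    """One full model year: emergence through next year's seed bank.

    ``rc`` holds the realized herbicide kill rate acting on each cohort
    (0 for no action) and ``cr`` the realized crop-rotation effect on this
    year's seed return (0 for none).
    """
    if rc_applies not in RC_APPLIES_MODES:
        raise ValueError(f"rc_applies must be one of {RC_APPLIES_MODES}, got {rc_applies!r}")
    rc_surv = rc if rc_applies in ("both", "survival_only") else (0.0, 0.0, 0.0)
    rc_fec = rc if rc_applies in ("both", "fecundity_only") else (0.0, 0.0, 0.0)

    sdl = emerged_seedlings(sb, params.e)
    sdl_i = allocate_cohorts(sdl, fractions)
    ap_i = tuple(adult_plants(sdl_i[i], params.sdls[i], rc_surv[i]) for i in range(3))
    sp_i = tuple(
        seeds_per_plant(params.f, params.fr[i], params.lp, rc_fec[i], params.b, ap_i[i])
        for i in range(3)
    )
    tsp_i = tuple(cohort_seed_return(sp_i[i], ap_i[i], params.sl) for i in range(3))
    tsp = total_seed_return(tsp_i)
    sb_next = update_seedbank(sb, params.e, params.sm, tsp, cr)
    if sb_next < extinction_floor:
        sb_next = 0.0
    return AnnualState(
        year=year, sb=sb, sdl=sdl, sdl_i=sdl_i, ap_i=ap_i, sp_i=sp_i,
        tsp_i=tsp_i, tsp=tsp, sb_next=sb_next,
    )
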