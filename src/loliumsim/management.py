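"""The ten management strategies: per-cohort herbicide actions and rotations.

M1 is the untreated baseline. M2--M4 are purely chemical: each cohort
receives no action, an early post-emergence application (before bloom, kill
rate ~0.98 on young plants) or a late one (after bloom, ~0.91 on adults),
identically every year. M5--M10 are purely cultural: a repeating cycle of
crop-rotation coefficients (wheat/soybean 0.89, oat/soybean 0.48, oat/corn
0.89) that discount each year's seed return; cycles repeat over the whole
simulated horizon. No strategy mixes chemistry and rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .stochastics import RateParam, RealizedParams

__all__ = [
    "ACTIONS",
    "ROTATIONS",
    "M4_VARIANTS",
    "ChemicalAction",
    "ControlRates",
    "StrategySpec",
    "YearActions",
    "strategy_library",
    "actions_for_year",
    "realized_rc",
]

#: Per-cohort chemical action kinds.
ACTIONS = ("none", "early", "late")

#: Crop-rotation identifiers (keys into ControlRates.cr).
ROTATIONS = ("wheat_soybean", "oat_soybean", "oat_corn")

ChemicalAction = tuple[str, str, str]

#: The source material describes M4 three inconsistent ways; all selectable.
M4_VARIANTS: dict[str, ChemicalAction] = {
    "table2": ("none", "late", "late"),     # late C2 + late C3 (default)
    "figure1": ("none", "early", "late"),   # early C2 + late C3
    "text": ("late", "none", "late"),       # late C1 + late C3
}


@dataclass(frozen=True)
class ControlRates:
    """Herbicide kill rates and crop-rotation effects with stochastic spreads."""

    rc_post_early: RateParam = field(
        default_factory=lambda: RateParam(0.98, 0.005, True, "rc_post_early")
    )
    rc_post_late: RateParam = field(
        default_factory=lambda: RateParam(0.91, 0.008, True, "rc_post_late")
    )
    cr: dict[str, RateParam] = field(
        default_factory=lambda: {
            "wheat_soybean": RateParam(0.89, 0.03, True, "cr_wheat_soybean"),
            "oat_soybean": RateParam(0.48, 0.13, True, "cr_oat_soybean"),
            "oat_corn": RateParam(0.89, 0.03, True, "cr_oat_corn"),
        }
    )

    def zero_spread(self) -> "ControlRates":
        return ControlRates(
            rc_post_early=self.rc_post_early.zeroed(),
            rc_post_late=self.rc_post_late.zeroed(),
            cr={key: p.zeroed() for key, p in self.cr.items()},
        )


@dataclass(frozen=True)
class StrategySpec:
    """One management strategy: constant chemical actions or a rotation cycle."""

    id: str
    chemical: ChemicalAction = ("none", "none", "none")
    rotation_cycle: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.chemical) != 3 or any(a not in ACTIONS for a in self.chemical):
            raise ValueError(f"{self.id}: chemical actions must be three of {ACTIONS}")
        if any(r not in ROTATIONS for r in self.rotation_cycle):
            raise ValueError(f"{self.id}: unknown rotation in {self.rotation_cycle}")
        if any(a != "none" for a in self.chemical) and self.rotation_cycle:
            raise ValueError(f"{self.id}: chemical and rotation must not be combined")

    @property
    def cycle_length(self) -> int:
        return max(1, len(self.rotation_cycle))


@dataclass(frozen=True)
class YearActions:
    """Resolved actions for one simulated year."""

    chemical: ChemicalAction
    rotation: str | None


def strategy_library(m4_variant: str = "table2") -> dict[str, StrategySpec]:
    """The ten packaged strategies M1--M10."""
    if m4_variant not in M4_VARIANTS:
        raise ValueError(f"m4_variant must be one of {sorted(M4_VARIANTS)}, got {m4_variant!r}")
    return {
        "M1": StrategySpec("M1"),
        "M2": StrategySpec("M2", chemical=("late", "early", "none")),
        "M3": StrategySpec("M3", chemical=("late", "late", "early")),
        "M4": StrategySpec("M4", chemical=M4_VARIANTS[m4_variant]),
        "M5": StrategySpec("M5", rotation_cycle=("wheat_soybean",)),
        "M6": StrategySpec("M6", rotation_cycle=("oat_soybean",)),
        "M7": StrategySpec("M7", rotation_cycle=("oat_corn",)),
        "M8": StrategySpec("M8", rotation_cycle=("wheat_soybean", "oat_corn")),
        "M9": StrategySpec("M9", rotation_cycle=("oat_soybean", "oat_corn")),
        "M10": StrategySpec("M10", rotation_cycle=("wheat_soybean", "oat_corn", "oat_soybean")),
    }


def get_strategy(strategy_id: str, m4_variant: str = "table2") -> StrategySpec:
    library = strategy_library(m4_variant)
    if strategy_id not in library:
        raise ValueError(f"unknown strategy {strategy_id!r}; expected one of {sorted(library)}")
    return library[strategy_id]


def actions_for_year(strategy: StrategySpec, year: int) -> YearActions:
    """Resolve a strategy in a given (1-based) simulation year.

    Chemical actions repeat identically every year; rotation cycles wrap
    around their length for horizons longer than the cycle.
    """
    if year < 1:
        raise ValueError("year index is 1-based")
    rotation = None
    if strategy.rotation_cycle:
        rotation = strategy.rotation_cycle[(year - 1) % len(strategy.rotation_cycle)]
    return YearActions(chemical=strategy.chemical, rotation=rotation)


def realized_rc(actions: YearActions, params: RealizedParams) -> tuple[float, float, float]:
    """Map a year's chemical actions to realized per-cohort kill rates."""
    lookup = {"none": 0.0, "early": params.rc_post_early, "late": params.rc_post_late}
    return tuple(lookup[a] for a in actions.chemical)


def realized_cr(actions: YearActions, params: RealizedParams) -> float:
    """Realized crop-rotation effect for the year (0 when no rotation)."""
    return params.cr[actions.rotation] if actions.rotation else 0.0
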