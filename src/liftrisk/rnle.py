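"""Revised NIOSH Lifting Equation (RNLE).

The RNLE estimates the Recommended Weight Limit (RWL) for a manual lifting
task as a multiplicative model

    RWL = LC * HM * VM * DM * AM * FM * GM

where LC is a load constant depending on the lifter's sex and age band, and
the six multipliers (each in [0, 1]) penalise unfavourable task geometry
(horizontal grip distance H, vertical origin height V, vertical displacement
D, asymmetry angle A), lifting frequency/duration, and coupling (hand-hold)
quality.  The Lifting Index LI = AWL / RWL compares the actual weight lifted
against this limit: LI < 1 is considered acceptable, LI >= 1 a potential
biomechanical risk.

All geometry is metric (cm, kg, degrees).  The frequency (FM) and coupling
(GM) multipliers are table look-ups shipped as plain-text data files; the
continuous multipliers use the standard published forms:

    HM = 25 / H        (H clamped below at 25 cm; 0 above 63 cm)
    VM = 1 - 0.003 |V - 75|        (0 above 175 cm)
    DM = 0.82 + 4.5 / D            (D floored at 25 cm; 0 above 175 cm)
    AM = 1 - 0.0032 A              (0 above 135 degrees)
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

TABLE_VERSION = "niosh-1994-metric"

# geometry limits beyond which a multiplier drops to zero
_H_MIN_CM = 25.0
_H_MAX_CM = 63.0
_V_MAX_CM = 175.0
_V_REF_CM = 75.0
_D_MIN_CM = 25.0
_D_MAX_CM = 175.0
_A_MAX_DEG = 135.0


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class AgeBand(str, Enum):
    UNDER45 = "under45"
    OVER45 = "over45"


class DurationCategory(str, Enum):
    SHORT = "short"    # <= 1 h
    MEDIUM = "medium"  # <= 2 h
    LONG = "long"      # <= 8 h


class Coupling(str, Enum):
    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"


class RiskClass(str, Enum):
    NO_RISK = "NO_RISK"
    RISK = "RISK"


_LOAD_CONSTANT_KG = {
    (Sex.MALE, AgeBand.UNDER45): 25.0,
    (Sex.MALE, AgeBand.OVER45): 20.0,
    (Sex.FEMALE, AgeBand.UNDER45): 20.0,
    (Sex.FEMALE, AgeBand.OVER45): 15.0,
}


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("liftrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


_FM_TABLE = _load_table("fm_table.csv")
_CM_TABLE = _load_table("cm_table.csv").set_index("coupling")


@dataclass(frozen=True)
class RnleTask:
    """One lifting-task configuration.

    Distances are grip-point coordinates in cm; ``horizontal_cm`` is the
    horizontal grip-to-ankle distance, ``vertical_origin_cm`` /
    ``vertical_dest_cm`` the grip heights at the start and end of the lift.
    """

    sex: Sex
    age_band: AgeBand
    load_kg: float
    horizontal_cm: float
    vertical_origin_cm: float
    vertical_dest_cm: float
    asymmetry_deg: float = 0.0
    lifts_per_min: float = 1.0
    duration_category: DurationCategory = DurationCategory.SHORT
    coupling: Coupling = Coupling.GOOD

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "age_band", AgeBand(self.age_band))
        object.__setattr__(
            self, "duration_category", DurationCategory(self.duration_category)
        )
        object.__setattr__(self, "coupling", Coupling(self.coupling))
        if self.load_kg <= 0:
            raise ValueError("load_kg must be > 0")
        if self.lifts_per_min <= 0:
            raise ValueError("lifts_per_min must be > 0")
        for name in ("horizontal_cm", "vertical_origin_cm", "vertical_dest_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.asymmetry_deg < 0:
            raise ValueError("asymmetry_deg must be >= 0")


@dataclass(frozen=True)
class RnleResult:
    lc_kg: float
    hm: float
    vm: float
    dm: float
    am: float
    fm: float
    gm: float
    rwl_kg: float
    li: float | None
    risk_class: RiskClass
    infinite_risk: bool = False
    table_version: str = TABLE_VERSION

    @property
    def multipliers(self) -> tuple[float, float, float, float, float, float]:
        return (self.hm, self.vm, self.dm, self.am, self.fm, self.gm)


def load_constant(sex: Sex | str, age_band: AgeBand | str) -> float:
    """Load constant LC in kg: 25/20 kg for males under/over 45, 20/15 for females."""
    return _LOAD_CONSTANT_KG[(Sex(sex), AgeBand(age_band))]


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def horizontal_multiplier(h_cm: float) -> float:
    if h_cm > _H_MAX_CM:
        return 0.0
    return _clamp01(_H_MIN_CM / max(h_cm, _H_MIN_CM))


def vertical_multiplier(v_cm: float) -> float:
    if v_cm > _V_MAX_CM:
        return 0.0
    return _clamp01(1.0 - 0.003 * abs(v_cm - _V_REF_CM))


def distance_multiplier(d_cm: float) -> float:
    if d_cm > _D_MAX_CM:
        return 0.0
    # lifts shorter than the 25 cm floor are treated as minimal displacement
    return _clamp01(0.82 + 4.5 / max(d_cm, _D_MIN_CM))


def asymmetry_multiplier(a_deg: float) -> float:
    if a_deg > _A_MAX_DEG:
        return 0.0
    return _clamp01(1.0 - 0.0032 * a_deg)


def frequency_multiplier(
    lifts_per_min: float,
    duration_category: DurationCategory | str,
    v_origin_cm: float,
) -> float:
    """FM from the published frequency x duration x height table.

    Frequencies between table rows use the next higher tabulated frequency
    (the conservative choice); above 15 lifts/min FM is 0.
    """
    duration_category = DurationCategory(duration_category)
    freqs = _FM_TABLE["freq_per_min"]
    if lifts_per_min > freqs.iloc[-1]:
        return 0.0
    row = _FM_TABLE[freqs >= lifts_per_min - 1e-12].iloc[0]
    col = duration_category.value + ("_v_lt75" if v_origin_cm < _V_REF_CM else "_v_ge75")
    return float(row[col])


def coupling_multiplier(coupling: Coupling | str, v_origin_cm: float) -> float:
    col = "v_lt75" if v_origin_cm < _V_REF_CM else "v_ge75"
    return float(_CM_TABLE.loc[Coupling(coupling).value, col])


def multipliers(task: RnleTask) -> tuple[float, float, float, float, float, float]:
    """(HM, VM, DM, AM, FM, GM) for a task, each in [0, 1]."""
    d = abs(task.vertical_dest_cm - task.vertical_origin_cm)
    return (
        horizontal_multiplier(task.horizontal_cm),
        vertical_multiplier(task.vertical_origin_cm),
        distance_multiplier(d),
        asymmetry_multiplier(task.asymmetry_deg),
        frequency_multiplier(
            task.lifts_per_min, task.duration_category, task.vertical_origin_cm
        ),
        coupling_multiplier(task.coupling, task.vertical_origin_cm),
    )


def classify_risk(li: float) -> RiskClass:
    """LI < 1 is acceptable; LI >= 1 is a potential biomechanical risk.

    The boundary LI == 1 is classified conservatively as RISK.
    """
    if li < 0:
        raise ValueError("lifting index must be >= 0")
    return RiskClass.NO_RISK if li < 1.0 else RiskClass.RISK


def compute_rwl_li(task: RnleTask) -> RnleResult:
    """Recommended weight limit, lifting index and risk class for a task.

    A geometry so extreme that some multiplier is zero gives RWL = 0; the
    lifting index is then undefined and the result carries an
    ``infinite_risk`` flag instead of a numeric LI.
    """
    lc = load_constant(task.sex, task.age_band)
    hm, vm, dm, am, fm, gm = multipliers(task)
    rwl = lc * hm * vm * dm * am * fm * gm
    if rwl > 0:
        li = task.load_kg / rwl
        return RnleResult(lc, hm, vm, dm, am, fm, gm, rwl, li, classify_risk(li))
    return RnleResult(
        lc, hm, vm, dm, am, fm, gm, 0.0, None, RiskClass.RISK, infinite_risk=True
    )


def result_to_dict(result: RnleResult) -> dict:
    return {
        "lc_kg": result.lc_kg,
        "hm": result.hm,
        "vm": result.vm,
        "dm": result.dm,
        "am": result.am,
        "fm": result.fm,
        "gm": result.gm,
        "rwl_kg": result.rwl_kg,
        "li": result.li if not result.infinite_risk else None,
        "risk_class": result.risk_class.value,
        "infinite_risk": result.infinite_risk,
        "table_version": result.table_version,
    }
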