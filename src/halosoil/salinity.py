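"""EC-to-salinity conversion and Non/Mild/Severe classification.

Soluble-salt content of a 1:5 soil-water suspension is estimated from its
electrical conductivity (EC, μS/cm) by an affine calibration established for
coastal saline soils::

    salinity [g/kg] = EC / (1000 × 0.39) − 0.0182        ("calibrated" form)

clamped at zero below the intercept. A literal alternative reading,
``(EC/1000 − 0.0182)/0.39``, is available via ``form="literal"``.

Samples are grouped by the conventional thresholds: Non-salinity below
1 g/kg, Mild-salinity in [1, 4) g/kg, Severe-salinity at or above 4 g/kg.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from halosoil.exceptions import InputError

#: Slope denominator of the affine EC→salinity calibration (μS/cm per g/kg ×1000).
_CAL_DENOM = 1000.0 * 0.39
#: Intercept of the calibration, g/kg.
_CAL_INTERCEPT = 0.0182

#: Class boundaries in g/kg: below the first → Non, below the second → Mild.
MILD_THRESHOLD = 1.0
SEVERE_THRESHOLD = 4.0


class SalinityClass(str, enum.Enum):
    """Salinity group of a plot, ordered Non < Mild < Severe."""

    NON = "Non"
    MILD = "Mild"
    SEVERE = "Severe"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SoilSample:
    """Plot-level soil metadata.

    Parameters
    ----------
    plot_id : str
        Plot label; must be unique within a survey.
    ec : float
        Electrical conductivity of the 1:5 suspension, μS/cm, ≥ 0.
    salinity : float, optional
        Derived soluble-salt content, g/kg. Populated by
        :func:`assign_groups` when absent.
    sal_class : SalinityClass, optional
        Derived salinity group.
    chemistry : dict, optional
        Additional chemistry (pH, SOC g/kg, Na g/kg, AN mg/kg, AP mg/kg,
        K mg/kg, dehydrogenase μg TPF/g).
    """

    plot_id: str
    ec: float
    salinity: float | None = None
    sal_class: SalinityClass | None = None
    chemistry: dict[str, float] = field(default_factory=dict)


def ec_to_salinity(ec: float, form: str = "calibrated") -> float:
    """Convert electrical conductivity (μS/cm) to salinity (g/kg).

    Negative results (EC below the calibration intercept) are clamped to 0,
    since the affine conversion is only valid above its intercept. Full
    precision is kept; round only at the presentation layer.

    Parameters
    ----------
    ec : float
        Electrical conductivity, μS/cm; finite and ≥ 0.
    form : {"calibrated", "literal"}
        ``calibrated`` (default) uses EC/(1000·0.39) − 0.0182;
        ``literal`` uses (EC/1000 − 0.0182)/0.39.
    """
    if not math.isfinite(ec) or ec < 0:
        raise InputError(f"EC must be finite and non-negative, got {ec!r}")
    if form == "calibrated":
        s = ec / _CAL_DENOM - _CAL_INTERCEPT
    elif form == "literal":
        s = (ec / 1000.0 - _CAL_INTERCEPT) / 0.39
    else:
        raise InputError(f"unknown conversion form {form!r}")
    return max(0.0, s)


def classify_salinity(salinity: float) -> SalinityClass:
    """Classify a salinity value (g/kg) into Non / Mild / Severe.

    Thresholds are closed on the left: [0, 1) → Non, [1, 4) → Mild,
    [4, ∞) → Severe.
    """
    if not math.isfinite(salinity) or salinity < 0:
        raise InputError(f"salinity must be finite and non-negative, got {salinity!r}")
    if salinity < MILD_THRESHOLD:
        return SalinityClass.NON
    if salinity < SEVERE_THRESHOLD:
        return SalinityClass.MILD
    return SalinityClass.SEVERE


def assign_groups(
    samples: list[SoilSample], form: str = "calibrated"
) -> dict[SalinityClass, list[str]]:
    """Populate salinity fields in place and group plot ids by class.

    Returns a mapping over all three classes in fixed order
    Non, Mild, Severe (empty lists for unpopulated classes); every sample
    lands in exactly one group.
    """
    seen: set[str] = set()
    groups: dict[SalinityClass, list[str]] = {c: [] for c in SalinityClass}
    for s in samples:
        if s.plot_id in seen:
            raise InputError(f"duplicate plot_id {s.plot_id!r}")
        seen.add(s.plot_id)
        s.salinity = ec_to_salinity(s.ec, form=form)
        s.sal_class = classify_salinity(s.salinity)
        groups[s.sal_class].append(s.plot_id)
    return groups


def classify_table(meta: pd.DataFrame, form: str = "calibrated") -> pd.DataFrame:
    """Add ``salinity_g_kg`` (2 dp) and ``sal_class`` columns to a metadata table.

    The input frame must carry ``plot_id`` and ``ec_uS_cm`` columns; it is
    not mutated.
    """
    for col in ("plot_id", "ec_uS_cm"):
        if col not in meta.columns:
            raise InputError(f"metadata is missing required column {col!r}")
    if meta["plot_id"].duplicated().any():
        dupes = meta.loc[meta["plot_id"].duplicated(), "plot_id"].tolist()
        raise InputError(f"duplicate plot_id values: {dupes}")
    out = meta.copy()
    sal = [ec_to_salinity(float(e), form=form) for e in out["ec_uS_cm"]]
    out["salinity_g_kg"] = [round(s, 2) for s in sal]
    out["sal_class"] = [classify_salinity(s).value for s in sal]
    return out
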