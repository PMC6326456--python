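"""LMS growth z-scores and the Bristol severe-undernutrition outcome.

A growth reference parameterises, for each sex and indicator, the
distribution of a measurement at a given age (or height) by the Box-Cox
power ``L``, the median ``M`` and the coefficient of variation ``S``.
The z-score of a measurement ``x`` is

    z = ((x / M)**L - 1) / (L * S)        if L != 0
    z = log(x / M) / S                    if L == 0

Three indicators are computed per child: weight-for-age, height-for-age
and weight-for-height.  Following the Bristol approach to severe
anthropometric failure, a child is classified as severely undernourished
when any indicator falls more than 3 SD below the reference median
(strict ``z < -3``).  Z-scores with ``|z| > 6`` are flagged biologically
implausible and excluded from classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from maternut.data_model_io import ChildRecord

INDICATORS = ("weight_for_age", "height_for_age", "weight_for_height")

#: |z| beyond this is treated as a measurement artefact, not biology
IMPLAUSIBLE_Z = 6.0

SEVERE_THRESHOLD = -3.0


class ReferenceRangeError(ValueError):
    """Query index (age or height) outside the tabulated reference grid."""


class GrowthReference:
    """LMS parameter table over a (sex, indicator, index_value) grid.

    ``index_value`` is age in months for the two age-indexed indicators
    and height in cm for weight-for-height.  Parameters are linearly
    interpolated between tabulated rows.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "indicator", "index_value", "L", "M", "S"}
        if not required <= set(table.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        if (table["M"] <= 0).any() or (table["S"] <= 0).any():
            raise ValueError("M and S must be strictly positive")
        self._grids: dict[tuple[str, str], np.ndarray] = {}
        for (sex, ind), group in table.groupby(["sex", "indicator"]):
            g = group.sort_values("index_value")
            idx = g["index_value"].to_numpy(dtype=float)
            if len(idx) < 2:
                raise ValueError(
                    f"need >= 2 rows per (sex, indicator), got {len(idx)} "
                    f"for ({sex}, {ind})")
            if not np.all(np.diff(idx) > 0):
                raise ValueError(
                    f"index_value not strictly increasing for ({sex}, {ind})")
            self._grids[(sex, ind)] = np.column_stack(
                [idx, g["L"].to_numpy(float), g["M"].to_numpy(float),
                 g["S"].to_numpy(float)])
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def bounds(self, sex: str, indicator: str) -> tuple[float, float]:
        grid = self._grid(sex, indicator)
        return float(grid[0, 0]), float(grid[-1, 0])

    def _grid(self, sex: str, indicator: str) -> np.ndarray:
        try:
            return self._grids[(sex, indicator)]
        except KeyError:
            raise KeyError(f"no reference for ({sex!r}, {indicator!r})")


def lms_zscore(x: float, L: float, M: float, S: float) -> float:
    """Box-Cox (LMS) z-score of measurement ``x``."""
    if x <= 0 or M <= 0 or S <= 0:
        raise ValueError("x, M and S must be strictly positive")
    if abs(L) < 1e-12:
        # the Box-Cox transform converges to the log form as L -> 0 and
        # the power form cancels catastrophically
        return math.log(x / M) / S
    return math.expm1(L * math.log(x / M)) / (L * S)


def invert_lms(z: float, L: float, M: float, S: float) -> float:
    """Measurement with z-score ``z`` under (L, M, S); inverse of lms_zscore."""
    if M <= 0 or S <= 0:
        raise ValueError("M and S must be strictly positive")
    if abs(L) < 1e-12:
        return M * math.exp(S * z)
    base = 1.0 + L * S * z
    if base <= 0:
        raise ValueError(f"z={z} outside the Box-Cox domain for L={L}, S={S}")
    # log1p form of base**(1/L): stable as L -> 0
    return M * math.exp(math.log1p(L * S * z) / L)


def interpolate_reference(ref: GrowthReference, sex: str, indicator: str,
                          index_value: float) -> tuple[float, float, float]:
    """(L, M, S) at ``index_value``, linearly interpolated between rows."""
    grid = ref._grid(sex, indicator)
    idx = grid[:, 0]
    if index_value < idx[0] or index_value > idx[-1]:
        raise ReferenceRangeError(
            f"{indicator} index {index_value} outside grid "
            f"[{idx[0]}, {idx[-1]}] for sex={sex}")
    L = float(np.interp(index_value, idx, grid[:, 1]))
    M = float(np.interp(index_value, idx, grid[:, 2]))
    S = float(np.interp(index_value, idx, grid[:, 3]))
    return L, M, S


def classify_severe_undernutrition(z_wa: float | None, z_ha: float | None,
                                   z_wh: float | None) -> bool:
    """Bristol any-indicator rule: true iff any non-missing z < -3 (strict)."""
    zs = [z for z in (z_wa, z_ha, z_wh)
          if z is not None and not math.isnan(z)]
    if not zs:
        raise ValueError("all three indicators missing; unclassifiable")
    return any(z < SEVERE_THRESHOLD for z in zs)


def classify_sanitation_deprivation(sanitation_access: bool) -> bool:
    """Severe sanitation deprivation: no toilet access of any kind."""
    return not sanitation_access


@dataclass
class AnthroResult:
    """Per-child z-scores, quality flags, and the binary outcome."""

    z_wa: float | None
    z_ha: float | None
    z_wh: float | None
    severe_undernutrition: bool | None
    flags: set[str] = field(default_factory=set)


def _zscore_or_none(ref: GrowthReference, sex: str, indicator: str,
                    index_value: float, x: float | None,
                    flags: set[str]) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    try:
        L, M, S = interpolate_reference(ref, sex, indicator, index_value)
    except ReferenceRangeError:
        flags.add(f"{indicator}:out_of_reference_range")
        return None
    return lms_zscore(x, L, M, S)


def compute_indicators(child: ChildRecord,
                       ref: GrowthReference) -> AnthroResult:
    """Compute the three indicator z-scores and classify the child.

    Implausible z-scores (|z| > 6) are flagged and excluded from
    classification; if every indicator ends up missing or flagged the
    result carries the ``unclassifiable`` flag and a ``None`` outcome.
    """
    flags: set[str] = set()
    z_wa = _zscore_or_none(ref, child.sex, "weight_for_age",
                           float(child.age_months), child.weight_kg, flags)
    z_ha = _zscore_or_none(ref, child.sex, "height_for_age",
                           float(child.age_months), child.height_cm, flags)
    z_wh = None
    if child.height_cm is not None and not (
            isinstance(child.height_cm, float) and math.isnan(child.height_cm)):
        z_wh = _zscore_or_none(ref, child.sex, "weight_for_height",
                               float(child.height_cm), child.weight_kg, flags)
    usable = {}
    for name, z in (("z_wa", z_wa), ("z_ha", z_ha), ("z_wh", z_wh)):
        if z is not None and abs(z) > IMPLAUSIBLE_Z:
            flags.add(f"{name}:implausible")
            usable[name] = None
        else:
            usable[name] = z
    try:
        severe = classify_severe_undernutrition(
            usable["z_wa"], usable["z_ha"], usable["z_wh"])
    except ValueError:
        flags.add("unclassifiable")
        severe = None
    return AnthroResult(z_wa=z_wa, z_ha=z_ha, z_wh=z_wh,
                        severe_undernutrition=severe, flags=flags)
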