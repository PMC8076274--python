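"""Piecewise-linear age-depth model from magnetostratigraphic tie points.

A tie point is a core depth with an independently known age — here
geomagnetic reversals (Brunhes–Matuyama, Jaramillo, Olduvai) identified by
magnetostratigraphy.  Between consecutive ties, age is linear in depth; the
slope of each segment is the sedimentation rate.  Units are fixed across
the package: depth in metres, age in Ma, rate in cm/ka (1 m/Ma =
0.1 cm/ka).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AgeModelError
from .tables import CountTable, TiePointTable

#: metres per Ma -> centimetres per ka
_M_PER_MA_TO_CM_PER_KA = 0.1

EXTRAPOLATION_POLICIES = ("nearest_rate", "forbid")


@dataclass(frozen=True)
class AgeModel:
    """Continuous, strictly increasing depth -> age map."""

    tie_points: TiePointTable
    extrapolation: str = "nearest_rate"

    def __post_init__(self):
        if self.extrapolation not in EXTRAPOLATION_POLICIES:
            raise AgeModelError(
                f"extrapolation must be one of {EXTRAPOLATION_POLICIES}"
            )

    @property
    def segments(self) -> pd.DataFrame:
        """One row per inter-tie segment with its sedimentation rate."""
        d, a = self.tie_points.depths, self.tie_points.ages
        rate = _M_PER_MA_TO_CM_PER_KA * np.diff(d) / np.diff(a)
        return pd.DataFrame({
            "depth_top_m": d[:-1], "depth_base_m": d[1:],
            "age_top_ma": a[:-1], "age_base_ma": a[1:],
            "rate_cm_per_ka": rate,
        })

    def age_at(self, depth_m) -> np.ndarray | float:
        """Interpolated age (Ma) at ``depth_m`` (scalar or array).

        Tie depths map to tie ages exactly.  Outside the tie span the
        behaviour follows the extrapolation policy: ``nearest_rate``
        extends the first/last segment's rate, ``forbid`` raises.
        """
        d, a = self.tie_points.depths, self.tie_points.ages
        x = np.asarray(depth_m, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        below, above = x < d[0], x > d[-1]
        if (below.any() or above.any()) and self.extrapolation == "forbid":
            bad = x[below | above][0]
            raise AgeModelError(
                f"depth {bad} m outside modelled span [{d[0]}, {d[-1]}] m "
                "and extrapolation is forbidden"
            )
        age = np.interp(x, d, a)
        if below.any():
            slope = (a[1] - a[0]) / (d[1] - d[0])
            age[below] = a[0] + slope * (x[below] - d[0])
        if above.any():
            slope = (a[-1] - a[-2]) / (d[-1] - d[-2])
            age[above] = a[-1] + slope * (x[above] - d[-1])
        return float(age[0]) if scalar else age

    def depth_at(self, age_ma) -> np.ndarray | float:
        """Inverse map, used when windows are specified in age."""
        d, a = self.tie_points.depths, self.tie_points.ages
        x = np.atleast_1d(np.asarray(age_ma, dtype=float))
        depth = np.interp(x, a, d)
        below, above = x < a[0], x > a[-1]
        if (below.any() or above.any()) and self.extrapolation == "forbid":
            raise AgeModelError("age outside modelled span")
        if below.any():
            depth[below] = d[0] + (x[below] - a[0]) * (d[1] - d[0]) / (a[1] - a[0])
        if above.any():
            depth[above] = d[-1] + (x[above] - a[-1]) * (d[-1] - d[-2]) / (a[-1] - a[-2])
        return float(depth[0]) if np.ndim(age_ma) == 0 else depth


def build_age_model(
    ties: TiePointTable | pd.DataFrame, extrapolation: str = "nearest_rate"
) -> AgeModel:
    """Validate tie points and return the piecewise-linear model.

    Raises :class:`AgeModelError` on fewer than two ties or an age
    reversal (the tie-point table constructor names the offending pair).
    """
    if not isinstance(ties, TiePointTable):
        ties = TiePointTable(ties)
    model = AgeModel(tie_points=ties, extrapolation=extrapolation)
    seg = model.segments
    if (seg["rate_cm_per_ka"] <= 0).any():
        raise AgeModelError("non-positive sedimentation rate in a segment")
    return model


def assign_ages(model: AgeModel, samples: CountTable) -> CountTable:
    """Return a CountTable whose metadata gains an ``age_ma`` column."""
    try:
        ages = model.age_at(samples.meta["depth_m"].to_numpy(float))
    except AgeModelError as e:
        raise AgeModelError(
            f"cannot assign ages to samples {list(samples.sample_ids)}: {e}"
        ) from e
    meta = samples.meta.copy()
    meta["age_ma"] = ages
    return CountTable(counts=samples.counts.copy(), meta=meta)
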