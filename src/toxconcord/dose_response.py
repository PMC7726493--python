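"""Concentration-response normalization and linear-segment IC50 estimation.

Raw assay readouts (e.g. luminescence from cytochrome P450 activity or ATP
assays) are normalized to the vehicle-control mean, either as a percentage
(100 x value / control mean) or as fold change.  The IC50 -- the
concentration at which the response falls to 50 % of the vehicle control --
is estimated from a straight line f(x) = a*x + b:

* ``bracket`` (default): the line is fitted through the first consecutive
  concentration pair whose mean responses bracket 50 % from above, and
  solved at f(x) = 50.  The estimate therefore always lies inside its
  bracketing interval, and equals a tested concentration exactly when that
  concentration's response is exactly 50.
* ``global``: a single least-squares line through all points, solved at 50,
  accepted only when the solution falls inside the tested range.

When the mean response never reaches 50 % at any tested concentration the
result status is ``not_reached``.  Replicates at a concentration are
averaged before crossing detection; responses above 100 % (stimulation) are
allowed -- only the downward crossing of 50 % is sought.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd


class DoseResponseError(ValueError):
    pass


@dataclass(frozen=True)
class Ic50Result:
    """Outcome of an IC50 estimation.

    ``status`` is ``estimated`` or ``not_reached``.  When estimated,
    ``a`` (% per uM) and ``b`` (%) describe the fitted segment and
    ``a * ic50 + b = 50`` holds exactly.
    """

    status: str
    ic50: float | None = None
    a: float | None = None
    b: float | None = None

    @property
    def reached(self) -> bool:
        return self.status == "estimated"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def normalize_to_control(
    readouts: pd.Series, groups: pd.Series, control_group: str, mode: str = "percent"
) -> pd.Series:
    """Normalize per-sample readouts to the mean of a control group.

    ``percent`` mode returns 100 * value / mean(control); ``fold`` mode
    returns value / mean(control).
    """
    if mode not in ("percent", "fold"):
        raise DoseResponseError(f"unknown mode {mode!r}")
    mask = groups == control_group
    if not mask.any():
        raise DoseResponseError(f"control group {control_group!r} is empty")
    control_mean = readouts[mask.to_numpy()].mean()
    if control_mean <= 0:
        raise DoseResponseError(
            f"control mean must be positive, got {control_mean}"
        )
    scale = 100.0 if mode == "percent" else 1.0
    return readouts * (scale / control_mean)


def _mean_curve(curve: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not {"concentration_uM", "response_pct"} <= set(curve.columns):
        raise DoseResponseError(
            "curve needs columns 'concentration_uM' and 'response_pct'"
        )
    means = (
        curve.groupby("concentration_uM", sort=True)["response_pct"].mean()
    )
    return means.index.to_numpy(dtype=float), means.to_numpy(dtype=float)


def estimate_ic50(curve: pd.DataFrame, method: str = "bracket") -> Ic50Result:
    """Estimate the IC50 of a percent-of-control concentration-response curve.

    ``curve`` has one row per well with columns ``concentration_uM`` and
    ``response_pct``; replicate wells are averaged per concentration.
    """
    conc, resp = _mean_curve(curve)
    if len(conc) < 2:
        raise DoseResponseError("need responses at >= 2 distinct concentrations")
    if method == "bracket":
        return _ic50_bracket(conc, resp)
    if method == "global":
        return _ic50_global(conc, resp)
    raise DoseResponseError(f"unknown method {method!r}")


def _ic50_bracket(conc: np.ndarray, resp: np.ndarray) -> Ic50Result:
    if resp[0] < 50.0:
        raise DoseResponseError(
            "response is already below 50 % of control at the lowest tested "
            "concentration; the half-maximal crossing is not bracketed"
        )
    for i in range(len(conc) - 1):
        if resp[i] >= 50.0 >= resp[i + 1]:
            if resp[i] == resp[i + 1]:  # flat segment sitting exactly at 50
                return Ic50Result("estimated", ic50=float(conc[i]), a=0.0, b=50.0)
            a = (resp[i + 1] - resp[i]) / (conc[i + 1] - conc[i])
            b = resp[i] - a * conc[i]
            return Ic50Result(
                "estimated", ic50=float((50.0 - b) / a), a=float(a), b=float(b)
            )
    return Ic50Result("not_reached")


def _ic50_global(conc: np.ndarray, resp: np.ndarray) -> Ic50Result:
    a, b = np.polyfit(conc, resp, 1)
    if a == 0.0:
        return Ic50Result("not_reached")
    x = (50.0 - b) / a
    if a < 0 and conc[0] <= x <= conc[-1]:
        return Ic50Result("estimated", ic50=float(x), a=float(a), b=float(b))
    return Ic50Result("not_reached")


def read_curve(path) -> pd.DataFrame:
    """Read a CSV curve (concentration_uM, response_pct)."""
    curve = pd.read_csv(path)
    if not {"concentration_uM", "response_pct"} <= set(curve.columns):
        raise DoseResponseError(
            f"{path}: expected columns concentration_uM, response_pct"
        )
    return curve
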