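"""Hydrogel characterization computations.

Two routine analyses verify that printed structures actually polymerized:

* **Swelling**: printed samples are immersed in deionized water and
  weighed over time; swelling percent at time *i* is
  ``100 * (W_i - W_0) / W_0`` with ``W_0`` the initial weight. A properly
  cross-linked GelMA network swells only a few percent and plateaus within
  hours.
* **Elastic modulus**: uniaxial compression up to 30% strain; the modulus
  is the least-squares slope of stress vs. strain over the linear portion
  of the curve. The paper's samples sit around 50 kPa.

Strain is a dimensionless fraction internally; stress in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "SwellingSeries",
    "StressStrainCurve",
    "SwellingSummary",
    "ModulusFit",
    "swelling_percent",
    "swelling_summary",
    "elastic_modulus",
    "read_swelling_csv",
    "read_stress_strain_csv",
]


@dataclass(frozen=True)
class SwellingSeries:
    """Weights (mg) of one sample over immersion time (h)."""

    times: tuple[float, ...]
    weights: tuple[float, ...]
    initial_weight: float

    def __post_init__(self) -> None:
        if not self.initial_weight > 0:
            raise ValueError("initial weight must be positive")
        if len(self.times) != len(self.weights):
            raise ValueError("times and weights must pair up")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")

    def percents(self) -> np.ndarray:
        w = np.asarray(self.weights)
        return 100.0 * (w - self.initial_weight) / self.initial_weight


def swelling_percent(W_i: float, W_0: float) -> float:
    """Swelling percent 100·(W_i − W_0)/W_0; negative = deswelling."""
    if not W_0 > 0:
        raise ValueError("initial weight W_0 must be positive")
    return 100.0 * (W_i - W_0) / W_0


@dataclass(frozen=True)
class SwellingSummary:
    times: tuple[float, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    plateau_time: float | None  # first time from which the mean stops drifting


def swelling_summary(
    series: list[SwellingSeries], plateau_rate_tol: float = 0.5
) -> SwellingSummary:
    """Replicate mean ± sd per time point and plateau onset.

    All series must share the time grid. The plateau time is the first
    time point after which the mean swelling drifts slower than
    ``plateau_rate_tol`` (percent points per hour) on every subsequent
    interval; ``None`` if the curve never settles.
    """
    if not series:
        raise ValueError("need at least one series")
    grid = series[0].times
    for s in series[1:]:
        if s.times != grid:
            raise ValueError("series do not share a time grid")
    data = np.vstack([s.percents() for s in series])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1) if len(series) > 1 else np.zeros(len(grid))
    t = np.asarray(grid)
    rates = np.abs(np.diff(mean)) / np.diff(t)
    plateau: float | None = None
    for i in range(len(rates)):
        if np.all(rates[i:] < plateau_rate_tol):
            plateau = float(t[i])
            break
    return SwellingSummary(tuple(grid), tuple(mean), tuple(sd), plateau)


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired strain (fraction) / stress (kPa) samples, ordered by strain."""

    strain: tuple[float, ...]
    stress: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must pair up")
        if any(b < a for a, b in zip(self.strain, self.strain[1:])):
            raise ValueError("strain must be non-decreasing")
        if self.strain and (min(self.strain) < 0 or max(self.strain) > 0.30 + 1e-9):
            raise ValueError("strain must lie within [0, 0.30]")

    @classmethod
    def from_percent(
        cls, strain_percent, stress
    ) -> "StressStrainCurve":
        """Build from strain given in percent (the lab convention)."""
        return cls(tuple(s / 100.0 for s in strain_percent), tuple(stress))


@dataclass(frozen=True)
class ModulusFit:
    modulus: float  # kPa
    intercept: float
    r_squared: float
    stderr: float  # standard error of the slope, kPa
    window: tuple[float, float]  # strain range used
    n_points: int


def _fit(strain: np.ndarray, stress: np.ndarray) -> tuple[float, float, float, float]:
    res = sstats.linregress(strain, stress)
    return res.slope, res.intercept, res.rvalue**2, res.stderr


def elastic_modulus(
    curve: StressStrainCurve,
    window: tuple[float, float] | None = None,
    r2_threshold: float = 0.99,
) -> ModulusFit:
    """Least-squares elastic modulus over the linear portion of the curve.

    With an explicit strain ``window`` the slope is fitted over it
    directly. Otherwise the linear portion is selected automatically as
    the widest contiguous run of points whose fit reaches
    ``r² ≥ r2_threshold`` (ties broken toward higher strain, away from
    the toe region). At least 3 points are required in either case.
    """
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    if window is not None:
        mask = (strain >= window[0]) & (strain <= window[1])
        if mask.sum() < 3:
            raise ValueError("fewer than 3 points in the requested window")
        slope, icpt, r2, se = _fit(strain[mask], stress[mask])
        lo, hi = float(strain[mask][0]), float(strain[mask][-1])
        return ModulusFit(slope, icpt, r2, se, (lo, hi), int(mask.sum()))

    n = len(strain)
    if n < 3:
        raise ValueError("need at least 3 points")
    best: tuple[int, int] | None = None
    for width in range(n, 2, -1):  # widest first
        for start in range(n - width, -1, -1):  # prefer high-strain windows
            seg = slice(start, start + width)
            _, _, r2, _ = _fit(strain[seg], stress[seg])
            if r2 >= r2_threshold:
                best = (start, start + width)
                break
        if best:
            break
    if best is None:
        raise ValueError(
            f"no contiguous window of >= 3 points reaches r^2 >= {r2_threshold}"
        )
    seg = slice(*best)
    slope, icpt, r2, se = _fit(strain[seg], stress[seg])
    return ModulusFit(
        slope, icpt, r2, se,
        (float(strain[best[0]]), float(strain[best[1] - 1])),
        best[1] - best[0],
    )


def read_swelling_csv(source) -> list[SwellingSeries]:
    """Read ``time,weight[,replicate]`` rows into per-replicate series.

    The weight at the earliest time of each replicate is its ``W_0``.
    """
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if "replicate" not in df.columns:
        df["replicate"] = 0
    out = []
    for _, grp in df.groupby("replicate"):
        grp = grp.sort_values("time")
        w0 = float(grp["weight"].iloc[0])
        out.append(
            SwellingSeries(
                tuple(grp["time"]), tuple(grp["weight"]), initial_weight=w0
            )
        )
    return out


def read_stress_strain_csv(source, strain_unit: str = "fraction"):
    """Read ``strain,stress[,replicate]`` rows into curves.

    ``strain_unit`` is ``"fraction"`` or ``"percent"``.
    """
    if strain_unit not in ("fraction", "percent"):
        raise ValueError("strain_unit must be 'fraction' or 'percent'")
    df = pd.read_csv(source)
    df.columns = [c.strip().lower() for c in df.columns]
    if "replicate" not in df.columns:
        df["replicate"] = 0
    out = []
    for _, grp in df.groupby("replicate"):
        grp = grp.sort_values("strain")
        strain = grp["strain"].tolist()
        if strain_unit == "percent":
            out.append(StressStrainCurve.from_percent(strain, tuple(grp["stress"])))
        else:
            out.append(StressStrainCurve(tuple(strain), tuple(grp["stress"])))
    return out
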