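"""Differential-potentiometry processing for unified-pH ladders.

Two glass electrodes in two solutions, joined by an ionic-liquid salt
bridge, give a potential difference trace sampled every ~10 s for at least
an hour.  The most stable 15-minute window of the trace is selected
(minimum standard deviation), averaged, and quality-controlled: a series is
accepted only if the window standard deviation is below 1 mV and the drift
below 4 mV/h.  The averaged potential difference converts to a pH
difference through the mean calibration slope of the electrode pair
(default -58.35 mV per pH unit):

    Delta pH_abs = Delta E / slope_mean

The resulting pairwise Delta pH_abs measurements feed the same ladder
least squares as the pK_a scale, anchored by bridging solutions of known
aqueous-aligned unified pH (10 mM ammonium formate in ethanol, 8.9;
acetonitrile / aqueous pH 4 formate 60/40, 6.0).  The combined standard
uncertainty of the anchored values is the root sum square of the bridging,
liquid-junction and scale-consistency components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._utils import round_up
from .ladder import AnchorSet, LadderMeasurement, LadderScale, ScaleFit

__all__ = [
    "PotentialTrace",
    "TraceQC",
    "SlopeCalibration",
    "UncertaintyBudget",
    "select_stable_window",
    "delta_phabs",
    "anchor_bridging",
    "combine_uncertainty",
    "QC_STD_MV",
    "QC_DRIFT_MV_PER_H",
    "BRIDGE_ETHANOL_FORMATE",
    "BRIDGE_MECN_FORMATE",
]

#: acceptance thresholds for one measurement series
QC_STD_MV = 1.0
QC_DRIFT_MV_PER_H = 4.0
#: stable-window length in seconds (15 min)
WINDOW_S = 900.0
#: aqueous-aligned unified pH of the two bridging solutions
BRIDGE_ETHANOL_FORMATE = 8.9
BRIDGE_MECN_FORMATE = 6.0


@dataclass
class PotentialTrace:
    """One differential-potentiometry record for a solution pair.

    ``polarity`` is +1 when Delta E = E(GE1) - E(GE2) corresponds to
    pH(solution1) - pH(solution2) = Delta E / slope, -1 for the opposite
    cell orientation; the cell diagram alone does not fix the sign, so it
    is explicit metadata.
    """

    times: np.ndarray  # seconds from start
    potentials: np.ndarray  # mV
    solution_pair: tuple[str, str] = ("solution1", "solution2")
    polarity: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.times.shape != self.potentials.shape:
            raise ValueError("times and potentials differ in length")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class TraceQC:
    """Stable-window statistics and the accept/reject verdict."""

    window_start: float
    window_end: float
    window_std: float  # mV
    drift: float  # mV / h
    mean_potential: float  # mV
    n_samples: int

    @property
    def passed(self) -> bool:
        return self.window_std < QC_STD_MV and abs(self.drift) < QC_DRIFT_MV_PER_H


@dataclass(frozen=True)
class SlopeCalibration:
    """Mean electrode-pair slope from aqueous standard-buffer calibration."""

    mean_slope: float = -58.35  # mV per pH unit

    def __post_init__(self) -> None:
        if self.mean_slope == 0:
            raise ValueError("electrode slope cannot be zero")


def select_stable_window(
    trace: PotentialTrace,
    window_s: float = WINDOW_S,
    cadence_tol_s: float = 20.0,
) -> TraceQC:
    """Slide a ``window_s``-long window over the trace and keep the one with
    the smallest potential standard deviation.

    Windows are defined over time, not sample count, so a nominal 10 s
    cadence with small irregularities is handled; a window must span at
    least ``window_s - cadence_tol_s`` seconds.  Drift is the least-squares
    slope over the selected window, in mV/h.
    """
    t, e = trace.times, trace.potentials
    if t.size == 0 or t[-1] - t[0] < window_s - cadence_tol_s:
        raise ValueError(
            f"trace spans {0.0 if t.size == 0 else t[-1] - t[0]:.0f} s; at least "
            f"{window_s:.0f} s are needed for one stable window"
        )
    best: Optional[TraceQC] = None
    for i in range(t.size):
        j = int(np.searchsorted(t, t[i] + window_s, side="right")) - 1
        if t[j] - t[i] < window_s - cadence_tol_s:
            continue
        seg_t, seg_e = t[i : j + 1], e[i : j + 1]
        std = float(seg_e.std())
        if best is None or std < best.window_std:
            slope_mv_s = float(np.polyfit(seg_t, seg_e, 1)[0]) if seg_t.size > 1 else 0.0
            best = TraceQC(
                window_start=float(seg_t[0]),
                window_end=float(seg_t[-1]),
                window_std=std,
                drift=slope_mv_s * 3600.0,
                mean_potential=float(seg_e.mean()),
                n_samples=int(seg_t.size),
            )
    if best is None:
        raise ValueError("no window of the required length fits the trace")
    return best


def delta_phabs(
    delta_e_mv: float,
    cal: SlopeCalibration = SlopeCalibration(),
    polarity: int = 1,
) -> float:
    """Delta pH_abs = Delta E / mean slope (sign set by the cell polarity).

    With the negative slope of a pH-responsive glass electrode, a positive
    potential difference means the first solution is more acidic:
    Delta E = +58.35 mV with slope -58.35 gives Delta pH_abs = -1.0.
    """
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    return polarity * delta_e_mv / cal.mean_slope


def anchor_bridging(
    measurements: Iterable[LadderMeasurement],
    bridges: dict,
    exclusion_threshold: Optional[float] = None,
) -> ScaleFit:
    """Fit the Delta pH_abs ladder anchored to bridging solutions.

    ``bridges`` maps bridging-solution node ids to their known
    aqueous-aligned unified pH values; the fit runs in offset (bridging)
    mode, so with several consistent bridges the applied shift is the mean
    of the implied offsets.
    """
    measurements = list(measurements)
    nodes = {m.node_a for m in measurements} | {m.node_b for m in measurements}
    missing = [b for b in bridges if b not in nodes]
    if missing:
        raise ValueError(f"bridging nodes absent from the measurement graph: {missing}")
    est = LadderScale(
        anchors=AnchorSet("bridging", dict(bridges)),
        exclusion_threshold=exclusion_threshold,
    )
    return est.fit(measurements).fit_result_


@dataclass(frozen=True)
class UncertaintyBudget:
    """Root-sum-square combination of the pH_abs uncertainty components.

    Components (pH units): bridging-solution reference values (default
    0.13), liquid-junction-potential cancellation (6.3 mV -> 0.11), and the
    scale consistency standard deviation.  The recommended value is the
    combination rounded upward to one decimal.
    """

    u_bridge: float = 0.13
    u_ljp: float = 0.11
    u_consistency: float = 0.30

    def __post_init__(self) -> None:
        for name in ("u_bridge", "u_ljp", "u_consistency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def u_combined(self) -> float:
        return math.sqrt(self.u_bridge**2 + self.u_ljp**2 + self.u_consistency**2)

    @property
    def u_recommended(self) -> float:
        return round_up(self.u_combined, 1)


def combine_uncertainty(
    u_bridge: float = 0.13, u_ljp: float = 0.11, u_consistency: float = 0.30
) -> UncertaintyBudget:
    """Assemble the standard uncertainty budget of anchored pH_abs values."""
    return UncertaintyBudget(u_bridge, u_ljp, u_consistency)
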