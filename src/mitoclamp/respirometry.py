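"""Oxygraph trace processing: steady-state JO2 extraction and QC.

A trace is chamber O2 concentration versus time with addition events
(substrate, PCr steps, ADP, cytochrome c).  Flux is the negative local
O2 slope scaled to the chamber:

    JO2 [pmol O2 s^-1 mg^-1] = -dO2/dt [uM/s] * volume [mL] * 1000 / protein [mg]

Within each inter-event interval the extractor looks for the *latest*
window of at least ``min_window_s`` whose point-flux coefficient of
variation is at or below ``cv_max_percent`` — the plateau closest to the
true steady state for that titration step.  Intervals with no qualifying
window are flagged absent, never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import CV_MAX_PERCENT, CYTC_THRESHOLD_PERCENT, MIN_WINDOW_S
from .errors import InvalidInputError, NoSteadyStateError, ProtocolError

#: points in the rolling-OLS slope used as the point-flux series; wide
#: enough that sensor noise does not swamp the CV of shallow O2 slopes
_ROLL_POINTS = 21


@dataclass
class OxygraphTrace:
    """Annotated respirometry time series for one chamber run."""

    time_s: np.ndarray
    o2_uM: np.ndarray
    events: list[tuple[float, str]]
    chamber_volume_mL: float = 2.0
    protein_mg: float = 0.025
    sample_id: str = ""
    group: str = ""
    sex: str = ""
    substrate_label: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_uM = np.asarray(self.o2_uM, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.o2_uM.shape:
            raise InvalidInputError("time_s and o2_uM must be 1-D arrays of equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        if self.chamber_volume_mL <= 0 or self.protein_mg <= 0:
            raise InvalidInputError("chamber volume and protein mass must be positive")
        t0, t1 = self.time_s[0], self.time_s[-1]
        for t, label in self.events:
            if not t0 <= t <= t1:
                raise InvalidInputError(f"event {label!r} at {t} s outside trace range")
        self.events = sorted(self.events, key=lambda e: e[0])


@dataclass
class SteadyStateFlux:
    """Steady-state JO2 for one titration step."""

    jo2: float  # pmol O2 s^-1 mg^-1; nan when absent
    window: tuple[float, float]
    cv_percent: float
    event_label: str
    ok: bool = True


@dataclass
class QCResult:
    """Cytochrome-c outer-membrane integrity check."""

    cytc_response_percent: float
    passed: bool
    threshold_percent: float = CYTC_THRESHOLD_PERCENT


def _flux_scale(trace: OxygraphTrace) -> float:
    # uM/s * mL = nmol/s; *1000 -> pmol/s; / mg protein
    return trace.chamber_volume_mL * 1000.0 / trace.protein_mg


def _rolling_slopes(t: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Centered rolling OLS slope, one value per full window."""
    n = len(t)
    if n < w:
        return np.empty(0)
    out = np.empty(n - w + 1)
    for i in range(n - w + 1):
        tt = t[i : i + w]
        yy = y[i : i + w]
        tc = tt - tt.mean()
        out[i] = tc @ (yy - yy.mean()) / (tc @ tc)
    return out


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    sd = values.std(ddof=0)
    if abs(mean) < 1e-12:
        return 0.0 if sd < 1e-12 else float("inf")
    return float(sd / abs(mean) * 100.0)


def _interval_steady_state(
    trace: OxygraphTrace,
    i0: int,
    i1: int,
    label: str,
    min_window_s: float,
    cv_max_percent: float,
) -> SteadyStateFlux:
    t = trace.time_s[i0:i1]
    y = trace.o2_uM[i0:i1]
    scale = _flux_scale(trace)
    absent = SteadyStateFlux(
        jo2=float("nan"), window=(float("nan"), float("nan")), cv_percent=float("nan"),
        event_label=label, ok=False,
    )
    if len(t) < _ROLL_POINTS + 2:
        return absent
    slopes = _rolling_slopes(t, y, _ROLL_POINTS)
    t_mid = t[_ROLL_POINTS // 2 : _ROLL_POINTS // 2 + len(slopes)]
    # slide a min_window_s window from the end of the interval backwards;
    # accept the latest position whose point-flux CV meets the policy
    n = len(slopes)
    for end in range(n, 0, -1):
        start = int(np.searchsorted(t_mid, t_mid[end - 1] - min_window_s, side="right")) - 1
        if start < 0:
            break  # remaining interval shorter than the window
        sub = slopes[start:end]
        cv = _cv_percent(sub)
        if cv <= cv_max_percent:
            tt = t[start : end + _ROLL_POINTS - 1]
            yy = y[start : end + _ROLL_POINTS - 1]
            tc = tt - tt.mean()
            slope = tc @ (yy - yy.mean()) / (tc @ tc)
            return SteadyStateFlux(
                jo2=float(-slope * scale),
                window=(float(tt[0]), float(tt[-1])),
                cv_percent=cv,
                event_label=label,
            )
    return absent


def segment_steady_states(
    trace: OxygraphTrace,
    min_window_s: float = MIN_WINDOW_S,
    cv_max_percent: float = CV_MAX_PERCENT,
) -> list[SteadyStateFlux]:
    """Steady-state flux for each inter-event interval of the trace.

    Returns one entry per interval following each event (the stretch before
    the first event is labelled ``baseline``).  Windows never cross event
    boundaries.  Intervals with no qualifying window come back with
    ``ok=False`` and ``jo2=nan``.
    """
    if len(trace.events) < 2:
        raise ProtocolError("trace needs at least 2 events to define titration intervals")
    dt = np.median(np.diff(trace.time_s))
    if dt > 2.0:
        raise InvalidInputError(
            f"sampling interval {dt:.2f} s too coarse; need >= 0.5 Hz equivalent"
        )
    bounds = [trace.time_s[0]] + [t for t, _ in trace.events] + [trace.time_s[-1]]
    labels = ["baseline"] + [lab for _, lab in trace.events]
    out: list[SteadyStateFlux] = []
    for k in range(len(labels)):
        lo, hi = bounds[k], bounds[k + 1]
        i0 = int(np.searchsorted(trace.time_s, lo, side="left"))
        i1 = int(np.searchsorted(trace.time_s, hi, side="right"))
        out.append(
            _interval_steady_state(trace, i0, i1, labels[k], min_window_s, cv_max_percent)
        )
    return out


def cytochrome_c_test(
    jo2_before: float,
    jo2_after: float,
    threshold_percent: float = CYTC_THRESHOLD_PERCENT,
) -> QCResult:
    """Outer-membrane integrity QC.

    Response = percent JO2 increase on cytochrome-c addition; a response
    *strictly greater* than the threshold (default 15%) fails the sample.
    """
    if jo2_before <= 0:
        raise InvalidInputError(f"jo2_before must be positive, got {jo2_before}")
    response = (jo2_after - jo2_before) / jo2_before * 100.0
    return QCResult(
        cytc_response_percent=float(response),
        passed=response <= threshold_percent,
        threshold_percent=threshold_percent,
    )


@dataclass
class CapacityResult:
    """ADP-stimulated maximal respiration (state 3) with its baseline."""

    state3: SteadyStateFlux
    baseline: SteadyStateFlux
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = (
            self.state3.jo2 / self.baseline.jo2 if self.baseline.jo2 else float("nan")
        )


def adp_capacity(
    trace: OxygraphTrace,
    min_window_s: float = MIN_WINDOW_S,
    cv_max_percent: float = CV_MAX_PERCENT,
) -> CapacityResult:
    """State-3 flux after the ADP bolus, with the substrate baseline.

    The trace must carry an event whose label contains ``adp``; the interval
    before it provides the state-2 baseline for the state-3/state-2 ratio.
    """
    idx = next(
        (i for i, (_, lab) in enumerate(trace.events) if "adp" in lab.lower()), None
    )
    if idx is None:
        raise ProtocolError("no ADP event in trace")
    fluxes = segment_steady_states(trace, min_window_s, cv_max_percent)
    baseline = fluxes[idx]  # interval preceding the ADP event
    state3 = fluxes[idx + 1]
    if not state3.ok:
        raise NoSteadyStateError("no qualifying steady-state window after the ADP bolus")
    return CapacityResult(state3=state3, baseline=baseline)
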