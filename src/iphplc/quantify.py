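"""From trace to expression level.

The IP-HPLC readout for one antibody is the whole-protein elution peak area
in mAU*s. Quantification runs four steps:

1. baseline correction — subtract the straight line through the absorbance
   values at the integration-window endpoints (a local linear baseline);
2. trapezoidal integration over the window, minutes converted to seconds so
   areas come out in mAU*s;
3. subtraction of the negative-control antibody's peak area (nonspecific
   binding), floored at zero;
4. square-root transform: the reported expression level is sqrt(net area),
   which linearizes the quadratic dependence of peak area on the amount of
   captured protein.

The window is configuration, shared across a cohort so that sequentially run
control and treated samples stay comparable; no automatic peak detection is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import WindowError
from .io import ARM_NEGATIVE, ChromatogramTrace, PeakAreaRecord, PeakWindow

BASELINE_MODEL = "linear-endpoints"


@dataclass(frozen=True)
class ExpressionLevel:
    """Net peak area and its square root for one run."""

    antibody: str
    arm: str
    timepoint_h: int | None
    replicate: int
    net_area_mAU_s: float
    level: float
    clamped: bool


def _window_slice(trace: ChromatogramTrace, window: PeakWindow) -> slice:
    window.check_within(trace)
    t = trace.time_min
    i0 = int(np.searchsorted(t, window.start_min - 1e-12, side="left"))
    i1 = int(np.searchsorted(t, window.end_min + 1e-12, side="right"))
    return slice(i0, i1)


def correct_baseline(
    trace: ChromatogramTrace, window: PeakWindow
) -> ChromatogramTrace:
    """Subtract the line through the signal at the window endpoints.

    Absorbance outside the window is left untouched; a flat or linearly
    drifting baseline is removed exactly inside it.
    """
    sl = _window_slice(trace, window)
    t = trace.time_min
    if sl.stop - sl.start < 2:
        raise WindowError(
            f"{trace.sample_id}: window contains fewer than 2 samples"
        )
    t0, t1 = t[sl.start], t[sl.stop - 1]
    a0, a1 = trace.absorbance_mAU[sl.start], trace.absorbance_mAU[sl.stop - 1]
    corrected = trace.absorbance_mAU.copy()
    tw = t[sl]
    baseline = a0 + (a1 - a0) * (tw - t0) / (t1 - t0)
    corrected[sl] = corrected[sl] - baseline
    out = ChromatogramTrace(
        sample_id=trace.sample_id,
        antibody=trace.antibody,
        arm=trace.arm,
        timepoint_h=trace.timepoint_h,
        replicate=trace.replicate,
        time_min=t,
        absorbance_mAU=corrected,
        wavelength_nm=trace.wavelength_nm,
        flow_mL_min=trace.flow_mL_min,
        duration_min=trace.duration_min,
    )
    return out


def integrate_window(trace: ChromatogramTrace, window: PeakWindow) -> float:
    """Trapezoidal peak area over the window, in mAU*s.

    The trace is integrated as-is (no rectification of negative excursions);
    callers baseline-correct first.
    """
    sl = _window_slice(trace, window)
    if sl.stop - sl.start < 2:
        raise WindowError(
            f"{trace.sample_id}: window contains fewer than 2 samples"
        )
    t_s = trace.time_min[sl] * 60.0
    return float(np.trapezoid(trace.absorbance_mAU[sl], t_s))


def net_peak_area(
    raw_area: float, negative_control_area: float
) -> tuple[float, bool]:
    """Subtract the nonspecific-binding (negative-control) area, floored at 0.

    Returns ``(net_area, clamped)``; ``clamped`` flags runs where the
    negative control exceeded the raw peak, so the floor was applied.
    """
    if raw_area < 0 or negative_control_area < 0:
        raise ValueError(
            f"areas must be non-negative, got ({raw_area}, {negative_control_area})"
        )
    net = raw_area - negative_control_area
    return (max(net, 0.0), net < 0)


def expression_level(net_area: float) -> float:
    """sqrt(net peak area): the normalized expression level, in sqrt(mAU*s)."""
    if net_area < 0:
        raise ValueError(
            f"net area must be non-negative (clamp upstream), got {net_area}"
        )
    return math.sqrt(net_area)


def quantify_trace(
    trace: ChromatogramTrace,
    window: PeakWindow,
    negative_control_area: float = 0.0,
) -> tuple[PeakAreaRecord, ExpressionLevel]:
    """Full single-trace quantification: baseline, integrate, subtract, sqrt."""
    corrected = correct_baseline(trace, window)
    raw = integrate_window(corrected, window)
    raw = max(raw, 0.0)  # noise can push a near-empty window slightly negative
    record = PeakAreaRecord(
        sample_id=trace.sample_id,
        antibody=trace.antibody,
        arm=trace.arm,
        timepoint_h=trace.timepoint_h,
        replicate=trace.replicate,
        raw_area_mAU_s=raw,
        window=window,
        baseline_model=BASELINE_MODEL,
    )
    net, clamped = net_peak_area(raw, negative_control_area)
    return record, ExpressionLevel(
        antibody=trace.antibody,
        arm=trace.arm,
        timepoint_h=trace.timepoint_h,
        replicate=trace.replicate,
        net_area_mAU_s=net,
        level=expression_level(net),
        clamped=clamped,
    )


def quantify_cohort(
    traces: list[ChromatogramTrace], window: PeakWindow
) -> tuple[list[PeakAreaRecord], list[ExpressionLevel]]:
    """Quantify a whole cohort with negative-control subtraction.

    Negative-control runs (arm ``negative_control``) are integrated first;
    each specific run is corrected with the negative area of the matching
    replicate, or the mean negative area when no replicate match exists.
    """
    neg_by_rep: dict[int, float] = {}
    for tr in traces:
        if tr.arm == ARM_NEGATIVE:
            corrected = correct_baseline(tr, window)
            neg_by_rep[tr.replicate] = max(integrate_window(corrected, window), 0.0)
    neg_mean = sum(neg_by_rep.values()) / len(neg_by_rep) if neg_by_rep else 0.0

    records: list[PeakAreaRecord] = []
    levels: list[ExpressionLevel] = []
    for tr in traces:
        if tr.arm == ARM_NEGATIVE:
            continue
        neg = neg_by_rep.get(tr.replicate, neg_mean)
        rec, lv = quantify_trace(tr, window, negative_control_area=neg)
        records.append(rec)
        levels.append(lv)
    return records, levels
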