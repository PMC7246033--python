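"""From per-replicate expression levels to percent expression changes.

For each antibody and timepoint the treated expression level is expressed as
a percent of the same replicate's control level. Each replicate's percent map
is then rescaled so the three housekeeping proteins (α-tubulin, β-actin,
GAPDH) average exactly 100% — the "proportional basal line" adjustment, a
single multiplicative factor per run that removes shared loading/injection
variation. Replicates are aggregated to mean / population SD / SEM with a
QC flag (SD ≤ 5 percentage points), and the mean change Δ% = mean − 100 is
classified into the study's bands:

    minimal  |Δ| ≤ 5      slight     5 < |Δ| ≤ 10
    meaningful 10 < |Δ| ≤ 20    marked   |Δ| > 20

Boundary values belong to the lower band (a deterministic half-open
convention; the printed band ranges overlap at 5, 10 and 20). QC failure
never drops an antibody — the bench rule is to re-run the instrument until
SD ≤ ±5%, which software cannot do, so the flag is surfaced instead.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InsufficientReplicatesError, UndefinedRatioError, ValidationError
from .io import ARM_CONTROL, ARM_TREATED
from .panel import PanelCatalog
from .quantify import ExpressionLevel

BANDS = ("minimal", "slight", "meaningful", "marked")

DEFAULT_HOUSEKEEPING = ("α-tubulin", "β-actin", "GAPDH")

RESULTS_COLUMNS = [
    "antibody",
    "category_label",
    "timepoint_h",
    "percent_level",
    "delta_pct",
    "sem",
    "n",
    "qc_pass",
    "band",
    "direction",
    "clamped_any",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable conventions of the expression pipeline.

    ``band_edges`` are the |Δ%| boundaries between minimal/slight/meaningful/
    marked; ``edges_to_lower`` assigns a boundary value to the lower band.
    ``variance_ddof`` = 0 uses the population variance in σ² (the SEM is
    written s = √(σ²/n) without a correction term); set 1 for sample variance.
    """

    band_edges: tuple[float, float, float] = (5.0, 10.0, 20.0)
    qc_sd_threshold: float = 5.0
    housekeeping: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    edges_to_lower: bool = True
    variance_ddof: int = 0
    min_replicates: int = 2
    max_replicates: int = 6

    def __post_init__(self) -> None:
        e = self.band_edges
        if not (0 < e[0] < e[1] < e[2]):
            raise ValidationError(f"band edges must increase from 0, got {e}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        data = dict(data or {})
        for key in ("band_edges", "housekeeping"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


class ChangeCall(NamedTuple):
    band: str
    direction: str


@dataclass(frozen=True)
class ExpressionChange:
    """Per antibody × timepoint summary across replicates."""

    antibody: str
    timepoint_h: int
    percent_level: float
    delta_pct: float
    sem: float
    n_replicates: int
    qc_pass: bool
    band: str
    direction: str
    sd: float = 0.0
    category_label: str = ""
    clamped_any: bool = False


@dataclass(frozen=True)
class AdjustmentReport:
    """Audit record of one proportional-basal-line rescale."""

    timepoint_h: int
    replicate: int
    scale_factor: float
    housekeeping_deltas_after: dict[str, float]
    within_tolerance: bool


# ---------------------------------------------------------------------------
# elementary operations


def expression_ratio(treated_level: float, control_level: float) -> float:
    """Treated expression level as a percent of the control level."""
    if control_level == 0:
        raise UndefinedRatioError(
            "control level is zero (failed control immunoprecipitation)"
        )
    return 100.0 * treated_level / control_level


def adjust_housekeeping(
    percent_levels: Mapping[str, float],
    housekeeping: Iterable[str] = DEFAULT_HOUSEKEEPING,
    tolerance_pct: float = 5.0,
    timepoint_h: int = 0,
    replicate: int = 0,
) -> tuple[dict[str, float], AdjustmentReport]:
    """Proportionally rescale a sample so the housekeeping mean is 100%.

    Every percent level in the sample is multiplied by
    k = 100 / mean(housekeeping percent levels); the ±tolerance check on each
    individual housekeeping protein is then *verified*, not forced.
    """
    hk = list(housekeeping)
    missing = [h for h in hk if h not in percent_levels]
    if missing:
        raise ValidationError(f"housekeeping antibodies missing from sample: {missing}")
    hk_levels = [percent_levels[h] for h in hk]
    if any(v <= 0 for v in hk_levels):
        raise ValidationError(f"non-positive housekeeping percent level in {hk_levels}")
    k = 100.0 / (sum(hk_levels) / len(hk_levels))
    adjusted = {ab: v * k for ab, v in percent_levels.items()}
    deltas = {h: adjusted[h] - 100.0 for h in hk}
    report = AdjustmentReport(
        timepoint_h=timepoint_h,
        replicate=replicate,
        scale_factor=k,
        housekeeping_deltas_after=deltas,
        within_tolerance=all(abs(d) < tolerance_pct for d in deltas.values()),
    )
    return adjusted, report


def aggregate_replicates(
    percent_levels: Sequence[float],
    qc_sd_threshold: float = 5.0,
    variance_ddof: int = 0,
    max_replicates: int = 6,
) -> tuple[float, float, float, bool]:
    """Mean, SD, SEM = √(σ²/n) and the SD ≤ threshold QC flag.

    σ² is the population variance by default, matching the plain s = √(σ²/n)
    standard-error convention. More than ``max_replicates`` values warns but
    still computes.
    """
    n = len(percent_levels)
    if n < 2:
        raise InsufficientReplicatesError(
            f"need at least 2 replicates for spread statistics, got {n}"
        )
    if n > max_replicates:
        warnings.warn(
            f"{n} replicates exceeds the usual maximum of {max_replicates}; "
            "computing anyway",
            stacklevel=2,
        )
    arr = np.asarray(percent_levels, dtype=float)
    mean = float(arr.mean())
    var = float(arr.var(ddof=variance_ddof))
    sd = math.sqrt(var)
    sem = math.sqrt(var / n)
    return mean, sd, sem, sd <= qc_sd_threshold


def classify_change(
    delta_pct: float, band_edges: Sequence[float] = (5.0, 10.0, 20.0)
) -> ChangeCall:
    """Band and direction of a signed percent change."""
    if not math.isfinite(delta_pct):
        raise ValidationError(f"delta_pct must be finite, got {delta_pct}")
    mag = abs(delta_pct)
    e1, e2, e3 = band_edges
    if mag <= e1:
        band = "minimal"
    elif mag <= e2:
        band = "slight"
    elif mag <= e3:
        band = "meaningful"
    else:
        band = "marked"
    direction = "none" if delta_pct == 0 else ("up" if delta_pct > 0 else "down")
    return ChangeCall(band, direction)


def filter_high_changes(
    changes: Sequence[ExpressionChange], threshold_pct: float = 10.0
) -> list[ExpressionChange]:
    """Antibodies whose |Δ%| exceeds the threshold at any analyzed timepoint.

    All timepoints of a qualifying antibody are retained; order is stable
    (input order — panel order then timepoint when built by this package).
    """
    if threshold_pct <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold_pct}")
    hot = {c.antibody for c in changes if abs(c.delta_pct) > threshold_pct}
    return [c for c in changes if c.antibody in hot]


# ---------------------------------------------------------------------------
# cohort-level pipeline


def percent_levels_by_sample(
    levels: Iterable[ExpressionLevel],
) -> dict[tuple[int, int], dict[str, float]]:
    """Pair treated with control levels replicate-by-replicate.

    Returns {(timepoint_h, replicate): {antibody: percent_level}}. Control and
    treated runs of the same replicate index form a pair (the arms are run
    sequentially on the instrument to keep them comparable).
    """
    by_key: dict[tuple[str, int, int, str], float] = {}
    for lv in levels:
        if lv.arm not in (ARM_TREATED, ARM_CONTROL):
            continue
        by_key[(lv.antibody, lv.timepoint_h, lv.replicate, lv.arm)] = lv.level
    out: dict[tuple[int, int], dict[str, float]] = {}
    for (ab, tp, rep, arm) in sorted(by_key, key=lambda k: (k[1], k[2], k[0])):
        if arm != ARM_TREATED:
            continue
        control = by_key.get((ab, tp, rep, ARM_CONTROL))
        if control is None:
            raise ValidationError(
                f"missing control run for {ab!r} at {tp} h replicate {rep}"
            )
        out.setdefault((tp, rep), {})[ab] = expression_ratio(
            by_key[(ab, tp, rep, ARM_TREATED)], control
        )
    return out


def analyze_levels(
    levels: Sequence[ExpressionLevel],
    catalog: PanelCatalog | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[list[ExpressionChange], list[AdjustmentReport]]:
    """Run the full percent/adjust/aggregate/classify pipeline on a cohort."""
    samples = percent_levels_by_sample(levels)
    reports: list[AdjustmentReport] = []
    adjusted_samples: dict[tuple[int, int], dict[str, float]] = {}
    for (tp, rep), pct in samples.items():
        adj, report = adjust_housekeeping(
            pct,
            config.housekeeping,
            tolerance_pct=config.qc_sd_threshold,
            timepoint_h=tp,
            replicate=rep,
        )
        adjusted_samples[(tp, rep)] = adj
        reports.append(report)

    clamped = {
        (lv.antibody, lv.timepoint_h)
        for lv in levels
        if lv.clamped and lv.arm in (ARM_TREATED, ARM_CONTROL)
    }

    # deterministic antibody order: panel order when a catalog is given
    antibodies: list[str] = []
    seen: set[str] = set()
    if catalog is not None:
        for name in catalog.primary_names():
            if name not in seen:
                antibodies.append(name)
                seen.add(name)
    for lv in levels:
        if lv.arm == ARM_TREATED and lv.antibody not in seen:
            antibodies.append(lv.antibody)
            seen.add(lv.antibody)

    timepoints = sorted({tp for tp, _ in adjusted_samples})
    changes: list[ExpressionChange] = []
    for ab in antibodies:
        for tp in timepoints:
            reps = [
                adjusted_samples[key][ab]
                for key in sorted(adjusted_samples)
                if key[0] == tp and ab in adjusted_samples[key]
            ]
            if not reps:
                continue
            mean, sd, sem, qc = aggregate_replicates(
                reps,
                qc_sd_threshold=config.qc_sd_threshold,
                variance_ddof=config.variance_ddof,
                max_replicates=config.max_replicates,
            )
            delta = mean - 100.0
            call = classify_change(delta, config.band_edges)
            changes.append(
                ExpressionChange(
                    antibody=ab,
                    timepoint_h=tp,
                    percent_level=mean,
                    delta_pct=delta,
                    sem=sem,
                    n_replicates=len(reps),
                    qc_pass=qc and len(reps) >= config.min_replicates,
                    band=call.band,
                    direction=call.direction,
                    sd=sd,
                    category_label=(
                        catalog.primary_category_of(ab) or "" if catalog else ""
                    ),
                    clamped_any=(ab, tp) in clamped,
                )
            )
    return changes, reports


def changes_to_frame(changes: Sequence[ExpressionChange]) -> pd.DataFrame:
    rows = [
        {
            "antibody": c.antibody,
            "category_label": c.category_label,
            "timepoint_h": c.timepoint_h,
            "percent_level": c.percent_level,
            "delta_pct": c.delta_pct,
            "sem": c.sem,
            "n": c.n_replicates,
            "qc_pass": c.qc_pass,
            "band": c.band,
            "direction": c.direction,
            "clamped_any": c.clamped_any,
        }
        for c in changes
    ]
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)
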