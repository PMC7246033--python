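"""In situ proliferation index from paired cell counts.

Cells are counted on the same photographed dish areas before and after a
culture interval (24 or 48 h), across ten representative image fields per
arm. The per-field index is the growth expressed as a percent of the initial
count, 100 × (final − initial)/initial; an arm's index is the unweighted mean
across fields, with the SD across fields reported as dispersion. The
treated-vs-control effect is the percentage-point difference of the two arm
means, reported to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

COUNT_COLUMNS = ["arm", "field_id", "duration_h", "initial_count", "final_count"]


@dataclass(frozen=True)
class CellCountRecord:
    arm: str
    field_id: str
    duration_h: int
    initial_count: int
    final_count: int

    def __post_init__(self) -> None:
        if self.initial_count < 0 or self.final_count < 0:
            raise ValidationError(
                f"{self.field_id}: cell counts must be non-negative integers"
            )
        if self.duration_h not in (24, 48):
            raise ValidationError(
                f"{self.field_id}: duration_h must be 24 or 48, got {self.duration_h}"
            )


@dataclass(frozen=True)
class ProliferationSummary:
    arm: str
    duration_h: int
    index_pct: float  # mean per-field index
    dispersion: float  # SD across fields (not an SEM)
    n_fields: int


def proliferation_index(initial_count: int, final_count: int) -> float:
    """100 × (final − initial) / initial, percent growth over the interval."""
    if initial_count <= 0:
        raise ValidationError(
            f"initial count must be positive, got {initial_count}"
        )
    return 100.0 * (final_count - initial_count) / initial_count


def summarize_counts(
    records: list[CellCountRecord], arm: str, duration_h: int, pooled: bool = False
) -> ProliferationSummary:
    """Summarize one arm × duration: mean of per-field indices (default) or,
    with ``pooled=True``, the index of the summed counts."""
    sel = [r for r in records if r.arm == arm and r.duration_h == duration_h]
    if not sel:
        raise ValidationError(f"no records for arm={arm!r}, duration={duration_h} h")
    indices = np.array(
        [proliferation_index(r.initial_count, r.final_count) for r in sel]
    )
    if pooled:
        index = proliferation_index(
            sum(r.initial_count for r in sel), sum(r.final_count for r in sel)
        )
    else:
        index = float(indices.mean())
    dispersion = float(indices.std(ddof=1)) if len(sel) > 1 else 0.0
    return ProliferationSummary(
        arm=arm,
        duration_h=duration_h,
        index_pct=index,
        dispersion=dispersion,
        n_fields=len(sel),
    )


def index_difference(
    treated: ProliferationSummary, control: ProliferationSummary
) -> float:
    """Treated − control mean index, in percentage points, to one decimal."""
    if treated.duration_h != control.duration_h:
        raise ValidationError(
            f"duration mismatch: {treated.duration_h} h vs {control.duration_h} h"
        )
    return round(treated.index_pct - control.index_pct, 1)


def read_cell_counts(path: str | Path) -> list[CellCountRecord]:
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CellCountRecord(
            arm=str(r.arm),
            field_id=str(r.field_id),
            duration_h=int(r.duration_h),
            initial_count=int(r.initial_count),
            final_count=int(r.final_count),
        )
        for r in df.itertuples()
    ]


def write_summaries(
    summaries: list[ProliferationSummary], path: str | Path
) -> Path:
    df = pd.DataFrame(
        [
            {
                "arm": s.arm,
                "duration_h": s.duration_h,
                "index_pct": s.index_pct,
                "dispersion_sd": s.dispersion,
                "n_fields": s.n_fields,
            }
            for s in summaries
        ]
    )
    df.to_csv(path, index=False)
    return Path(path)
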