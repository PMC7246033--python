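"""Chromatogram trace and manifest I/O.

A trace file is plain CSV with ``# key: value`` header comments carrying the
run identity and instrument metadata, followed by two columns
``time_min,absorbance_mAU``. One file holds one HPLC run — a single
(antibody, arm, timepoint, replicate) combination; a cohort is tied together
by a manifest CSV. Negative-control runs carry the reserved antibody label
``NEG_CONTROL`` and no timepoint.

The instrument settings mirrored by the metadata defaults are UV detection at
280 nm and a 0.4 mL/min mobile phase over a 30 min run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TraceError, WindowError

ARM_TREATED = "treated"
ARM_CONTROL = "control"
ARM_NEGATIVE = "negative_control"
ARMS = (ARM_TREATED, ARM_CONTROL, ARM_NEGATIVE)

NEG_CONTROL_LABEL = "NEG_CONTROL"

TIMEPOINTS_H = (12, 24, 48)

MANIFEST_COLUMNS = ["path", "sample_id", "antibody", "arm", "timepoint_h", "replicate"]


@dataclass
class ChromatogramTrace:
    """One UV-absorbance elution profile (minutes vs. mAU at 280 nm)."""

    sample_id: str
    antibody: str
    arm: str
    timepoint_h: int | None
    replicate: int
    time_min: np.ndarray
    absorbance_mAU: np.ndarray
    wavelength_nm: float = 280.0
    flow_mL_min: float = 0.4
    duration_min: float = 30.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.absorbance_mAU = np.asarray(self.absorbance_mAU, dtype=float)
        if self.arm not in ARMS:
            raise TraceError(f"{self.sample_id}: unknown arm {self.arm!r}")
        if self.arm == ARM_NEGATIVE:
            if self.timepoint_h is not None:
                raise TraceError(
                    f"{self.sample_id}: negative-control runs carry no timepoint"
                )
        elif self.timepoint_h not in TIMEPOINTS_H:
            raise TraceError(
                f"{self.sample_id}: timepoint_h must be one of {TIMEPOINTS_H}, "
                f"got {self.timepoint_h!r}"
            )
        if not self.antibody:
            raise TraceError(f"{self.sample_id}: antibody identity missing")
        if self.replicate < 1:
            raise TraceError(f"{self.sample_id}: replicate must be a positive integer")
        if self.time_min.ndim != 1 or self.time_min.shape != self.absorbance_mAU.shape:
            raise TraceError(
                f"{self.sample_id}: time and absorbance series must be equal-length 1-D"
            )
        if self.time_min.size < 2:
            raise TraceError(f"{self.sample_id}: trace needs at least 2 samples")
        if not np.all(np.diff(self.time_min) > 0):
            raise TraceError(f"{self.sample_id}: time grid must be strictly increasing")
        if self.time_min[0] < -1e-12 or (
            self.time_min[-1] - self.time_min[0]
        ) > 30.0 + 1e-9:
            raise TraceError(
                f"{self.sample_id}: elution times must lie in a 0-30 min run"
            )
        if not np.all(np.isfinite(self.absorbance_mAU)):
            raise TraceError(f"{self.sample_id}: absorbance values must be finite")

    def scaled(self, factor: float) -> "ChromatogramTrace":
        """Copy with absorbance multiplied by ``factor`` (detector-gain change)."""
        return replace(self, absorbance_mAU=self.absorbance_mAU * factor)


@dataclass(frozen=True)
class PeakWindow:
    """Elution-time window [start_min, end_min] for baseline and integration."""

    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.start_min < self.end_min:
            raise WindowError(
                f"window start {self.start_min} must precede end {self.end_min}"
            )

    def check_within(self, trace: ChromatogramTrace) -> None:
        if self.start_min < trace.time_min[0] - 1e-12 or (
            self.end_min > trace.time_min[-1] + 1e-12
        ):
            raise WindowError(
                f"window [{self.start_min}, {self.end_min}] min outside trace range "
                f"[{trace.time_min[0]}, {trace.time_min[-1]}] min"
            )


@dataclass(frozen=True)
class PeakAreaRecord:
    """Integrated peak area for one run, with its provenance."""

    sample_id: str
    antibody: str
    arm: str
    timepoint_h: int | None
    replicate: int
    raw_area_mAU_s: float
    window: PeakWindow
    baseline_model: str = "linear-endpoints"

    def __post_init__(self) -> None:
        if self.raw_area_mAU_s < 0:
            raise TraceError(
                f"{self.sample_id}: peak area must be non-negative, "
                f"got {self.raw_area_mAU_s}"
            )


# ---------------------------------------------------------------------------
# trace files


def write_trace(trace: ChromatogramTrace, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# sample_id: {trace.sample_id}",
        f"# antibody: {trace.antibody}",
        f"# arm: {trace.arm}",
    ]
    if trace.timepoint_h is not None:
        lines.append(f"# timepoint_h: {trace.timepoint_h}")
    lines += [
        f"# replicate: {trace.replicate}",
        f"# wavelength_nm: {trace.wavelength_nm:g}",
        f"# flow_mL_min: {trace.flow_mL_min:g}",
        f"# duration_min: {trace.duration_min:g}",
        "time_min,absorbance_mAU",
    ]
    # 9 significant digits keeps the round trip well under 1e-6 relative error
    for t, a in zip(trace.time_min, trace.absorbance_mAU):
        lines.append(f"{t:.9g},{a:.9g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_trace(path: str | Path) -> ChromatogramTrace:
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    absorb: list[float] = []
    header_seen = False
    for lineno, ln in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        s = ln.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            header_seen = True  # column-name line; names are informational
            continue
        parts = s.split(",")
        if len(parts) != 2:
            raise TraceError(f"{path}:{lineno}: expected two columns, got {s!r}")
        try:
            times.append(float(parts[0]))
            absorb.append(float(parts[1]))
        except ValueError as exc:
            raise TraceError(f"{path}:{lineno}: non-numeric value in {s!r}") from exc
    required = {"sample_id", "antibody", "arm", "replicate"}
    missing = required - set(meta)
    if missing:
        raise TraceError(f"{path}: missing identity fields {sorted(missing)}")
    tp = meta.get("timepoint_h")
    return ChromatogramTrace(
        sample_id=meta["sample_id"],
        antibody=meta["antibody"],
        arm=meta["arm"],
        timepoint_h=int(tp) if tp not in (None, "", "NA") else None,
        replicate=int(meta["replicate"]),
        time_min=np.array(times),
        absorbance_mAU=np.array(absorb),
        wavelength_nm=float(meta.get("wavelength_nm", 280.0)),
        flow_mL_min=float(meta.get("flow_mL_min", 0.4)),
        duration_min=float(meta.get("duration_min", 30.0)),
    )


# ---------------------------------------------------------------------------
# manifests


def write_manifest(records: Sequence[dict] | pd.DataFrame, path: str | Path) -> Path:
    df = pd.DataFrame(records, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"timepoint_h": "Int64"})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TraceError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def read_cohort(manifest_path: str | Path) -> list[ChromatogramTrace]:
    """Read every trace a manifest lists; paths resolve next to the manifest."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    traces = []
    for p in df["path"]:
        fp = Path(p)
        if not fp.is_absolute():
            fp = manifest_path.parent / fp
        traces.append(read_trace(fp))
    return traces
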