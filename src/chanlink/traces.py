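"""Trace containers and the normalization pipeline for TEVC recordings.

Implements the study's normalization chain: piecewise-linear baseline
subtraction anchored on pre-pulse windows (drift correction), peak
quantification per pulse, a linear fit to the PTX-bookend peak amplitudes
(rundown correction), and per-oocyte summary ratios
I_PTX/I_GABA-max and I_DZ-max/I_PTX.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from .exceptions import (BaselineWindowError, PeakWindowError, ProtocolError,
                         RundownError)
from .protocol import PulseEvent, validate_protocol

__all__ = [
    "Trace", "PeakRecord", "OocyteSummary", "subtract_baseline",
    "extract_peaks", "RundownFit", "fit_rundown", "correct_peaks",
    "summarize_oocyte", "process_trace", "peaks_frame", "summaries_frame",
    "read_trace", "write_trace",
]


@dataclass
class Trace:
    """One oocyte's current time series plus its pulse protocol.

    time in seconds (strictly increasing, uniform to 1%), current in nA.
    Sign convention: the stored current is the deflection from holding;
    downstream analysis operates on peak magnitudes.
    """

    oocyte_id: str
    construct_id: str
    time: np.ndarray
    current: np.ndarray
    protocol: List[PulseEvent]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be 1-D arrays of equal length")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if dt.size and (dt.max() - dt.min()) > 0.01 * dt.mean():
            raise ValueError("sampling must be uniform to within 1%")
        validate_protocol(self.protocol)
        for ev in self.protocol:
            if ev.t_start < self.time[0] - 1e-9 or ev.t_end > self.time[-1] + 1e-9:
                raise ProtocolError(
                    f"{ev.ligand} pulse at {ev.t_start} s lies outside the trace span"
                )

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def copy_with(self, current: np.ndarray) -> "Trace":
        return Trace(self.oocyte_id, self.construct_id, self.time.copy(),
                     np.asarray(current, dtype=float), list(self.protocol))


@dataclass(frozen=True)
class PeakRecord:
    """Quantified response of one pulse."""

    pulse_index: int
    ligand: str
    concentration: float
    raw_peak: float
    t_peak: float
    corrected_peak: Optional[float] = None


@dataclass(frozen=True)
class OocyteSummary:
    """Per-oocyte amplitude statistics and ratio estimates.

    I_PTX is the mean magnitude of the corrected PTX-blockable current
    (spontaneous activity). I_GABA_max / I_DZ_max are maximal currents
    referenced to the true zero-current level revealed by PTX block: the
    corrected evoked deflection at the highest non-excluded agonist
    concentration plus I_PTX. With currents proportional to open
    probability this makes I_PTX/I_GABA_max -> Po(0)/Po(GABA_max) and
    I_DZ_max/I_PTX -> Po(DZ_max)/Po(0). Ratios are None when a required
    quantity is missing or zero (never infinite).
    """

    oocyte_id: str
    construct_id: str
    I_PTX: float
    I_GABA_max: Optional[float] = None
    I_DZ_max: Optional[float] = None
    r_ptx_gaba: Optional[float] = None
    r_dz_ptx: Optional[float] = None


def subtract_baseline(trace: Trace, window: float = 5.0) -> Trace:
    """Remove drift via a piecewise-linear baseline through pre-pulse windows.

    For every pulse the mean current over the ``window`` seconds immediately
    before pulse onset anchors the baseline; anchors are joined by linear
    interpolation (linearly extrapolated at the ends) and subtracted from the
    whole trace. Windows containing another pulse are rejected.
    """
    if window <= 0:
        raise BaselineWindowError("window must be > 0")
    t = trace.time
    anchors_t, anchors_y = [], []
    for ev in trace.protocol:
        w0, w1 = ev.t_start - window, ev.t_start
        if w0 < t[0] - 1e-9:
            raise BaselineWindowError(
                f"baseline window before {ev.ligand} pulse at {ev.t_start} s "
                "starts before the trace"
            )
        for other in trace.protocol:
            if other is ev:
                continue
            if other.t_start < w1 and other.t_end > w0:
                raise BaselineWindowError(
                    f"baseline window ({w0:.1f}-{w1:.1f} s) overlaps the "
                    f"{other.ligand} pulse at {other.t_start} s; shorten the window"
                )
        mask = (t >= w0) & (t < w1)
        if not mask.any():
            raise BaselineWindowError("baseline window contains no samples")
        # anchor at the window's center of mass so a linear drift is
        # reproduced exactly by the interpolant
        anchors_t.append(float(t[mask].mean()))
        anchors_y.append(float(trace.current[mask].mean()))
    if len(anchors_t) == 1:
        baseline = np.full_like(t, anchors_y[0])
    else:
        f = interp1d(anchors_t, anchors_y, kind="linear", fill_value="extrapolate",
                     assume_sorted=True)
        baseline = f(t)
    return trace.copy_with(trace.current - baseline)


def extract_peaks(trace: Trace, grace: float = 1.0, smooth: float = 0.1,
                  peak_avg: float = 1.0) -> List[PeakRecord]:
    """Quantify each pulse response on a baseline-subtracted trace.

    The response location (t_peak) is the signed extremum of the
    moving-average-smoothed trace within [t_start, t_end + grace] (grace
    covers slow solution exchange), clipped to the trace. With the default
    ``peak_avg`` the amplitude is the mean current over the final
    ``peak_avg`` seconds of the drug application: for responses that rise
    mono-exponentially to a plateau well within the pulse this equals the
    peak while avoiding the upward bias an extremum estimator takes from
    picking the largest noise excursion. ``peak_avg=0`` reverts to the raw
    smoothed extremum value.
    """
    t = trace.time
    k = max(int(round(smooth * trace.sample_rate)), 1)
    sm = np.convolve(trace.current, np.ones(k) / k, mode="same")
    records = []
    for idx, ev in enumerate(trace.protocol):
        if ev.t_start < t[0] - 1e-9 or ev.t_start > t[-1]:
            raise PeakWindowError(f"pulse {idx} starts outside the trace")
        w1 = min(ev.t_end + grace, t[-1])
        mask = (t >= ev.t_start) & (t <= w1)
        seg = sm[mask]
        tseg = t[mask]
        if seg.size == 0:
            raise PeakWindowError(f"pulse {idx} window contains no samples")
        i = int(np.argmax(np.abs(seg)))
        if peak_avg > 0:
            p0 = max(ev.t_end - peak_avg, ev.t_start)
            pmask = (t >= p0) & (t < ev.t_end)
            value = float(trace.current[pmask].mean()) if pmask.any() else float(seg[i])
        else:
            value = float(seg[i])
        records.append(PeakRecord(idx, ev.ligand, ev.concentration,
                                  value, float(tseg[i])))
    return records


@dataclass(frozen=True)
class RundownFit:
    """Linear rundown scale s(t), normalized to 1 at the first PTX peak."""

    slope: float
    intercept: float
    t_ref: float
    a_ref: float

    def scale(self, t):
        return (self.intercept + self.slope * np.asarray(t, dtype=float)) / self.a_ref

    def apply(self, peaks: Sequence[PeakRecord]) -> List[PeakRecord]:
        return [replace(p, corrected_peak=p.raw_peak / float(self.scale(p.t_peak)))
                for p in peaks]


def fit_rundown(peaks: Sequence[PeakRecord]) -> RundownFit:
    """Least-squares line through the PTX peak magnitudes versus time.

    Requires >= 2 PTX peaks; a fitted line that reaches zero or below within
    the span of the recorded peaks is rejected as pathological rundown.
    """
    ptx = [p for p in peaks if p.ligand == "PTX"]
    if len(ptx) < 2:
        raise RundownError(f"rundown correction needs >= 2 PTX peaks, got {len(ptx)}")
    tp = np.array([p.t_peak for p in ptx])
    ap = np.abs([p.raw_peak for p in ptx])
    slope, intercept = np.polyfit(tp, ap, 1)
    a_ref = intercept + slope * tp[0]
    t_all = [p.t_peak for p in peaks]
    span = (intercept + slope * np.array([min(t_all), max(t_all)]))
    if a_ref <= 0 or np.any(span <= 0):
        raise RundownError(
            "fitted PTX rundown line crosses zero inside the recording; "
            "cannot rescale peaks"
        )
    return RundownFit(float(slope), float(intercept), float(tp[0]), float(a_ref))


def correct_peaks(peaks: Sequence[PeakRecord], bookend_tol: float = 0.05) -> List[PeakRecord]:
    """Fit and apply the rundown correction.

    After correction the first and last PTX peak magnitudes should agree;
    a relative mismatch above ``bookend_tol`` (possible only with >2 PTX
    pulses, where the line is a genuine fit) raises a warning.
    """
    fit = fit_rundown(peaks)
    corrected = fit.apply(peaks)
    ptx = [p for p in corrected if p.ligand == "PTX"]
    first, last = abs(ptx[0].corrected_peak), abs(ptx[-1].corrected_peak)
    if first > 0 and abs(last - first) / first > bookend_tol:
        warnings.warn(
            f"corrected PTX bookends differ by {abs(last - first) / first:.1%} "
            f"(tolerance {bookend_tol:.1%})", stacklevel=2)
    return corrected


def summarize_oocyte(
    peaks: Sequence[PeakRecord],
    oocyte_id: str = "",
    construct_id: str = "",
    exclude_conc: Sequence[float] = (),
) -> OocyteSummary:
    """Per-oocyte summary ratios from corrected peaks.

    Evoked peaks are measured as deflections from the spontaneous-current
    baseline, but the maximal-current ratios reference currents to the
    zero-current level revealed by PTX block, so the "maximal" current is
    the corrected deflection at the highest retained agonist concentration
    (measured-peak convention) plus the spontaneous I_PTX. ``exclude_conc``
    implements the dropping of suppressed top-concentration responses.
    Ratios are None when undefined rather than infinite.
    """
    if any(p.corrected_peak is None for p in peaks):
        raise ValueError("peaks must be rundown-corrected before summarizing")
    ptx = [p for p in peaks if p.ligand == "PTX"]
    if not ptx:
        raise ValueError("at least one PTX pulse is required")
    I_ptx = float(np.mean([abs(p.corrected_peak) for p in ptx]))

    def top_peak(ligand: str) -> Optional[float]:
        cands = [p for p in peaks if p.ligand == ligand
                 and not any(np.isclose(p.concentration, c, rtol=1e-6, atol=0.0)
                             for c in exclude_conc)]
        if not cands:
            return None
        top = max(cands, key=lambda p: p.concentration)
        return abs(top.corrected_peak) + I_ptx

    I_gaba = top_peak("GABA")
    I_dz = top_peak("DZ")
    r_pg = I_ptx / I_gaba if (I_gaba is not None and I_gaba > 0) else None
    r_dp = I_dz / I_ptx if (I_dz is not None and I_ptx > 0) else None
    return OocyteSummary(oocyte_id, construct_id, I_ptx, I_gaba, I_dz, r_pg, r_dp)


def process_trace(
    trace: Trace,
    window: float = 5.0,
    grace: float = 1.0,
    smooth: float = 0.1,
    peak_avg: float = 1.0,
    exclude_conc: Sequence[float] = (),
    on_rundown_error: str = "raise",
) -> tuple:
    """Full per-trace pipeline: baseline -> peaks -> rundown -> summary.

    ``on_rundown_error="identity"`` falls back to uncorrected peaks when the
    rundown fit is impossible (e.g. wild-type oocytes whose PTX-sensitive
    current is within the noise).

    Returns (peaks, summary).
    """
    corrected_trace = subtract_baseline(trace, window=window)
    raw = extract_peaks(corrected_trace, grace=grace, smooth=smooth,
                        peak_avg=peak_avg)
    try:
        peaks = correct_peaks(raw)
    except RundownError:
        if on_rundown_error != "identity":
            raise
        peaks = [replace(p, corrected_peak=p.raw_peak) for p in raw]
    summary = summarize_oocyte(peaks, trace.oocyte_id, trace.construct_id,
                               exclude_conc=exclude_conc)
    return peaks, summary


# ---------------------------------------------------------------------------
# Tabular / file IO
# ---------------------------------------------------------------------------

def peaks_frame(oocyte_id: str, construct_id: str, peaks: Sequence[PeakRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(oocyte_id=oocyte_id, construct_id=construct_id, pulse_index=p.pulse_index,
             ligand=p.ligand, concentration_M=p.concentration,
             raw_peak_nA=p.raw_peak, corrected_peak_nA=p.corrected_peak,
             t_peak_s=p.t_peak)
        for p in peaks
    ])


def summaries_frame(summaries: Sequence[OocyteSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(oocyte_id=s.oocyte_id, construct_id=s.construct_id, I_PTX_nA=s.I_PTX,
             I_GABA_max_nA=s.I_GABA_max, I_DZ_max_nA=s.I_DZ_max,
             r_ptx_gaba=s.r_ptx_gaba, r_dz_ptx=s.r_dz_ptx)
        for s in summaries
    ])


def write_trace(trace: Trace, directory) -> Path:
    """Write a trace as two-column CSV plus a JSON protocol sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{trace.oocyte_id}.csv"
    pd.DataFrame({"time_s": trace.time, "current_nA": trace.current}).to_csv(
        csv_path, index=False, float_format="%.6f")
    sidecar = dict(
        oocyte_id=trace.oocyte_id,
        construct_id=trace.construct_id,
        protocol=[ev.to_dict() for ev in trace.protocol],
    )
    (directory / f"{trace.oocyte_id}.protocol.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path


def read_trace(csv_path) -> Trace:
    """Read a trace CSV written by :func:`write_trace` (sidecar required)."""
    csv_path = Path(csv_path)
    sidecar = json.loads(
        (csv_path.parent / f"{csv_path.stem}.protocol.json").read_text())
    df = pd.read_csv(csv_path)
    protocol = [PulseEvent.from_dict(d) for d in sidecar["protocol"]]
    return Trace(sidecar["oocyte_id"], sidecar["construct_id"],
                 df["time_s"].to_numpy(), df["current_nA"].to_numpy(), protocol)
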