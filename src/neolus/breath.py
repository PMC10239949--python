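"""Respiratory metrics from intrapleural / tracheal pressure traces.

Spontaneous inspiration appears as a negative-going deflection of the
intrapleural pressure; breaths are segmented by locating these inspiratory
troughs and the end-expiratory plateaus between them.  Derived metrics are
the respiratory rate (60 / mean breath length), the coefficient of variation
of breath length within a window (a marker of breathing regularity), and the
intrapleural pressure swing from end-inspiration to end-expiration (a marker
of respiratory effort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PressureTrace",
    "Breath",
    "segment_breaths",
    "respiratory_rate",
    "breath_length_cov",
    "ip_swing",
    "timepoint_snapshot",
    "five_breath_blocks",
    "DEFAULT_APNOEA_GAP_S",
]

#: Inter-breath gap (s) above which the pause is reported as an apnoea
#: rather than folded into a breath length.
DEFAULT_APNOEA_GAP_S = 10.0


@dataclass
class PressureTrace:
    """Dual-channel pressure recording (cmH2O) at a fixed sample rate."""

    sample_rate: float
    intrapleural: np.ndarray
    tracheal: np.ndarray
    t0_min: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        ip = np.asarray(self.intrapleural, dtype=float)
        tr = np.asarray(self.tracheal, dtype=float)
        if ip.ndim != 1 or tr.shape != ip.shape:
            raise ValueError("channels must be equal-length 1-D arrays")
        self.intrapleural = ip
        self.tracheal = tr

    @property
    def n_samples(self) -> int:
        return self.intrapleural.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class Breath:
    """One segmented breath (sample indices into the trace)."""

    start: int
    peak_inspiration: int
    end: int
    length_s: float
    ip_swing_cmh2o: float

    def __post_init__(self) -> None:
        if not self.start < self.peak_inspiration < self.end:
            raise ValueError("breath requires start < peak < end")
        if self.length_s <= 0:
            raise ValueError("breath length must be positive")


def segment_breaths(
    trace: PressureTrace,
    min_period_s: float = 0.3,
    prominence_cmh2o: float | None = None,
    max_gap_s: float = DEFAULT_APNOEA_GAP_S,
) -> list[Breath]:
    """Segment breaths from the intrapleural channel.

    Inspiratory troughs are detected with a minimum spacing ``min_period_s``
    and a prominence that defaults to 25% of the trace's robust swing
    amplitude (2.5th-97.5th intensity percentile range).  Breath boundaries
    sit at the end-expiratory maxima between successive troughs.  Pauses
    longer than ``max_gap_s`` are treated as apnoeic gaps: no breath spans
    them and the flanking breath boundaries stay local to their own troughs.

    A flat trace yields an empty list.
    """
    ip = trace.intrapleural
    fs = trace.sample_rate
    if ip.size < 2 * int(min_period_s * fs) + 2:
        raise ValueError("trace too short for the requested minimum period")
    robust_swing = float(np.percentile(ip, 97.5) - np.percentile(ip, 2.5))
    if robust_swing <= 1e-9:
        return []
    prom = prominence_cmh2o if prominence_cmh2o is not None else 0.25 * robust_swing
    troughs, _ = signal.find_peaks(-ip, distance=max(1, int(min_period_s * fs)), prominence=prom)
    if troughs.size < 1:
        return []

    intervals = np.diff(troughs) / fs
    short = intervals[intervals <= max_gap_s]
    typical = float(np.median(short)) if short.size else float(np.median(intervals))

    def _boundary(lo: int, hi: int) -> int | None:
        """End-expiratory maximum in the open sample interval (lo, hi)."""
        if hi - lo < 2:
            return None
        seg = ip[lo + 1 : hi]
        return lo + 1 + int(np.argmax(seg))

    half = max(1, int(0.75 * typical * fs))
    breaths: list[Breath] = []
    # breath k spans trough k to trough k+1; its length is the inspiratory
    # period, which is edge-clean, and pauses longer than max_gap_s form no
    # breath at all
    for k in range(len(troughs) - 1):
        peak = troughs[k]
        if (troughs[k + 1] - peak) / fs > max_gap_s:
            continue
        if k == 0:
            lo = max(-1, peak - half - 1)
        else:
            gap = (peak - troughs[k - 1]) / fs
            lo = troughs[k - 1] if gap <= max_gap_s else max(troughs[k - 1], peak - half - 1)
        start = _boundary(lo, peak)
        end = _boundary(peak, troughs[k + 1])
        if start is None or end is None:
            continue
        length = (troughs[k + 1] - peak) / fs
        swing = float(max(ip[start], ip[end]) - ip[peak])
        breaths.append(
            Breath(
                start=int(start),
                peak_inspiration=int(peak),
                end=int(end),
                length_s=length,
                ip_swing_cmh2o=swing,
            )
        )
    return breaths


def _in_window(breaths: list[Breath], fs: float, window_s: tuple[float, float] | None) -> list[Breath]:
    if window_s is None:
        return list(breaths)
    lo, hi = window_s
    return [b for b in breaths if lo <= b.peak_inspiration / fs <= hi]


def respiratory_rate(
    breaths: list[Breath],
    sample_rate: float | None = None,
    window_s: tuple[float, float] | None = None,
) -> float:
    """Respiratory rate (breaths/min) as 60 / mean breath length.

    Returns NaN if the window holds no breaths.
    """
    if window_s is not None and sample_rate is None:
        raise ValueError("sample_rate is required to apply a time window")
    sel = _in_window(breaths, sample_rate or 1.0, window_s)
    if not sel:
        return float("nan")
    return 60.0 / float(np.mean([b.length_s for b in sel]))


def breath_length_cov(
    breaths: list[Breath],
    sample_rate: float | None = None,
    window_s: tuple[float, float] | None = None,
) -> float:
    """Coefficient of variation (sample SD / mean) of breath lengths.

    Requires >= 2 breaths in the window; otherwise NaN.
    """
    if window_s is not None and sample_rate is None:
        raise ValueError("sample_rate is required to apply a time window")
    sel = _in_window(breaths, sample_rate or 1.0, window_s)
    if len(sel) < 2:
        return float("nan")
    lengths = np.array([b.length_s for b in sel])
    return float(lengths.std(ddof=1) / lengths.mean())


def ip_swing(breath: Breath, trace: PressureTrace) -> float:
    """Intrapleural pressure change from end-inspiration to end-expiration.

    Positive magnitude of the deflection: the end-expiratory level within the
    breath minus the pressure at peak inspiration.
    """
    ip = trace.intrapleural
    plateau = float(ip[breath.start : breath.end + 1].max())
    return plateau - float(ip[breath.peak_inspiration])


def timepoint_snapshot(
    trace: PressureTrace,
    t_min: float,
    half_width_min: float = 1.0,
    avg_window_s: float = 5.0,
) -> dict[str, float]:
    """Breath metrics in the cleanest short window around an imaging time.

    Scans ``avg_window_s``-long sub-windows within +/- ``half_width_min`` of
    ``t_min`` (minutes on the trace's clock), scores each by its band-limited
    (> 10 Hz) energy on the intrapleural channel, and averages per-breath
    metrics in the quietest one — avoiding movement/vocalisation artefacts,
    which are broadband bursts.  Returns NaNs with a warning if the chosen
    window contains no breaths.
    """
    fs = trace.sample_rate
    centre_s = (t_min - trace.t0_min) * 60.0
    lo_s = centre_s - 60.0 * half_width_min
    hi_s = centre_s + 60.0 * half_width_min
    if hi_s < 0 or lo_s > trace.duration_s:
        raise ValueError("snapshot window lies outside the trace")
    lo_s, hi_s = max(0.0, lo_s), min(trace.duration_s, hi_s)
    if hi_s - lo_s < avg_window_s:
        raise ValueError("snapshot window shorter than the averaging window")

    if fs > 24.0:
        sos = signal.butter(4, 10.0, btype="highpass", fs=fs, output="sos")
        hf = signal.sosfiltfilt(sos, trace.intrapleural)
    else:  # Nyquist too low for a 10 Hz cut: fall back to first differences
        hf = np.diff(trace.intrapleural, prepend=trace.intrapleural[0])

    step = max(1, int(0.5 * fs))
    wlen = int(avg_window_s * fs)
    starts = np.arange(int(lo_s * fs), int(hi_s * fs) - wlen + 1, step)
    energies = [float(np.sum(hf[s : s + wlen] ** 2)) for s in starts]
    best = int(starts[int(np.argmin(energies))])
    win = (best / fs, (best + wlen) / fs)

    breaths = segment_breaths(trace)
    sel = _in_window(breaths, fs, win)
    if not sel:
        warnings.warn(
            f"no clean breaths found near t={t_min} min; snapshot is missing",
            stacklevel=2,
        )
        keys = (
            "rate_bpm",
            "ip_peak_insp_cmh2o",
            "ip_end_exp_cmh2o",
            "trach_peak_insp_cmh2o",
            "trach_end_exp_cmh2o",
        )
        return {k: float("nan") for k in keys} | {"window_start_s": win[0]}
    ip, tr = trace.intrapleural, trace.tracheal
    peaks = [b.peak_inspiration for b in sel]
    ends = [b.end for b in sel]
    return {
        "rate_bpm": respiratory_rate(sel),
        "ip_peak_insp_cmh2o": float(np.mean(ip[peaks])),
        "ip_end_exp_cmh2o": float(np.mean(ip[ends])),
        "trach_peak_insp_cmh2o": float(np.mean(tr[peaks])),
        "trach_end_exp_cmh2o": float(np.mean(tr[ends])),
        "window_start_s": win[0],
    }


def five_breath_blocks(
    trace: PressureTrace,
    event_time_s: float,
    n_after: int = 30,
    block_size: int = 5,
) -> pd.DataFrame:
    """Block-wise breath metrics around a gas-flow change.

    Returns one pre-event block (the last ``block_size`` breaths before the
    event) and consecutive non-overlapping ``block_size``-breath blocks
    covering the first ``n_after`` breaths after it (6 post blocks for the
    defaults).  Per block: respiratory rate, breath-length CoV and mean
    intrapleural swing.  Truncates with a warning if breaths run out.
    """
    fs = trace.sample_rate
    breaths = segment_breaths(trace)
    # the breath straddling the event belongs to neither side
    before = [b for b in breaths if b.end / fs < event_time_s]
    after = [b for b in breaths if b.peak_inspiration / fs >= event_time_s]
    if len(before) < block_size or len(after) < n_after:
        warnings.warn(
            f"insufficient breaths around event ({len(before)} before, "
            f"{len(after)} after); blocks truncated",
            stacklevel=2,
        )
    blocks: list[tuple[str, list[Breath]]] = []
    pre = before[-block_size:]
    if pre:
        blocks.append(("pre", pre))
    post = after[:n_after]
    for k in range(0, len(post), block_size):
        chunk = post[k : k + block_size]
        if chunk:
            blocks.append((f"post{k // block_size + 1}", chunk))
    rows = []
    for label, chunk in blocks:
        rows.append(
            {
                "block": label,
                "n_breaths": len(chunk),
                "rate_bpm": respiratory_rate(chunk),
                "breath_length_cov": breath_length_cov(chunk),
                "ip_swing_cmh2o": float(np.mean([b.ip_swing_cmh2o for b in chunk])),
            }
        )
    return pd.DataFrame(rows)
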