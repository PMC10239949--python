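"""Ordinal lung-ultrasound grading and backsliding detection.

The ordinal grade describes the appearance of a lung-ultrasound image during
the transition to air breathing:

* 0   — "hepatisation": the beam meets no air; liquid and soft tissue only.
* 0.5 — "speckled", patchy pleural line before the pleural line establishes.
* 1   — "white-out" lung, associated with respiratory distress syndrome.
* 2   — vertical B-lines from the pleural line with some horizontal A-lines.
* 3   — horizontal A-lines: reverberation between transducer and aerated lung.

"Backsliding" is a deterioration of lung aeration between consecutive scans:
either a reduction of the grade, or a drop of the estimated proportion of air
(EPA) by more than a threshold (default 0.2) in either lung.  It is *severe*
when the grade falls to 1 or worse, or when an EPA drop leaves the mean EPA
of both lungs below 0.6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GRADE_VALUES",
    "LUSGrade",
    "LambTimeline",
    "BackslidingEvent",
    "median_grade",
    "percent_agreement",
    "detect_backsliding",
    "count_backsliding",
    "ClipFeatures",
    "extract_clip_features",
    "rule_based_grade",
    "GradeRuleConfig",
]

GRADE_VALUES = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class LUSGrade:
    """One ordinal lung-ultrasound grade in {0, 0.5, 1, 2, 3}."""

    value: float

    def __post_init__(self) -> None:
        if float(self.value) not in GRADE_VALUES:
            raise ValueError(f"grade must be one of {GRADE_VALUES}, got {self.value}")

    def __float__(self) -> float:
        return float(self.value)


def _as_grade_values(grades: Sequence) -> np.ndarray:
    vals = np.array([float(g) for g in grades], dtype=float)
    for v in vals:
        if v not in GRADE_VALUES:
            raise ValueError(f"invalid grade value {v}")
    return vals


@dataclass
class LambTimeline:
    """Longitudinal record for one lamb.

    ``timepoints_min`` must be strictly increasing.  ``grades`` and ``epa``
    map lung side -> per-timepoint arrays (NaN = not assessed); at least one
    of grade/EPA must be present at each timepoint for backsliding detection
    to consider the transition out of it.
    """

    lamb_id: str
    group: str
    timepoints_min: np.ndarray
    grades: dict[str, np.ndarray] = field(default_factory=dict)
    epa: dict[str, np.ndarray] = field(default_factory=dict)
    blood_gas: pd.DataFrame | None = None
    support: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("timepoints must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints_min = t
        for name, mapping in (("grades", self.grades), ("epa", self.epa)):
            for side, arr in mapping.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != t.shape:
                    raise ValueError(f"{name}[{side}] length mismatch with timepoints")
                mapping[side] = arr

    @property
    def n_timepoints(self) -> int:
        return self.timepoints_min.size


@dataclass(frozen=True)
class BackslidingEvent:
    """One deterioration between two consecutive timepoints."""

    lamb_id: str
    time_from_min: float
    time_to_min: float
    trigger: str  # "grade_drop" | "epa_drop"
    severe: bool
    side: str
    delta_epa: float | None = None
    grade_after: float | None = None

    def __post_init__(self) -> None:
        if self.trigger not in ("grade_drop", "epa_drop"):
            raise ValueError("trigger must be 'grade_drop' or 'epa_drop'")
        if not self.time_to_min > self.time_from_min:
            raise ValueError("time_to must exceed time_from")


def median_grade(grades: Sequence) -> tuple[float, tuple[float, float]]:
    """Median and IQR of ordinal grades.

    The median uses the mean-of-middle-pair convention for even n, so summary
    values like 1.5 (not themselves grades) can appear.  The IQR is
    (Q1, Q3) with linear-interpolation quantiles.
    """
    vals = _as_grade_values(grades)
    if vals.size == 0:
        raise ValueError("cannot take the median of zero grades")
    med = float(np.median(vals))
    q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))
    return med, (q1, q3)


def percent_agreement(rater_a: Sequence, rater_b: Sequence) -> float:
    """Inter-rater reliability as the percentage of exactly matching grades."""
    a = _as_grade_values(rater_a)
    b = _as_grade_values(rater_b)
    if a.size != b.size:
        raise ValueError("rater grade lists must have equal length")
    if a.size == 0:
        raise ValueError("need at least one graded image")
    return float(100.0 * np.mean(a == b))


def detect_backsliding(
    timeline: LambTimeline,
    epa_drop_threshold: float = 0.2,
    severe_epa_level: float = 0.6,
    severe_grade_level: float = 1.0,
) -> list[BackslidingEvent]:
    """Detect backsliding events on consecutive timepoint pairs.

    For each pair (t_i, t_{i+1}):

    * ``grade_drop`` — any lung's grade strictly decreases (0.5-steps count).
      Severe when the grade after the drop is <= ``severe_grade_level``.
    * ``epa_drop`` — any lung's EPA decreases by strictly more than
      ``epa_drop_threshold``.  Severe when the mean EPA over the available
      lungs after the drop is strictly below ``severe_epa_level``.

    A pair can yield both kinds of event (reported separately).  A pair where
    a timepoint has neither grade nor EPA in any lung is skipped with a
    warning.  When only one lung is assessed, "either lung" and "both-lung
    mean" reduce to that lung.
    """
    events: list[BackslidingEvent] = []
    t = timeline.timepoints_min
    sides_g = sorted(timeline.grades)
    sides_e = sorted(timeline.epa)

    def _has_data(i: int) -> bool:
        has_g = any(np.isfinite(timeline.grades[s][i]) for s in sides_g)
        has_e = any(np.isfinite(timeline.epa[s][i]) for s in sides_e)
        return has_g or has_e

    for i in range(timeline.n_timepoints - 1):
        j = i + 1
        if not (_has_data(i) and _has_data(j)):
            logger.warning(
                "lamb %s: missing grade and EPA around %.1f -> %.1f min; pair skipped",
                timeline.lamb_id,
                t[i],
                t[j],
            )
            continue
        # grade criterion: strict decrease in either lung
        for side in sides_g:
            g0, g1 = timeline.grades[side][i], timeline.grades[side][j]
            if np.isfinite(g0) and np.isfinite(g1) and g1 < g0:
                events.append(
                    BackslidingEvent(
                        lamb_id=timeline.lamb_id,
                        time_from_min=float(t[i]),
                        time_to_min=float(t[j]),
                        trigger="grade_drop",
                        severe=bool(g1 <= severe_grade_level),
                        side=side,
                        grade_after=float(g1),
                    )
                )
        # EPA criterion: drop > threshold in either lung
        dropping = []
        for side in sides_e:
            e0, e1 = timeline.epa[side][i], timeline.epa[side][j]
            if np.isfinite(e0) and np.isfinite(e1) and (e0 - e1) > epa_drop_threshold:
                dropping.append((side, float(e0 - e1)))
        if dropping:
            after = [
                timeline.epa[s][j] for s in sides_e if np.isfinite(timeline.epa[s][j])
            ]
            mean_after = float(np.mean(after))
            side, delta = max(dropping, key=lambda sd: sd[1])
            events.append(
                BackslidingEvent(
                    lamb_id=timeline.lamb_id,
                    time_from_min=float(t[i]),
                    time_to_min=float(t[j]),
                    trigger="epa_drop",
                    severe=bool(mean_after < severe_epa_level),
                    side=side,
                    delta_epa=delta,
                )
            )
    return events


def count_backsliding(
    events: Sequence[BackslidingEvent],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Group-level backsliding summary in the study's report layout.

    ``groups`` maps every lamb id in the cohort (including lambs without
    events) to its group label.  Returns one row per
    (group, trigger, severity) cell with the number of lambs, the proportion
    of lambs with >= 1 event, and the mean +/- SEM event count per lamb.
    """
    lamb_ids = sorted(groups)
    rows = []
    for trigger in ("grade_drop", "epa_drop"):
        for severe_only in (False, True):
            counts = {lid: 0 for lid in lamb_ids}
            for ev in events:
                if ev.trigger != trigger or (severe_only and not ev.severe):
                    continue
                if ev.lamb_id not in counts:
                    raise ValueError(f"event for unknown lamb {ev.lamb_id}")
                counts[ev.lamb_id] += 1
            for group in sorted(set(groups.values())):
                vals = np.array(
                    [counts[lid] for lid in lamb_ids if groups[lid] == group],
                    dtype=float,
                )
                n = vals.size
                sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
                rows.append(
                    {
                        "group": group,
                        "trigger": trigger,
                        "severity": "severe" if severe_only else "any",
                        "n_lambs": n,
                        "n_with_event": int((vals > 0).sum()),
                        "pct_with_event": float(100.0 * (vals > 0).mean()),
                        "mean_occurrences": float(vals.mean()),
                        "sem_occurrences": sem,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rule-based auto-grader (demonstrator)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClipFeatures:
    """Image features feeding the rule-based grader.

    All features are normalised to roughly [0, 1]:

    * ``pleural_brightness`` — peak row-mean intensity in the expected pleural
      band, scaled by 255; a bright established pleural line scores high.
    * ``aline_periodicity`` — strength of periodic horizontal banding below
      the pleural line (autocorrelation peak of the detrended row-mean
      profile); A-lines score high.
    * ``bline_count`` — number of bright vertical streaks crossing the
      sub-pleural field (raw count, not normalised).
    * ``subpleural_homogeneity`` — 1 minus the normalised spatial SD of the
      sub-pleural field; homogeneous liquid ("hepatisation") scores high.
    """

    pleural_brightness: float
    aline_periodicity: float
    bline_count: int
    subpleural_homogeneity: float


@dataclass(frozen=True)
class GradeRuleConfig:
    """Thresholds of the decision list mapping features to a grade.

    Sub-pleural homogeneity falls monotonically as the lung aerates, so the
    list walks down a homogeneity ladder (liquid -> speckled -> white-out),
    then separates the mixed B-line/A-line appearance from the purely
    A-line one by B-line count and reverberation periodicity.
    """

    pleural_absent: float = 0.52
    homogeneity_liquid: float = 0.73
    homogeneity_speckled: float = 0.62
    homogeneity_whiteout: float = 0.47
    homogeneity_mixed: float = 0.30
    bline_many: int = 3
    aline_strong: float = 0.45


def extract_clip_features(
    frames: np.ndarray, pleural_row: int, shadow_mask: np.ndarray | None = None
) -> ClipFeatures:
    """Compute grader features from a clip's mean frame.

    ``pleural_row`` is the expected pleural-line row; ``shadow_mask`` is an
    optional boolean column mask (True = rib shadow) excluded from the
    analysis.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    img = frames.mean(axis=0)
    if shadow_mask is not None:
        img = img[:, ~np.asarray(shadow_mask, dtype=bool)]
    h, w = img.shape
    band = img[max(0, pleural_row - 3) : pleural_row + 4]
    pleural_brightness = float(band.mean(axis=1).max() / 255.0)

    sub = img[pleural_row + 4 :]
    if sub.shape[0] < 8:
        raise ValueError("sub-pleural field too shallow for feature extraction")
    profile = sub.mean(axis=1)
    prof = profile - profile.mean()
    denom = float(np.sum(prof**2))
    if denom > 0:
        # autocorrelation at lags spanning plausible A-line spacings
        lags = range(max(4, pleural_row // 2), min(len(prof) - 1, 3 * pleural_row + 8))
        ac = [float(np.sum(prof[:-k] * prof[k:]) / denom) for k in lags] or [0.0]
        aline_periodicity = max(0.0, max(ac))
    else:
        aline_periodicity = 0.0

    col_mean = sub.mean(axis=0)
    col_bg = float(np.median(col_mean))
    streaks = col_mean > col_bg + 0.25 * max(col_bg, 1.0)
    # count contiguous runs of bright columns
    bline_count = int(np.sum(np.diff(np.concatenate(([0], streaks.view(np.int8), [0]))) == 1))

    mean_sub = float(sub.mean())
    homogeneity = 1.0 - float(sub.std() / mean_sub) if mean_sub > 0 else 0.0
    return ClipFeatures(
        pleural_brightness=pleural_brightness,
        aline_periodicity=aline_periodicity,
        bline_count=bline_count,
        subpleural_homogeneity=max(0.0, min(1.0, homogeneity)),
    )


def rule_based_grade(
    features: ClipFeatures, cfg: GradeRuleConfig | None = None
) -> LUSGrade:
    """Decision-list grade from clip features.

    The list mirrors the descriptive scale: no pleural line over a
    homogeneous liquid-like field -> 0; a faint, poorly defined pleural line
    -> 0.5; a bright homogeneous field without reverberation structure
    (white-out) -> 1; strong periodic A-lines with at most a few B-lines
    -> 3; otherwise mixed B-line/A-line appearance -> 2.
    """
    cfg = cfg or GradeRuleConfig()
    f = features
    if f.pleural_brightness < cfg.pleural_absent and f.subpleural_homogeneity >= cfg.homogeneity_liquid:
        return LUSGrade(0.0)  # hepatisation: no pleural line, liquid field
    if f.subpleural_homogeneity >= cfg.homogeneity_speckled:
        return LUSGrade(0.5)  # speckled / poorly defined pleural line
    if f.subpleural_homogeneity >= cfg.homogeneity_whiteout:
        return LUSGrade(1.0)  # white-out: bright, still largely structureless
    if f.bline_count >= cfg.bline_many or f.subpleural_homogeneity >= cfg.homogeneity_mixed:
        return LUSGrade(2.0)  # B-lines with areas of A-lines
    if f.aline_periodicity >= cfg.aline_strong:
        return LUSGrade(3.0)  # dominant horizontal A-line reverberation
    return LUSGrade(2.0)
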