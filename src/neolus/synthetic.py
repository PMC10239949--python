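"""Synthetic lamb-cohort generator with known ground truth.

Emulates the structure of a neonatal lung-aeration study: two groups of
near-term lambs (controls with normal lung liquid and a group with elevated
liquid at birth), imaged on a fixed schedule from before the onset of air
breathing until four hours after it.  Each lamb carries

* per-lung aeration trajectories — saturating-exponential rise of the true
  proportion of air with a group-specific time constant, a shared lamb-level
  random effect, bounded noise, and transient one-timepoint "backsliding"
  drops injected at a Poisson rate;
* multi-frame ultrasound clips rendered so that the pixel-intensity CoV in
  valid regions of interest rises monotonically and approximately linearly
  with the true proportion of air (homogeneous tissue-like speckle when
  liquid-filled; a bright pleural line, periodic A-line bands and occasional
  B-line streaks over a dark field when aerated), with rib shadows flanking
  the ROI zones and optional motion-corrupted frames;
* blood gases whose alveolar-arterial oxygen gradient is linear in the
  unaerated fraction, back-computed so the emitted record reproduces the true
  gradient exactly;
* dual-channel breathing traces with configurable rate, breath-length jitter
  and intrapleural swing, perturbed after gas-flow-change events (rate drop,
  increased variability and effort, optional apnoea) with recovery over a
  configured breath count.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .gas import BloodGas, GasExchangeConfig, svp_mmhg
from .quant import LUSClip, ROI

__all__ = [
    "default_schedule",
    "CohortConfig",
    "GroundTruth",
    "simulate_trajectories",
    "ClipGeometry",
    "synthesize_lus_clip",
    "simulate_blood_gases",
    "BreathingConfig",
    "simulate_breathing_trace",
    "epa_to_grade",
    "DEFAULT_GRADE_THRESHOLDS",
]

#: True-EPA cut points mapping aeration to the ordinal grade
#: (<0.1 -> 0, <0.3 -> 0.5, <0.5 -> 1, <0.85 -> 2, else 3).
DEFAULT_GRADE_THRESHOLDS = (0.1, 0.3, 0.5, 0.85)


def default_schedule() -> tuple[float, ...]:
    """Imaging schedule in minutes after the onset of air breathing.

    One pre-breathing scan (encoded as -1 min), then every 2.5 min during the
    first 10 min, every 5 min until 30 min, every 10 min until 60 min, and
    every 20 min until 4 h.
    """
    times = [-1.0, 2.5, 5.0, 7.5, 10.0]
    times += [15.0, 20.0, 25.0, 30.0]
    times += [40.0, 50.0, 60.0]
    times += list(np.arange(80.0, 241.0, 20.0))
    return tuple(times)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the emulated study: 10 control and 9 elevated-liquid
    lambs on the standard imaging schedule.  Aeration follows
    ``epa_max * (1 - exp(-t / tau))`` with the elevated-liquid group given a
    slower time constant; backsliding events arrive at ``backslide_rate`` per
    lamb per experiment with one-timepoint depths drawn uniformly from
    ``backslide_depth``; the alveolar-arterial gradient is
    ``aado2_intercept + aado2_slope * (1 - EPA)`` mmHg.
    """

    n_control: int = 10
    n_elevated: int = 9
    schedule: tuple[float, ...] = field(default_factory=default_schedule)
    tau_control: float = 15.0
    tau_elevated: float = 30.0
    epa_max: float = 0.95
    epa_noise_sd: float = 0.04
    lamb_effect_sd: float = 0.04
    backslide_rate: float = 2.0
    backslide_depth: tuple[float, float] = (0.2, 0.5)
    grade_thresholds: tuple[float, float, float, float] = DEFAULT_GRADE_THRESHOLDS
    aado2_intercept: float = 30.0
    aado2_slope: float = 400.0
    aado2_noise_sd: float = 15.0
    paco2_mean: float = 45.0
    paco2_sd: float = 5.0
    temperature_c: float = 39.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_elevated < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 < self.epa_max <= 1.0:
            raise ValueError("epa_max must lie in (0, 1]")
        if self.tau_control <= 0 or self.tau_elevated <= 0:
            raise ValueError("time constants must be positive")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size < 2 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing with >= 2 times")
        if sched[0] >= 0:
            raise ValueError("schedule must start with a pre-breathing (negative) time")
        lo, hi = self.backslide_depth
        if not 0 < lo <= hi:
            raise ValueError("backslide_depth must be an increasing positive range")
        if self.backslide_rate < 0 or self.epa_noise_sd < 0 or self.lamb_effect_sd < 0:
            raise ValueError("rates and noise SDs must be non-negative")
        if list(self.grade_thresholds) != sorted(self.grade_thresholds):
            raise ValueError("grade thresholds must be increasing")


def epa_to_grade(epa: float, thresholds: tuple[float, ...] = DEFAULT_GRADE_THRESHOLDS) -> float:
    """Ordinal grade implied by a true proportion of air."""
    t0, t1, t2, t3 = thresholds
    if epa < t0:
        return 0.0
    if epa < t1:
        return 0.5
    if epa < t2:
        return 1.0
    if epa < t3:
        return 2.0
    return 3.0


@dataclass
class GroundTruth:
    """Known truth for one lamb: per-lung EPA and grade at every timepoint."""

    lamb_id: str
    group: str  # "control" | "elevated"
    timepoints_min: np.ndarray
    epa: dict[str, np.ndarray]
    grades: dict[str, np.ndarray]
    backslide_times_min: tuple[float, ...] = ()

    def mean_epa(self) -> np.ndarray:
        return np.mean([self.epa[s] for s in sorted(self.epa)], axis=0)


def simulate_trajectories(config: CohortConfig) -> list[GroundTruth]:
    """Simulate per-lung aeration trajectories for the whole cohort.

    For each lamb, EPA(t) = 0 before breathing onset and
    ``epa_max * (1 - exp(-t/tau_group)) + u_lamb + noise`` afterwards,
    clamped to [0, 1]; ``u_lamb`` is a shared lamb-level random intercept.
    Backsliding events (Poisson count per lamb) each subtract a uniform depth
    from one randomly chosen lung at one randomly chosen timepoint.  True
    grades are derived from the final true EPA via fixed thresholds.
    """
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.schedule, dtype=float)
    post = t > 0
    # injection sites need a post-onset predecessor so the drop reads as a
    # reduction from an established level
    eligible = np.nonzero(post & np.concatenate(([False], post[:-1])))[0]

    truths: list[GroundTruth] = []
    plan = [("control", config.tau_control, config.n_control),
            ("elevated", config.tau_elevated, config.n_elevated)]
    for group, tau, n in plan:
        for k in range(n):
            lamb_id = f"{group[:2]}{k + 1:02d}"
            u = rng.normal(0.0, config.lamb_effect_sd) if config.lamb_effect_sd else 0.0
            epa: dict[str, np.ndarray] = {}
            for side in ("left", "right"):
                base = np.where(post, config.epa_max * (1.0 - np.exp(-np.maximum(t, 0.0) / tau)), 0.0)
                noise = (
                    rng.normal(0.0, config.epa_noise_sd, size=t.size)
                    if config.epa_noise_sd
                    else np.zeros(t.size)
                )
                vals = base + np.where(post, u + noise, 0.0)
                epa[side] = vals
            n_events = int(rng.poisson(config.backslide_rate)) if config.backslide_rate else 0
            n_events = min(n_events, eligible.size)
            event_times: list[float] = []
            if n_events:
                sites = rng.choice(eligible, size=n_events, replace=False)
                for i in np.sort(sites):
                    side = "left" if rng.random() < 0.5 else "right"
                    depth = rng.uniform(*config.backslide_depth)
                    epa[side][i] -= depth
                    event_times.append(float(t[i]))
            for side in epa:
                epa[side] = np.clip(epa[side], 0.0, 1.0)
            grades = {
                side: np.array([epa_to_grade(v, config.grade_thresholds) for v in epa[side]])
                for side in epa
            }
            truths.append(
                GroundTruth(
                    lamb_id=lamb_id,
                    group=group,
                    timepoints_min=t.copy(),
                    epa=epa,
                    grades=grades,
                    backslide_times_min=tuple(event_times),
                )
            )
    return truths


# ---------------------------------------------------------------------------
# Clip synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClipGeometry:
    """Layout of a synthetic clip (pixels unless noted)."""

    height: int = 96
    width: int = 128
    n_frames: int = 6
    frame_rate: float = 15.0
    pleural_row: int = 18
    aline_spacing: int = 12
    aline_width: int = 3
    rib_shadow_width: int = 10
    roi_height: int = 40
    speckle_shape: float = 16.0  # gamma shape; speckle CoV = 1/sqrt(shape)
    frame_jitter_sd: float = 0.06  # per-frame multiplicative perturbation
    max_blines: int = 5

    def __post_init__(self) -> None:
        if self.height < self.pleural_row + 8 + self.roi_height:
            raise ValueError("geometry too shallow for the ROI below the pleural line")
        if self.width < 3 * (self.rib_shadow_width + 12):
            raise ValueError("geometry too narrow for three inter-shadow ROI zones")
        if self.n_frames < 1 or self.frame_rate <= 0 or self.speckle_shape <= 0:
            raise ValueError("degenerate geometry")


def _zones_and_shadows(geom: ClipGeometry) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Three inter-shadow column zones and the boolean shadow column mask."""
    w = geom.width
    sw = geom.rib_shadow_width
    centers = [w // 3, 2 * w // 3]
    mask = np.zeros(w, dtype=bool)
    for c in centers:
        mask[max(0, c - sw // 2) : c + sw - sw // 2] = True
    starts = [0, centers[0] + sw - sw // 2, centers[1] + sw - sw // 2]
    stops = [max(0, centers[0] - sw // 2), max(0, centers[1] - sw // 2), w]
    zones = [(a + 2, b - 2) for a, b in zip(starts, stops)]
    return zones, mask


def _bline_columns(geom: ClipGeometry, n_blines: int) -> list[int]:
    """Deterministic, evenly spread B-line column positions inside the zones."""
    if n_blines <= 0:
        return []
    zones, _ = _zones_and_shadows(geom)
    cols: list[int] = []
    for i in range(n_blines):
        zone = zones[i % len(zones)]
        frac = 0.25 + 0.5 * ((i // len(zones)) % 2)
        cols.append(int(zone[0] + frac * (zone[1] - zone[0] - 2)))
    return cols


def _render_pattern(u: float, geom: ClipGeometry) -> np.ndarray:
    """Noiseless intensity pattern for blend weight ``u`` in [0, 1].

    ``u = 0`` renders a liquid-filled field (homogeneous tissue echo, faint
    pleural line); ``u = 1`` an aerated one (bright pleural line, periodic
    A-line reverberations over a dark field).  B-line streaks appear at
    intermediate aeration.  Rib shadows darken two vertical bands.
    """
    h, w = geom.height, geom.width
    pr = geom.pleural_row

    liquid = np.full((h, w), 120.0)
    liquid[:pr] = 100.0

    aerated = np.full((h, w), 40.0)
    aerated[:pr] = 80.0
    aerated[pr : pr + 2] = 235.0
    row = pr + geom.aline_spacing
    k = 1
    while row < h:
        b = 220.0 * (0.85 ** (k - 1))
        aerated[row : row + geom.aline_width] = np.maximum(
            aerated[row : row + geom.aline_width], b
        )
        row += geom.aline_spacing
        k += 1

    img = (1.0 - u) * liquid + u * aerated

    # B-lines: bright vertical streaks, most numerous at intermediate aeration
    n_b = int(round(geom.max_blines * 4.0 * u * (1.0 - u)))
    for c in _bline_columns(geom, n_b):
        img[pr:, c : c + 2] = np.maximum(img[pr:, c : c + 2], 200.0 * min(1.0, u / 0.3 + 0.2))

    _, shadow = _zones_and_shadows(geom)
    img[:, shadow] *= 0.12
    return img


def default_rois(geom: ClipGeometry) -> list[ROI]:
    """Three ROIs below the pleural line, between the rib shadows."""
    zones, _ = _zones_and_shadows(geom)
    y = geom.pleural_row + 4
    return [ROI(x=a, y=y, width=b - a, height=geom.roi_height) for a, b in zones]


def _pattern_cov(img: np.ndarray, geom: ClipGeometry) -> float:
    """Analytic expected pixel CoV over the default ROIs.

    With multiplicative unit-mean speckle of coefficient of variation ``s``,
    a region with noiseless pattern B has pixel variance
    ``Var(B) + s^2 E[B^2]`` and mean ``E[B]``.
    """
    s2 = 1.0 / geom.speckle_shape + geom.frame_jitter_sd**2
    covs = []
    for roi in default_rois(geom):
        b = roi.extract(img).astype(float)
        mean = b.mean()
        var = b.var() + s2 * np.mean(b**2)
        covs.append(np.sqrt(var) / mean)
    return float(np.mean(covs))


@lru_cache(maxsize=8)
def _linearising_map(geom: ClipGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Monotone blend-weight grid making expected CoV linear in true EPA.

    Returns (epa_grid, u_grid): rendering with blend weight ``u(epa)`` gives
    an expected ROI CoV that interpolates linearly between the liquid and
    aerated endpoints.
    """
    u_grid = np.linspace(0.0, 1.0, 101)
    cov_u = np.array([_pattern_cov(_render_pattern(u, geom), geom) for u in u_grid])
    cov_u = np.maximum.accumulate(cov_u)  # guard tiny non-monotone wiggles
    target = cov_u[0] + (cov_u[-1] - cov_u[0]) * u_grid  # linear in epa
    u_of_epa = np.interp(target, cov_u, u_grid)
    return u_grid.copy(), u_of_epa


def synthesize_lus_clip(
    true_epa: float,
    geometry: ClipGeometry | None = None,
    seed: int | np.random.Generator = 0,
    n_motion_frames: int = 0,
    lamb_id: str = "",
    side: str = "left",
    acquisition_time_min: float = 0.0,
) -> tuple[LUSClip, dict]:
    """Render a multi-frame 8-bit clip for a given true proportion of air.

    Frames share one multiplicative gamma speckle field (so consecutive
    frames are strongly correlated, as in a real clip) plus a small
    independent per-frame perturbation.  ``n_motion_frames`` final frames are
    corrupted by a global translation and blur and flagged in the returned
    info dict (``motion_frames``), alongside the valid ROIs (``rois``), the
    rib-shadow column mask and the pleural row.
    """
    if not 0.0 <= true_epa <= 1.0:
        raise ValueError("true_epa must lie in [0, 1]")
    geom = geometry or ClipGeometry()
    if not 0 <= n_motion_frames < geom.n_frames:
        raise ValueError("n_motion_frames must leave at least one clean frame")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    epa_grid, u_grid = _linearising_map(geom)
    u = float(np.interp(true_epa, epa_grid, u_grid))
    pattern = _render_pattern(u, geom)

    speckle = rng.gamma(geom.speckle_shape, 1.0 / geom.speckle_shape, size=pattern.shape)
    frames = np.empty((geom.n_frames, geom.height, geom.width), dtype=np.uint8)
    n_clean = geom.n_frames - n_motion_frames
    for i in range(geom.n_frames):
        jitter = 1.0 + rng.normal(0.0, geom.frame_jitter_sd, size=pattern.shape)
        if i < n_clean:
            img = pattern * speckle * jitter
        else:  # motion frame: independent shift + smoothing
            shift = int(rng.integers(6, 14)) * (1 if rng.random() < 0.5 else -1)
            moved = np.roll(pattern * speckle, shift, axis=0)
            kernel = np.ones(5) / 5.0
            moved = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 0, moved)
            img = moved * jitter
        frames[i] = np.clip(img, 0.0, 255.0).astype(np.uint8)

    clip = LUSClip(
        frames=frames,
        frame_rate=geom.frame_rate,
        acquisition_time_min=acquisition_time_min,
        lamb_id=lamb_id,
        side=side,
        metadata={"true_epa": float(true_epa), "depth_cm": 4.0, "gain": 74},
    )
    _, shadow = _zones_and_shadows(geom)
    info = {
        "rois": default_rois(geom),
        "motion_frames": set(range(n_clean, geom.n_frames)),
        "shadow_mask": shadow,
        "pleural_row": geom.pleural_row,
        "true_epa": float(true_epa),
    }
    return clip, info


# ---------------------------------------------------------------------------
# Blood gases
# ---------------------------------------------------------------------------


def simulate_blood_gases(
    truth: GroundTruth,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    gas_cfg: GasExchangeConfig | None = None,
    fio2_policy: str = "titrated",
) -> tuple[list[BloodGas], np.ndarray]:
    """Blood gases at each post-onset timepoint, consistent with the truth.

    The true gradient is ``aado2_intercept + aado2_slope * (1 - meanEPA(t))``
    plus noise; PaCO2 is drawn near its configured mean, temperature is fixed,
    and PaO2 is back-computed from the alveolar gas equation so that
    recomputing AaDO2 from the emitted record returns the true gradient
    exactly.  FiO2 follows a support policy: "titrated" raises the inspired
    fraction while the lung is poorly aerated (and whenever needed to keep
    PaO2 positive); "air" holds 0.21 where feasible.

    Returns (records, true_aado2) aligned on post-onset schedule times.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    gas_cfg = gas_cfg or GasExchangeConfig()
    t = truth.timepoints_min
    post = t > 0
    mean_epa = truth.mean_epa()[post]
    times = t[post]

    svp = svp_mmhg(config.temperature_c)
    alveolar_per_fio2 = gas_cfg.patm_mmhg - svp

    records: list[BloodGas] = []
    true_vals = np.empty(times.size)
    for i, (tm, epa) in enumerate(zip(times, mean_epa)):
        noise = rng.normal(0.0, config.aado2_noise_sd) if config.aado2_noise_sd else 0.0
        aado2_true = config.aado2_intercept + config.aado2_slope * (1.0 - epa) + noise
        paco2 = max(15.0, rng.normal(config.paco2_mean, config.paco2_sd) if config.paco2_sd else config.paco2_mean)
        if fio2_policy == "titrated":
            fio2 = float(np.clip(0.30 + 0.70 * (1.0 - epa), 0.21, 1.0))
        elif fio2_policy == "air":
            fio2 = 0.21
        else:
            raise ValueError(f"unknown fio2 policy {fio2_policy!r}")
        pao2 = fio2 * alveolar_per_fio2 - paco2 / gas_cfg.respiratory_quotient - aado2_true
        if pao2 < 20.0:  # titrate up to keep an achievable arterial tension
            fio2 = min(1.0, (aado2_true + paco2 / gas_cfg.respiratory_quotient + 20.0) / alveolar_per_fio2)
            pao2 = fio2 * alveolar_per_fio2 - paco2 / gas_cfg.respiratory_quotient - aado2_true
        if pao2 <= 0:
            raise ValueError(
                "infeasible blood-gas configuration: AaDO2 too large for FiO2 = 1"
            )
        true_vals[i] = aado2_true
        records.append(
            BloodGas(
                time_min=float(tm),
                fio2=fio2,
                pao2_mmhg=float(pao2),
                paco2_mmhg=float(paco2),
                temperature_c=config.temperature_c,
            )
        )
    return records, true_vals


# ---------------------------------------------------------------------------
# Breathing traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathingConfig:
    """Quasi-periodic breathing-trace generator settings.

    The flow-change perturbation defaults follow the emulated study's
    observed effects: a rate drop of ~20.7 breaths/min, a 31% relative rise
    in breath-length CoV and a 13.4 cmH2O rise in intrapleural swing, fully
    expressed over post-event breaths 1-10 and recovering linearly by breath
    ``recovery_breaths``.
    """

    sample_rate: float = 100.0
    duration_s: float = 120.0
    rate_bpm: float = 60.0
    breath_jitter_cov: float = 0.08
    ip_baseline_cmh2o: float = -2.0
    ip_swing_cmh2o: float = 8.0
    trach_baseline_cmh2o: float = 2.0
    trach_gain: float = 0.5
    channel_noise_sd: float = 0.0
    rate_drop_bpm: float = 20.74
    blcov_increase_frac: float = 0.31
    swing_increase_cmh2o: float = 13.4
    plateau_breaths: int = 10
    recovery_breaths: int = 30
    apnoea_s: float = 0.0
    artefact_times_s: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate < 20:
            raise ValueError("sample_rate must be >= 20 Hz")
        if not 20 <= self.rate_bpm <= 120:
            raise ValueError("rate_bpm outside plausible newborn range")
        if self.recovery_breaths <= self.plateau_breaths:
            raise ValueError("recovery_breaths must exceed plateau_breaths")
        if self.rate_drop_bpm >= self.rate_bpm:
            raise ValueError("rate drop must leave a positive breathing rate")


def _event_envelope(b: int, cfg: BreathingConfig) -> float:
    """Perturbation strength for the b-th breath after an event (b >= 1)."""
    if b < 1:
        return 0.0
    if b <= cfg.plateau_breaths:
        return 1.0
    if b >= cfg.recovery_breaths:
        return 0.0
    span = cfg.recovery_breaths - cfg.plateau_breaths
    return float((cfg.recovery_breaths - b) / span)


def simulate_breathing_trace(
    config: BreathingConfig,
    events_s: tuple[float, ...] | list[float] = (),
) -> tuple["PressureTrace", dict]:
    """Generate a dual-channel pressure trace with flow-change perturbations.

    Breaths are laid down one at a time: each has a negative intrapleural
    deflection of the configured swing over the first 40% of its period, then
    an end-expiratory plateau at baseline.  After each event in ``events_s``
    the rate drops, breath-length jitter and swing rise per the config, and
    an optional apnoea (flat gap) is inserted immediately after the event.
    The tracheal channel is a scaled copy of the intrapleural deflection
    around its own baseline.  Events whose recovery windows would overlap
    raise an error.

    Returns (trace, info) with ground truth in ``info``: per-breath start
    times and target rates, apnoea intervals and artefact times.
    """
    from .breath import PressureTrace  # local import to avoid cycle at import time

    events = sorted(float(e) for e in events_s)
    min_rate = config.rate_bpm - config.rate_drop_bpm
    window_s = config.recovery_breaths * 60.0 / max(min_rate, 1.0) + config.apnoea_s
    for a, b in zip(events, events[1:]):
        if b - a < window_s:
            raise ValueError(f"events at {a} s and {b} s overlap (window {window_s:.0f} s)")

    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n_total = int(config.duration_s * fs)
    ip = np.full(n_total, config.ip_baseline_cmh2o)

    t = 0.0
    breath_starts: list[float] = []
    true_rates: list[float] = []
    apnoeas: list[tuple[float, float]] = []
    breaths_since: dict[float, int] = {e: 0 for e in events}
    untriggered = set(events)

    while t < config.duration_s:
        fired = [e for e in untriggered if t >= e]
        if fired:
            untriggered.difference_update(fired)
            if config.apnoea_s > 0:  # apnoea right after the event boundary
                apnoeas.append((t, t + config.apnoea_s))
                t += config.apnoea_s
                continue
        env = 0.0
        for e in events:
            if t >= e:
                breaths_since[e] += 1
                env = max(env, _event_envelope(breaths_since[e], config))
        rate = config.rate_bpm - config.rate_drop_bpm * env
        jit_cov = config.breath_jitter_cov * (1.0 + config.blcov_increase_frac * env)
        swing = config.ip_swing_cmh2o + config.swing_increase_cmh2o * env
        period = 60.0 / rate
        if jit_cov > 0:
            period *= float(np.clip(1.0 + rng.normal(0.0, jit_cov), 0.3, 2.5))
        i0, i1 = int(t * fs), min(int((t + period) * fs), n_total)
        n = i1 - i0
        if n > 3:
            tt = np.arange(n) / fs
            t_insp = 0.4 * period
            wave = np.where(
                tt < t_insp, -swing * np.sin(np.pi * tt / t_insp), 0.0
            )
            ip[i0:i1] = config.ip_baseline_cmh2o + wave
            breath_starts.append(t)
            true_rates.append(rate)
        t += period

    trach = config.trach_baseline_cmh2o + config.trach_gain * (ip - config.ip_baseline_cmh2o)
    if config.channel_noise_sd > 0:
        ip = ip + rng.normal(0.0, config.channel_noise_sd, size=n_total)
        trach = trach + rng.normal(0.0, config.channel_noise_sd, size=n_total)

    for ta in config.artefact_times_s:
        i0 = int(ta * fs)
        i1 = min(i0 + int(1.0 * fs), n_total)
        if i0 >= n_total:
            continue
        tt = np.arange(i1 - i0) / fs
        burst = 15.0 * np.sin(2 * np.pi * 30.0 * tt) * np.hanning(i1 - i0)
        ip[i0:i1] += burst
        trach[i0:i1] += 0.5 * burst

    trace = PressureTrace(sample_rate=fs, intrapleural=ip, tracheal=trach)
    info = {
        "breath_starts_s": np.array(breath_starts),
        "true_rates_bpm": np.array(true_rates),
        "apnoeas_s": apnoeas,
        "artefact_times_s": tuple(config.artefact_times_s),
        "events_s": tuple(events),
    }
    return trace, info
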