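"""Alveolar-arterial oxygen gradient (AaDO2) from arterial blood gases.

The AaDO2 summarises how well the lung transfers oxygen from the alveolar gas
to the arterial blood.  For a newborn breathing a gas mixture with inspired
oxygen fraction FiO2 at atmospheric pressure Patm, the alveolar oxygen tension
is approximated by the alveolar gas equation and the gradient is

    AaDO2 = FiO2 * (Patm - P_H2O(T)) - PaCO2 / RQ - PaO2      [mmHg]

where P_H2O(T) is the saturated water vapour pressure at body temperature T,
RQ is the respiratory quotient (default 0.8), and PaO2/PaCO2 are the arterial
oxygen and carbon dioxide tensions.  Lower AaDO2 means better gas exchange; a
fully liquid-filled lung produces a very large gradient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BloodGas",
    "GasExchangeConfig",
    "svp_mmhg",
    "aado2",
    "aado2_series",
]

#: hPa -> mmHg conversion factor.
_HPA_TO_MMHG = 0.750061683

_TEMP_MIN_C = 30.0
_TEMP_MAX_C = 45.0


@dataclass(frozen=True)
class BloodGas:
    """One arterial blood-gas record.

    Parameters
    ----------
    time_min : minutes after cord clamping.
    fio2 : inspired oxygen fraction, in [0.21, 1.0].
    pao2_mmhg, paco2_mmhg : arterial O2 / CO2 partial pressures (mmHg), > 0.
    temperature_c : rectal temperature (deg C), in [30, 45].
    sao2_pct : optional arterial oxygen saturation (%).
    """

    time_min: float
    fio2: float
    pao2_mmhg: float
    paco2_mmhg: float
    temperature_c: float = 39.0
    sao2_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError(f"fio2 must be in [0.21, 1.0], got {self.fio2}")
        if self.pao2_mmhg <= 0 or self.paco2_mmhg <= 0:
            raise ValueError("partial pressures must be positive")
        if not _TEMP_MIN_C <= self.temperature_c <= _TEMP_MAX_C:
            raise ValueError(
                f"temperature {self.temperature_c} degC outside "
                f"[{_TEMP_MIN_C}, {_TEMP_MAX_C}]"
            )


@dataclass(frozen=True)
class GasExchangeConfig:
    """Constants of the alveolar gas equation."""

    patm_mmhg: float = 760.0
    respiratory_quotient: float = 0.8
    #: if set, use this fixed water vapour pressure instead of recomputing it
    #: from each record's temperature (some labs use a single body-temperature
    #: value, e.g. 52 mmHg at 39 degC, for the whole study).
    fixed_svp_mmhg: float | None = None

    def __post_init__(self) -> None:
        if self.patm_mmhg <= 0:
            raise ValueError("patm_mmhg must be positive")
        if self.respiratory_quotient <= 0:
            raise ValueError("respiratory_quotient must be positive")


def svp_mmhg(temperature_c: float) -> float:
    """Saturated water vapour pressure (mmHg) at a body temperature.

    Uses Buck's (1981) formulation over liquid water,
    ``e_s = 6.1121 * exp(17.502 T / (240.97 + T))`` hPa, converted to mmHg.
    Monotone increasing on the supported range; 39 degC gives 52.49 mmHg
    (52 mmHg to the nearest integer).
    """
    t = float(temperature_c)
    if not _TEMP_MIN_C <= t <= _TEMP_MAX_C:
        raise ValueError(
            f"temperature {t} degC outside physiological range "
            f"[{_TEMP_MIN_C}, {_TEMP_MAX_C}]"
        )
    e_hpa = 6.1121 * math.exp(17.502 * t / (240.97 + t))
    return e_hpa * _HPA_TO_MMHG


def aado2(bg: BloodGas, cfg: GasExchangeConfig | None = None) -> float:
    """Alveolar-arterial oxygen difference (mmHg) for one record.

    ``fio2 * (patm - svp) - paco2 / RQ - pao2``.  A negative result is
    physically implausible but can arise from measurement noise; it is
    returned as computed with a warning rather than clipped.
    """
    cfg = cfg or GasExchangeConfig()
    svp = (
        cfg.fixed_svp_mmhg
        if cfg.fixed_svp_mmhg is not None
        else svp_mmhg(bg.temperature_c)
    )
    value = (
        bg.fio2 * (cfg.patm_mmhg - svp)
        - bg.paco2_mmhg / cfg.respiratory_quotient
        - bg.pao2_mmhg
    )
    if value < 0:
        warnings.warn(
            f"negative AaDO2 ({value:.2f} mmHg) at t={bg.time_min} min; "
            "retained as computed",
            stacklevel=2,
        )
    return value


def aado2_series(
    records: list[BloodGas], cfg: GasExchangeConfig | None = None
) -> pd.DataFrame:
    """Per-record AaDO2 for a time-sorted blood-gas series.

    Returns a tidy frame with columns ``time_min``, ``aado2_mmhg`` and a
    boolean ``negative`` flag.  Raises if the records are not sorted by time.
    """
    times = [bg.time_min for bg in records]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("blood-gas records must be sorted by time")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = np.array([aado2(bg, cfg) for bg in records], dtype=float)
    return pd.DataFrame(
        {
            "time_min": np.asarray(times, dtype=float),
            "aado2_mmhg": values,
            "negative": values < 0,
        }
    )
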