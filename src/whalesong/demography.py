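"""Logistic population recovery from the 1960 whaling bottleneck.

Each population is summarised by three male abundances: ``N_min`` at the
bottleneck, ``N_2015`` at the end of the calibrated growth window, and the
carrying capacity ``N_K``.  The per-year logistic growth rate ``r`` is the
unique rate for which the closed-form logistic trajectory started at
``N_min`` passes through ``N_2015`` after ``calibration_years`` years:

    N(t) = K * N0 * exp(r t) / (K + N0 * (exp(r t) - 1))

which gives ``r = ln[N_2015 (K - N_min) / (N_min (K - N_2015))] / T``.

Growth is deterministic and monotone; no mortality or emigration is
modelled, so yearly population change is recruitment only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import round_half_up


@dataclass(frozen=True)
class PopulationDemography:
    name: str
    N_min: float
    N_2015: float
    N_K: float
    calibration_years: int = 50

    def __post_init__(self):
        if not (0 < self.N_min <= self.N_2015 <= self.N_K):
            raise ValueError(
                f"{self.name}: require 0 < N_min <= N_2015 <= N_K, got "
                f"{self.N_min}, {self.N_2015}, {self.N_K}"
            )

    @property
    def r(self) -> float:
        return solve_growth_rate(
            self.N_min, self.N_2015, self.N_K, self.calibration_years
        )


def solve_growth_rate(N_min, N_2015, N_K, calibration_years: int) -> float:
    """Logistic growth rate hitting ``N_2015`` after ``calibration_years`` years."""
    if calibration_years < 1:
        raise ValueError("calibration_years must be >= 1")
    if not (N_min <= N_2015 <= N_K):
        raise ValueError("require N_min <= N_2015 <= N_K")
    if N_2015 == N_K and N_min < N_K:
        raise ValueError(
            "the logistic trajectory never attains N_K in finite time; "
            "pass N_2015 < N_K (the trajectory still saturates towards N_K)"
        )
    if N_2015 == N_min:
        return 0.0
    return (
        math.log(N_2015 * (N_K - N_min) / (N_min * (N_K - N_2015)))
        / calibration_years
    )


def logistic_size(N_min, N_K, r, year) -> float:
    ert = np.exp(r * np.asarray(year, dtype=float))
    return N_K * N_min * ert / (N_K + N_min * (ert - 1.0))


def population_size(demog: PopulationDemography, year: int) -> int:
    """Male abundance in ``year`` (round-half-up of the logistic closed form).

    Year 0 is the bottleneck (``N_min``); the trajectory passes through
    ``N_2015`` at ``calibration_years`` and saturates towards ``N_K`` for
    long horizons (used by the 500-year projection runs).
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    n = logistic_size(demog.N_min, demog.N_K, demog.r, year)
    return min(round_half_up(n), round_half_up(demog.N_K))
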