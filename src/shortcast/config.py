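"""Simulation configuration for the synthetic pharmacy world.

The generator emulates the three tables a Canadian community-pharmacy
shortage analysis runs on: a drug catalog (DIN -> interchangeable group ->
AHFS therapeutic-class code, with per-DIN pack listings), monthly dispensing
aggregates per DIN, and raw shortage reports filed per DIN/pack-size with
free-text pack descriptions and imperfect dates.  Every knob that shapes the
statistical structure downstream stages rely on is exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .months import month, month_range


class ConfigError(ValueError):
    """Raised when a simulation parameter is out of its admissible range."""


DEFAULT_DIALECTS = (
    "{n} Bottle",
    "{n} BTL",
    "{n}",
    "BOTTLE OF {n}",
    "UNKNOWN",
)

#: Dialect templates whose rendered text allows exact numeric recovery of the
#: pack size (no "UNKNOWN", no extra digits).
PARSEABLE_DIALECTS = ("{n} Bottle", "{n} BTL", "{n}", "BOTTLE OF {n}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic pharmacy world.

    Defaults mirror the study conditions of the analysis this package
    supports: months spanning January 2017 to April 2021 (48 months of
    train/test plus a 4-month holdout), 100 interchangeable groups with on
    average ~8 component DINs each, and shortage dynamics (multi-month
    durations, demand substitution away from shorted DINs, days-of-supply
    rationing during large shortages, propagation to therapeutic-class
    siblings) qualitatively matching what pharmacy dispensing data shows
    around reported shortages.
    """

    n_igs: int = 100
    dins_per_ig: tuple[int, int] = (4, 12)
    packs_per_din: tuple[int, int] = (1, 3)
    months: tuple[str, str] = ("2017-01", "2021-04")
    n_patients_scale: float = 200.0
    preference_concentration: float = 0.5
    shortage_rate: float = 0.007
    shortage_duration_p: float = 0.4
    tc_correlation: float = 0.2
    substitution_strength: float = 0.7
    dos_drop: float = 0.3
    seasonal_amplitude: float = 0.15
    text_dialects: tuple[str, ...] = DEFAULT_DIALECTS
    missing_date_rate: float = 0.0
    inverted_date_rate: float = 0.0
    spurious_report_rate: float = 0.1
    day_level_dates: bool = False
    seed: int = 0
    share_walk_sigma: float = 0.05

    def __post_init__(self) -> None:
        def _check_prob(name: str) -> None:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")

        if self.n_igs < 1:
            raise ConfigError(f"n_igs must be >= 1, got {self.n_igs!r}")
        for name in ("dins_per_ig", "packs_per_din"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"{name} must be a non-empty range with 1 <= lo <= hi, got {(lo, hi)!r}")
        for name in (
            "shortage_rate",
            "tc_correlation",
            "substitution_strength",
            "dos_drop",
            "seasonal_amplitude",
            "missing_date_rate",
            "inverted_date_rate",
            "spurious_report_rate",
        ):
            _check_prob(name)
        if not 0.0 < self.shortage_duration_p <= 1.0:
            raise ConfigError(f"shortage_duration_p must lie in (0, 1], got {self.shortage_duration_p!r}")
        if self.n_patients_scale <= 0:
            raise ConfigError(f"n_patients_scale must be positive, got {self.n_patients_scale!r}")
        if self.preference_concentration <= 0:
            raise ConfigError(
                f"preference_concentration must be positive, got {self.preference_concentration!r}"
            )
        if not self.text_dialects:
            raise ConfigError("text_dialects must be non-empty")
        n_months = len(self.month_index)
        if n_months < 18:
            raise ConfigError(
                f"months must span at least 18 calendar months (4 lags + minimum "
                f"training window + holdout), got {n_months}"
            )

    @property
    def month_index(self):
        start, end = self.months
        if month(start) > month(end):
            raise ConfigError(f"months range is empty: {self.months!r}")
        return month_range(start, end)

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)
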