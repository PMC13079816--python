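"""Live/dead classification and live-cell-ratio (LCR) statistics.

The viability assay counts Hoechst-stained nuclei in 10 random fields per
day; a cell is live iff its fluorescence intensity is strictly below
100 a.u.  Per day N the live counts x_i(N) are summarised by their mean
x̄(N) and population standard deviation σ(N) (divisor n), converted to an
areal concentration x̄(N)/1.77 mm², and normalised to Day 0:

    LCR(N) = [live cell concentration of day N] / [live cell concentration of day 0]

so LCR(0) = 1 by definition.  The error of the ratio is propagated from
(σ(N), σ(0)) in one of two modes, and the headline per-condition summary is
the arithmetic mean of LCR(1..3) with independence-propagated error.

Error-propagation modes
-----------------------
``"printed"`` (default) evaluates the ratio-error formula exactly as the
source assay typeset it,

    sqrt((eps1 / M1)**2 + (eps2 / M2**2)**2),

whose first term is dimensionless and hence dimensionally inconsistent with
an absolute error of M1/M2.  ``"standard"`` is the usual first-order formula

    (M1/M2) * sqrt((eps1/M1)**2 + (eps2/M2)**2),

validated against Monte-Carlo resampling in the test suite.  Both are always
available; neither intent is guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DayCounts",
    "LCRSeries",
    "classify_viability",
    "day_summary",
    "concentration",
    "lcr",
    "propagate_ratio_error",
    "three_day_average",
    "student_t_two_tailed",
    "percent_change",
    "build_lcr_series",
    "DEFAULT_AREA_MM2",
    "DEFAULT_FI_THRESHOLD_AU",
]

DEFAULT_AREA_MM2 = 1.77
DEFAULT_FI_THRESHOLD_AU = 100.0


def classify_viability(
    fi_au: float, threshold_au: float = DEFAULT_FI_THRESHOLD_AU
) -> Literal["live", "dead"]:
    """Live iff FI is strictly below the threshold (default 100 a.u.)."""
    if fi_au < 0:
        raise ValueError("fluorescence intensity must be non-negative")
    return "live" if fi_au < threshold_au else "dead"


def day_summary(
    x_i: Sequence[float], ddof: int = 0
) -> tuple[float, float]:
    """Mean and SD of per-image counts; population SD (divisor n) by default.

    ``ddof=1`` gives the sample SD as an alternative.
    """
    if len(x_i) == 0:
        raise ValueError("at least one image count is required")
    x = np.asarray(x_i, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if ddof >= len(x):
        return float(x.mean()), 0.0
    return float(x.mean()), float(x.std(ddof=ddof))


def concentration(x_bar: float, area_mm2: float = DEFAULT_AREA_MM2) -> float:
    """Areal live-cell concentration: mean count per field area (cells/mm²)."""
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    return x_bar / area_mm2


def lcr(day_concentrations: Mapping[int, float]) -> dict[int, float]:
    """Live cell ratio per day, normalised to Day 0; LCR(0) = 1 exactly."""
    if 0 not in day_concentrations:
        raise ValueError("Day-0 concentration is required to define the LCR")
    c0 = day_concentrations[0]
    if c0 <= 0:
        raise ZeroDivisionError("Day-0 concentration must be positive")
    out = {n: c / c0 for n, c in day_concentrations.items()}
    out[0] = 1.0
    return out


def propagate_ratio_error(
    m1: float,
    m2: float,
    eps1: float,
    eps2: float,
    mode: Literal["printed", "standard"] = "printed",
) -> float:
    """Error of the ratio m1/m2 given absolute errors eps1, eps2 (see module docs)."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("m1 and m2 must be positive")
    if eps1 < 0 or eps2 < 0:
        raise ValueError("errors must be non-negative")
    if mode == "printed":
        return float(np.sqrt((eps1 / m1) ** 2 + (eps2 / m2**2) ** 2))
    if mode == "standard":
        return float((m1 / m2) * np.sqrt((eps1 / m1) ** 2 + (eps2 / m2) ** 2))
    raise ValueError(f"unknown error mode {mode!r}")


def three_day_average(
    lcr_values: Mapping[int, float], lcr_errors: Mapping[int, float]
) -> tuple[float, float]:
    """Mean of LCR(1..3) with errors combined in quadrature (independence assumed)."""
    days = (1, 2, 3)
    missing = [n for n in days if n not in lcr_values]
    if missing:
        raise ValueError(f"LCR missing for days {missing}")
    vals = np.array([lcr_values[n] for n in days])
    errs = np.array([lcr_errors.get(n, 0.0) for n in days])
    return float(vals.mean()), float(np.sqrt(np.sum(errs**2)) / len(days))


def student_t_two_tailed(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance unpaired t with two-tailed p (df = n_a + n_b - 2).

    Degenerate inputs (both samples constant) use the convention t = 0, p = 1
    when the means coincide and |t| = inf, p = 0 otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def percent_change(
    before: float,
    after: float,
    convention: Literal["after-minus-before", "before-minus-after"] = "after-minus-before",
) -> float:
    """Percent change of a quantity relative to its baseline.

    The default is 100*(after - before)/before.  The alternative sign
    convention 100*(before - after)/before is provided because a reported
    change below -100% is only reachable when the difference is taken that
    way round.
    """
    if before <= 0:
        raise ValueError("baseline must be positive")
    if convention == "after-minus-before":
        return 100.0 * (after - before) / before
    if convention == "before-minus-after":
        return 100.0 * (before - after) / before
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class DayCounts:
    """Per-day live-count summary: counts, mean, SD, areal concentration."""

    day: int
    x_i: list[int]
    x_bar: float
    sigma: float
    concentration_per_mm2: float

    @classmethod
    def from_counts(
        cls, day: int, x_i: Sequence[int],
        area_mm2: float = DEFAULT_AREA_MM2, ddof: int = 0,
    ) -> "DayCounts":
        x_bar, sigma = day_summary(x_i, ddof=ddof)
        return cls(day, list(x_i), x_bar, sigma, concentration(x_bar, area_mm2))


@dataclass
class LCRSeries:
    """LCR(N) with propagated errors and the 3-day average summary."""

    lcr: dict[int, float]
    lcr_err: dict[int, float]
    three_day_avg: float | None = None
    three_day_avg_err: float | None = None


def build_lcr_series(
    day_counts: Mapping[int, DayCounts],
    error_mode: Literal["printed", "standard"] = "printed",
) -> LCRSeries:
    """Assemble the LCR time course from per-day summaries.

    Ratio errors are propagated from the per-day count means and SDs
    (M1 = x̄(N), M2 = x̄(0), eps = σ); the common field area cancels in the
    ratio.  Day 0 carries zero error since LCR(0) = 1 by definition.  The
    3-day average is filled in when Days 1..3 are all present.
    """
    if 0 not in day_counts:
        raise ValueError("Day 0 is required to define the LCR")
    d0 = day_counts[0]
    ratios = lcr({n: dc.concentration_per_mm2 for n, dc in day_counts.items()})
    errors: dict[int, float] = {}
    for n, dc in day_counts.items():
        if n == 0:
            errors[0] = 0.0
        else:
            errors[n] = propagate_ratio_error(
                dc.x_bar, d0.x_bar, dc.sigma, d0.sigma, mode=error_mode
            )
    series = LCRSeries(ratios, errors)
    if all(n in ratios for n in (1, 2, 3)):
        series.three_day_avg, series.three_day_avg_err = three_day_average(
            ratios, errors
        )
    return series
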