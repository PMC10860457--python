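"""Population error decomposition and van Herk planning-margin estimation.

Each patient contributes a deviation series (e.g., diaphragm-vs-marker
absolute differences per axis, or detected-vs-predicted 3D differences).
Per patient this reduces to a mean absolute deviation and an SD. Across
patients:

* systematic error  Sigma = SD (n-1) of the per-patient means — a
  preparation-type error that shifts the whole dose distribution;
* random error      sigma = RMS of the per-patient SDs — an execution-type
  error that blurs the distribution.

The CTV-to-PTV margin follows the classic van Herk recipe
``margin = k_sys * Sigma + k_rand * sigma`` with the usual coefficients
2.5 and 0.7 (minimum cumulative CTV dose >= 95% of prescription for 90% of
patients). Both coefficients are configurable and echoed in the result, and
independent error sources combine in quadrature.

The study's per-patient deviation tables are packaged as CSV fixtures
(``mdtt/data/table*.csv``) so the population rows can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "PatientStats",
    "PopulationErrors",
    "MarginResult",
    "patient_stats",
    "population_errors",
    "combine_error_sources",
    "van_herk_margin",
    "load_table",
    "table_population_errors",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at report time (2.345 -> 2.35, not 2.34).

    Internal computation stays at full precision; this is applied only when
    comparing against, or printing, fixed-precision report values. The
    float is first snapped to 10 decimals so representation error (e.g.
    62.65 stored as 62.64999...) cannot flip a half-way case.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(round(x, 10))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PatientStats:
    """One patient's deviation summary: mean absolute deviation and SD (mm)."""

    patient_id: str
    mean: float
    sd: float
    axis: str = "3d"  # "ml" | "si" | "ap" | "3d"

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("deviation statistics must be non-negative")


@dataclass(frozen=True)
class PopulationErrors:
    """Population decomposition of a deviation quantity (all mm)."""

    mean_of_means: float
    sigma_systematic: float  # SD (n-1) of the per-patient means
    sigma_random: float  # RMS of the per-patient SDs
    n_patients: int
    axis: str = "3d"


@dataclass(frozen=True)
class MarginResult:
    """A CTV-to-PTV margin and the rule that produced it."""

    margin_mm: float
    k_sys: float
    k_rand: float
    sigma_systematic: float
    sigma_random: float
    axis: str = "3d"
    rule: str = "k_sys*Sigma + k_rand*sigma"


def patient_stats(
    deviation_series, patient_id: str = "", axis: str = "3d"
) -> PatientStats:
    """Reduce one patient's deviation series to (mean |dev|, SD).

    The mean is taken over absolute deviations; the SD (n-1 denominator)
    is of the same absolute series. Requires at least 2 samples.
    """
    d = np.abs(np.asarray(deviation_series, dtype=float))
    if d.size < 2:
        raise ValueError("need at least 2 samples per patient")
    return PatientStats(
        patient_id=patient_id, mean=float(d.mean()), sd=float(d.std(ddof=1)), axis=axis
    )


def population_errors(stats, axis: str | None = None) -> PopulationErrors:
    """Aggregate per-patient stats into Sigma (systematic) and sigma (random).

    mean_of_means is the arithmetic mean of the per-patient means; Sigma is
    their SD with the n-1 denominator; sigma is the root mean square of the
    per-patient SDs. Requires >= 2 patients. If ``axis`` is given, every
    patient must carry that axis label.
    """
    stats = list(stats)
    if len(stats) < 2:
        raise ValueError("population errors need >= 2 patients")
    if axis is not None:
        missing = [s.patient_id for s in stats if s.axis != axis]
        if missing:
            raise ValueError(f"axis {axis!r} missing for patients {missing}")
    else:
        axis = stats[0].axis
    means = np.array([s.mean for s in stats])
    sds = np.array([s.sd for s in stats])
    return PopulationErrors(
        mean_of_means=float(means.mean()),
        sigma_systematic=float(means.std(ddof=1)),
        sigma_random=float(np.sqrt(np.mean(sds**2))),
        n_patients=len(stats),
        axis=axis,
    )


def combine_error_sources(components) -> PopulationErrors:
    """Combine independent error sources in quadrature (per component type)."""
    components = list(components)
    if not components:
        raise ValueError("need at least one component")
    return PopulationErrors(
        mean_of_means=float(np.sqrt(sum(c.mean_of_means**2 for c in components))),
        sigma_systematic=float(
            np.sqrt(sum(c.sigma_systematic**2 for c in components))
        ),
        sigma_random=float(np.sqrt(sum(c.sigma_random**2 for c in components))),
        n_patients=min(c.n_patients for c in components),
        axis=components[0].axis,
    )


def van_herk_margin(
    errors: PopulationErrors, k_sys: float = 2.5, k_rand: float = 0.7
) -> MarginResult:
    """CTV-to-PTV margin ``k_sys * Sigma + k_rand * sigma`` (mm)."""
    if k_sys < 0 or k_rand < 0:
        raise ValueError("margin coefficients must be non-negative")
    return MarginResult(
        margin_mm=k_sys * errors.sigma_systematic + k_rand * errors.sigma_random,
        k_sys=k_sys,
        k_rand=k_rand,
        sigma_systematic=errors.sigma_systematic,
        sigma_random=errors.sigma_random,
        axis=errors.axis,
    )


def load_table(n: int) -> pd.DataFrame:
    """Load a packaged per-patient fixture table (1-4)."""
    if n not in (1, 2, 3, 4):
        raise ValueError("tables 1-4 are packaged")
    with resources.files("mdtt.data").joinpath(f"table{n}.csv").open() as fh:
        return pd.read_csv(fh)


def table_population_errors(table: pd.DataFrame, axis: str) -> PopulationErrors:
    """Population errors from a per-patient fixture table.

    ``axis`` is one of ml/si/ap (tables with per-axis columns) or 3d
    (tables with a single 3D column pair).
    """
    if axis == "3d":
        mean_col, sd_col = "mean_3d_mm", "sd_3d_mm"
    else:
        mean_col, sd_col = f"{axis}_mean_mm", f"{axis}_sd_mm"
    stats = [
        PatientStats(
            str(r["patient_id"]), float(r[mean_col]), float(r[sd_col]), axis=axis
        )
        for _, r in table.iterrows()
    ]
    return population_errors(stats, axis=axis)
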