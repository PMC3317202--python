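"""Human kinetic adjustment factors (HKAFs) and coverage analysis.

The HKAF is the data-derived replacement for the default toxicokinetic half
(3.16) of the 10-fold interindividual uncertainty factor.  Two approaches
are computed:

- *whole population*: an upper percentile (95th or 99th) of the dose metric
  in the mixed-demography population divided by a referent median (the
  population's own median, or the median of a separately simulated adult
  population);
- *distinct subpopulation*: the upper percentile within one presumed
  susceptible subgroup divided by the referent median; the greatest value
  across subgroups is the candidate adjustment factor.

Coverage quantifies protectiveness: the fraction of a (sub)population whose
dose metric falls strictly below the threshold implied by a factor times
the referent median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import PopulationDataset

__all__ = [
    "HkafResult",
    "CoverageResult",
    "percentile_value",
    "hkaf_whole",
    "hkaf_distinct",
    "coverage",
    "threshold_from_factor",
    "build_reports",
]

#: Default toxicokinetic half of the 10-fold interindividual factor.
DEFAULT_TK_FACTOR = 3.16


@dataclass(frozen=True)
class HkafResult:
    """One cell of the HKAF grid."""

    approach: str  # "whole_population" | "distinct_subpopulation"
    referent: str  # "adult_median" | "population_median"
    percentile: float
    metric: str  # "cass" | "ram"
    value: float
    subpop: str | None = None  # distinct approach only


@dataclass(frozen=True)
class CoverageResult:
    """Fraction of a group lying strictly below a threshold dose metric."""

    group: str
    metric: str
    threshold: float
    fraction_covered: float


def percentile_value(samples, p: float) -> float:
    """Order-statistic percentile with linear interpolation between ranks.

    This is the fixed percentile convention of the package (numpy's
    ``linear`` method); the whole HKAF grid uses it.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot take a percentile of an empty sample")
    if not 0 < p < 100:
        raise ValueError(f"percentile must lie in (0, 100), got {p}")
    return float(np.percentile(samples, p, method="linear"))


def _referent_median(
    pop: PopulationDataset,
    metric: str,
    referent: str,
    adult_data: PopulationDataset | None,
) -> float:
    if referent == "population_median":
        return percentile_value(pop.metric(metric), 50)
    if referent == "adult_median":
        if adult_data is None:
            raise ValueError("adult_median referent requires an adult-only dataset")
        return percentile_value(adult_data.metric(metric), 50)
    raise ValueError(f"unknown referent {referent!r}")


def hkaf_whole(
    pop: PopulationDataset,
    metric: str,
    percentile: float,
    referent: str = "population_median",
    adult_data: PopulationDataset | None = None,
) -> HkafResult:
    """Whole-population HKAF: population upper percentile over a referent median."""
    ref_median = _referent_median(pop, metric, referent, adult_data)
    if ref_median <= 0:
        raise ValueError("referent median must be positive")
    value = percentile_value(pop.metric(metric), percentile) / ref_median
    return HkafResult(
        approach="whole_population",
        referent=referent,
        percentile=percentile,
        metric=metric,
        value=value,
    )


def hkaf_distinct(
    subpop_data: PopulationDataset,
    referent_median: float,
    percentile: float,
    metric: str = "cass",
) -> HkafResult:
    """Distinct-subpopulation HKAF: subgroup upper percentile over a referent median."""
    if referent_median <= 0:
        raise ValueError("referent median must be positive")
    value = percentile_value(subpop_data.metric(metric), percentile) / referent_median
    subpop = subpop_data.samples.subpop.iloc[0]
    return HkafResult(
        approach="distinct_subpopulation",
        referent="external",
        percentile=percentile,
        metric=metric,
        value=value,
        subpop=str(subpop),
    )


def coverage(group: PopulationDataset, metric: str, threshold: float) -> CoverageResult:
    """Fraction of ``group`` with dose metric strictly below ``threshold``.

    Ties count as not covered (the threshold itself is not "lower than").
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = group.metric(metric)
    return CoverageResult(
        group=group.label,
        metric=metric,
        threshold=float(threshold),
        fraction_covered=float(np.mean(values < threshold)),
    )


def threshold_from_factor(factor: float, referent_median: float) -> float:
    """Dose-metric threshold implied by an adjustment factor times a median."""
    if factor <= 0 or referent_median <= 0:
        raise ValueError("factor and referent median must be positive")
    return factor * referent_median


# ---------------------------------------------------------------------------
# report assembly

_METRICS = ("cass", "ram")


def build_reports(
    population: PopulationDataset,
    subpopulations: dict[str, PopulationDataset],
    percentiles: tuple[float, ...] = (95, 99),
    factors: tuple[float, ...] = (DEFAULT_TK_FACTOR,),
) -> dict[str, pd.DataFrame]:
    """Assemble the three standard report tables for one chemical.

    Parameters
    ----------
    population
        The merged mixed-demography dataset.
    subpopulations
        Independently simulated per-subpopulation datasets (typically
        100,000 individuals each); must include ``adults``, which provides
        the adult referent median.
    percentiles
        Upper percentiles for the HKAF grid (may be empty, in which case
        only distribution statistics are reported).
    factors
        Fixed adjustment factors for the coverage table (default 3.16).

    Returns
    -------
    dict with keys ``distribution`` (1st/median/99th percentiles per group
    and metric), ``hkaf`` (the full approach x referent x percentile x
    metric grid) and ``coverage`` (per-subgroup coverage under the
    whole-population HKAF thresholds and the fixed factors, plus
    whole-population coverage under the greatest distinct-subpopulation
    HKAF).
    """
    if "adults" not in subpopulations:
        raise ValueError("missing dataset: subpopulation 'adults' is required")
    for name, ds in subpopulations.items():
        if ds is None or len(ds) == 0:
            raise ValueError(f"missing dataset: subpopulation {name!r} is empty")

    adults = subpopulations["adults"]

    # --- distribution statistics -----------------------------------------
    dist_rows = []
    groups: list[tuple[str, PopulationDataset]] = [
        *subpopulations.items(),
        (population.label, population),
    ]
    for name, ds in groups:
        for metric in _METRICS:
            x = ds.metric(metric)
            dist_rows.append(
                {
                    "group": name,
                    "metric": metric,
                    "p1": percentile_value(x, 1),
                    "median": percentile_value(x, 50),
                    "p99": percentile_value(x, 99),
                }
            )
    distribution = pd.DataFrame(dist_rows)

    # --- HKAF grid --------------------------------------------------------
    hkaf_rows = []
    results: list[HkafResult] = []
    for metric in _METRICS:
        medians = {
            "adult_median": percentile_value(adults.metric(metric), 50),
            "population_median": percentile_value(population.metric(metric), 50),
        }
        for p in percentiles:
            for referent in ("adult_median", "population_median"):
                results.append(
                    hkaf_whole(population, metric, p, referent, adult_data=adults)
                )
            for name, ds in subpopulations.items():
                for referent, med in medians.items():
                    r = hkaf_distinct(ds, med, p, metric)
                    results.append(
                        HkafResult(
                            approach=r.approach,
                            referent=referent,
                            percentile=p,
                            metric=metric,
                            value=r.value,
                            subpop=name,
                        )
                    )
    for r in results:
        hkaf_rows.append(
            {
                "approach": r.approach,
                "subpop": r.subpop or "",
                "referent": r.referent,
                "percentile": r.percentile,
                "metric": r.metric,
                "hkaf": r.value,
            }
        )
    hkaf_grid = pd.DataFrame(hkaf_rows)

    # --- coverage ---------------------------------------------------------
    cov_rows = []
    for metric in _METRICS:
        pop_values = population.metric(metric)
        pop_median = percentile_value(pop_values, 50)
        thresholds: list[tuple[str, float]] = [
            (f"whole_population_hkaf_p{p:g}", percentile_value(pop_values, p))
            for p in percentiles
        ]
        thresholds += [(f"factor_{f:g}", threshold_from_factor(f, pop_median)) for f in factors]
        for name, ds in subpopulations.items():
            for desc, thr in thresholds:
                c = coverage(ds, metric, thr)
                cov_rows.append(
                    {
                        "group": name,
                        "metric": metric,
                        "descriptor": desc,
                        "threshold": thr,
                        "fraction_covered": c.fraction_covered,
                    }
                )
        # whole-population coverage under the greatest distinct-subpop HKAF
        for p in percentiles:
            adult_median = percentile_value(adults.metric(metric), 50)
            greatest = max(
                hkaf_distinct(ds, adult_median, p, metric).value
                for ds in subpopulations.values()
            )
            thr = threshold_from_factor(greatest, pop_median)
            c = coverage(population, metric, thr)
            cov_rows.append(
                {
                    "group": population.label,
                    "metric": metric,
                    "descriptor": f"greatest_distinct_hkaf_p{p:g}",
                    "threshold": thr,
                    "fraction_covered": c.fraction_covered,
                }
            )
        for f in factors:
            thr = threshold_from_factor(f, pop_median)
            c = coverage(population, metric, thr)
            cov_rows.append(
                {
                    "group": population.label,
                    "metric": metric,
                    "descriptor": f"factor_{f:g}",
                    "threshold": thr,
                    "fraction_covered": c.fraction_covered,
                }
            )
    coverage_table = pd.DataFrame(cov_rows)

    return {"distribution": distribution, "hkaf": hkaf_grid, "coverage": coverage_table}
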