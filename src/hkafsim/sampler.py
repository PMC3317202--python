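"""Monte Carlo sampling of virtual individuals.

Body weight and hepatic CYP2E1 content are drawn from truncated lognormals;
the allometric equations below then yield each individual's alveolar
ventilation rate (Qp), liver volume (Vl) and liver blood flow (Ql), each
multiplied by an independently drawn truncated-normal "variability term".

Conventions (fixed across the package):

- Lognormals specified by arithmetic mean/SD are converted to log-scale
  parameters by exact moment matching.
- Truncation is enforced by rejection sampling (resample until inside the
  bounds), never by clipping, so no probability mass piles up at the bounds.
- The allometric formulas for Qp and Ql evaluate to L/min and are converted
  to L/h; Vl is in litres.
- Pregnant women: liver volume and liver blood flow are computed from the
  non-pregnant body weight, while the ventilation rate uses the pregnant
  weight (non-pregnant weight plus gestational gain), reflecting the raised
  ventilation of pregnancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import DistributionSpec, SubpopulationSpec

__all__ = [
    "Individual",
    "lognormal_params_from_arithmetic",
    "sample_truncated",
    "compute_qp",
    "compute_vl",
    "compute_ql",
    "sample_individual",
    "sample_cohort",
]

#: Minimum probability mass a truncation interval may contain before
#: sampling refuses to run (rejection would be hopelessly inefficient).
MIN_ACCEPTANCE = 1e-4


@dataclass(frozen=True)
class Individual:
    """One sampled virtual human.

    ``bw`` is the non-pregnant body weight (kg); for subgroups other than
    pregnant women ``bw_pregnant == bw``.  ``qp``, ``ql`` are in L/h and
    ``vl`` in L; ``cyp2e1`` is in pmol/mg microsomal protein.
    """

    subpop: str
    bw: float
    bw_pregnant: float
    cyp2e1: float
    qp: float
    vl: float
    ql: float

    def __post_init__(self) -> None:
        for attr in ("bw", "bw_pregnant", "cyp2e1", "qp", "vl", "ql"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.bw_pregnant < self.bw:
            raise ValueError("pregnant body weight cannot be below non-pregnant weight")


def lognormal_params_from_arithmetic(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (location, shape) of the lognormal with given arithmetic moments.

    Returns ``(mu, sigma)`` such that ``exp(Normal(mu, sigma))`` has
    arithmetic mean ``mean`` and arithmetic SD ``sd``:
    ``sigma^2 = ln(1 + (sd/mean)^2)`` and ``mu = ln(mean) - sigma^2 / 2``.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _log_params(spec: DistributionSpec) -> tuple[float, float]:
    if spec.kind == "lognormal-geometric":
        return float(np.log(spec.central)), float(np.log(spec.spread))
    return lognormal_params_from_arithmetic(spec.central, spec.spread)


def _truncation_mass(spec: DistributionSpec) -> float:
    """Probability mass of the untruncated distribution inside the bounds."""
    if spec.kind == "truncated-normal":
        dist = stats.norm(spec.central, spec.spread)
        return float(dist.cdf(spec.upper) - dist.cdf(spec.lower))
    mu, sigma = _log_params(spec)
    dist = stats.norm(mu, sigma)
    lo = -np.inf if spec.lower <= 0 else np.log(spec.lower)
    return float(dist.cdf(np.log(spec.upper)) - dist.cdf(lo))


def sample_truncated(
    spec: DistributionSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw from ``spec`` by rejection sampling within its truncation bounds.

    Returns a scalar when ``size`` is None, else an array of length ``size``.
    Raises ``ValueError`` when the bounds capture less than ``MIN_ACCEPTANCE``
    of the distribution's mass (instead of looping forever).
    """
    if _truncation_mass(spec) < MIN_ACCEPTANCE:
        raise ValueError(
            f"truncation interval [{spec.lower}, {spec.upper}] holds negligible "
            f"probability mass for {spec.kind} ({spec.central} +/- {spec.spread})"
        )
    n = 1 if size is None else int(size)
    if spec.kind == "truncated-normal":
        draw = lambda k: rng.normal(spec.central, spec.spread, k)
    else:
        mu, sigma = _log_params(spec)
        draw = lambda k: rng.lognormal(mu, sigma, k)
    out = np.empty(n)
    pending = np.arange(n)
    while pending.size:
        x = draw(pending.size)
        ok = (x >= spec.lower) & (x <= spec.upper)
        out[pending[ok]] = x[ok]
        pending = pending[~ok]
    return float(out[0]) if size is None else out


def compute_qp(bw, var):
    """Alveolar ventilation rate, L/h.

    Mean of two allometric power laws in body weight (each yielding L/min),
    converted to L/h and scaled by the dimensionless variability term.
    """
    bw = np.asarray(bw, dtype=float)
    base = (0.2519 * bw**0.7609 + 0.2508 * bw**0.7815) / 2.0
    return base * 60.0 * var


def compute_vl(bw, var):
    """Liver volume, L: ``0.05012 * BW^0.78`` times the variability term."""
    bw = np.asarray(bw, dtype=float)
    return 0.05012 * bw**0.78 * var


def compute_ql(vl, var):
    """Liver blood flow, L/h: ``0.92 * Vl`` L/min, converted to L/h, times var."""
    return 0.92 * np.asarray(vl, dtype=float) * 60.0 * var


def sample_cohort(
    spec: SubpopulationSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample ``n`` independent individuals from one subpopulation.

    Returns a DataFrame with one row per individual and columns ``subpop,
    bw, bw_pregnant, cyp2e1, qp, vl, ql`` (units as in :class:`Individual`).
    Draw order is fixed (bw, cyp2e1, gain, qp_var, vl_var, ql_var), so a
    given seed always yields the identical cohort.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    bw = sample_truncated(spec.bw_dist, rng, n)
    cyp = sample_truncated(spec.cyp2e1_dist, rng, n)
    if spec.pregnancy_gain_dist is not None:
        gain = sample_truncated(spec.pregnancy_gain_dist, rng, n)
    else:
        gain = np.zeros(n)
    qp_var = sample_truncated(spec.qp_var, rng, n)
    vl_var = sample_truncated(spec.vl_var, rng, n)
    ql_var = sample_truncated(spec.ql_var, rng, n)

    bw_pregnant = bw + gain
    vl = compute_vl(bw, vl_var)  # non-pregnant weight by convention
    return pd.DataFrame(
        {
            "subpop": spec.name,
            "bw": bw,
            "bw_pregnant": bw_pregnant,
            "cyp2e1": cyp,
            "qp": compute_qp(bw_pregnant, qp_var) * spec.qp_scale,
            "vl": vl,
            "ql": compute_ql(vl, ql_var),
        }
    )


def sample_individual(spec: SubpopulationSpec, rng: np.random.Generator) -> Individual:
    """Sample a single virtual individual (see :func:`sample_cohort`)."""
    row = sample_cohort(spec, 1, rng).iloc[0]
    return Individual(
        subpop=row["subpop"],
        bw=float(row["bw"]),
        bw_pregnant=float(row["bw_pregnant"]),
        cyp2e1=float(row["cyp2e1"]),
        qp=float(row["qp"]),
        vl=float(row["vl"]),
        ql=float(row["ql"]),
    )
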