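"""Closed-form steady-state toxicokinetics for continuous inhalation.

For an individual continuously inhaling a volatile organic chemical at air
concentration Ci, the arterial blood concentration at steady state balances
pulmonary uptake against hepatic (Ql * E_hep) and pulmonary (Qp / Pb)
clearance::

    CAss = Qp * Ci / (Ql * E_hep + Qp / Pb)

with the hepatic extraction ratio of the well-stirred liver,
``E_hep = Clint / (Clint + Ql)``, and the rate of metabolism per litre of
liver ``RAM = CAss * Ql * E_hep / Vl``.

Interindividual variability enters through the physiology (Qp, Ql, Vl) and
through the whole-liver maximal metabolic rate, scaled from a reference
adult by the individual's hepatic CYP2E1 content and liver volume::

    Vmax_ind = Vmax_c * BW_ref^0.75 / (CYP2E1_ref * Vl_ref) * CYP2E1_ind * Vl_ind

In the first-order (low-concentration) regime the intrinsic clearance is
``Clint = Vmax / Km``.

All internal computation is in mg, L and h; CAss is reported in ug/L and
RAM in ug/h per L liver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import Chemical, SubpopulationSpec, builtin_subpopulations

__all__ = [
    "ReferenceAdult",
    "default_reference_adult",
    "vmax_individual",
    "intrinsic_clearance",
    "hepatic_extraction",
    "cass",
    "ram",
    "dose_metrics",
]


@dataclass(frozen=True)
class ReferenceAdult:
    """Average adult anchoring the metabolic capacity scaling.

    ``cyp2e1_avg`` is the *arithmetic* mean of the adult hepatic CYP2E1
    distribution.  With the built-in adult parameters this convention puts
    the central intrinsic clearance near 400 L/h for benzene and 1.7 L/h
    for 1,4-dioxane, consistent with the flow-limited/enzyme-limited
    contrast the two chemicals are meant to span.
    """

    bw_avg: float
    vl_avg: float
    cyp2e1_avg: float

    def __post_init__(self) -> None:
        for attr in ("bw_avg", "vl_avg", "cyp2e1_avg"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @classmethod
    def from_subpopulation(cls, spec: SubpopulationSpec) -> "ReferenceAdult":
        """Build the reference from an adult subpopulation specification.

        Body weight is the distribution's arithmetic mean; liver volume is
        the allometric value at that weight with variability term 1; CYP2E1
        is the arithmetic mean of the (untruncated) content distribution.
        """
        bw = spec.bw_dist.central
        if spec.cyp2e1_dist.kind == "lognormal-geometric":
            gm, gsd = spec.cyp2e1_dist.central, spec.cyp2e1_dist.spread
            cyp = gm * np.exp(np.log(gsd) ** 2 / 2.0)
        else:
            cyp = spec.cyp2e1_dist.central
        vl = 0.05012 * bw**0.78
        return cls(bw_avg=float(bw), vl_avg=float(vl), cyp2e1_avg=float(cyp))


def default_reference_adult() -> ReferenceAdult:
    """Reference adult derived from the built-in adult distributions."""
    return ReferenceAdult.from_subpopulation(builtin_subpopulations()["adults"])


def vmax_individual(chem: Chemical, ref: ReferenceAdult, ind) -> float:
    """Whole-liver maximal metabolic rate of one individual, mg/h.

    Scales the reference-adult capacity ``vmax_c * bw_avg^0.75`` by the
    individual's CYP2E1 content and liver volume relative to the reference.
    ``ind`` may be an :class:`~hkafsim.sampler.Individual` or a cohort
    DataFrame (vectorized over rows).
    """
    per_unit = chem.vmax_c * ref.bw_avg**0.75 / (ref.cyp2e1_avg * ref.vl_avg)
    return per_unit * ind.cyp2e1 * ind.vl


def intrinsic_clearance(vmax, km: float):
    """First-order intrinsic clearance ``Clint = Vmax / Km``, L/h."""
    if km <= 0:
        raise ValueError("km must be positive")
    return vmax / km


def hepatic_extraction(clint, ql):
    """Well-stirred hepatic extraction ratio ``Clint / (Clint + Ql)`` in [0, 1)."""
    clint = np.asarray(clint, dtype=float)
    return clint / (clint + ql)


def cass(chem: Chemical, ind, ehep):
    """Steady-state arterial blood concentration, ug/L.

    The exposure concentration is converted from mg/m^3 to mg/L; the result
    is converted from mg/L to ug/L at the boundary.
    """
    ci_mg_per_l = chem.exposure_conc / 1000.0
    denom = np.asarray(ind.ql * ehep + ind.qp / chem.pb, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("no steady state: hepatic and pulmonary clearance both zero")
    return ind.qp * ci_mg_per_l / denom * 1000.0


def ram(cass_value, ind, ehep):
    """Rate of metabolism per litre of liver, ug/h-L: ``CAss * Ql * E_hep / Vl``."""
    return cass_value * ind.ql * ehep / ind.vl


def dose_metrics(
    chem: Chemical, cohort: pd.DataFrame, ref: ReferenceAdult | None = None
) -> pd.DataFrame:
    """Run a sampled cohort through the steady-state core.

    Returns a DataFrame with columns ``subpop``, ``cass`` (ug/L) and ``ram``
    (ug/h per L liver), one row per individual of ``cohort`` (as produced by
    :func:`hkafsim.sampler.sample_cohort`).
    """
    if ref is None:
        ref = default_reference_adult()
    vmax = vmax_individual(chem, ref, cohort)
    clint = intrinsic_clearance(vmax, chem.km)
    ehep = hepatic_extraction(clint, cohort.ql)
    ca = cass(chem, cohort, ehep)
    return pd.DataFrame(
        {
            "subpop": cohort.subpop.to_numpy(),
            "cass": np.asarray(ca, dtype=float),
            "ram": np.asarray(ram(ca, cohort, ehep), dtype=float),
        }
    )
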