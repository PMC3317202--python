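"""Built-in chemical, physiological and demographic parameter registries.

Chemicals, subpopulation sampling distributions and demographic profiles are
shipped as plain YAML files under :mod:`hkafsim.data` so that users can add
new chemicals or population structures without touching code.  The loaders
here turn those files into validated, immutable domain objects.

Seven discrete subpopulations are modelled: adults (18-64 yr), neonates
(0-30 d), infants (1-12 mo), toddlers (1-3 yr), children and adolescents
(4-17 yr), elderly (65-90 yr) and pregnant women (15-44 yr).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SUBPOPULATIONS",
    "Chemical",
    "DistributionSpec",
    "SubpopulationSpec",
    "DemographicProfile",
    "builtin_chemicals",
    "get_chemical",
    "builtin_subpopulations",
    "load_chemical",
    "canadian_profile",
    "younger_profile",
    "load_profile",
]

#: Canonical ordering of the seven subpopulations (used for deterministic
#: iteration everywhere).
SUBPOPULATIONS = (
    "adults",
    "neonates",
    "infants",
    "toddlers",
    "children_adolescents",
    "elderly",
    "pregnant_women",
)

#: Subgroups aged under 18 years.
UNDER_18 = ("neonates", "infants", "toddlers", "children_adolescents")

_DIST_KINDS = ("lognormal-arithmetic", "lognormal-geometric", "truncated-normal")


@dataclass(frozen=True)
class Chemical:
    """Chemical-specific constants of the steady-state algorithm.

    Parameters
    ----------
    name
        Chemical name.
    vmax_c
        Maximum rate of metabolism constant, mg/h per kg^0.75 body weight.
    km
        Michaelis-Menten affinity constant, mg/L.
    pb
        Blood:air partition coefficient (dimensionless); governs pulmonary
        uptake and clearance.
    exposure_conc
        Continuously inhaled air concentration, mg/m^3.
    """

    name: str
    vmax_c: float
    km: float
    pb: float
    exposure_conc: float

    def __post_init__(self) -> None:
        if self.vmax_c < 0:
            raise ValueError(f"vmax_c must be >= 0, got {self.vmax_c}")
        for attr in ("km", "pb", "exposure_conc"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")


@dataclass(frozen=True)
class DistributionSpec:
    """A truncated sampling distribution for one physiological quantity.

    ``kind`` selects the parameterization:

    - ``lognormal-arithmetic``: ``central``/``spread`` are the arithmetic
      mean and SD of the (untruncated) lognormal.
    - ``lognormal-geometric``: ``central``/``spread`` are the geometric mean
      and geometric SD.
    - ``truncated-normal``: ``central``/``spread`` are the normal mean/SD.

    ``lower``/``upper`` are hard truncation bounds; sampling rejects draws
    outside them.
    """

    kind: str
    central: float
    spread: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in _DIST_KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(f"require lower < upper, got [{self.lower}, {self.upper}]")
        if self.spread <= 0:
            raise ValueError(f"spread must be > 0, got {self.spread}")
        if self.kind.startswith("lognormal") and self.central <= 0:
            raise ValueError("lognormal central value must be > 0")
        if self.kind == "lognormal-geometric" and self.spread <= 1:
            raise ValueError("geometric SD must exceed 1")


@dataclass(frozen=True)
class SubpopulationSpec:
    """Sampling distributions and metadata for one demographic subgroup.

    ``qp_scale`` is a fixed multiplier on the allometric alveolar
    ventilation rate (1 everywhere except pregnant women, whose ventilation
    is raised beyond the weight-gain effect).
    """

    name: str
    age_range: str
    bw_dist: DistributionSpec
    cyp2e1_dist: DistributionSpec
    qp_var: DistributionSpec
    vl_var: DistributionSpec
    ql_var: DistributionSpec
    pregnancy_gain_dist: DistributionSpec | None = None
    qp_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.name == "pregnant_women" and self.pregnancy_gain_dist is None:
            raise ValueError("pregnant_women requires a pregnancy_gain_dist")
        if self.qp_scale <= 0:
            raise ValueError("qp_scale must be positive")


@dataclass(frozen=True)
class DemographicProfile:
    """Number of simulated individuals per subpopulation."""

    name: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SUBPOPULATIONS)
        if unknown:
            raise ValueError(f"unknown subpopulations in profile: {sorted(unknown)}")
        for sub, n in self.counts.items():
            if n <= 0:
                raise ValueError(f"count for {sub} must be > 0, got {n}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction_under_18(self) -> float:
        """Fraction of the profile aged under 18 years."""
        return sum(self.counts.get(s, 0) for s in UNDER_18) / self.total


# ---------------------------------------------------------------------------
# loaders

def _data_root():
    return resources.files("hkafsim") / "data"


def _chemical_from_mapping(raw: Mapping) -> Chemical:
    return Chemical(
        name=str(raw["name"]),
        vmax_c=float(raw["vmax_c"]),
        km=float(raw["km"]),
        pb=float(raw["pb"]),
        exposure_conc=float(raw["exposure_conc"]),
    )


def load_chemical(path: str | Path) -> Chemical:
    """Load a chemical definition from a user-supplied YAML file."""
    with open(path) as fh:
        return _chemical_from_mapping(yaml.safe_load(fh))


def builtin_chemicals() -> list[Chemical]:
    """The two built-in surrogate chemicals, benzene and 1,4-dioxane.

    They bracket the clearance spectrum of CYP2E1 substrates: benzene is
    extensively cleared (low pb, high hepatic extraction), 1,4-dioxane is
    poorly cleared (very high pb, low hepatic extraction).
    """
    out = []
    for name in ("benzene", "dioxane"):
        raw = yaml.safe_load((_data_root() / "chemicals" / f"{name}.yaml").read_text())
        out.append(_chemical_from_mapping(raw))
    return out


def get_chemical(name: str) -> Chemical:
    """Look up a built-in chemical by (normalized) name."""
    key = name.lower().replace(",", "").replace("-", "").replace(" ", "")
    for chem in builtin_chemicals():
        if chem.name.lower().replace(",", "").replace("-", "") == key or (
            key in ("dioxane", "14dioxane") and "dioxane" in chem.name
        ):
            return chem
    raise KeyError(f"no built-in chemical named {name!r}")


def _dist_from_mapping(raw: Mapping) -> DistributionSpec:
    return DistributionSpec(
        kind=str(raw["kind"]),
        central=float(raw["central"]),
        spread=float(raw["spread"]),
        lower=float(raw["lower"]),
        upper=float(raw["upper"]),
    )


def builtin_subpopulations() -> dict[str, SubpopulationSpec]:
    """Registry of the seven subpopulation specifications, in canonical order.

    Elderly and pregnant women reuse the adult hepatic CYP2E1 distribution.
    """
    raw = yaml.safe_load((_data_root() / "subpopulations.yaml").read_text())
    raw.pop("_variability", None)
    specs: dict[str, SubpopulationSpec] = {}
    for name in SUBPOPULATIONS:
        entry = raw[name]
        cyp = entry["cyp2e1"]
        if "same_as" in cyp:
            cyp_dist = specs[cyp["same_as"]].cyp2e1_dist
        else:
            cyp_dist = _dist_from_mapping(cyp)
        gain = entry.get("pregnancy_gain")
        specs[name] = SubpopulationSpec(
            name=name,
            age_range=str(entry["age_range"]),
            bw_dist=_dist_from_mapping(entry["body_weight"]),
            cyp2e1_dist=cyp_dist,
            qp_var=_dist_from_mapping(entry["qp_var"]),
            vl_var=_dist_from_mapping(entry["vl_var"]),
            ql_var=_dist_from_mapping(entry["ql_var"]),
            pregnancy_gain_dist=_dist_from_mapping(gain) if gain else None,
            qp_scale=float(entry.get("qp_scale", 1.0)),
        )
    return specs


def _largest_remainder(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` across keys proportionally to ``fractions``.

    Largest-remainder (Hamilton) rounding: deterministic and sum-preserving.
    Every subgroup receives at least one individual.
    """
    if total < len(fractions):
        raise ValueError(f"total {total} too small for {len(fractions)} subpopulations")
    quotas = {k: f * total for k, f in fractions.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    leftover = total - sum(counts.values())
    order = sorted(fractions, key=lambda k: (quotas[k] - math.floor(quotas[k]), k), reverse=True)
    for k in order[:leftover]:
        counts[k] += 1
    # every subgroup keeps at least one individual, at the expense of the largest
    for k, n in counts.items():
        if n == 0:
            counts[max(counts, key=counts.get)] -= 1
            counts[k] = 1
    return counts


def canadian_profile(total: int = 100_000) -> DemographicProfile:
    """Demographic profile with the proportions of the Canadian population.

    For ``total=100_000`` the built-in census-derived counts are returned
    exactly; other totals are apportioned proportionally with
    largest-remainder rounding so the counts always sum to ``total``.
    """
    raw = yaml.safe_load((_data_root() / "profiles" / "canadian.yaml").read_text())
    base = {k: int(v) for k, v in raw["counts"].items()}
    base_total = sum(base.values())
    if total == base_total:
        counts = base
    else:
        if total < len(base):
            raise ValueError(f"total {total} smaller than number of subpopulations")
        counts = _largest_remainder({k: v / base_total for k, v in base.items()}, total)
    return DemographicProfile(name=str(raw["name"]), counts=counts)


def load_profile(path: str | Path) -> DemographicProfile:
    """Load a demographic profile from a user-supplied YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DemographicProfile(
        name=str(raw["name"]), counts={k: int(v) for k, v in raw["counts"].items()}
    )


def younger_profile(base: DemographicProfile) -> DemographicProfile:
    """Hypothetical "younger population" variant of ``base``.

    All under-18 subgroups and pregnant women are tripled, the elderly count
    is kept, and the adult count absorbs the difference so the total is
    preserved exactly.
    """
    tripled = set(UNDER_18) | {"pregnant_women"}
    counts = {}
    for sub, n in base.counts.items():
        counts[sub] = 3 * n if sub in tripled else n
    inflation = sum(counts[s] - base.counts[s] for s in tripled if s in counts)
    if "adults" not in counts:
        raise ValueError("base profile has no adults to rebalance against")
    counts["adults"] = base.counts["adults"] - inflation
    if counts["adults"] <= 0:
        raise ValueError("tripling the younger subgroups exhausts the adult population")
    return DemographicProfile(name=f"younger_{base.name}", counts=counts)
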