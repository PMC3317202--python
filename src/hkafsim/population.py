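"""Assembly of whole-population dose-metric datasets.

A virtual population is a demographically weighted mixture: each
subpopulation is simulated with exactly the number of individuals its
profile prescribes, and the per-individual dose metrics are concatenated
into one labelled dataset.  Sub-seeds are derived deterministically from
the master seed and the subpopulation name, so the draws for one subgroup
do not depend on which other subgroups are simulated.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    Chemical,
    DemographicProfile,
    SubpopulationSpec,
    builtin_subpopulations,
)
from .sampler import sample_cohort
from .steady_state import ReferenceAdult, dose_metrics

__all__ = [
    "PopulationDataset",
    "subpopulation_rng",
    "simulate_subpopulation",
    "simulate_population",
]


@dataclass(frozen=True)
class PopulationDataset:
    """Dose metrics for a simulated (sub)population.

    ``samples`` has columns ``subpop``, ``cass`` (ug/L), ``ram`` (ug/h-L);
    row order is by subpopulation then draw index.
    """

    label: str
    chemical: str
    seed: int
    samples: pd.DataFrame

    def __len__(self) -> int:
        return len(self.samples)

    def metric(self, name: str) -> np.ndarray:
        """All values of one dose metric (``'cass'`` or ``'ram'``)."""
        if name not in ("cass", "ram"):
            raise KeyError(f"unknown dose metric {name!r}")
        return self.samples[name].to_numpy()

    def subset(self, subpop: str) -> "PopulationDataset":
        """Stratum of one subpopulation (same draws, not re-sampled)."""
        part = self.samples[self.samples.subpop == subpop]
        if part.empty:
            raise KeyError(f"no samples for subpopulation {subpop!r} in {self.label}")
        return PopulationDataset(
            label=f"{self.label}:{subpop}",
            chemical=self.chemical,
            seed=self.seed,
            samples=part.reset_index(drop=True),
        )

    def counts(self) -> dict[str, int]:
        return self.samples.subpop.value_counts().to_dict()

    def to_csv(self, path: str | Path) -> None:
        """Write one row per sample plus a JSON sidecar with the metadata."""
        path = Path(path)
        out = self.samples.rename(
            columns={"cass": "cass_ug_per_L", "ram": "ram_ug_per_h_L"}
        )
        out.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {"label": self.label, "chemical": self.chemical, "seed": self.seed,
                 "n": len(self)},
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationDataset":
        path = Path(path)
        df = pd.read_csv(path).rename(
            columns={"cass_ug_per_L": "cass", "ram_ug_per_h_L": "ram"}
        )
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            label=meta.get("label", path.stem),
            chemical=meta.get("chemical", "unknown"),
            seed=meta.get("seed", -1),
            samples=df,
        )


def subpopulation_rng(seed: int, subpop: str) -> np.random.Generator:
    """Deterministic random stream for one subpopulation under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(subpop.encode())])
    )


def simulate_subpopulation(
    chem: Chemical,
    spec: SubpopulationSpec,
    n: int,
    seed: int,
    ref: ReferenceAdult | None = None,
) -> PopulationDataset:
    """Simulate ``n`` individuals of one subpopulation through the model."""
    rng = subpopulation_rng(seed, spec.name)
    cohort = sample_cohort(spec, n, rng)
    return PopulationDataset(
        label=f"subpop:{spec.name}",
        chemical=chem.name,
        seed=seed,
        samples=dose_metrics(chem, cohort, ref),
    )


def simulate_population(
    chem: Chemical,
    profile: DemographicProfile,
    seed: int,
    specs: dict[str, SubpopulationSpec] | None = None,
    ref: ReferenceAdult | None = None,
) -> PopulationDataset:
    """Simulate a mixed-demography population of ``profile.total`` people.

    Each subpopulation contributes exactly its profile count; the merged
    dataset keeps per-sample subpopulation labels for stratified queries.
    """
    if specs is None:
        specs = builtin_subpopulations()
    parts = []
    for name in specs:
        if name not in profile.counts:
            continue
        parts.append(
            simulate_subpopulation(chem, specs[name], profile.counts[name], seed, ref).samples
        )
    missing = set(profile.counts) - set(specs)
    if missing:
        raise KeyError(f"profile names unknown subpopulations: {sorted(missing)}")
    return PopulationDataset(
        label=profile.name,
        chemical=chem.name,
        seed=seed,
        samples=pd.concat(parts, ignore_index=True),
    )
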