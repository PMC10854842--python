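"""Synthetic flock generator with known ground truth.

Generates individually-caged laying hens on a restricted ration (~70 g DM/d,
capped at the 80 g/d allowance) fed either a pure commercial diet or the same
feed with a small plant (alfalfa) inclusion.  The generative model mirrors
the marker-balance assumptions of the estimation pipeline:

* realized plant fraction = formulated fraction + an optional selectivity
  shift (hens sorting a mash can eat less plant than formulated);
* daily marker intake follows from the realized diet profile and DM intake;
* fecal marker output = intake x a diet- and chain-length-specific true
  recovery;
* fecal DM output = intake x (1 - whole-diet digestibility), a constant the
  proportion estimator is invariant to (it cancels in the coefficient ratio);
* measured fecal concentrations get multiplicative lognormal noise with
  mean exactly 1 (mu = -sigma^2/2), emulating relative assay error on a
  positive quantity.

Everything is deterministic given the seed.  The packaged default component
profiles and true recoveries are the published reference values for dried
alfalfa and a commercial layer feed (see :func:`reference_profiles` and
:func:`default_recoveries`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .profiles import (
    DEFAULT_MARKERS,
    AlkaneID,
    AlkaneProfile,
    AnimalRecord,
    DietSpec,
    mix_profiles,
)
from .recovery import RecoveryTable

__all__ = [
    "SimConfig",
    "simulate_flock",
    "reference_profiles",
    "default_recoveries",
    "default_fixtures",
    "default_diets",
]

_C = {n: AlkaneID(n) for n in (25, 27, 29, 31, 33)}


def reference_profiles() -> dict[str, AlkaneProfile]:
    """Published alkane fingerprints (mg/kg DM): commercial layer feed,
    dried alfalfa (*Medicago sativa*), and the analyzed 1%-alfalfa mix.

    The ``mixed_analyzed`` entry is the *assayed* profile of the physical
    mixture; it differs slightly from the calculated 99:1 blend of the other
    two (e.g. C29 blends to 5.44 but assayed at 5.69), as analytical values
    of mixtures routinely do.
    """
    return {
        "feed": AlkaneProfile(
            "feed",
            {_C[25]: 1.18, _C[27]: 1.59, _C[29]: 2.58, _C[31]: 1.79, _C[33]: 1.19},
        ),
        "alfalfa": AlkaneProfile(
            "alfalfa",
            {_C[25]: 8.12, _C[27]: 44.3, _C[29]: 289.0, _C[31]: 358.0, _C[33]: 26.9},
        ),
        "mixed_analyzed": AlkaneProfile(
            "mixed_analyzed",
            {_C[25]: 1.28, _C[27]: 2.20, _C[29]: 5.69, _C[31]: 5.13, _C[33]: 1.51},
        ),
    }


def default_recoveries() -> RecoveryTable:
    """Published mean fecal recoveries per (diet, alkane), as fractions."""
    return RecoveryTable.from_means(
        {
            "commercial": {
                _C[25]: 0.439,
                _C[27]: 0.369,
                _C[29]: 0.302,
                _C[31]: 0.297,
                _C[33]: 0.339,
            },
            "mixed": {
                _C[25]: 0.479,
                _C[27]: 0.375,
                _C[29]: 0.372,
                _C[31]: 0.437,
                _C[33]: 0.409,
            },
        }
    )


def default_diets() -> list[DietSpec]:
    return [
        DietSpec("commercial", {"feed": 1.0}),
        DietSpec("mixed", {"feed": 0.99, "alfalfa": 0.01}),
    ]


def default_fixtures() -> tuple[list[AlkaneProfile], RecoveryTable]:
    """(components [feed, alfalfa], recovery table) with the reference values."""
    profiles = reference_profiles()
    return [profiles["feed"], profiles["alfalfa"]], default_recoveries()


def _default_true_recovery() -> dict[tuple[str, AlkaneID], float]:
    table = default_recoveries()
    return {key: cell.mean for key, cell in table.entries.items()}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic flock.

    Defaults emulate the reference trial: 24 hens per diet, restricted-fed
    ~70 g DM/d (sd 5, truncated at (0, 80]), published component profiles
    and true recoveries, 5% relative assay noise on fecal concentrations.
    """

    components: tuple[AlkaneProfile, ...] = field(
        default_factory=lambda: tuple(default_fixtures()[0])
    )
    diets: tuple[DietSpec, ...] = field(default_factory=lambda: tuple(default_diets()))
    n_per_diet: int = 24
    intake_mean: float = 70.0  # g DM/d
    intake_sd: float = 5.0
    intake_max: float = 80.0  # daily allowance; intakes are truncated to (0, max]
    digestibility: float = 0.65  # whole-diet DM digestibility (non-marker DM)
    true_recovery: Mapping[tuple[str, AlkaneID], float] = field(
        default_factory=_default_true_recovery
    )
    noise_cv: float = 0.05  # relative sd of the multiplicative assay noise
    selectivity_shift: float = 0.0  # realized - formulated plant fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_diet < 1:
            raise ValidationError("n_per_diet must be >= 1")
        if not 0 < self.digestibility < 1:
            raise ValidationError("digestibility must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.intake_mean <= 0 or self.intake_sd < 0 or self.intake_max <= 0:
            raise ValidationError("implausible intake parameters")
        for (diet, alkane), r in self.true_recovery.items():
            if not 0 < r <= 1:
                raise ValidationError(
                    f"true recovery for ({diet}, {alkane.label}) must be in (0, 1], got {r}"
                )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimConfig":
        """Load a flat key-value config; only scalar fields are settable."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scalar = {
            "n_per_diet", "intake_mean", "intake_sd", "intake_max",
            "digestibility", "noise_cv", "selectivity_shift", "seed",
        }
        unknown = set(raw) - scalar
        if unknown:
            raise ValidationError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        raw.update(overrides)
        return cls(**raw)


def _truncated_normal(rng: np.random.Generator, mean, sd, upper) -> float:
    """Draw from N(mean, sd) truncated to (0, upper] by rejection."""
    if sd == 0:
        if not 0 < mean <= upper:
            raise ValidationError("degenerate intake outside (0, max]")
        return float(mean)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if 0 < x <= upper:
            return float(x)
    raise ValidationError("intake truncation region has negligible mass")


def simulate_flock(
    config: SimConfig,
) -> tuple[list[AnimalRecord], dict[str, float]]:
    """Generate one flock; returns (animals, animal_id -> realized plant fraction).

    Bit-identical output for identical configs (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    components = list(config.components)
    feed_name = components[0].component_name
    plant_names = [p.component_name for p in components[1:]]
    markers = components[0].markers

    sigma2 = math.log1p(config.noise_cv**2)
    mu = -sigma2 / 2  # lognormal mean exactly 1
    sigma = math.sqrt(sigma2)

    animals: list[AnimalRecord] = []
    truth: dict[str, float] = {}
    counter = 0
    for diet in config.diets:
        formulated_plant = sum(diet.composition.get(n, 0.0) for n in plant_names)
        for _ in range(config.n_per_diet):
            counter += 1
            animal_id = f"hen{counter:03d}"
            intake = _truncated_normal(
                rng, config.intake_mean, config.intake_sd, config.intake_max
            )
            realized_plant = min(
                1.0, max(0.0, formulated_plant + config.selectivity_shift)
            )
            # Rescale plant fractions to the realized total; feed absorbs the rest.
            if formulated_plant > 0:
                scale = realized_plant / formulated_plant
                comp = {
                    n: q * scale if n != feed_name else 0.0
                    for n, q in diet.composition.items()
                }
            else:
                comp = {n: 0.0 for n in diet.composition}
            comp[feed_name] = 1.0 - sum(comp.values())
            realized_profile = mix_profiles(
                components, DietSpec(diet.diet_id, comp)
            )

            fecal_dm = intake * (1.0 - config.digestibility)  # g/d
            fecal_conc: dict[AlkaneID, float] = {}
            for i in markers:
                marker_intake = realized_profile.concentration(i) * intake / 1000.0
                try:
                    r = config.true_recovery[(diet.diet_id, i)]
                except KeyError:
                    raise ValidationError(
                        f"no true recovery configured for ({diet.diet_id}, {i.label})"
                    ) from None
                output = marker_intake * r  # mg/d
                conc = output * 1000.0 / fecal_dm  # mg/kg excreta DM
                if config.noise_cv > 0:
                    conc *= math.exp(rng.normal(mu, sigma))
                fecal_conc[i] = conc
            animals.append(
                AnimalRecord(
                    animal_id=animal_id,
                    diet_id=diet.diet_id,
                    dm_intake=intake,
                    fecal_dm_output=fecal_dm,
                    fecal_conc=fecal_conc,
                )
            )
            truth[animal_id] = realized_plant
    return animals, truth
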