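"""Diet-composition estimation from recovery-corrected fecal alkane profiles.

For one animal the model is the linear marker-balance system

    x_f * F_i + x_a * A_i = E_i*,      i in the chosen marker subset,

where F_i and A_i are the alkane concentrations of the feed and plant
components (mg/kg DM), E_i* is the animal's fecal concentration after
recovery correction, and the coefficients are constrained non-negative.  The
plant share of dietary DM supply is then

    p = x_a / (x_a + x_f),

which is invariant to any common rescaling of the corrected fecal vector
(the fecal-DM/intake factor the coefficients absorb cancels in the ratio).

Recovery correction divides each observed fecal concentration by the mean
recovery of that (diet, marker) cell: division maps fecal concentrations
back onto an intake-equivalent scale, which is the direction under which the
coefficient ratio is a DM-intake proportion.

The statsmodels-style surface is :class:`DietCompositionModel` /
:class:`DietCompositionResults`; the per-animal primitives are plain
functions underneath.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CorrectionError, ValidationError
from .nnls import nnls_solve
from .profiles import (
    CSV_FLOAT_FORMAT,
    AlkaneID,
    AlkaneProfile,
    AnimalRecord,
)
from .recovery import RecoveryTable

__all__ = [
    "EstimateResult",
    "correct_excreta",
    "build_design",
    "plant_proportion",
    "estimate_animal",
    "DietCompositionModel",
    "DietCompositionResults",
]


@dataclass(frozen=True)
class EstimateResult:
    """NNLS fit for one animal on one marker subset."""

    animal_id: str
    diet_id: str
    markers: tuple[AlkaneID, ...]
    coefficients: Mapping[str, float]  # component name -> x >= 0
    proportion: float | None  # plant share of DM supply; None when all x = 0
    residual_ss: float

    @property
    def undefined(self) -> bool:
        return self.proportion is None

    def marker_key(self) -> str:
        """Hyphen-joined ascending label, e.g. ``C25-C29-C33``."""
        return "-".join(i.label for i in self.markers)


def correct_excreta(
    animal: AnimalRecord,
    recovery: RecoveryTable,
    diet_for_correction: str | None = None,
    markers: Sequence[AlkaneID] | None = None,
) -> dict[AlkaneID, float]:
    """Recovery-correct an animal's fecal concentrations.

    Corrected ``E_i = observed E_i / R(diet, i)``.  The correction diet
    defaults to the animal's own diet; pass ``diet_for_correction`` to use a
    different recovery column (e.g. the control diet for animals of unknown
    diet).
    """
    diet = diet_for_correction if diet_for_correction is not None else animal.diet_id
    if markers is None:
        markers = animal.markers
    corrected: dict[AlkaneID, float] = {}
    for i in markers:
        try:
            r = recovery.mean(diet, i)
        except ValidationError as exc:
            raise CorrectionError(str(exc)) from None
        if not r > 0:
            raise CorrectionError(
                f"non-positive mean recovery {r} for diet {diet!r}, marker {i.label}"
            )
        corrected[i] = animal.fecal_conc[i] / r
    return corrected


def build_design(
    components: Sequence[AlkaneProfile], markers: Sequence[AlkaneID]
) -> np.ndarray:
    """Design matrix with one column per component, rows in ascending carbon order."""
    ordered = sorted(markers)
    return np.column_stack([p.vector(ordered) for p in components])


def plant_proportion(
    coefficients: Mapping[str, float],
    plant_components: Sequence[str],
) -> float | None:
    """Plant share of dietary DM supply from NNLS coefficients.

    ``sum(plant x) / sum(all x)``; ``None`` (an explicit undefined flag,
    never a silent 0) when all coefficients are zero.
    """
    unknown = [c for c in plant_components if c not in coefficients]
    if unknown:
        raise ValidationError(f"unknown plant component(s): {', '.join(unknown)}")
    total = sum(coefficients.values())
    if total <= 0:
        return None
    return sum(coefficients[c] for c in plant_components) / total


def estimate_animal(
    animal: AnimalRecord,
    components: Sequence[AlkaneProfile],
    recovery: RecoveryTable,
    markers: Sequence[AlkaneID] | None = None,
    plant_components: Sequence[str] | None = None,
    correction_diet: str | None = None,
) -> EstimateResult:
    """Recovery-correct, solve the marker-balance system, return the estimate.

    ``plant_components`` defaults to every component except the first, so
    the conventional ordering is (feed, plant, ...).
    """
    if markers is None:
        markers = animal.markers
    markers = tuple(sorted(markers))
    if len(markers) < len(components):
        raise ValidationError(
            f"{len(markers)} markers cannot identify {len(components)} components"
        )
    if len(markers) == len(components):
        warnings.warn(
            "as many markers as components: exactly identified system, "
            "no residual degrees of freedom",
            stacklevel=2,
        )
    if plant_components is None:
        plant_components = [p.component_name for p in components[1:]]
    corrected = correct_excreta(animal, recovery, correction_diet, markers)
    design = build_design(components, markers)
    target = np.array([corrected[i] for i in markers])
    x, residual_ss = nnls_solve(design, target)
    coefficients = {p.component_name: float(v) for p, v in zip(components, x)}
    return EstimateResult(
        animal_id=animal.animal_id,
        diet_id=animal.diet_id,
        markers=markers,
        coefficients=coefficients,
        proportion=plant_proportion(coefficients, plant_components),
        residual_ss=residual_ss,
    )


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class DietCompositionModel:
    """Plant-intake estimation model for a flock of animals.

    Parameters
    ----------
    animals
        Per-animal records (intake, excreta output, fecal concentrations).
    components
        Alkane profiles of the dietary components; by convention the first
        is the base feed and the rest are plant components.
    recovery
        Diet-specific mean recoveries used to correct fecal concentrations.
    markers
        Marker subset to use; defaults to the animals' full panel.
    correction_diet
        Recovery column to use for every animal; defaults to each animal's
        own diet.
    """

    def __init__(
        self,
        animals: Sequence[AnimalRecord],
        components: Sequence[AlkaneProfile],
        recovery: RecoveryTable,
        markers: Sequence[AlkaneID] | None = None,
        plant_components: Sequence[str] | None = None,
        correction_diet: str | None = None,
    ):
        if not animals:
            raise ValidationError("no animals supplied")
        if len(components) < 2:
            raise ValidationError("need at least a feed and one plant component")
        self.animals = list(animals)
        self.components = list(components)
        self.recovery = recovery
        self.markers = tuple(sorted(markers)) if markers is not None else None
        self.plant_components = (
            list(plant_components)
            if plant_components is not None
            else [p.component_name for p in self.components[1:]]
        )
        self.correction_diet = correction_diet

    @classmethod
    def from_csv(
        cls,
        animals_path,
        profiles_path,
        recovery_path,
        markers: Sequence[AlkaneID] | None = None,
        **kwargs,
    ) -> "DietCompositionModel":
        from .profiles import DEFAULT_MARKERS, read_animals, read_profiles
        from .recovery import read_recovery

        panel = tuple(markers) if markers is not None else DEFAULT_MARKERS
        return cls(
            animals=read_animals(animals_path, panel),
            components=read_profiles(profiles_path),
            recovery=read_recovery(recovery_path),
            markers=markers,
            **kwargs,
        )

    def fit(self) -> "DietCompositionResults":
        estimates = [
            estimate_animal(
                a,
                self.components,
                self.recovery,
                markers=self.markers,
                plant_components=self.plant_components,
                correction_diet=self.correction_diet,
            )
            for a in self.animals
        ]
        return DietCompositionResults(self, estimates)


class DietCompositionResults:
    """Fitted per-animal composition estimates with reporting helpers."""

    def __init__(self, model: DietCompositionModel, estimates: list[EstimateResult]):
        self.model = model
        self.estimates = estimates

    @property
    def proportions(self) -> pd.Series:
        return pd.Series(
            {e.animal_id: e.proportion for e in self.estimates}, name="proportion"
        )

    def frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            row = {
                "animal_id": e.animal_id,
                "diet_id": e.diet_id,
                "markers": e.marker_key(),
            }
            for name, x in e.coefficients.items():
                row[f"x_{name}"] = x
            row["proportion"] = e.proportion
            row["residual_ss"] = e.residual_ss
            row["undefined_flag"] = e.undefined
            rows.append(row)
        return pd.DataFrame(rows)

    def error_metrics(self, truth_by_diet: Mapping[str, float]):
        """Per-diet bias/variance/MSE/RMSE against known true proportions."""
        from .evaluation import error_metrics

        out = {}
        for diet in dict.fromkeys(e.diet_id for e in self.estimates):
            preds = [
                e.proportion
                for e in self.estimates
                if e.diet_id == diet and not e.undefined
            ]
            out[diet] = error_metrics(preds, truth_by_diet[diet])
        return out

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    def summary(self, truth_by_diet: Mapping[str, float] | None = None) -> str:
        marker_key = (
            self.estimates[0].marker_key() if self.estimates else "-"
        )
        lines = [
            "Diet composition estimates (recovery-corrected NNLS)",
            f"  markers: {marker_key}",
            f"  components: {', '.join(p.component_name for p in self.model.components)}",
            f"  animals: {len(self.estimates)} "
            f"({sum(e.undefined for e in self.estimates)} undefined)",
            "",
        ]
        frame = self.frame()
        grouped = frame[~frame["undefined_flag"]].groupby("diet_id")["proportion"]
        table = grouped.agg(n="size", mean="mean", sd="std").reset_index()
        if truth_by_diet is not None:
            metrics = self.error_metrics(truth_by_diet)
            table["truth"] = table["diet_id"].map(truth_by_diet)
            table["bias"] = table["diet_id"].map(lambda d: metrics[d].bias)
            table["rmse"] = table["diet_id"].map(lambda d: metrics[d].rmse)
        lines.append(table.to_string(index=False, float_format="%.5f".__mod__))
        return "\n".join(lines)
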