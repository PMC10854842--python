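"""Domain types and table I/O for n-alkane dietary marker work.

n-Alkanes of the plant epicuticular wax (odd chain lengths C25-C33) serve as
internal dietary markers: every dietary component has a characteristic alkane
fingerprint, and the fingerprint recovered in excreta is a recovery-attenuated
mixture of the components eaten.  This module holds the shared vocabulary --
marker identities, component profiles, diet formulations and per-animal
records -- together with the CSV readers/writers and the mixing arithmetic
used by every downstream stage.

All concentrations are mg/kg of dry matter (DM); intakes and excreta outputs
are g DM per day.  There is no fresh-matter basis anywhere in the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, UndefinedRatioError, ValidationError

__all__ = [
    "AlkaneID",
    "AlkaneProfile",
    "DietSpec",
    "AnimalRecord",
    "DEFAULT_MARKERS",
    "read_profiles",
    "write_profiles",
    "read_animals",
    "write_animals",
    "read_diets",
    "write_diets",
    "mix_profiles",
    "percent_increase",
]

_LABEL_RE = re.compile(r"^[Cc](\d+)$")

#: Float formatting used by every CSV writer (6 significant digits).
CSV_FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True, order=True)
class AlkaneID:
    """Identity of one n-alkane marker, e.g. C29 (nonacosane).

    Ordering is by carbon-chain length, so sorted marker collections are
    always in ascending chain order.
    """

    carbon_length: int

    def __post_init__(self) -> None:
        if self.carbon_length < 2:
            raise ValidationError(
                f"implausible alkane chain length {self.carbon_length}"
            )

    @property
    def label(self) -> str:
        return f"C{self.carbon_length}"

    @classmethod
    def from_label(cls, label: str) -> "AlkaneID":
        m = _LABEL_RE.match(label.strip())
        if not m:
            raise ValidationError(f"cannot parse alkane label {label!r} (expected e.g. 'C29')")
        return cls(int(m.group(1)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AlkaneID({self.label})"


#: The study's marker panel: the major odd-chain plant-wax alkanes.
DEFAULT_MARKERS: tuple[AlkaneID, ...] = tuple(AlkaneID(n) for n in (25, 27, 29, 31, 33))


@dataclass(frozen=True)
class AlkaneProfile:
    """Alkane fingerprint of one dietary component (mg/kg DM)."""

    component_name: str
    concentrations: Mapping[AlkaneID, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", dict(self.concentrations))
        if not self.concentrations:
            raise ValidationError(f"profile {self.component_name!r} has no markers")
        for alkane, conc in self.concentrations.items():
            if conc < 0:
                raise ValidationError(
                    f"negative concentration {conc} for {alkane.label} in "
                    f"component {self.component_name!r}"
                )

    @property
    def markers(self) -> tuple[AlkaneID, ...]:
        return tuple(sorted(self.concentrations))

    def concentration(self, alkane: AlkaneID) -> float:
        """Concentration of ``alkane``; a missing marker is an error, never 0."""
        try:
            return self.concentrations[alkane]
        except KeyError:
            raise ValidationError(
                f"component {self.component_name!r} has no entry for {alkane.label}"
            ) from None

    def vector(self, markers: Sequence[AlkaneID]) -> list[float]:
        return [self.concentration(i) for i in markers]

    def total(self) -> float:
        """Sum of all marker concentrations (computed, never a stored total)."""
        return float(sum(self.concentrations.values()))


@dataclass(frozen=True)
class DietSpec:
    """Formulated diet: inclusion fraction of each component (w/w, DM basis)."""

    diet_id: str
    composition: Mapping[str, float]

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", dict(self.composition))
        if not self.composition:
            raise ValidationError(f"diet {self.diet_id!r} has no components")
        for name, q in self.composition.items():
            if q < 0:
                raise ValidationError(
                    f"negative inclusion fraction {q} for {name!r} in diet {self.diet_id!r}"
                )
        total = sum(self.composition.values())
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValidationError(
                f"inclusion fractions of diet {self.diet_id!r} sum to {total!r}, not 1"
            )


@dataclass(frozen=True)
class AnimalRecord:
    """One bird: intake, excreta output and fecal alkane concentrations.

    ``fecal_conc`` is on the excreta-DM basis (mg marker per kg excreta DM),
    before any recovery correction.
    """

    animal_id: str
    diet_id: str
    dm_intake: float  # g DM/day
    fecal_dm_output: float  # g DM/day
    fecal_conc: Mapping[AlkaneID, float]  # mg/kg excreta DM

    def __post_init__(self) -> None:
        object.__setattr__(self, "fecal_conc", dict(self.fecal_conc))
        if not self.dm_intake > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: dm_intake must be > 0, got {self.dm_intake}"
            )
        if self.fecal_dm_output < 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: fecal_dm_output must be >= 0"
            )
        for alkane, conc in self.fecal_conc.items():
            if conc < 0:
                raise ValidationError(
                    f"animal {self.animal_id!r}: negative fecal concentration "
                    f"{conc} for {alkane.label}"
                )

    @property
    def markers(self) -> tuple[AlkaneID, ...]:
        return tuple(sorted(self.fecal_conc))

    def fecal_vector(self, markers: Sequence[AlkaneID]) -> list[float]:
        out = []
        for i in markers:
            try:
                out.append(self.fecal_conc[i])
            except KeyError:
                raise ValidationError(
                    f"animal {self.animal_id!r} has no fecal value for {i.label}"
                ) from None
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ("component", "alkane", "concentration_mg_per_kg_dm")
ANIMAL_FIXED_COLUMNS = ("animal_id", "diet_id", "dm_intake_g_d", "fecal_dm_output_g_d")
DIET_COLUMNS = ("diet_id", "component", "fraction")


def _require_columns(frame: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_profiles(path) -> list[AlkaneProfile]:
    """Read component alkane profiles from a long-format CSV.

    Expected columns: ``component, alkane, concentration_mg_per_kg_dm``.
    Row order is irrelevant; one profile is returned per distinct component.
    """
    frame = pd.read_csv(path, dtype={"component": str, "alkane": str})
    _require_columns(frame, PROFILE_COLUMNS, path)
    seen: set[tuple[str, AlkaneID]] = set()
    data: dict[str, dict[AlkaneID, float]] = {}
    for row in frame.itertuples():
        alkane = AlkaneID.from_label(row.alkane)
        conc = float(row.concentration_mg_per_kg_dm)
        if conc < 0:
            raise ValidationError(
                f"{path}: negative concentration {conc} at row {row.Index + 2}"
            )
        key = (row.component, alkane)
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate entry for ({row.component}, {alkane.label}) "
                f"at row {row.Index + 2}"
            )
        seen.add(key)
        data.setdefault(row.component, {})[alkane] = conc
    return [AlkaneProfile(name, concs) for name, concs in data.items()]


def write_profiles(profiles: Sequence[AlkaneProfile], path) -> None:
    rows = [
        (p.component_name, i.label, p.concentrations[i])
        for p in profiles
        for i in p.markers
    ]
    frame = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_animals(path, markers: Sequence[AlkaneID] = DEFAULT_MARKERS) -> list[AnimalRecord]:
    """Read per-animal records; one fecal concentration column per marker.

    Expected columns: ``animal_id, diet_id, dm_intake_g_d, fecal_dm_output_g_d``
    plus ``fecal_<label>`` for every marker in ``markers``.
    """
    frame = pd.read_csv(path, dtype={"animal_id": str, "diet_id": str})
    marker_cols = [f"fecal_{i.label}" for i in markers]
    _require_columns(frame, list(ANIMAL_FIXED_COLUMNS) + marker_cols, path)
    records = []
    for row in frame.itertuples():
        fecal = {
            i: float(getattr(row, col)) for i, col in zip(markers, marker_cols)
        }
        try:
            records.append(
                AnimalRecord(
                    animal_id=row.animal_id,
                    diet_id=row.diet_id,
                    dm_intake=float(row.dm_intake_g_d),
                    fecal_dm_output=float(row.fecal_dm_output_g_d),
                    fecal_conc=fecal,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {row.Index + 2}: {exc}") from None
    return records


def write_animals(animals: Sequence[AnimalRecord], path) -> None:
    if not animals:
        raise ValidationError("refusing to write an empty animal table")
    markers = animals[0].markers
    rows = []
    for a in animals:
        row = {
            "animal_id": a.animal_id,
            "diet_id": a.diet_id,
            "dm_intake_g_d": a.dm_intake,
            "fecal_dm_output_g_d": a.fecal_dm_output,
        }
        for i in markers:
            row[f"fecal_{i.label}"] = a.fecal_conc[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_diets(path) -> list[DietSpec]:
    frame = pd.read_csv(path, dtype={"diet_id": str, "component": str})
    _require_columns(frame, DIET_COLUMNS, path)
    data: dict[str, dict[str, float]] = {}
    for row in frame.itertuples():
        data.setdefault(row.diet_id, {})[row.component] = float(row.fraction)
    return [DietSpec(diet_id, comp) for diet_id, comp in data.items()]


def write_diets(diets: Sequence[DietSpec], path) -> None:
    rows = [
        (d.diet_id, name, q) for d in diets for name, q in sorted(d.composition.items())
    ]
    pd.DataFrame(rows, columns=list(DIET_COLUMNS)).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT
    )


# ---------------------------------------------------------------------------
# Profile arithmetic
# ---------------------------------------------------------------------------


def mix_profiles(components: Sequence[AlkaneProfile], spec: DietSpec) -> AlkaneProfile:
    """Alkane profile of a formulated mixture, by linear mixing on a DM basis.

    ``M_i = sum_c q_c * C_{c,i}`` for every marker i, where q_c is the DM
    inclusion fraction of component c.  Every component named in ``spec``
    must be present in ``components``.
    """
    by_name = {p.component_name: p for p in components}
    missing = [name for name in spec.composition if name not in by_name]
    if missing:
        raise ValidationError(
            f"diet {spec.diet_id!r} names unknown component(s): {', '.join(missing)}"
        )
    used = [by_name[name] for name in spec.composition]
    markers = used[0].markers
    mixed = {
        i: sum(q * by_name[name].concentration(i) for name, q in spec.composition.items())
        for i in markers
    }
    return AlkaneProfile(spec.diet_id, mixed)


def percent_increase(base: AlkaneProfile, other: AlkaneProfile, i: AlkaneID) -> float:
    """Percent change of marker ``i`` from ``base`` to ``other``, unrounded.

    Callers round for reporting (the convention here is round-half-to-even to
    integers for display).
    """
    b = base.concentration(i)
    if b == 0:
        raise UndefinedRatioError(
            f"percent increase undefined: {base.component_name!r} has zero {i.label}"
        )
    return 100.0 * (other.concentration(i) - b) / b
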