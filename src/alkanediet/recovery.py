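"""Fecal recovery rates of n-alkane markers.

Marker recovery in excreta is incomplete and depends on chain length and on
the diet, so fecal profiles must be corrected by diet-specific mean
recoveries before any composition estimate.  Recovery for one animal and one
marker is the standard marker balance:

    recovery = (fecal concentration x fecal DM output) /
               (dietary concentration x DM intake)

i.e. daily marker excretion divided by daily marker ingestion.  Animals with
an implausibly high whole-panel recovery (typically driven by anomalously low
intake) are flagged by an explicit, configurable rule and excluded from the
mean-recovery aggregation -- never from the raw observation table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UndefinedRecoveryError, ValidationError
from .profiles import CSV_FLOAT_FORMAT, AlkaneID, AlkaneProfile, AnimalRecord

__all__ = [
    "RecoveryObservation",
    "RecoveryCell",
    "RecoveryTable",
    "OutlierRule",
    "animal_recovery",
    "total_recovery",
    "observe_flock",
    "flag_outliers",
    "mean_recovery",
    "read_recovery",
    "write_recovery",
    "write_raw_observations",
]


@dataclass(frozen=True)
class RecoveryObservation:
    """Marker balance of one (animal, alkane): intake, output, recovery."""

    animal_id: str
    diet_id: str
    alkane: AlkaneID
    alkane_intake_mg_d: float
    alkane_output_mg_d: float
    recovery: float


@dataclass(frozen=True)
class RecoveryCell:
    mean: float
    sem: float  # NaN when n == 1
    n: int


@dataclass
class RecoveryTable:
    """Per-(diet, alkane) mean recoveries used for fecal correction."""

    entries: dict[tuple[str, AlkaneID], RecoveryCell] = field(default_factory=dict)

    def get(self, diet_id: str, alkane: AlkaneID) -> RecoveryCell:
        try:
            return self.entries[(diet_id, alkane)]
        except KeyError:
            raise ValidationError(
                f"recovery table has no entry for diet {diet_id!r}, marker {alkane.label}"
            ) from None

    def mean(self, diet_id: str, alkane: AlkaneID) -> float:
        return self.get(diet_id, alkane).mean

    @property
    def diets(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(d for d, _ in self.entries))

    @classmethod
    def from_means(
        cls, means: Mapping[str, Mapping[AlkaneID, float]], n: int = 1
    ) -> "RecoveryTable":
        """Build a table from bare means (e.g. published values); sem is NaN."""
        entries = {
            (diet, alkane): RecoveryCell(mean=float(r), sem=math.nan, n=n)
            for diet, per_alkane in means.items()
            for alkane, r in per_alkane.items()
        }
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (diet, alkane.label, cell.mean, cell.sem, cell.n)
            for (diet, alkane), cell in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1])
            )
        ]
        return pd.DataFrame(
            rows, columns=["diet_id", "alkane", "mean_recovery", "sem", "n"]
        )


def read_recovery(path) -> RecoveryTable:
    frame = pd.read_csv(path, dtype={"diet_id": str, "alkane": str})
    required = ("diet_id", "alkane", "mean_recovery")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    entries = {}
    for row in frame.itertuples():
        sem = float(getattr(row, "sem", math.nan))
        n = int(getattr(row, "n", 1))
        entries[(row.diet_id, AlkaneID.from_label(row.alkane))] = RecoveryCell(
            mean=float(row.mean_recovery), sem=sem, n=n
        )
    return RecoveryTable(entries)


def write_recovery(table: RecoveryTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def write_raw_observations(
    observations: Sequence[RecoveryObservation], flagged: set[str], path
) -> None:
    rows = [
        {
            "animal_id": o.animal_id,
            "diet_id": o.diet_id,
            "alkane": o.alkane.label,
            "intake_mg_d": o.alkane_intake_mg_d,
            "output_mg_d": o.alkane_output_mg_d,
            "recovery": o.recovery,
            "flagged": o.animal_id in flagged,
        }
        for o in observations
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Per-animal balances
# ---------------------------------------------------------------------------


def animal_recovery(
    animal: AnimalRecord, diet_profile: AlkaneProfile, alkane: AlkaneID
) -> RecoveryObservation:
    """Marker balance for one animal and one alkane.

    ``diet_profile`` is the consumed diet's as-fed profile (analyzed or
    mixed).  Daily flows are in mg/d: concentration (mg/kg DM) times DM mass
    (g/d) divided by 1000.
    """
    diet_conc = diet_profile.concentration(alkane)
    intake_mg_d = diet_conc * animal.dm_intake / 1000.0
    if intake_mg_d <= 0:
        raise UndefinedRecoveryError(
            f"animal {animal.animal_id!r}: zero dietary intake of {alkane.label}, "
            "recovery undefined"
        )
    output_mg_d = animal.fecal_conc[alkane] * animal.fecal_dm_output / 1000.0
    r = output_mg_d / intake_mg_d
    if r > 1:
        warnings.warn(
            f"animal {animal.animal_id!r}: recovery {r:.3f} > 1 for {alkane.label} "
            "(biologically impossible in expectation; measurement noise?)",
            stacklevel=2,
        )
    return RecoveryObservation(
        animal_id=animal.animal_id,
        diet_id=animal.diet_id,
        alkane=alkane,
        alkane_intake_mg_d=intake_mg_d,
        alkane_output_mg_d=output_mg_d,
        recovery=r,
    )


def total_recovery(animal: AnimalRecord, diet_profile: AlkaneProfile) -> float:
    """Whole-panel recovery: summed marker output over summed marker intake.

    Equals the intake-weighted mean of the per-marker recoveries, so it
    always lies between the animal's minimum and maximum per-marker recovery.
    """
    markers = animal.markers
    intake = sum(diet_profile.concentration(i) * animal.dm_intake for i in markers)
    output = sum(animal.fecal_conc[i] * animal.fecal_dm_output for i in markers)
    if intake <= 0:
        raise UndefinedRecoveryError(
            f"animal {animal.animal_id!r}: zero total marker intake"
        )
    return output / intake


def observe_flock(
    animals: Sequence[AnimalRecord],
    diet_profiles: Mapping[str, AlkaneProfile],
    markers: Sequence[AlkaneID] | None = None,
) -> list[RecoveryObservation]:
    """All per-(animal, marker) balances, using each animal's own diet profile."""
    out = []
    for a in animals:
        if a.diet_id not in diet_profiles:
            raise ValidationError(
                f"no diet profile supplied for diet {a.diet_id!r} "
                f"(animal {a.animal_id!r})"
            )
        for i in markers if markers is not None else a.markers:
            out.append(animal_recovery(a, diet_profiles[a.diet_id], i))
    return out


# ---------------------------------------------------------------------------
# Outlier screening and aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierRule:
    """Explicit screen for implausible whole-panel recoveries.

    An animal is flagged when its total recovery exceeds ``total_threshold``
    (absolute, default 0.60) OR lies more than ``mad_k`` scaled median
    absolute deviations from its diet group's median (default 3.5).  Set
    ``total_threshold=inf`` and ``mad_k=inf`` to disable.
    """

    total_threshold: float = 0.60
    mad_k: float = 3.5

    _MAD_SCALE = 1.4826  # consistency factor for a normal distribution


def _totals_by_animal(
    observations: Iterable[RecoveryObservation],
) -> dict[str, tuple[str, float]]:
    """animal_id -> (diet_id, total recovery) pooled over its markers."""
    intake: dict[str, float] = {}
    output: dict[str, float] = {}
    diet: dict[str, str] = {}
    for o in observations:
        intake[o.animal_id] = intake.get(o.animal_id, 0.0) + o.alkane_intake_mg_d
        output[o.animal_id] = output.get(o.animal_id, 0.0) + o.alkane_output_mg_d
        diet[o.animal_id] = o.diet_id
    return {
        a: (diet[a], output[a] / intake[a]) for a in intake if intake[a] > 0
    }


def flag_outliers(
    observations: Sequence[RecoveryObservation],
    rule: OutlierRule = OutlierRule(),
) -> set[str]:
    """Animals whose total recovery fails the configured screen.

    Flagged animals should be excluded from mean aggregation; the raw table
    keeps them (with a flag) so the exclusion is auditable.
    """
    totals = _totals_by_animal(observations)
    if not totals:
        return set()
    flagged: set[str] = set()
    by_diet: dict[str, list[tuple[str, float]]] = {}
    for animal_id, (diet_id, total) in totals.items():
        by_diet.setdefault(diet_id, []).append((animal_id, total))
    for diet_id, group in by_diet.items():
        values = np.array([t for _, t in group])
        med = float(np.median(values))
        mad = OutlierRule._MAD_SCALE * float(np.median(np.abs(values - med)))
        for animal_id, total in group:
            if total > rule.total_threshold:
                flagged.add(animal_id)
            elif math.isfinite(rule.mad_k) and abs(total - med) > rule.mad_k * mad:
                flagged.add(animal_id)
    for a in sorted(flagged):
        warnings.warn(
            f"animal {a!r} flagged as recovery outlier "
            f"(total recovery {totals[a][1]:.3f})",
            stacklevel=2,
        )
    return flagged


def mean_recovery(
    observations: Sequence[RecoveryObservation],
    excluded: set[str] = frozenset(),
) -> RecoveryTable:
    """Aggregate per-(diet, alkane) arithmetic mean, SEM and n.

    ``excluded`` animals (e.g. outliers from :func:`flag_outliers`) are
    dropped before aggregation.  A diet whose animals are all excluded is an
    error: correction for that diet would be impossible.
    """
    diets_before = {o.diet_id for o in observations}
    kept = [o for o in observations if o.animal_id not in excluded]
    cells: dict[tuple[str, AlkaneID], list[float]] = {}
    for o in kept:
        cells.setdefault((o.diet_id, o.alkane), []).append(o.recovery)
    lost = diets_before - {d for d, _ in cells}
    if lost:
        raise ValidationError(
            f"all animals excluded for diet(s) {', '.join(sorted(lost))}; "
            "no recovery mean can be formed"
        )
    entries = {}
    for key, values in cells.items():
        arr = np.asarray(values)
        n = arr.size
        sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        entries[key] = RecoveryCell(mean=float(arr.mean()), sem=sem, n=n)
    return RecoveryTable(entries)
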