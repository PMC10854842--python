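"""Scoring predictions against known truth and exhaustive marker-subset search.

Prediction error for a group of animals with a common true plant proportion
is summarised by the mean-squared-error decomposition

    MSE = bias^2 + variance,      RMSE = sqrt(MSE),

with bias the mean error and variance the *population* variance of the
errors (divide by n).  Only the population variance makes the decomposition
an exact identity, which every emitted metric satisfies to float round-off.

The subset search solves the marker-balance system for every subset of the
marker panel from ``min_size`` up to the full panel (26 subsets for the
5-marker panel with min_size 2) and ranks the subsets by a configurable
criterion — minimum RMSE by default, smallest absolute bias as an
alternative.  Collinear markers can make larger subsets *worse*, which is
exactly what the search is for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .estimate import estimate_animal
from .profiles import CSV_FLOAT_FORMAT, AlkaneID, AlkaneProfile, AnimalRecord
from .recovery import RecoveryTable

__all__ = [
    "ErrorMetrics",
    "CombinationRow",
    "CombinationReport",
    "error_metrics",
    "enumerate_subsets",
    "combination_search",
]

RANK_CRITERIA = ("rmse", "abs_bias")


@dataclass(frozen=True)
class ErrorMetrics:
    """Bias/variance decomposition of prediction error for one group."""

    n: int
    mean_prediction: float
    bias: float
    variance: float  # population variance of the errors (/n)
    mse: float
    rmse: float


def error_metrics(predictions: Sequence[float], truth: float) -> ErrorMetrics:
    """Decomposed prediction error of ``predictions`` against a scalar truth.

    ``bias = mean(e)``, ``variance = population var(e)``, ``mse = mean(e^2)``
    with ``e_j = p_j - truth``; the identity ``mse = bias^2 + variance``
    holds by construction.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.size == 0:
        raise ValidationError("cannot score an empty prediction set")
    if not np.all(np.isfinite(preds)):
        raise ValidationError("non-finite predictions; exclude undefined estimates upstream")
    errors = preds - truth
    bias = float(errors.mean())
    variance = float(errors.var())  # ddof=0: population variance
    mse = float((errors**2).mean())
    return ErrorMetrics(
        n=preds.size,
        mean_prediction=float(preds.mean()),
        bias=bias,
        variance=variance,
        mse=mse,
        rmse=math.sqrt(mse),
    )


def enumerate_subsets(
    markers: Sequence[AlkaneID], min_size: int = 2
) -> list[tuple[AlkaneID, ...]]:
    """All marker subsets of size ``min_size`` .. m, each in ascending carbon
    order; overall order is by size then lexicographic (deterministic)."""
    ordered = tuple(sorted(markers))
    if min_size > len(ordered):
        raise ValidationError(
            f"min_size {min_size} exceeds the {len(ordered)}-marker panel"
        )
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    return [
        subset
        for size in range(min_size, len(ordered) + 1)
        for subset in combinations(ordered, size)
    ]


@dataclass(frozen=True)
class CombinationRow:
    markers: tuple[AlkaneID, ...]
    per_diet: Mapping[str, ErrorMetrics]
    pooled: ErrorMetrics | None  # None when every estimate was undefined
    n_undefined: int

    def marker_key(self) -> str:
        return "-".join(i.label for i in self.markers)


@dataclass
class CombinationReport:
    """Full subset-search table plus the ranking by the chosen criterion."""

    rows: list[CombinationRow]
    ranking: list[int]  # indices into rows, best first
    criterion: str

    @property
    def best(self) -> CombinationRow:
        return self.rows[self.ranking[0]]

    def frame(self) -> pd.DataFrame:
        """Long-format table: one row per (subset, diet) plus a pooled row."""
        rank_of = {idx: rank + 1 for rank, idx in enumerate(self.ranking)}
        records = []
        for idx, row in enumerate(self.rows):
            scopes = dict(row.per_diet)
            if row.pooled is not None:
                scopes["all"] = row.pooled
            for diet, m in scopes.items():
                records.append(
                    {
                        "markers": row.marker_key(),
                        "diet_id": diet,
                        "n": m.n,
                        "mean_prediction": m.mean_prediction,
                        "bias": m.bias,
                        "variance": m.variance,
                        "mse": m.mse,
                        "rmse": m.rmse,
                        "rank": rank_of.get(idx),
                        "n_undefined": row.n_undefined,
                    }
                )
            if not scopes:
                records.append(
                    {
                        "markers": row.marker_key(),
                        "diet_id": "all",
                        "n": 0,
                        "mean_prediction": math.nan,
                        "bias": math.nan,
                        "variance": math.nan,
                        "mse": math.nan,
                        "rmse": math.nan,
                        "rank": None,
                        "n_undefined": row.n_undefined,
                    }
                )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def _rank_value(row: CombinationRow, criterion: str) -> float:
    if row.pooled is None:
        return math.inf  # fully undefined subsets sort last, never dropped
    if criterion == "rmse":
        return row.pooled.rmse
    if criterion == "abs_bias":
        return abs(row.pooled.bias)
    raise ValidationError(
        f"unknown ranking criterion {criterion!r}; use one of {RANK_CRITERIA}"
    )


def combination_search(
    animals: Sequence[AnimalRecord],
    components: Sequence[AlkaneProfile],
    recovery: RecoveryTable,
    truth_by_diet: Mapping[str, float],
    min_size: int = 2,
    criterion: str = "rmse",
    plant_components: Sequence[str] | None = None,
    correction_diet: str | None = None,
    markers: Sequence[AlkaneID] | None = None,
) -> CombinationReport:
    """Estimate every animal under every marker subset and rank the subsets.

    Per subset the report carries per-diet metrics and metrics pooled over
    all animals; the ranking criterion (``rmse`` or ``abs_bias``, ascending)
    is evaluated on the pooled errors.  Subsets whose estimates are all
    undefined are kept in the table with a flag, ranked last.
    """
    if criterion not in RANK_CRITERIA:
        raise ValidationError(
            f"unknown ranking criterion {criterion!r}; use one of {RANK_CRITERIA}"
        )
    panel = tuple(sorted(markers)) if markers is not None else tuple(
        sorted(animals[0].markers)
    )
    missing_truth = {a.diet_id for a in animals} - set(truth_by_diet)
    if missing_truth:
        raise ValidationError(
            f"no truth value for diet(s): {', '.join(sorted(missing_truth))}"
        )
    if min_size < len(components):
        raise ValidationError(
            f"min_size {min_size} below the number of components ({len(components)})"
        )

    rows: list[CombinationRow] = []
    for subset in enumerate_subsets(panel, min_size):
        estimates = [
            estimate_animal(
                a,
                components,
                recovery,
                markers=subset,
                plant_components=plant_components,
                correction_diet=correction_diet,
            )
            for a in animals
        ]
        defined = [e for e in estimates if not e.undefined]
        n_undefined = len(estimates) - len(defined)
        per_diet = {}
        for diet in dict.fromkeys(a.diet_id for a in animals):
            preds = [e.proportion for e in defined if e.diet_id == diet]
            if preds:
                per_diet[diet] = error_metrics(preds, truth_by_diet[diet])
        if defined:
            pooled_errors = [e.proportion - truth_by_diet[e.diet_id] for e in defined]
            on_errors = error_metrics(pooled_errors, 0.0)
            # Same error decomposition, but report the mean *prediction*.
            pooled = ErrorMetrics(
                n=on_errors.n,
                mean_prediction=float(
                    np.mean([e.proportion for e in defined])
                ),
                bias=on_errors.bias,
                variance=on_errors.variance,
                mse=on_errors.mse,
                rmse=on_errors.rmse,
            )
        else:
            pooled = None
        rows.append(
            CombinationRow(
                markers=subset, per_diet=per_diet, pooled=pooled, n_undefined=n_undefined
            )
        )

    ranking = sorted(
        range(len(rows)),
        key=lambda idx: (_rank_value(rows[idx], criterion), idx),
    )
    return CombinationReport(rows=rows, ranking=ranking, criterion=criterion)
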