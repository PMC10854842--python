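"""Diet classification from fecal alkane profiles by linear discriminant analysis.

Fisher's LDA with a pooled within-class covariance: the discriminant
directions are the leading eigenvectors of the within/between generalized
eigenproblem, scaled so that discriminant scores have unit pooled
within-class variance, with the sign fixed so the first nonzero coefficient
is positive.  Prediction assigns the class maximising the Gaussian
discriminant score

    delta_k(x) = mu_k' S^-1 x - 0.5 mu_k' S^-1 mu_k + log pi_k

with S the pooled covariance and pi_k the class priors (observed class
frequencies by default).  The implementation is deliberately from scratch --
the classifier IS the analysis step here -- and is cross-checked against an
independent density-ratio oracle in the test suite.

The report-level entry point fits one model on all markers and one per
single marker, each with its LD1 coefficients and a resubstitution (or
optionally leave-one-out) confusion matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DegenerateModelError, ValidationError
from .profiles import CSV_FLOAT_FORMAT, AlkaneID, AnimalRecord

__all__ = [
    "LDAModel",
    "lda_fit",
    "lda_predict",
    "confusion_matrix",
    "per_marker_report",
    "PerMarkerRow",
    "DietClassifier",
    "DietClassifierResults",
    "features_from_animals",
]

_EIGVAL_TOL = 1e-10


@dataclass(frozen=True)
class LDAModel:
    """Fitted linear discriminant model (pooled-covariance Gaussian)."""

    classes: tuple[str, ...]
    class_means: np.ndarray  # (g, p)
    pooled_cov: np.ndarray  # (p, p), symmetric PD
    ld_coefficients: np.ndarray  # (p, min(g-1, p)) columns = LD directions
    priors: np.ndarray  # (g,)
    marker_names: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def scores(self, features: np.ndarray) -> np.ndarray:
        """Discriminant scores (projections on the LD directions)."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature matrix has {X.shape[1]} columns, model expects {self.n_features}"
            )
        return X @ self.ld_coefficients


def _validate_features(features, labels):
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = list(labels)
    if X.shape[0] != len(y):
        raise ValidationError(
            f"{X.shape[0]} feature rows but {len(y)} labels"
        )
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite values in feature matrix")
    return X, y


def lda_fit(
    features: np.ndarray,
    labels: Sequence[str],
    priors: Mapping[str, float] | None = None,
    ridge: float = 0.0,
    marker_names: Sequence[str] | None = None,
) -> LDAModel:
    """Fit an LDA model; class order follows first appearance in ``labels``.

    ``ridge`` adds ``ridge * mean(diag) * I`` to the pooled covariance for
    near-singular panels (off by default).
    """
    X, y = _validate_features(features, labels)
    classes = tuple(dict.fromkeys(y))
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    n, p = X.shape
    g = len(classes)
    counts = np.array([y.count(c) for c in classes])
    if counts.min() < 2:
        raise ValidationError("every class needs at least two animals")
    if n <= p + g - 1:
        warnings.warn(
            f"only {n} animals for {p} markers and {g} classes: "
            "covariance estimate will be unstable",
            stacklevel=2,
        )

    means = np.vstack([X[[yi == c for yi in y]].mean(axis=0) for c in classes])
    pooled = np.zeros((p, p))
    for k, c in enumerate(classes):
        Xc = X[[yi == c for yi in y]] - means[k]
        pooled += Xc.T @ Xc
    pooled /= n - g
    if ridge > 0:
        pooled = pooled + ridge * np.mean(np.diag(pooled)) * np.eye(p)

    try:
        scipy.linalg.cholesky(pooled, lower=True)
    except scipy.linalg.LinAlgError:
        raise DegenerateModelError(
            "singular pooled within-class covariance; consider the ridge option"
        ) from None

    if priors is None:
        pi = counts / n
    else:
        pi = np.array([priors[c] for c in classes], dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValidationError(f"priors sum to {pi.sum()!r}, not 1")

    grand = (counts[:, None] * means).sum(axis=0) / n
    between = np.zeros((p, p))
    for k in range(g):
        d = (means[k] - grand)[:, None]
        between += counts[k] * (d @ d.T)
    between /= n - g  # common scaling; eigenvectors are unaffected

    # Generalized symmetric eigenproblem B v = lambda W v; eigh returns
    # eigenvectors with v' W v = 1, i.e. unit within-class score variance.
    eigvals, eigvecs = scipy.linalg.eigh(between, pooled)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_ld = min(g - 1, p)
    if eigvals[0] <= _EIGVAL_TOL:
        raise DegenerateModelError(
            "no between-class separation (coincident class means); LD undefined"
        )
    ld = eigvecs[:, :n_ld].copy()
    for j in range(n_ld):  # deterministic sign: first nonzero coefficient > 0
        nz = np.flatnonzero(np.abs(ld[:, j]) > _EIGVAL_TOL)
        if nz.size and ld[nz[0], j] < 0:
            ld[:, j] = -ld[:, j]

    return LDAModel(
        classes=classes,
        class_means=means,
        pooled_cov=pooled,
        ld_coefficients=ld,
        priors=pi,
        marker_names=tuple(marker_names) if marker_names is not None else None,
    )


def lda_predict(model: LDAModel, features: np.ndarray) -> list[str]:
    """Assign each row the class with the highest Gaussian discriminant score.

    Exact ties go to the first class in model order, with a warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature matrix has {X.shape[1]} columns, model expects {model.n_features}"
        )
    # delta_k(x) = mu_k' S^-1 x - 0.5 mu_k' S^-1 mu_k + log pi_k
    Sinv_mu = scipy.linalg.solve(model.pooled_cov, model.class_means.T, assume_a="pos")
    linear = X @ Sinv_mu  # (n, g)
    const = -0.5 * np.sum(model.class_means.T * Sinv_mu, axis=0) + np.log(model.priors)
    delta = linear + const
    out = []
    for row in delta:
        best = int(np.argmax(row))
        scale = max(1.0, float(np.max(np.abs(row))))
        ties = np.flatnonzero(row >= row[best] - 1e-12 * scale)
        if ties.size > 1:  # tie goes to the first class in model order
            best = int(ties.min())
            warnings.warn(
                "tied discriminant scores; assigning the first class "
                f"({model.classes[best]!r})",
                stacklevel=2,
            )
        out.append(model.classes[best])
    return out


def confusion_matrix(
    true_labels: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Counts[i, j] = animals of true class i predicted as class j."""
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted):
        counts[index[t], index[p]] += 1
    return counts


def _loo_predictions(
    features: np.ndarray, labels: Sequence[str], priors, marker_names
) -> list[str]:
    X, y = _validate_features(features, labels)
    preds = []
    for i in range(X.shape[0]):
        keep = [j for j in range(X.shape[0]) if j != i]
        m = lda_fit(X[keep], [y[j] for j in keep], priors=priors,
                    marker_names=marker_names)
        preds.append(lda_predict(m, X[i : i + 1])[0])
    return preds


@dataclass(frozen=True)
class PerMarkerRow:
    model_name: str  # "all" or a marker label
    coefficients: Mapping[str, float] | None  # marker -> LD1 coefficient
    confusion: np.ndarray | None
    error: str | None = None


def per_marker_report(
    features: np.ndarray,
    labels: Sequence[str],
    marker_names: Sequence[str],
    priors: Mapping[str, float] | None = None,
    leave_one_out: bool = False,
) -> list[PerMarkerRow]:
    """One LDA on the full panel plus one per single marker.

    Confusion matrices are training-set resubstitution by default (matching
    the design where all animals fit and score the model); pass
    ``leave_one_out=True`` for LOO confusion counts.  A degenerate single
    marker (zero variance or coincident means) is recorded as an error row;
    the other rows are unaffected.
    """
    X, y = _validate_features(features, labels)
    if X.shape[1] != len(marker_names):
        raise ValidationError(
            f"{X.shape[1]} feature columns but {len(marker_names)} marker names"
        )
    rows: list[PerMarkerRow] = []
    jobs = [("all", list(range(X.shape[1])))] + [
        (name, [j]) for j, name in enumerate(marker_names)
    ]
    for name, cols in jobs:
        sub = X[:, cols]
        names = [marker_names[j] for j in cols]
        try:
            model = lda_fit(sub, y, priors=priors, marker_names=names)
            if leave_one_out:
                preds = _loo_predictions(sub, y, priors, names)
            else:
                preds = lda_predict(model, sub)
            rows.append(
                PerMarkerRow(
                    model_name=name,
                    coefficients=dict(zip(names, model.ld_coefficients[:, 0])),
                    confusion=confusion_matrix(y, preds, model.classes),
                )
            )
        except DegenerateModelError as exc:
            rows.append(
                PerMarkerRow(
                    model_name=name, coefficients=None, confusion=None, error=str(exc)
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


def features_from_animals(
    animals: Sequence[AnimalRecord], markers: Sequence[AlkaneID] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """(features, labels, marker names) from fecal concentrations."""
    if not animals:
        raise ValidationError("no animals supplied")
    panel = tuple(sorted(markers)) if markers is not None else animals[0].markers
    X = np.array([a.fecal_vector(panel) for a in animals])
    return X, [a.diet_id for a in animals], [i.label for i in panel]


class DietClassifier:
    """Diet classifier over a flock's fecal alkane profiles."""

    def __init__(
        self,
        animals: Sequence[AnimalRecord],
        markers: Sequence[AlkaneID] | None = None,
        priors: Mapping[str, float] | None = None,
    ):
        self.features, self.labels, self.marker_names = features_from_animals(
            animals, markers
        )
        self.priors = priors

    def fit(
        self, per_marker: bool = True, leave_one_out: bool = False
    ) -> "DietClassifierResults":
        model = lda_fit(
            self.features, self.labels, priors=self.priors,
            marker_names=self.marker_names,
        )
        rows = None
        if per_marker:
            rows = per_marker_report(
                self.features,
                self.labels,
                self.marker_names,
                priors=self.priors,
                leave_one_out=leave_one_out,
            )
        return DietClassifierResults(self, model, rows)


class DietClassifierResults:
    def __init__(
        self,
        classifier: DietClassifier,
        model: LDAModel,
        per_marker_rows: list[PerMarkerRow] | None,
    ):
        self.classifier = classifier
        self.model = model
        self.per_marker_rows = per_marker_rows

    @property
    def confusion(self) -> np.ndarray:
        preds = lda_predict(self.model, self.classifier.features)
        return confusion_matrix(self.classifier.labels, preds, self.model.classes)

    @property
    def accuracy(self) -> float:
        cm = self.confusion
        return float(np.trace(cm) / cm.sum())

    def frame(self) -> pd.DataFrame:
        """Report table: per model, LD1 coefficients and confusion cells."""
        rows = self.per_marker_rows or per_marker_report(
            self.classifier.features,
            self.classifier.labels,
            self.classifier.marker_names,
            priors=self.classifier.priors,
        )
        classes = self.model.classes
        records = []
        for r in rows:
            rec: dict = {"model": r.model_name}
            for name in self.classifier.marker_names:
                rec[f"ld1_{name}"] = (
                    r.coefficients.get(name) if r.coefficients else None
                )
            if r.confusion is not None:
                for i, true_c in enumerate(classes):
                    for j, pred_c in enumerate(classes):
                        rec[f"n_{true_c}_as_{pred_c}"] = r.confusion[i, j]
            rec["error"] = r.error
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    def summary(self) -> str:
        lines = [
            "Linear discriminant diet classification",
            f"  classes: {', '.join(self.model.classes)}",
            f"  markers: {', '.join(self.classifier.marker_names)}",
            f"  resubstitution accuracy: {100 * self.accuracy:.1f}%",
            "",
            self.frame().to_string(index=False, float_format="%.4g".__mod__),
        ]
        return "\n".join(lines)
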