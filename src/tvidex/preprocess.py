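"""Probe-level QC filtering, covariate adjustment, and sex-concordance QC."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .dataio import ExpressionMatrix, SampleManifest
from .errors import ValidationError

logger = logging.getLogger(__name__)

SEX_UNDETERMINED = "undetermined"


@dataclass
class FilterReport:
    n_input_probes: int
    n_removed: int
    removed_probe_ids: list[str]
    threshold: float
    fraction_rule: float

    @property
    def n_retained(self) -> int:
        return self.n_input_probes - self.n_removed


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: float = 6.0, fraction: float = 2.0 / 3.0
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop probes whose values fall below ``threshold`` in more than
    ``fraction`` of samples (strict inequality on the count).

    Probe order is preserved in the retained matrix.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must lie in (0, 1], got {fraction}")
    with np.errstate(invalid="ignore"):
        n_below = np.sum(matrix.values < threshold, axis=1)
    cutoff = fraction * matrix.n_samples
    remove = n_below > cutoff
    keep_idx = np.flatnonzero(~remove)
    retained = ExpressionMatrix(
        [matrix.probe_ids[i] for i in keep_idx],
        list(matrix.sample_ids),
        matrix.values[keep_idx],
    )
    report = FilterReport(
        n_input_probes=matrix.n_probes,
        n_removed=int(remove.sum()),
        removed_probe_ids=[matrix.probe_ids[i] for i in np.flatnonzero(remove)],
        threshold=threshold,
        fraction_rule=fraction,
    )
    return retained, report


def adjust_age_sex(
    matrix: ExpressionMatrix, manifest: SampleManifest
) -> ExpressionMatrix:
    """Regress out age and sex per probe, preserving each probe's grand level.

    One least-squares fit per probe on intercept + centered age + centered sex
    over all samples; the returned values are residuals plus the fitted
    intercept.  A constant covariate column is dropped with a warning.
    """
    mat = matrix.reorder_samples(manifest.sample_ids)
    age = manifest.ages()
    sex = manifest.sex_codes()

    columns = [np.ones(len(manifest))]
    for name, col in (("age", age), ("sex", sex)):
        if np.ptp(col) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped from adjustment")
            logger.warning("covariate %s constant across samples; dropped", name)
            continue
        columns.append(col - col.mean())
    X = np.column_stack(columns)

    Y = mat.values  # probes x samples; NaN handled pairwise below
    finite = np.isfinite(Y)
    out = Y.copy()
    if finite.all():
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        out = (resid + beta[0]).T
    else:
        for i in range(Y.shape[0]):
            m = finite[i]
            if m.sum() <= X.shape[1]:
                continue
            beta, *_ = np.linalg.lstsq(X[m], Y[i, m], rcond=None)
            out[i, m] = Y[i, m] - X[m] @ beta + beta[0]
    return ExpressionMatrix(list(mat.probe_ids), list(mat.sample_ids), out)


@dataclass
class SexCheckRecord:
    sample_id: str
    recorded_sex: str
    predicted_sex: str
    mismatch_flag: bool


def _nsc_fit(X: np.ndarray, y01: np.ndarray, delta: float):
    """Nearest-shrunken-centroid statistics for a two-class problem.

    Returns (overall centroid, shrunken class centroids, per-feature scale,
    class priors); shrunken centroids follow the soft-thresholded
    standardized-difference construction.
    """
    n, _ = X.shape
    classes = (0, 1)
    xbar = X.mean(axis=0)
    cent = np.stack([X[y01 == k].mean(axis=0) for k in classes])
    nk = np.array([(y01 == k).sum() for k in classes])
    within = np.zeros(X.shape[1])
    for k in classes:
        within += ((X[y01 == k] - cent[k]) ** 2).sum(axis=0)
    s = np.sqrt(within / max(n - 2, 1))
    s0 = np.median(s)
    scale = s + s0
    if np.all(scale == 0):
        raise ValidationError(
            "all marker probes have zero variance; review the marker list"
        )
    mk = np.sqrt(1.0 / nk + 1.0 / n)
    d = (cent - xbar) / (mk[:, None] * scale)
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    cent_shrunk = xbar + mk[:, None] * scale * d_shrunk
    priors = nk / n
    return xbar, cent_shrunk, scale, priors, d_shrunk


def _nsc_predict(X: np.ndarray, cent_shrunk, scale, priors) -> np.ndarray:
    scores = []
    for k in range(2):
        dist = (((X - cent_shrunk[k]) / scale) ** 2).sum(axis=1)
        scores.append(dist - 2.0 * np.log(priors[k]))
    return np.argmin(np.stack(scores), axis=0)


def _nsc_choose_delta(X: np.ndarray, y01: np.ndarray, rng_seed: int = 0) -> float:
    """Pick the largest shrinkage achieving maximal CV accuracy (small grid)."""
    _, _, _, _, d = _nsc_fit(X, y01, 0.0)
    dmax = float(np.abs(d).max())
    if dmax == 0:
        return 0.0
    grid = np.linspace(0.0, 0.9 * dmax, 8)
    n_splits = min(3, int(np.bincount(y01).min()))
    if n_splits < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rng_seed)
    best_acc, best_delta = -1.0, 0.0
    for delta in grid:
        correct = 0
        for train, test in skf.split(X, y01):
            try:
                xbar, cs, sc, pr, _ = _nsc_fit(X[train], y01[train], delta)
            except ValidationError:
                continue
            correct += int((_nsc_predict(X[test], cs, sc, pr) == y01[test]).sum())
        acc = correct / len(y01)
        if acc >= best_acc:  # prefer more shrinkage at equal accuracy
            best_acc, best_delta = acc, float(delta)
    return best_delta


def sex_check(
    matrix: ExpressionMatrix,
    manifest: SampleManifest,
    marker_probes: list[str],
    method: str = "shrunken_centroid",
    shrinkage: float | None = None,
) -> list[SexCheckRecord]:
    """Predict sex from marker-probe expression and flag mismatches.

    ``method='shrunken_centroid'`` uses soft-thresholded class centroids on
    standardized marker expression (shrinkage chosen by a small internal CV
    grid unless given); ``method='lda'`` uses two-class linear discriminant
    analysis.  A fully shrunken centroid model abstains: every prediction is
    ``'undetermined'`` and no mismatch is flagged.
    """
    if method not in ("shrunken_centroid", "lda"):
        raise ValidationError(f"unknown sex_check method {method!r}")
    missing = [p for p in marker_probes if p not in matrix.probe_ids]
    if missing:
        raise ValidationError(f"marker probes absent from matrix: {missing}")
    mat = matrix.reorder_samples(manifest.sample_ids)
    sub = mat.subset_probes(marker_probes)
    X = sub.values.T  # samples x markers
    if not np.isfinite(X).all():
        raise ValidationError("marker expression contains missing values")
    recorded = [r.sex for r in manifest.records]
    y01 = np.array([1 if s == "M" else 0 for s in recorded])
    if len(set(recorded)) < 2:
        raise ValidationError("both sexes must be present to train the sex check")
    if np.all(X.std(axis=0) == 0):
        raise ValidationError(
            "all marker probes have zero variance; review the marker list"
        )

    label = {0: "F", 1: "M"}
    if method == "lda":
        clf = LinearDiscriminantAnalysis()
        clf.fit(X, y01)
        pred = clf.predict(X)
        predicted = [label[int(k)] for k in pred]
    else:
        delta = shrinkage if shrinkage is not None else _nsc_choose_delta(X, y01)
        xbar, cs, sc, pr, d_shrunk = _nsc_fit(X, y01, delta)
        if np.all(d_shrunk == 0):
            warnings.warn(
                "shrinkage removed all centroid differences; sex predictions abstain"
            )
            predicted = [SEX_UNDETERMINED] * len(recorded)
        else:
            pred = _nsc_predict(X, cs, sc, pr)
            predicted = [label[int(k)] for k in pred]

    return [
        SexCheckRecord(
            sample_id=rec.sample_id,
            recorded_sex=rec.sex,
            predicted_sex=pred_sex,
            mismatch_flag=(pred_sex in ("F", "M") and pred_sex != rec.sex),
        )
        for rec, pred_sex in zip(manifest.records, predicted)
    ]
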