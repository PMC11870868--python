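"""Evaluation protocol: localization error, agreement statistics, splits.

Implements the full battery used to compare automated against manual
pelvimetry:

* per-landmark Euclidean localization error, summarized as MAE +- SD;
* per-dimension agreement: MAE, coefficient of determination R^2
  (1 - SS_res/SS_tot about the reference mean, *not* squared Pearson r),
  Spearman rank correlation, Bland-Altman bias and limits of agreement,
  and R^2 recomputed after excluding LoA outliers;
* inter-observer variability from dual-annotated patients;
* center-stratified k-fold cross-validation where every patient is
  tested exactly once and each institute contributes proportionally to
  every fold.

Sign convention everywhere: differences are reference minus predicted.
Standard deviations are sample SDs (n-1).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .geometry import (
    DIMENSION_LANDMARKS,
    LANDMARK_LABELS,
    LandmarkSet,
    compute_dimensions,
    euclidean_distance,
)
from .preprocess import VolumeGrid

#: factor defining the 95% limits of agreement
LOA_FACTOR = 1.96


# -- cohort container ------------------------------------------------------

@dataclass
class PatientRecord:
    """One patient: id, institute, annotations and (optionally) image data."""

    volume_id: str
    institute_id: str
    reference: LandmarkSet
    volume: Optional[VolumeGrid] = None
    observer2: Optional[LandmarkSet] = None
    predicted: Optional[LandmarkSet] = None


@dataclass
class CohortTable:
    """A cohort of patients with unique volume ids."""

    records: List[PatientRecord]

    def __post_init__(self):
        ids = [r.volume_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate volume ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> List[str]:
        return [r.volume_id for r in self.records]

    def by_id(self, volume_id: str) -> PatientRecord:
        for r in self.records:
            if r.volume_id == volume_id:
                return r
        raise KeyError(volume_id)

    def ids_by_institute(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for r in self.records:
            out.setdefault(r.institute_id, []).append(r.volume_id)
        return out


# -- localization error ----------------------------------------------------

def localization_errors(pred: LandmarkSet, truth: LandmarkSet) -> Dict[str, float]:
    """Per-landmark Euclidean distance (mm) over commonly present landmarks."""
    common = [
        l for l in LANDMARK_LABELS if not pred.is_missing(l) and not truth.is_missing(l)
    ]
    if not common:
        raise DataError("no landmark present in both sets")
    return {l: euclidean_distance(pred[l], truth[l]) for l in common}


def mae_summary(values: Sequence[float]) -> Tuple[float, float]:
    """Mean absolute error and its sample SD (n-1; 0.0 for a single value)."""
    v = np.abs(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DataError("mae_summary requires at least one value")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd


# -- agreement -------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    """Agreement between predicted and reference dimension measurements."""

    n: int
    mae: float
    mae_sd: float
    r2: float
    r2_without_outliers: float
    spearman_rho: float
    bias: float
    loa_halfwidth: float
    outlier_indices: Tuple[int, ...]
    constant_reference: bool = False

    def as_dict(self) -> Dict[str, object]:
        d = {
            "n": self.n,
            "mae": self.mae,
            "mae_sd": self.mae_sd,
            "r2": self.r2,
            "r2_without_outliers": self.r2_without_outliers,
            "spearman_rho": self.spearman_rho,
            "bias": self.bias,
            "loa_halfwidth": self.loa_halfwidth,
            "outlier_indices": list(self.outlier_indices),
            "constant_reference": self.constant_reference,
        }
        return d


def _r2_score(reference: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination of predictions about the reference mean."""
    ss_tot = float(np.sum((reference - reference.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((reference - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def dimension_agreement(
    predicted: Sequence[float], reference: Sequence[float]
) -> AgreementReport:
    """Full agreement report for one dimension over paired patients.

    Outliers are pairs whose difference (reference - predicted) falls
    strictly outside bias +- 1.96 * SD(differences); the LoA are
    computed once on the full sample and R^2 is then recomputed on the
    retained pairs.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise DataError("predicted and reference must be equal-length 1D sequences")
    if p.size < 3:
        raise DataError("agreement statistics need at least 3 pairs")
    diffs = r - p
    mae, mae_sd = mae_summary(diffs)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    halfwidth = LOA_FACTOR * sd
    outliers = np.flatnonzero((diffs < bias - halfwidth) | (diffs > bias + halfwidth))
    keep = np.setdiff1d(np.arange(p.size), outliers)
    constant = bool(np.all(r == r[0]))
    r2 = _r2_score(r, p)
    r2_wo = _r2_score(r[keep], p[keep]) if keep.size >= 2 else float("nan")
    if constant:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(p, r).statistic)
    return AgreementReport(
        n=int(p.size),
        mae=mae,
        mae_sd=mae_sd,
        r2=r2,
        r2_without_outliers=r2_wo,
        spearman_rho=rho,
        bias=bias,
        loa_halfwidth=halfwidth,
        outlier_indices=tuple(int(i) for i in outliers),
        constant_reference=constant,
    )


def interobserver_mae(cohort: CohortTable) -> Tuple[float, float]:
    """MAE +- SD over all per-landmark distances between the two observers."""
    distances: List[float] = []
    for rec in cohort:
        if rec.observer2 is None:
            continue
        distances.extend(localization_errors(rec.observer2, rec.reference).values())
    if not distances:
        raise DataError("no dual-annotated patients in cohort")
    return mae_summary(distances)


# -- stratified k-fold -----------------------------------------------------

@dataclass(frozen=True)
class Fold:
    train_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]


@dataclass(frozen=True)
class SplitPlan:
    k: int
    seed: int
    folds: Tuple[Fold, ...]
    small_institutes: Tuple[str, ...] = ()

    @property
    def test_sizes(self) -> Tuple[int, ...]:
        return tuple(len(f.test_ids) for f in self.folds)


def _institute_rng(seed: int, institute: str) -> np.random.Generator:
    # global seed + label hash: adding an institute never reshuffles others
    return np.random.default_rng([seed, zlib.crc32(str(institute).encode())])


def stratified_kfold_ids(
    ids_by_institute: Mapping[str, Sequence[str]], k: int, seed: int
) -> SplitPlan:
    """Center-stratified k-fold on explicit per-institute id lists.

    Within each institute patients are shuffled (seeded) and dealt into
    k folds whose per-institute sizes differ by at most one; institutes'
    remainder patients go to the globally smallest folds so pooled fold
    sizes also differ by at most one. Every patient appears in exactly
    one test fold.
    """
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    fold_test: List[List[str]] = [[] for _ in range(k)]
    fold_totals = np.zeros(k, dtype=int)
    small: List[str] = []
    for institute in sorted(ids_by_institute, key=str):
        ids = list(ids_by_institute[institute])
        if len(ids) < k:
            small.append(str(institute))
        rng = _institute_rng(seed, str(institute))
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n = len(ids)
        base, extra = divmod(n, k)
        # remainders to currently smallest folds (ties -> lowest index)
        receive_extra = set(np.argsort(fold_totals, kind="stable")[:extra].tolist())
        pos = 0
        for f in range(k):
            size = base + (1 if f in receive_extra else 0)
            fold_test[f].extend(shuffled[pos : pos + size])
            fold_totals[f] += size
            pos += size
    all_ids = [i for ids in ids_by_institute.values() for i in ids]
    folds = []
    for f in range(k):
        test = tuple(fold_test[f])
        test_set = set(test)
        train = tuple(i for i in all_ids if i not in test_set)
        folds.append(Fold(train_ids=train, test_ids=test))
    return SplitPlan(k=k, seed=seed, folds=tuple(folds), small_institutes=tuple(small))


def stratified_kfold(cohort: CohortTable, k: int, seed: int) -> SplitPlan:
    """Center-stratified k-fold over a cohort (see :func:`stratified_kfold_ids`)."""
    return stratified_kfold_ids(cohort.ids_by_institute(), k, seed)


def cohort_flow(enrolled: int, exclusions: Mapping[str, int]) -> Dict[str, object]:
    """Patient-flow accounting: enrolled minus staged exclusions."""
    eligible = int(enrolled) - sum(int(v) for v in exclusions.values())
    if eligible < 0:
        raise DataError("exclusions exceed enrolled patients")
    return {"enrolled": int(enrolled), "exclusions": dict(exclusions), "eligible": eligible}


# -- cross-validation ------------------------------------------------------

class StubTrainer:
    """Trainer stand-in whose predictor returns the reference landmarks,
    optionally shifted by a fixed per-landmark offset (mm). Used to audit
    evaluation bookkeeping independently of any model."""

    def __init__(self, offsets: Optional[Mapping[str, Sequence[float]]] = None):
        self.offsets = {k: np.asarray(v, dtype=float) for k, v in (offsets or {}).items()}

    def fit(self, train_records: Sequence[PatientRecord]):
        def predict(record: PatientRecord) -> LandmarkSet:
            pts = {}
            for l in LANDMARK_LABELS:
                p = record.reference.get(l)
                if p is None:
                    pts[l] = None
                else:
                    pts[l] = p + self.offsets.get(l, np.zeros(3))
            return LandmarkSet(pts)

        return predict


@dataclass
class CrossValResult:
    """Outputs of a stratified cross-validation run."""

    errors: pd.DataFrame  # long: volume_id, institute, fold, landmark, error_mm
    localization_mean: pd.DataFrame  # institute x landmark (+ Mean col, All row)
    localization_sd: pd.DataFrame
    patients_per_institute: pd.Series
    agreement: Dict[str, AgreementReport]
    split: SplitPlan
    predictions: Dict[str, LandmarkSet]


def summarize_localization(
    errors: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Institute x landmark MAE table with pooled 'Mean' column and 'All' row."""
    institutes = sorted(errors["institute"].unique())
    cols = list(LANDMARK_LABELS) + ["Mean"]
    mean_df = pd.DataFrame(index=institutes + ["All"], columns=cols, dtype=float)
    sd_df = mean_df.copy()
    for inst in institutes + ["All"]:
        sub = errors if inst == "All" else errors[errors["institute"] == inst]
        for lm in LANDMARK_LABELS:
            vals = sub.loc[sub["landmark"] == lm, "error_mm"].to_numpy()
            if vals.size:
                m, s = mae_summary(vals)
                mean_df.loc[inst, lm], sd_df.loc[inst, lm] = m, s
        m, s = mae_summary(sub["error_mm"].to_numpy())
        mean_df.loc[inst, "Mean"], sd_df.loc[inst, "Mean"] = m, s
    n = errors.groupby("institute")["volume_id"].nunique()
    n["All"] = errors["volume_id"].nunique()
    return mean_df, sd_df, n


def crossvalidate(
    cohort: CohortTable,
    trainer,
    k: int = 5,
    seed: int = 0,
) -> CrossValResult:
    """Run center-stratified k-fold cross-validation over a cohort.

    ``trainer.fit(train_records)`` must return a callable mapping a
    PatientRecord to a predicted LandmarkSet. Emits the per-institute,
    per-landmark localization-error table and per-dimension agreement
    reports on the pooled out-of-fold predictions.
    """
    split = stratified_kfold(cohort, k, seed)
    rows = []
    predictions: Dict[str, LandmarkSet] = {}
    for fi, fold in enumerate(split.folds):
        train_records = [cohort.by_id(i) for i in fold.train_ids]
        predictor = trainer.fit(train_records)
        for vid in fold.test_ids:
            rec = cohort.by_id(vid)
            pred = predictor(rec)
            predictions[vid] = pred
            for lm, err in localization_errors(pred, rec.reference).items():
                rows.append(
                    {
                        "volume_id": vid,
                        "institute": rec.institute_id,
                        "fold": fi,
                        "landmark": lm,
                        "error_mm": err,
                    }
                )
    errors = pd.DataFrame(rows)
    mean_df, sd_df, n = summarize_localization(errors)

    agreement: Dict[str, AgreementReport] = {}
    dims_pred: Dict[str, List[float]] = {d: [] for d in DIMENSION_LANDMARKS}
    dims_ref: Dict[str, List[float]] = {d: [] for d in DIMENSION_LANDMARKS}
    for rec in cohort:
        pred = predictions.get(rec.volume_id)
        if pred is None:
            continue
        dp = compute_dimensions(pred).as_dict()
        dr = compute_dimensions(rec.reference).as_dict()
        for dim in DIMENSION_LANDMARKS:
            if dp[dim] is not None and dr[dim] is not None:
                dims_pred[dim].append(dp[dim])
                dims_ref[dim].append(dr[dim])
    for dim in DIMENSION_LANDMARKS:
        if len(dims_pred[dim]) >= 3:
            agreement[dim] = dimension_agreement(dims_pred[dim], dims_ref[dim])

    return CrossValResult(
        errors=errors,
        localization_mean=mean_df,
        localization_sd=sd_df,
        patients_per_institute=n,
        agreement=agreement,
        split=split,
        predictions=predictions,
    )


# -- Bland-Altman plotting -------------------------------------------------

def bland_altman_figure(
    predicted: Sequence[float],
    reference: Sequence[float],
    title: str = "",
    units: str = "mm",
):
    """Bland-Altman plot: per-pair mean vs difference (reference - predicted),
    with bias and 95% limits-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    diffs = r - p
    means = (r + p) / 2.0
    bias = float(np.mean(diffs))
    half = LOA_FACTOR * float(np.std(diffs, ddof=1))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(bias, color="k", lw=1, label=f"bias {bias:.2f} {units}")
    for y, style in ((bias + half, "--"), (bias - half, "--")):
        ax.axhline(y, color="gray", lw=1, ls=style)
    ax.set_xlabel(f"mean of methods ({units})")
    ax.set_ylabel(f"reference - predicted ({units})")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig
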