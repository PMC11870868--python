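"""End-to-end phantom studies: train, predict, evaluate in one place.

Ties the phantom generator, the heatmap-regression localizer and the
evaluation battery together so that the whole workflow -- simulate a
multi-institute cohort, train a tiny U-Net, localize landmarks on
held-out phantoms, measure errors -- runs from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .errors import DataError
from .evaluation import PatientRecord, localization_errors, mae_summary
from .geometry import LandmarkSet
from .localizer import TrainingHistory, predict_landmarks, train
from .nn import UNet3D
from .phantom import generate_cohort


def _pairs(records: Sequence[PatientRecord]) -> List[Tuple]:
    missing = [r.volume_id for r in records if r.volume is None]
    if missing:
        raise DataError(f"records without volumes: {missing}")
    return [(r.volume, r.reference) for r in records]


def train_on_records(
    records: Sequence[PatientRecord],
    run: RunConfig,
    val_fraction: float = 0.2,
) -> Tuple[UNet3D, TrainingHistory]:
    """Train the localizer on a record list, holding out a validation tail."""
    n_val = max(1, int(round(val_fraction * len(records))))
    if n_val >= len(records):
        raise DataError("too few records to split off a validation set")
    train_recs, val_recs = records[:-n_val], records[-n_val:]
    return train(
        _pairs(train_recs),
        _pairs(val_recs),
        run.localizer,
        preprocess_config=run.preprocess,
        heatmap_config=run.heatmap,
    )


def evaluate_on_records(
    model, records: Sequence[PatientRecord], run: RunConfig
) -> Dict[str, object]:
    """Predict landmarks on each record and summarize localization error."""
    all_errors: List[float] = []
    per_patient: Dict[str, Dict[str, float]] = {}
    predictions: Dict[str, LandmarkSet] = {}
    for rec in records:
        lm, conf, flags = predict_landmarks(
            model, rec.volume, preprocess_config=run.preprocess, heatmap_config=run.heatmap
        )
        predictions[rec.volume_id] = lm
        errs = localization_errors(lm, rec.reference)
        per_patient[rec.volume_id] = errs
        all_errors.extend(errs.values())
    mean, sd = mae_summary(all_errors)
    return {
        "mean_error_mm": mean,
        "sd_error_mm": sd,
        "per_patient": per_patient,
        "predictions": predictions,
    }


class UNetTrainer:
    """Trainer protocol adapter so :func:`pelvimetry.evaluation.crossvalidate`
    can drive real U-Net training fold by fold."""

    def __init__(self, run: RunConfig, val_fraction: float = 0.2):
        self.run = run
        self.val_fraction = val_fraction

    def fit(self, train_records: Sequence[PatientRecord]):
        model, _history = train_on_records(list(train_records), self.run, self.val_fraction)

        def predict(record: PatientRecord) -> LandmarkSet:
            lm, _conf, _flags = predict_landmarks(
                model,
                record.volume,
                preprocess_config=self.run.preprocess,
                heatmap_config=self.run.heatmap,
            )
            return lm

        return predict


def parameter_recovery_study(
    seed: int = 0,
    train_sizes: Sequence[int] = (5, 20),
    n_test: int = 5,
    n_runs: int = 3,
    run_config: Optional[RunConfig] = None,
) -> Dict[str, object]:
    """Seeded end-to-end recovery: does the pipeline find the blobs it planted?

    For each of ``n_runs`` independent replicates, a phantom cohort of
    ``max(train_sizes) + n_test`` patients is generated; the localizer is
    trained on growing prefixes of the training pool and evaluated on the
    same held-out phantoms. Reports the per-size mean landmark error
    (mm, averaged over runs) and the in-plane-spacing-based recovery
    threshold.
    """
    sizes = sorted(train_sizes)
    base = run_config or RunConfig.tiny(seed=seed)
    n_pool = max(sizes)
    per_run: Dict[int, List[float]] = {s: [] for s in sizes}
    for r in range(n_runs):
        cohort_seed = int(np.random.default_rng([seed, r]).integers(2**31 - 1))
        cohort = generate_cohort(
            n_pool + n_test, config=base.phantom, seed=cohort_seed
        )
        pool = cohort.records[:n_pool]
        test = cohort.records[n_pool:]
        for s in sizes:
            # equal per-volume exposure across sizes (fixed passes over the
            # pool, the standard learning-curve protocol): scale the step
            # budget with the training-set size
            steps = max(1, round(base.localizer.steps_per_epoch * s / n_pool))
            run = replace(
                base,
                localizer=replace(
                    base.localizer,
                    random_seed=cohort_seed % (2**16) + s,
                    steps_per_epoch=steps,
                ),
            )
            model, _hist = train_on_records(pool[:s], run)
            result = evaluate_on_records(model, test, run)
            per_run[s].append(result["mean_error_mm"])
    mean_error = {s: float(np.mean(v)) for s, v in per_run.items()}
    inplane = float(max(base.phantom.spacing[0], base.phantom.spacing[1]))
    return {
        "train_sizes": sizes,
        "n_test": n_test,
        "n_runs": n_runs,
        "per_run_error_mm": {s: list(map(float, v)) for s, v in per_run.items()},
        "mean_error_mm": mean_error,
        "recovery_threshold_mm": 2.0 * inplane,
    }
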