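"""Patient-wise holdout and cross-validation of the pain-score regressors.

Splits are always by patient: a patient's windows never appear in more than
one of the train/validation/test sets, and standardization statistics come
from the training patients only.  Errors are reported the way clinical
prediction papers tabulate them: mean absolute error per test patient, then
mean +/- sample SD across patients (holdout) or across fold MAEs
(cross-validation, which reuses one fixed test set and rotates the
validation patients through the folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anihrv.ani import AniConfig, compute_ani_series
from anihrv.labels import consensus_label, rater_mean_matrix, select_raters
from anihrv.models import (
    FeatureWindowSet,
    ModelSpec,
    TrainedModel,
    apply_standardizer,
    concat_window_sets,
    fit_standardizer,
    make_feature_windows,
    predict,
    train_lstm,
    train_mlp,
)

__all__ = [
    "SplitPlan",
    "CvPlan",
    "EvalReport",
    "CvReport",
    "PreparedPatient",
    "holdout_split",
    "make_cv_plan",
    "mae_per_patient",
    "aggregate_mae",
    "prepare_cohort",
    "run_experiment",
]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/validation/test patient-ID sets."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test sets must be pairwise disjoint")


@dataclass(frozen=True)
class CvPlan:
    """Cross-validation folds sharing a single fixed test set.

    Validation sets are pairwise disjoint across folds and together cover
    every non-test patient exactly once.
    """

    folds: tuple

    def __post_init__(self) -> None:
        test = set(self.folds[0].test_ids)
        seen_val: set = set()
        for f in self.folds:
            if set(f.test_ids) != test:
                raise ValueError("all folds must share the same test set")
            v = set(f.val_ids)
            if v & seen_val:
                raise ValueError("validation sets must be disjoint across folds")
            seen_val |= v


@dataclass(frozen=True)
class EvalReport:
    """One model's test-set performance: per-patient MAE and mean +/- SD."""

    model_kind: str
    per_patient_mae: dict
    overall_mean: float
    overall_sd: float
    history: list = field(default_factory=list)
    predictions: dict = field(default_factory=dict)  # pid -> (pred, label) arrays


@dataclass(frozen=True)
class CvReport:
    model_kind: str
    folds: tuple  # EvalReport per fold
    best_fold: int  # 0-based argmin of fold overall MAE
    overall_mean: float  # across fold MAEs
    overall_sd: float


def holdout_split(patient_ids, sizes: tuple = (60, 10, 10), seed: int = 0) -> SplitPlan:
    """Seeded random disjoint train/validation/test sets of the given sizes."""
    ids = list(patient_ids)
    n_train, n_val, n_test = sizes
    if len(ids) < n_train + n_val + n_test:
        raise ValueError(f"need {n_train + n_val + n_test} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return SplitPlan(
        train_ids=tuple(perm[:n_train]),
        val_ids=tuple(perm[n_train : n_train + n_val]),
        test_ids=tuple(perm[n_train + n_val : n_train + n_val + n_test]),
    )


def make_cv_plan(patient_ids, test_ids, n_folds: int = 7, val_size: int = 10, seed: int = 0) -> CvPlan:
    """Rotate the non-test patients through ``n_folds`` disjoint validation sets.

    Requires len(patient_ids) - len(test_ids) == n_folds * val_size; each
    fold's training set is every non-test, non-validation patient.
    """
    ids = list(patient_ids)
    test = list(test_ids)
    rest = [p for p in ids if p not in set(test)]
    if len(rest) != n_folds * val_size:
        raise ValueError(f"{len(rest)} non-test patients cannot split into {n_folds} folds of {val_size}")
    rng = np.random.default_rng(seed)
    perm = [rest[i] for i in rng.permutation(len(rest))]
    folds = []
    for k in range(n_folds):
        val = perm[k * val_size : (k + 1) * val_size]
        train = [p for p in perm if p not in set(val)]
        folds.append(SplitPlan(train_ids=tuple(train), val_ids=tuple(val), test_ids=tuple(test)))
    return CvPlan(folds=tuple(folds))


def mae_per_patient(predictions: np.ndarray, labels: np.ndarray, patient_ids) -> dict:
    """MAE over each patient's windows: mean |prediction - label| per patient."""
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=float)
    pid = np.asarray(patient_ids)
    if pred.shape != lab.shape or pred.shape != pid.shape:
        raise ValueError("predictions, labels and patient_ids must align")
    out = {}
    for p in np.unique(pid):
        m = pid == p
        out[p] = float(np.mean(np.abs(pred[m] - lab[m])))
    return out


def aggregate_mae(values) -> tuple:
    """Arithmetic mean and sample SD (denominator n - 1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("sample SD needs at least 2 values")
    return float(np.mean(v)), float(np.std(v, ddof=1))


@dataclass(frozen=True)
class PreparedPatient:
    """Aligned per-second feature/label pair for one patient."""

    patient_id: str
    time_s: np.ndarray
    opposite_ani: np.ndarray
    eaps: np.ndarray


def prepare_cohort(cohort, ani_config: AniConfig | None = None, alpha: float = 0.05) -> dict:
    """ANI + consensus labels for every patient of a synthetic cohort.

    Runs the full ANI pipeline per patient, performs the cohort-level rater
    exclusion, averages the included raters, and aligns (100 - ANI) with the
    consensus on their common seconds.  Returns pid -> PreparedPatient.
    """
    all_scores = [p.raters for p in cohort]
    included = select_raters(all_scores, alpha=alpha)
    prepared = {}
    for p in cohort:
        ani = compute_ani_series(p.rr, ani_config)
        lab = consensus_label(p.raters, included)
        t_common, ia, il = np.intersect1d(np.round(ani.time_s), np.round(lab.time_s), return_indices=True)
        prepared[p.patient_id] = PreparedPatient(
            patient_id=p.patient_id,
            time_s=t_common,
            opposite_ani=ani.opposite[ia],
            eaps=lab.eaps[il],
        )
    return prepared


def _windows_for(prepared: dict, pids, standardizer=None) -> FeatureWindowSet:
    sets = []
    for pid in pids:
        rec = prepared[pid]
        if rec.opposite_ani.size < 10:
            import warnings

            warnings.warn(f"patient {pid} shorter than one window; skipped")
            continue
        x = rec.opposite_ani if standardizer is None else apply_standardizer(standardizer, rec.opposite_ani)
        sets.append(make_feature_windows(x, rec.eaps, patient_id=pid))
    return concat_window_sets(sets)


def _run_single(prepared: dict, plan: SplitPlan, spec: ModelSpec) -> EvalReport:
    raw_train = _windows_for(prepared, plan.train_ids)
    std = fit_standardizer(raw_train.windows)
    train = _windows_for(prepared, plan.train_ids, std)
    val = _windows_for(prepared, plan.val_ids, std) if plan.val_ids else None
    test = _windows_for(prepared, plan.test_ids, std)
    trainer = train_mlp if spec.kind == "mlp" else train_lstm
    model = trainer(train, val, spec)
    preds = predict(model, test)
    per_patient = mae_per_patient(preds, test.labels, test.patient_ids)
    mean, sd = aggregate_mae(per_patient.values()) if len(per_patient) >= 2 else (
        float(np.mean(list(per_patient.values()))), float("nan"))
    predictions = {}
    for pid in np.unique(test.patient_ids):
        m = test.patient_ids == pid
        predictions[pid] = (preds[m], test.labels[m])
    return EvalReport(
        model_kind=spec.kind, per_patient_mae=per_patient,
        overall_mean=mean, overall_sd=sd, history=model.history, predictions=predictions,
    )


def run_experiment(prepared: dict, plan, model_specs) -> dict:
    """Fit and score every model spec under a holdout or cross-validation plan.

    ``prepared`` maps patient id -> :class:`PreparedPatient` (see
    :func:`prepare_cohort`).  For a :class:`SplitPlan` the result maps model
    kind -> :class:`EvalReport`; for a :class:`CvPlan` it maps model kind ->
    :class:`CvReport`, where the best fold is the argmin of the fold MAEs and
    the overall row aggregates fold MAEs as mean +/- sample SD.
    """
    if isinstance(model_specs, ModelSpec):
        model_specs = [model_specs]
    results = {}
    for spec in model_specs:
        if isinstance(plan, SplitPlan):
            results[spec.kind] = _run_single(prepared, plan, spec)
        elif isinstance(plan, CvPlan):
            fold_reports = tuple(_run_single(prepared, f, spec) for f in plan.folds)
            fold_maes = [r.overall_mean for r in fold_reports]
            mean, sd = aggregate_mae(fold_maes)
            results[spec.kind] = CvReport(
                model_kind=spec.kind, folds=fold_reports,
                best_fold=int(np.argmin(fold_maes)), overall_mean=mean, overall_sd=sd,
            )
        else:
            raise TypeError("plan must be SplitPlan or CvPlan")
    return results
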