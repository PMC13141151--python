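"""Quantile-rule labeling, random-forest regime partitioning, leave-one-model-
out evaluation, threshold sensitivity and abundance-heuristic baselines.

Ground truth is a conservative abundance rule on the deterministic
pre-simulation: a species is *stochastic* (label 1) iff both its 80th and
99th trajectory quantiles fall strictly below a molecule threshold (200 by
default).  The forest is trained on 18 trajectory features, its raw
probabilities are remapped by isotonic regression fitted on leave-one-model-
out (LOMO) fold predictions, and a fixed 0.5 decision threshold is used
everywhere; the classifier is evaluated model-wise (LOMO) so that reported
performance measures generalization to unseen systems.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.isotonic import IsotonicRegression

from .model import OdeModel
from .presim import FEATURE_NAMES, PresimSettings, extract_features, run_presim
from .zoo import Corpus

__all__ = [
    "DEFAULT_LABEL_THRESHOLD",
    "label_by_rule",
    "build_training_table",
    "PartitionModel",
    "train_partition_model",
    "ClassifierReport",
    "evaluate_lomo",
    "predict_partition",
    "threshold_sensitivity",
    "heuristic_baseline",
    "fold_metrics",
]

#: Molecule threshold of the labeling rule: stochastic iff q80 < tau AND q99 < tau.
DEFAULT_LABEL_THRESHOLD = 200.0


def label_by_rule(features: pd.DataFrame | pd.Series,
                  threshold: float = DEFAULT_LABEL_THRESHOLD):
    """Apply the quantile labeling rule (strict inequalities, molecule units).

    Returns an int (for a single feature row) or an int Series (for a
    feature table): 1 iff q80 < threshold and q99 < threshold, else 0.
    """
    if isinstance(features, pd.Series):
        return int(features["q80"] < threshold and features["q99"] < threshold)
    lab = ((features["q80"] < threshold) & (features["q99"] < threshold))
    return lab.astype(int)


def build_training_table(corpus: Corpus,
                         settings: PresimSettings | None = None,
                         threshold: float = DEFAULT_LABEL_THRESHOLD) -> pd.DataFrame:
    """Pre-simulate every corpus model, extract features and label species.

    Returns one row per species with columns ``model_id``, ``species``, the
    18 features, and ``label``.  Models whose pre-simulation fails are
    skipped with a warning and listed in ``table.attrs['skipped_models']``.
    Corpus models must be in count units (the rule is in molecules).
    """
    settings = settings or PresimSettings(horizon=corpus.spec.presim_horizon)
    for m in corpus.models:
        if any(k != "count" for k in m.unit_kinds):
            raise ValueError(f"corpus model {m.name!r} is not in count units; "
                             f"convert before labeling")
    rows: list[pd.DataFrame] = []
    skipped: list[str] = []
    for model in corpus.models:
        try:
            traj = run_presim(model, horizon=settings.horizon,
                              n_grid=settings.n_grid, rtol=settings.rtol,
                              atol=settings.atol, method=settings.method)
        except Exception as exc:  # noqa: BLE001 - skip-and-report contract
            warnings.warn(f"pre-simulation of {model.name!r} failed ({exc!r}); "
                          f"model skipped", stacklevel=2)
            skipped.append(model.name)
            continue
        feats = extract_features(traj)
        feats = feats.reset_index()
        feats.insert(0, "model_id", model.name)
        feats["label"] = label_by_rule(feats, threshold).values
        rows.append(feats)
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["model_id", "species", *FEATURE_NAMES, "label"])
    table.attrs["skipped_models"] = skipped
    table.attrs["label_threshold"] = threshold
    return table


@dataclass
class PartitionModel:
    """Trained forest + isotonic calibrator + fixed 0.5 decision threshold."""

    forest: RandomForestClassifier
    calibrator: IsotonicRegression
    feature_names: list[str]
    decision_threshold: float = 0.5
    training_info: dict = field(default_factory=dict)

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        return features[self.feature_names].to_numpy(dtype=float)

    def raw_probability(self, features: pd.DataFrame) -> np.ndarray:
        X = self._matrix(features)
        cls = list(self.forest.classes_)
        return self.forest.predict_proba(X)[:, cls.index(1)]

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Calibrated per-species stochastic probability in [0, 1]."""
        p = self.calibrator.predict(self.raw_probability(features))
        return np.clip(p, 0.0, 1.0)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Binary labels; ties at the threshold go stochastic."""
        return (self.predict_proba(features) >= self.decision_threshold).astype(int)

    def save(self, path: str | Path) -> None:
        """Persist to a joblib artifact plus a JSON sidecar with the contract."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "format_version": 1,
            "feature_names": self.feature_names,
            "decision_threshold": self.decision_threshold,
            "training_info": self.training_info,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "PartitionModel":
        pm = joblib.load(path)
        if not isinstance(pm, PartitionModel):
            raise TypeError(f"{path} does not contain a PartitionModel")
        return pm


def _fit_forest(table: pd.DataFrame, n_trees: int, seed: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(table[FEATURE_NAMES].to_numpy(dtype=float),
               table["label"].to_numpy(dtype=int))
    return forest


def train_partition_model(table: pd.DataFrame, n_trees: int = 300,
                          seed: int = 0,
                          calibration_n_trees: int | None = None) -> PartitionModel:
    """Fit the forest on all examples and calibrate on LOMO fold predictions.

    Out-of-fold probabilities are collected by leaving out one model at a
    time, the isotonic calibrator is fitted on those (probability, label)
    pairs, and the final forest is refitted on the full table.  Requires at
    least two models and both labels present.  ``calibration_n_trees``
    optionally shrinks the fold forests used only to estimate calibration
    probabilities (the final predictor keeps ``n_trees``); forest
    probabilities stabilise well below 300 trees at this feature count, so
    this trades negligible calibration noise for a large speedup in
    model-wise cross-validation.
    """
    model_ids = table["model_id"].unique()
    if len(model_ids) < 2:
        raise ValueError("training needs examples from at least two models")
    if table["label"].nunique() < 2:
        raise ValueError("training data contains a single class; the corpus "
                         "must include both regimes")
    cal_trees = n_trees if calibration_n_trees is None else calibration_n_trees
    oof_prob = np.empty(len(table))
    for mid in model_ids:
        held = table["model_id"] == mid
        train_tab = table.loc[~held]
        if train_tab["label"].nunique() < 2:
            # degenerate fold: every other model is single-class; predict prior
            oof_prob[held.to_numpy()] = float(train_tab["label"].mean())
            continue
        forest = _fit_forest(train_tab, cal_trees, seed)
        cls = list(forest.classes_)
        p = forest.predict_proba(
            table.loc[held, FEATURE_NAMES].to_numpy(dtype=float))[:, cls.index(1)]
        oof_prob[held.to_numpy()] = p
    calibrator = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True,
                                    out_of_bounds="clip")
    calibrator.fit(oof_prob, table["label"].to_numpy(dtype=int))
    forest = _fit_forest(table, n_trees, seed)
    return PartitionModel(
        forest=forest,
        calibrator=calibrator,
        feature_names=list(FEATURE_NAMES),
        decision_threshold=0.5,
        training_info={
            "n_examples": int(len(table)),
            "n_models": int(len(model_ids)),
            "n_trees": int(n_trees),
            "seed": int(seed),
            "label_threshold": float(table.attrs.get("label_threshold",
                                                     DEFAULT_LABEL_THRESHOLD)),
        },
    )


def fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Balanced accuracy and MCC from one fold's confusion matrix.

    Balanced accuracy is (TPR + TNR)/2; on single-class ground truth it is
    the recall of the present class (mean over defined classes).  MCC is NaN
    on single-class ground truth (such folds are flagged and excluded from
    mean MCC); with two-class truth but a vanishing denominator (degenerate
    predictions) it is 0 by the usual convention.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    recalls = []
    if tp + fn > 0:
        recalls.append(tp / (tp + fn))
    if tn + fp > 0:
        recalls.append(tn / (tn + fp))
    ba = float(np.mean(recalls)) if recalls else np.nan
    single_class = (tp + fn == 0) or (tn + fp == 0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if single_class:
        mcc = np.nan
    elif denom > 0:
        mcc = float((tp * tn - fp * fn) / np.sqrt(denom))
    else:
        mcc = 0.0
    return {"balanced_accuracy": ba, "mcc": mcc,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "single_class_truth": single_class}


@dataclass
class ClassifierReport:
    """Per-fold and aggregate LOMO performance."""

    per_fold: pd.DataFrame
    mean_balanced_accuracy: float
    mean_mcc: float
    pooled_confusion: np.ndarray  # [[tn, fp], [fn, tp]]
    pooled_balanced_accuracy: float
    pooled_mcc: float
    excluded_from_mcc: list[str] = field(default_factory=list)
    classifier_name: str = "random_forest"

    def to_json_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "mean_mcc": self.mean_mcc,
            "pooled_balanced_accuracy": self.pooled_balanced_accuracy,
            "pooled_mcc": self.pooled_mcc,
            "pooled_confusion": self.pooled_confusion.tolist(),
            "single_class_folds_excluded_from_mcc": self.excluded_from_mcc,
            "n_folds": int(len(self.per_fold)),
        }


def _report_from_folds(folds: list[dict], name: str) -> ClassifierReport:
    per_fold = pd.DataFrame(folds)
    tn = int(per_fold["tn"].sum())
    fp = int(per_fold["fp"].sum())
    fn = int(per_fold["fn"].sum())
    tp = int(per_fold["tp"].sum())
    pooled = fold_metrics(
        np.concatenate([np.ones(tp + fn, int), np.zeros(tn + fp, int)]),
        np.concatenate([np.ones(tp, int), np.zeros(fn, int),
                        np.zeros(tn, int), np.ones(fp, int)]),
    )
    excluded = per_fold.loc[~np.isfinite(per_fold["mcc"]), "model_id"].tolist()
    finite_mcc = per_fold["mcc"][np.isfinite(per_fold["mcc"])]
    return ClassifierReport(
        per_fold=per_fold,
        mean_balanced_accuracy=float(per_fold["balanced_accuracy"].mean()),
        mean_mcc=float(finite_mcc.mean()) if len(finite_mcc) else np.nan,
        pooled_confusion=np.array([[tn, fp], [fn, tp]]),
        pooled_balanced_accuracy=pooled["balanced_accuracy"],
        pooled_mcc=pooled["mcc"],
        excluded_from_mcc=excluded,
        classifier_name=name,
    )


def evaluate_lomo(
    corpus_or_table: Corpus | pd.DataFrame,
    settings: PresimSettings | None = None,
    n_trees: int = 300,
    seed: int = 0,
    calibration_n_trees: int | None = 100,
) -> ClassifierReport:
    """Leave-one-model-out evaluation of the calibrated forest.

    Each fold trains a full partition model (forest + inner LOMO isotonic
    calibration) on the remaining models and predicts the held-out model's
    species.  Per-fold balanced accuracy and MCC are reported together with
    their means and the pooled confusion matrix; folds with single-class
    ground truth contribute balanced accuracy over defined classes and are
    excluded (flagged) from the mean MCC.  The nested calibration forests
    default to 100 trees (see :func:`train_partition_model`), which keeps
    the quadratic fold x fold cost manageable without affecting held-out
    labels.
    """
    table = (corpus_or_table if isinstance(corpus_or_table, pd.DataFrame)
             else build_training_table(corpus_or_table, settings))
    model_ids = table["model_id"].unique()
    if len(model_ids) < 3:
        raise ValueError("LOMO evaluation needs at least 3 models")
    folds = []
    for mid in model_ids:
        held = table["model_id"] == mid
        pm = train_partition_model(table.loc[~held], n_trees=n_trees, seed=seed,
                                   calibration_n_trees=calibration_n_trees)
        y_pred = pm.predict(table.loc[held])
        m = fold_metrics(table.loc[held, "label"].to_numpy(), y_pred)
        m["model_id"] = mid
        m["n_species"] = int(held.sum())
        folds.append(m)
    return _report_from_folds(folds, "random_forest")


def predict_partition(
    model: OdeModel,
    pm: PartitionModel,
    settings: PresimSettings | None = None,
) -> pd.DataFrame:
    """Pre-simulate an unseen count-unit model and classify its species.

    Returns a frame indexed by species with calibrated ``probability`` and
    binary ``label`` (1 iff probability >= 0.5; the tie goes stochastic).
    The assignment is computed once and is meant to stay fixed for the whole
    hybrid simulation.
    """
    if any(k != "count" for k in model.unit_kinds):
        raise ValueError("predict_partition requires a count-unit model")
    settings = settings or PresimSettings()
    traj = run_presim(model, horizon=settings.horizon, n_grid=settings.n_grid,
                      rtol=settings.rtol, atol=settings.atol,
                      method=settings.method)
    feats = extract_features(traj)
    prob = pm.predict_proba(feats)
    return pd.DataFrame(
        {"probability": prob,
         "label": (prob >= pm.decision_threshold).astype(int)},
        index=feats.index,
    )


def threshold_sensitivity(
    corpus_or_table: Corpus | pd.DataFrame,
    thresholds: list[float] | np.ndarray,
    settings: PresimSettings | None = None,
    baseline: float = DEFAULT_LABEL_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of species whose rule label flips as the threshold varies.

    Labels at each threshold are compared with the baseline (200 molecules);
    the returned frame has columns ``threshold`` and ``flip_fraction`` and
    carries the grid maximum in ``attrs['max_flip_fraction']``.
    """
    table = (corpus_or_table if isinstance(corpus_or_table, pd.DataFrame)
             else build_training_table(corpus_or_table, settings))
    base = label_by_rule(table, baseline).to_numpy()
    rows = []
    for tau in thresholds:
        lab = label_by_rule(table, float(tau)).to_numpy()
        rows.append({"threshold": float(tau),
                     "flip_fraction": float(np.mean(lab != base))})
    out = pd.DataFrame(rows)
    out.attrs["max_flip_fraction"] = float(out["flip_fraction"].max())
    out.attrs["baseline"] = float(baseline)
    out.attrs["n_species"] = int(len(table))
    return out


def heuristic_baseline(
    table: pd.DataFrame,
    statistic: str = "mean",
    cutoff: float = DEFAULT_LABEL_THRESHOLD,
) -> ClassifierReport:
    """Abundance-only baseline: stochastic iff trajectory mean (or median)
    falls below the cutoff, evaluated on the same LOMO folds and metrics as
    the forest for comparability."""
    col = {"mean": "mean", "median": "q50"}.get(statistic)
    if col is None:
        raise ValueError("statistic must be 'mean' or 'median'")
    folds = []
    for mid in table["model_id"].unique():
        held = table["model_id"] == mid
        y_pred = (table.loc[held, col].to_numpy(dtype=float) < cutoff).astype(int)
        m = fold_metrics(table.loc[held, "label"].to_numpy(), y_pred)
        m["model_id"] = mid
        m["n_species"] = int(held.sum())
        folds.append(m)
    return _report_from_folds(folds, f"{statistic}_heuristic")
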