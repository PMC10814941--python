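"""Tumor-grouped leave-one-out classification of skin neoplasms.

:class:`NeoplasmClassifier` is a model object built from a fused observation
table (84 features per observation, keyed by tumor and diagnosis).  Its
:meth:`~NeoplasmClassifier.fit` runs leave-one-tumor-out cross-validation:
in each fold every observation of one tumor is held out, 0–1 feature scaling
and inverse-frequency class weights are re-learned from the training rows
only, and a gradient-boosted decision-tree multiclass model (softmax loss,
early stopping on a stratified slice of the training fold) produces
out-of-fold class-probability vectors for the held-out tumor.

The returned :class:`ClassificationResults` carries the out-of-fold
probabilities, the argmax confusion matrix, the Sens/Spec/Prec/F1/IoU metric
suite (six-class and collapsed binary bcc-vs-benign views), probability
threshold FPR/FNR curves, ROC curves, loss-based feature importances and
Shapley-value attributions from a final model trained on all observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from . import fusion, metrics
from .fusion import (
    BINARY_LABELS,
    DIAGNOSIS_LABELS,
    ScalingParams,
    apply_minmax,
    compute_class_weights,
    feature_columns,
    fit_minmax,
    to_binary_label,
)
from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    confusion_from_predictions,
    metrics_from_confusion,
    roc_curves,
    threshold_curves,
)

__all__ = ["ClassifierConfig", "NeoplasmClassifier", "ClassificationResults"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Training and evaluation configuration.

    The boosted-tree hyperparameters default to shallow trees (depth 4),
    learning rate 0.1 and at most 500 boosting rounds with early stopping
    after 50 non-improving rounds on a stratified 20% slice of the training
    fold.  ``scaling`` selects leakage-free per-fold min-max scaling
    (default) or the literal global pre-scaling variant.
    """

    depth: int = 4
    learning_rate: float = 0.1
    n_estimators: int = 500
    early_stopping_rounds: int = 50
    validation_fraction: float = 0.2
    seed: int = 0
    threshold_step: float = 0.01
    scaling: str = "per_fold"  # or "global"
    n_jobs: int = 1

    def __post_init__(self):
        if self.scaling not in ("per_fold", "global"):
            raise ValueError("scaling must be 'per_fold' or 'global'")


def _stratified_validation_split(
    y: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; classes too small to split stay in training."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = int(np.floor(fraction * len(idx)))
        if len(idx) - n_val < 1:
            n_val = 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx, int)), np.sort(np.asarray(val_idx, int))


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[str],
    weights: dict[str, float],
    config: ClassifierConfig,
) -> tuple[xgb.XGBClassifier, list[str]]:
    """Train the boosted multiclass model on one training partition.

    Returns the fitted model and the ordered class list its probability
    columns refer to.  Early stopping uses a stratified validation slice;
    when the slice would be empty (tiny folds) training runs the full
    schedule instead.
    """
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training fold contains a single class; untrainable")
    class_to_int = {c: i for i, c in enumerate(classes)}
    y_int = np.asarray([class_to_int[c] for c in y])
    w = np.asarray([weights[c] for c in y])

    tr, va = _stratified_validation_split(
        y_int, config.validation_fraction, config.seed
    )
    use_es = len(va) > 0 and len(np.unique(y_int[tr])) == len(classes)

    model = xgb.XGBClassifier(
        max_depth=config.depth,
        learning_rate=config.learning_rate,
        n_estimators=config.n_estimators,
        # softmax multiclass loss; its two-class special case is the
        # binary logistic objective the wrapper selects automatically
        objective="multi:softprob" if len(classes) > 2 else "binary:logistic",
        eval_metric="mlogloss" if len(classes) > 2 else "logloss",
        tree_method="hist",
        random_state=config.seed,
        n_jobs=config.n_jobs,
        early_stopping_rounds=config.early_stopping_rounds if use_es else None,
        verbosity=0,
    )
    Xv = X.to_numpy(dtype=float)
    if use_es:
        model.fit(
            Xv[tr],
            y_int[tr],
            sample_weight=w[tr],
            eval_set=[(Xv[va], y_int[va])],
            sample_weight_eval_set=[w[va]],
            verbose=False,
        )
    else:
        model.fit(Xv, y_int, sample_weight=w)
    return model, classes


class NeoplasmClassifier:
    """Multiclass skin-neoplasm classifier over a fused observation table.

    Parameters
    ----------
    table : DataFrame
        Fused observations with ``tumor_id``, ``label``, ``obs_idx`` and the
        84 feature columns (see :func:`dermafuse.fusion.pair_modalities`).
    config : ClassifierConfig, optional
    """

    def __init__(self, table: pd.DataFrame, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        missing = [c for c in ("tumor_id", "label") if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks required columns {missing}")
        self.feature_names = [c for c in feature_columns() if c in table.columns]
        if not self.feature_names:
            raise ValueError("table has none of the expected feature columns")
        self.table = table.reset_index(drop=True)
        labels = set(self.table["label"])
        unknown = labels - set(DIAGNOSIS_LABELS)
        if unknown:
            raise ValueError(f"unknown diagnosis labels {sorted(unknown)}")
        #: class list in canonical order, restricted to represented classes
        self.classes_ = tuple(l for l in DIAGNOSIS_LABELS if l in labels)

    @classmethod
    def from_modalities(
        cls,
        drs: pd.DataFrame,
        oct_: pd.DataFrame,
        us: pd.DataFrame,
        labels,
        *,
        pairing_seed: int,
        config: ClassifierConfig | None = None,
    ) -> "NeoplasmClassifier":
        """Build the model directly from the three modality feature tables."""
        table = fusion.pair_modalities(drs, oct_, us, labels, seed=pairing_seed)
        return cls(table, config)

    # -- cross-validation ---------------------------------------------------

    def loocv_splits(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (held-out tumor id, train row index, test row index).

        One fold per tumor; every observation of the held-out tumor is
        test-only in its fold.
        """
        tumors = sorted(self.table["tumor_id"].unique())
        if len(tumors) < 3:
            raise ValueError("need at least 3 tumors for leave-one-tumor-out CV")
        tumor_col = self.table["tumor_id"].to_numpy()
        for tumor in tumors:
            test = np.flatnonzero(tumor_col == tumor)
            train = np.flatnonzero(tumor_col != tumor)
            yield tumor, train, test

    def _fold_probabilities(self) -> pd.DataFrame:
        """Out-of-fold class probabilities for every observation."""
        cfg = self.config
        X_all = self.table[self.feature_names]
        y_all = self.table["label"].to_numpy()

        global_params: ScalingParams | None = None
        if cfg.scaling == "global":
            global_params = fit_minmax(self.table, self.feature_names)

        probs = pd.DataFrame(
            0.0, index=self.table.index, columns=list(self.classes_)
        )
        for tumor, train, test in self.loocv_splits():
            y_train = y_all[train]
            present = set(y_train)
            if len(present) < len(self.classes_):
                warnings.warn(
                    f"fold holding out tumor {tumor!r} lost class(es) "
                    f"{sorted(set(self.classes_) - present)} from training"
                )
            if cfg.scaling == "per_fold":
                params = fit_minmax(self.table.iloc[train], self.feature_names)
            else:
                params = global_params
            X_scaled = apply_minmax(X_all, params)
            weights = compute_class_weights(y_train)
            model, fold_classes = train_classifier(
                X_scaled.iloc[train], y_train, weights, cfg
            )
            p = model.predict_proba(X_scaled.iloc[test].to_numpy(dtype=float))
            for j, cls_name in enumerate(fold_classes):
                probs.loc[probs.index[test], cls_name] = p[:, j]
        return probs

    def fit(self) -> "ClassificationResults":
        """Run the grouped LOOCV evaluation and train the final model."""
        probs = self._fold_probabilities()
        y_true = self.table["label"].to_numpy()

        # final model on all observations (for importances / attributions)
        final_params = fit_minmax(self.table, self.feature_names)
        X_scaled = apply_minmax(self.table[self.feature_names], final_params)
        weights = compute_class_weights(y_true)
        final_model, final_classes = train_classifier(
            X_scaled, y_true, weights, self.config
        )
        return ClassificationResults(
            model=self,
            oof_probs=probs,
            final_model=final_model,
            final_classes=tuple(final_classes),
            final_scaling=final_params,
        )


@dataclass
class ClassificationResults:
    """Outputs of a tumor-grouped LOOCV evaluation."""

    model: NeoplasmClassifier
    oof_probs: pd.DataFrame
    final_model: xgb.XGBClassifier
    final_classes: tuple[str, ...]
    final_scaling: ScalingParams

    # -- predictions --------------------------------------------------------

    @property
    def y_true(self) -> np.ndarray:
        return self.model.table["label"].to_numpy()

    @property
    def y_pred(self) -> np.ndarray:
        """Argmax diagnosis per observation (highest probability wins)."""
        return self.oof_probs.idxmax(axis=1).to_numpy()

    # -- metric suite -------------------------------------------------------

    @property
    def confusion(self) -> ConfusionMatrix:
        return confusion_from_predictions(
            self.y_true, self.y_pred, self.model.classes_
        )

    @property
    def report(self) -> MetricsReport:
        return metrics_from_confusion(self.confusion)

    @property
    def binary_confusion(self) -> ConfusionMatrix:
        """Confusion of the argmax predictions collapsed to bcc vs benign."""
        yt = [to_binary_label(l) for l in self.y_true]
        yp = [to_binary_label(l) for l in self.y_pred]
        labels = tuple(l for l in BINARY_LABELS if l in set(yt) | set(yp)) or BINARY_LABELS
        return confusion_from_predictions(yt, yp, labels)

    @property
    def binary_report(self) -> MetricsReport:
        return metrics_from_confusion(self.binary_confusion)

    def threshold_curves(self) -> pd.DataFrame:
        return threshold_curves(
            self.oof_probs, self.y_true, step=self.model.config.threshold_step
        )

    def roc_curves(self) -> pd.DataFrame:
        return roc_curves(
            self.oof_probs, self.y_true, step=self.model.config.threshold_step
        )

    # -- interpretation -----------------------------------------------------

    def feature_importance(self) -> pd.Series:
        """Loss-influence (total gain) importance of all features.

        Features never used as a split (e.g. constant in training) score 0.
        Sorted descending.
        """
        booster = self.final_model.get_booster()
        booster.feature_names = list(self.model.feature_names)
        gains = booster.get_score(importance_type="total_gain")
        imp = pd.Series(
            {name: gains.get(name, 0.0) for name in self.model.feature_names},
            name="importance",
        )
        return imp.sort_values(ascending=False)

    def shap_attributions(self, table: pd.DataFrame | None = None) -> np.ndarray:
        """Per-observation, per-class additive Shapley-value attributions.

        Returns an array of shape ``(n_obs, n_classes, n_features + 1)``; the
        last slot is the expected-value base term, and for every observation
        the attributions plus base equal the model's output margin for that
        class (TreeSHAP's local-accuracy property).
        """
        if table is None:
            table = self.model.table
        X = apply_minmax(table[self.model.feature_names], self.final_scaling)
        dm = xgb.DMatrix(
            X.to_numpy(dtype=float), feature_names=list(self.model.feature_names)
        )
        contribs = self.final_model.get_booster().predict(dm, pred_contribs=True)
        if contribs.ndim == 2:  # binary folds collapse the class axis
            contribs = contribs[:, None, :]
        return contribs

    def predict_margin(self, table: pd.DataFrame | None = None) -> np.ndarray:
        """Raw per-class margins of the final model (pre-softmax)."""
        if table is None:
            table = self.model.table
        X = apply_minmax(table[self.model.feature_names], self.final_scaling)
        dm = xgb.DMatrix(
            X.to_numpy(dtype=float), feature_names=list(self.model.feature_names)
        )
        margins = self.final_model.get_booster().predict(dm, output_margin=True)
        if margins.ndim == 1:  # binary: single margin column
            margins = margins[:, None]
        return margins

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable evaluation summary (paper-style mean ± sd rows)."""
        rep, brep = self.report, self.binary_report
        lines = [
            "Tumor-grouped leave-one-out evaluation",
            "=" * 54,
            f"observations: {len(self.model.table)}   "
            f"tumors: {self.model.table['tumor_id'].nunique()}   "
            f"classes: {len(self.model.classes_)}",
            "",
            "Per-class metrics",
            rep.per_class.round(3).to_string(),
            "",
            "Macro (mean ± across-class sd):",
        ]
        for m in ("Sens", "Spec", "Prec", "F1", "IoU"):
            lines.append(
                f"  {m:>4}: {100 * rep.macro[m]:5.1f} ± {100 * rep.macro_std[m]:4.1f} %"
            )
        lines += ["", "Binary (bcc vs benign) macro:"]
        for m in ("Sens", "Spec", "Prec", "F1", "IoU"):
            lines.append(
                f"  {m:>4}: {100 * brep.macro[m]:5.1f} ± {100 * brep.macro_std[m]:4.1f} %"
            )
        if rep.undefined:
            lines.append(f"flagged zero-denominator classes: {rep.undefined}")
        return "\n".join(lines)

    # -- plots --------------------------------------------------------------

    def plot_confusion(self, ax=None):
        """Heatmap of the multiclass confusion matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        cm = self.confusion
        im = ax.imshow(cm.counts, cmap="Blues")
        ax.set_xticks(range(len(cm.labels)), cm.labels, rotation=45, ha="right")
        ax.set_yticks(range(len(cm.labels)), cm.labels)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(cm.labels)):
            for j in range(len(cm.labels)):
                ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
        ax.figure.colorbar(im, ax=ax)
        return ax

    def plot_roc(self, ax=None):
        """One-vs-rest ROC curves from the out-of-fold probabilities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        roc = self.roc_curves()
        for cls, grp in roc.groupby("class"):
            grp = grp.sort_values("FPR")
            ax.plot(grp["FPR"], grp["TPR"], label=cls)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        return ax

    def plot_threshold_curves(self, ax=None):
        """FPR (solid) and FNR (dashed) vs decision threshold per class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        curves = self.threshold_curves()
        for cls, grp in curves.groupby("class"):
            (line,) = ax.plot(grp["threshold"], grp["FPR"], label=f"{cls} FPR")
            ax.plot(
                grp["threshold"], grp["FNR"], "--", color=line.get_color(),
                label=f"{cls} FNR",
            )
        ax.set_xlabel("probability threshold")
        ax.set_ylabel("rate")
        ax.legend(fontsize=6)
        return ax

    def plot_importance(self, top: int = 25, ax=None):
        """Bar chart of the most important features (total gain)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 7))
        imp = self.feature_importance().head(top)[::-1]
        ax.barh(imp.index, imp.to_numpy())
        ax.set_xlabel("total gain")
        ax.tick_params(axis="y", labelsize=7)
        return ax
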