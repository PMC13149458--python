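"""PD-vs-HC classification harness.

Four models, evaluated with stratified 5-fold cross-validation on one
(metric, filtering) cell at a time:

* SVM    — linear-kernel SVM on the 4005 upper-triangle edge weights;
* SVM64  — the same after PCA to (at most) 64 components;
* GCN    — graph network with node-concat message passing (Eq. 1 style);
* GAT    — the attention-scaled variant.

Features are standardized, and PCA is fitted, on the training fold only.
PD is the positive class for precision/recall/F1; AUC uses the decision
function.  Reported per fold and as mean +/- std in the wide grid of
2 filterings x 5 metrics x 4 models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import Cohort, CohortManifest
from .nn import GNNClassifier, MessagePassingSpec, TrainingConfig

MODELS = ("GAT", "GCN", "SVM", "SVM64")
METRIC_COLS = ("accuracy", "precision", "recall", "auc", "f1")


def make_folds(manifest: CohortManifest, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment (one validation-fold id per subject, in
    manifest order); deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = manifest.group_mask("PD").astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} subjects; cannot make {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for fold_id, (_, val_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        folds[val_idx] = fold_id
    return folds


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                  decision: np.ndarray) -> dict[str, float]:
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, zero_division=0),
        "recall": recall_score(y_true, y_pred, zero_division=0),
        "auc": roc_auc_score(y_true, decision),
        "f1": f1_score(y_true, y_pred, zero_division=0),
    }


def train_eval_svm(cohort: Cohort, metric: str, filtering: str,
                   folds: np.ndarray, use_pca64: bool = False,
                   C: float = 1.0, seed: int = 0, return_models: bool = False):
    """Per-fold metrics for SVM (or SVM64 with training-fold PCA).

    Standardization and PCA are fitted on the training fold only.  With
    ``return_models`` the fitted per-fold ``(scaler, pca, svm)`` triples are
    returned alongside the metric rows (pca is None without ``use_pca64``).
    """
    x = cohort.edge_matrix(metric, filtering)
    y = cohort.manifest.group_mask("PD").astype(int)
    rows, models = [], {}
    for fold in sorted(set(folds)):
        val = folds == fold
        scaler = StandardScaler().fit(x[~val])
        x_tr, x_va = scaler.transform(x[~val]), scaler.transform(x[val])
        pca = None
        if use_pca64:
            n_comp = min(64, x_tr.shape[0] - 1, x_tr.shape[1])
            pca = PCA(n_components=n_comp, random_state=seed).fit(x_tr)
            x_tr, x_va = pca.transform(x_tr), pca.transform(x_va)
        clf = SVC(kernel="linear", C=C, random_state=seed).fit(x_tr, y[~val])
        row = {"filtering": filtering, "metric": metric,
               "model": "SVM64" if use_pca64 else "SVM", "fold": int(fold)}
        row.update(_fold_metrics(y[val], clf.predict(x_va), clf.decision_function(x_va)))
        rows.append(row)
        models[int(fold)] = (scaler, pca, clf)
    out = pd.DataFrame(rows)
    return (out, models) if return_models else out


def _graph_tensors(cohort: Cohort, metric: str, filtering: str):
    """Node features (connection profiles) and adjacency, (B, N, N) each."""
    w = cohort.stack(metric, filtering)
    return w.copy(), w


def train_eval_gnn(cohort: Cohort, metric: str, filtering: str,
                   folds: np.ndarray, spec: MessagePassingSpec,
                   train_cfg: TrainingConfig = TrainingConfig(),
                   seed: int = 0) -> pd.DataFrame:
    """Per-fold metrics for a GCN or GAT on connection-profile features.

    Node features are the rows of the connectome, standardized edgewise on
    the training fold; the adjacency (neighborhood structure) is the dense
    weight matrix itself.
    """
    x_all, adj_all = _graph_tensors(cohort, metric, filtering)
    y = cohort.manifest.group_mask("PD").astype(int)
    model_name = "GAT" if spec.variant == "node_concat_attention" else "GCN"
    rows = []
    for fold in sorted(set(folds)):
        val = folds == fold
        mu = x_all[~val].mean(axis=0, keepdims=True)
        sd = x_all[~val].std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x_all - mu) / sd
        clf = GNNClassifier(n_node_features=x.shape[-1], spec=spec,
                            train_cfg=train_cfg, seed=seed + int(fold))
        clf.fit(x[~val], adj_all[~val], y[~val])
        decision = clf.decision_function(x[val], adj_all[val])
        row = {"filtering": filtering, "metric": metric,
               "model": model_name, "fold": int(fold)}
        row.update(_fold_metrics(y[val], (decision >= 0).astype(int), decision))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClassifierSuiteConfig:
    """Which models to run and with what settings."""

    models: tuple[str, ...] = MODELS
    k_folds: int = 5
    svm_C: float = 1.0
    gnn_spec: MessagePassingSpec = MessagePassingSpec()
    gnn_train: TrainingConfig = TrainingConfig()


def run_classifier_suite(cohort: Cohort, metrics: tuple[str, ...],
                         filterings: tuple[str, ...] = ("unfiltered", "filtered"),
                         cfg: ClassifierSuiteConfig = ClassifierSuiteConfig(),
                         seed: int = 0) -> pd.DataFrame:
    """Fold-level results for the full model x metric x filtering grid."""
    folds = make_folds(cohort.manifest, cfg.k_folds, seed)
    frames = []
    for filtering in filterings:
        for metric in metrics:
            for model in cfg.models:
                if model == "SVM":
                    frames.append(train_eval_svm(cohort, metric, filtering, folds,
                                                 use_pca64=False, C=cfg.svm_C, seed=seed))
                elif model == "SVM64":
                    frames.append(train_eval_svm(cohort, metric, filtering, folds,
                                                 use_pca64=True, C=cfg.svm_C, seed=seed))
                elif model == "GCN":
                    spec = replace(cfg.gnn_spec, variant="node_concat")
                    frames.append(train_eval_gnn(cohort, metric, filtering, folds,
                                                 spec, cfg.gnn_train, seed=seed))
                elif model == "GAT":
                    spec = replace(cfg.gnn_spec, variant="node_concat_attention")
                    frames.append(train_eval_gnn(cohort, metric, filtering, folds,
                                                 spec, cfg.gnn_train, seed=seed))
                else:
                    raise ValueError(f"unknown model {model!r}")
    return pd.concat(frames, ignore_index=True)


def report_table(fold_rows: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std summary grid over folds.

    One row per (filtering, metric, model) block in the canonical order;
    per performance column, the best mean within each (filtering, metric)
    block is flagged in ``best_<column>``.
    """
    summary = (fold_rows.groupby(["filtering", "metric", "model"])[list(METRIC_COLS)]
               .agg(["mean", "std"]).reset_index())
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    order_f = {"unfiltered": 0, "filtered": 1}
    order_m = {m: i for i, m in enumerate(("SC", "FA", "AD", "RD", "MD"))}
    order_c = {c: i for i, c in enumerate(MODELS)}
    summary = summary.sort_values(
        ["filtering", "metric", "model"],
        key=lambda s: s.map({**order_f, **order_m, **order_c}),
    ).reset_index(drop=True)
    for col in METRIC_COLS:
        best = summary.groupby(["filtering", "metric"])[f"{col}_mean"].transform("max")
        summary[f"best_{col}"] = summary[f"{col}_mean"] >= best - 1e-12
        summary[col] = (summary[f"{col}_mean"].map("{:.2f}".format) + " ± "
                        + summary[f"{col}_std"].fillna(0.0).map("{:.2f}".format))
    return summary
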