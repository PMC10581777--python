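"""Metrics, hierarchical metric composition, paired comparison, sweeps.

Per-class precision = TP/(TP+FP) and recall = TP/(TP+FN) are computed from
the confusion matrix (rows = true class, columns = predicted); accuracy is
its trace over the total. One-vs-rest ROC-AUC evaluates class-score rankings
on imbalanced data. For the hierarchical classifier, a caller's final
precision/recall is the product of the sex layer's score for the caller's
sex and the identity layer's score for the caller within that sex:
``Y_final(ind) = Y(sex(ind)) * Y(ind | sex(ind))``. Flat-versus-hierarchical
comparisons use the two-sided Wilcoxon signed-rank test paired by class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, roc_auc_score

from .core import FeatureMatrix, check_labels


@dataclass
class EvaluationReport:
    """Confusion matrix with per-class precision/recall and summaries."""

    classes: list
    confusion: np.ndarray  # rows = true, columns = predicted
    per_class: pd.DataFrame  # columns: precision, recall, support
    accuracy: float
    roc_auc: dict | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        cm = np.asarray(self.confusion)
        k = len(self.classes)
        if cm.shape != (k, k):
            raise ValueError("confusion matrix shape must match class count")
        supports = self.per_class["support"].to_numpy()
        if not np.array_equal(cm.sum(axis=1), supports):
            raise ValueError("confusion row sums must equal class supports")
        total = cm.sum()
        if total and not np.isclose(np.trace(cm) / total, self.accuracy):
            raise ValueError("accuracy must equal trace/total of the confusion")
        row_sums = cm.sum(axis=1)
        with np.errstate(invalid="ignore"):
            recall_check = np.where(row_sums > 0, np.diag(cm) / row_sums, 0.0)
        if not np.allclose(recall_check,
                           self.per_class["recall"].to_numpy()):
            raise ValueError("per-class recall must equal diagonal/row sum")

    @property
    def summary(self) -> dict:
        return {
            "precision_mean": float(self.per_class["precision"].mean()),
            "precision_sd": float(self.per_class["precision"].std(ddof=1))
            if len(self.per_class) > 1 else 0.0,
            "recall_mean": float(self.per_class["recall"].mean()),
            "recall_sd": float(self.per_class["recall"].std(ddof=1))
            if len(self.per_class) > 1 else 0.0,
            "accuracy": self.accuracy,
        }

    def to_dict(self) -> dict:
        out = {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class": {
                str(c): {k: float(v) for k, v in row.items()}
                for c, row in self.per_class.iterrows()
            },
            "accuracy": self.accuracy,
            "summary": self.summary,
            "flags": list(self.flags),
        }
        if self.roc_auc is not None:
            out["roc_auc"] = {str(k): (None if v is None or not np.isfinite(v)
                                       else float(v))
                              for k, v in self.roc_auc.items()}
        return out


def per_class_metrics(true_labels, pred_labels) -> EvaluationReport:
    """Confusion matrix, per-class precision/recall and accuracy.

    A class never predicted gets precision 0 and is flagged. Disjoint true
    and predicted label sets raise (almost certainly a column mix-up).
    """
    y_true = check_labels(true_labels, "true_labels")
    y_pred = check_labels(pred_labels, "pred_labels")
    if y_true.size != y_pred.size:
        raise ValueError("true and predicted labels must have equal length")
    true_set, pred_set = set(y_true.tolist()), set(y_pred.tolist())
    if not (true_set & pred_set):
        raise ValueError(
            "true and predicted label sets are disjoint — are the columns "
            "swapped or from different experiments?")
    classes = sorted(true_set | pred_set, key=str)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    diag = np.diag(cm).astype(float)
    col_sums = cm.sum(axis=0)
    row_sums = cm.sum(axis=1)
    flags = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col_sums > 0, diag / col_sums, 0.0)
        recall = np.where(row_sums > 0, diag / row_sums, 0.0)
    for cls, cs in zip(classes, col_sums):
        if cs == 0:
            flags.append(f"class {cls!r} never predicted; precision set to 0")
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "support": row_sums},
        index=pd.Index(classes, name="class"))
    return EvaluationReport(
        classes=classes, confusion=cm, per_class=per_class,
        accuracy=float(np.trace(cm) / cm.sum()), flags=flags)


def roc_auc_ovr(scores, true_labels, classes=None) -> dict:
    """Per-class one-vs-rest ROC-AUC from class scores.

    ``scores`` is calls x classes (column order = sorted classes unless
    given). A class with no positive calls gets ``None`` and a warning and
    is excluded from any mean the caller takes. Ties in the score ranking
    are handled by midranks.
    """
    y_true = check_labels(true_labels, "true_labels")
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise ValueError("scores must be a calls x classes matrix")
    if classes is None:
        classes = sorted(set(y_true.tolist()), key=str)
    if len(classes) != scores.shape[1]:
        raise ValueError(
            f"{scores.shape[1]} score columns for {len(classes)} classes")
    out: dict = {}
    for j, cls in enumerate(classes):
        pos = y_true == cls
        if pos.sum() == 0 or pos.all():
            warnings.warn(f"class {cls!r} has no positives (or no negatives); "
                          "AUC undefined", stacklevel=2)
            out[cls] = None
            continue
        out[cls] = float(roc_auc_score(pos.astype(int), scores[:, j]))
    return out


def combine_hierarchical_metrics(
    sex_report: EvaluationReport, id_reports: dict[str, EvaluationReport]
) -> pd.DataFrame:
    """Compose per-individual precision/recall through the hierarchy.

    For each individual, final precision (recall) is the sex layer's
    precision (recall) for that individual's sex times the identity layer's
    precision (recall) for the individual within that sex. Returns a frame
    indexed by individual with columns precision/recall/sex.
    """
    rows = {}
    for s, rep in id_reports.items():
        if s not in sex_report.per_class.index:
            raise ValueError(f"sex class {s!r} missing from the sex report")
        sex_p = sex_report.per_class.loc[s, "precision"]
        sex_r = sex_report.per_class.loc[s, "recall"]
        for ind in rep.per_class.index:
            if ind in rows:
                raise ValueError(f"individual {ind!r} appears in two id reports")
            rows[ind] = {
                "precision": sex_p * rep.per_class.loc[ind, "precision"],
                "recall": sex_r * rep.per_class.loc[ind, "recall"],
                "sex": s,
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "individual_id"
    return df.sort_index()


def paired_compare(scores_a, scores_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on per-class score pairs.

    Zero differences are dropped (standard convention); the exact
    distribution is used for n <= 25 pairs, otherwise the normal
    approximation with continuity correction. All-zero differences yield
    p = 1 with a flag.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired score vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired classes")
    d = b - a
    nz = d[d != 0]
    if nz.size == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_effective": 0,
                "flag": "all paired differences are zero"}
    method = "exact" if nz.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             method="approx")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n_effective": int(nz.size),
            "median_difference": float(np.median(nz)), "flag": None}


def chance_level_pct(n_classes: int) -> float:
    """Chance classification probability for a balanced K-class task, in %."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 100.0 / n_classes


# ---------------------------------------------------------------------------
# experiment-level helpers: flat and hierarchical evaluation, sample sweeps


def evaluate_flat(ds, config: dict | None = None,
                  random_state: int | None = None,
                  compute_roc_auc: bool = False):
    """Train a flat multi-class model and evaluate pooled out-of-fold
    predictions. Returns (report, fitted model)."""
    from .model import BoostedTreesCV

    config = dict(config or {})
    config.setdefault("n_trees", 2500)
    model = BoostedTreesCV(random_state=random_state, **config).fit(ds.X, ds.y)
    report = per_class_metrics(ds.y, model.oof_pred_)
    if compute_roc_auc:
        report.roc_auc = roc_auc_ovr(model.oof_proba_, ds.y,
                                     classes=list(model.classes_))
    return report, model


def evaluate_hierarchical(ds, config_sex: dict | None = None,
                          config_id: dict | None = None,
                          random_state: int | None = None):
    """Train the hierarchy and evaluate it both ways.

    Returns a dict with the per-component reports (out-of-fold), the
    composed per-individual metrics ("paper mode") and the end-to-end
    routed report ("deployment mode"), plus the fitted model.
    """
    from .model import HierarchicalBoostedClassifier

    config_sex = dict(config_sex or {})
    config_id = dict(config_id or {})
    clf = HierarchicalBoostedClassifier(
        n_trees_sex=config_sex.get("n_trees", 500),
        n_trees_id=config_id.get("n_trees", 2500),
        learning_rate=config_sex.get("learning_rate", 0.1),
        max_depth=config_sex.get("max_depth", 3),
        n_folds=config_sex.get("n_folds", 10),
        random_state=random_state)
    sex = ds.matrix.labels["sex"].to_numpy()
    clf.fit(ds.X, ds.y, sex=sex)

    sex_report = per_class_metrics(sex, clf.sex_model_.oof_pred_)
    id_reports = {}
    for s, model in clf.id_models_.items():
        rows = clf.id_row_index_[s]
        id_reports[s] = per_class_metrics(ds.y[rows], model.oof_pred_)
    composed = combine_hierarchical_metrics(sex_report, id_reports)

    routed_sex, routed_id = clf.predict(ds.X, routing="predicted_sex")
    routed_report = per_class_metrics(ds.y, routed_id)
    return {
        "sex_report": sex_report,
        "id_reports": id_reports,
        "composed": composed,
        "routed_report": routed_report,
        "model": clf,
    }


def sample_size_sweep(features_by_call_type: dict[str, FeatureMatrix],
                      caps=(50, 99, 197, None), config: dict | None = None,
                      recipe=None, random_state: int = 0) -> pd.DataFrame:
    """Flat vs hierarchical summary metrics across per-class sample sizes.

    For each call type and cap: balance (min-call filter, cap undersample,
    SMOTE), train both approaches with identical seeds within a cap, and
    summarize mean +/- sd precision and recall. Returns a tidy frame with
    one row per (call_type, cap, approach).
    """
    from .balance import BalanceRecipe, build_balanced_dataset

    config = dict(config or {})
    rows = []
    for call_type, m in features_by_call_type.items():
        for cap in caps:
            base = recipe or BalanceRecipe()
            r = BalanceRecipe(
                min_calls=base.min_calls, cap=cap, smote_k=base.smote_k,
                seed=random_state, scale_for_knn=base.scale_for_knn)
            ds = build_balanced_dataset(m, target="individual", recipe=r)
            n_classes = len(np.unique(ds.y))
            shared = {k: v for k, v in config.items()
                      if k in ("learning_rate", "max_depth", "n_folds")}
            n_trees_id = config.get("n_trees_id", config.get("n_trees", 2500))
            n_trees_sex = config.get("n_trees_sex", 500)
            flat_report, _ = evaluate_flat(
                ds, config={**shared, "n_trees": n_trees_id},
                random_state=random_state)
            hier = evaluate_hierarchical(
                ds,
                config_sex={**shared, "n_trees": n_trees_sex},
                config_id={**shared, "n_trees": n_trees_id},
                random_state=random_state)
            sample_size = int(pd.Series(ds.y).value_counts().iloc[0])
            for approach, (p, rcl) in {
                "flat": (flat_report.per_class["precision"],
                         flat_report.per_class["recall"]),
                "hierarchical": (hier["composed"]["precision"],
                                 hier["composed"]["recall"]),
            }.items():
                rows.append({
                    "call_type": call_type,
                    "cap": -1 if cap is None else cap,
                    "sample_size_per_class": sample_size,
                    "approach": approach,
                    "precision_mean": float(p.mean()),
                    "precision_sd": float(p.std(ddof=1)),
                    "recall_mean": float(rcl.mean()),
                    "recall_sd": float(rcl.std(ddof=1)),
                    "chance_pct": chance_level_pct(n_classes),
                })
    df = pd.DataFrame(rows).sort_values(
        ["call_type", "sample_size_per_class", "approach"]).reset_index(drop=True)
    return df
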