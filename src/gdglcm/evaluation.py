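"""Cross-validated evaluation: metrics, per-class ROC/AUC, experiment grid.

Sensitivity = TP/(TP+FN) x 100, selectivity = TP/(TP+FP) x 100 and
accuracy = (TP+TN)/total x 100 are computed per class from argmax
decisions; one ROC curve and AUC (trapezoidal) is produced per class.
``run_experiment`` sweeps {standard, gm-glcm, gd-glcm} x (levels, group)
x architecture with 5-fold cross-validation and returns tidy results.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers, glcm, haralick
from .classifiers import TrainConfig, mlp_fit, predict, slp_fit

log = logging.getLogger(__name__)

CLASSES = ("healthy", "dying")
METHODS = ("standard", "gm-glcm", "gd-glcm")
ARCHS = ("slp", "mlp1", "mlp2")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def kfold_split(n_samples: int, k: int = 5, seed: int = 0,
                cell_ids: np.ndarray | None = None,
                group_by_cell: bool = False) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded partition into k near-equal folds.

    Returns a list of (train_idx, val_idx) pairs; each sample lands in the
    validation part exactly once.  With ``group_by_cell`` every sample of a
    cell stays in the same fold (no per-cell leakage across the split).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n_samples < k:
        raise ValueError(f"need at least k={k} samples, got {n_samples}")
    rng = np.random.default_rng(seed)
    if group_by_cell:
        if cell_ids is None:
            raise ValueError("group_by_cell requires cell_ids")
        uniq = np.unique(cell_ids)
        if len(uniq) < k:
            raise ValueError(f"need at least k={k} distinct cells, got {len(uniq)}")
        cell_folds = np.array_split(rng.permutation(uniq), k)
        folds = [np.flatnonzero(np.isin(cell_ids, part)) for part in cell_folds]
    else:
        folds = np.array_split(rng.permutation(n_samples), k)
    out = []
    for i in range(k):
        val = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, val))
    return out


def score_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, selectivity, accuracy) in percent.

    Sensitivity (or selectivity) is NaN when its denominator is zero — a
    recordable "could not be calculated" outcome, not an error.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    sens = counts.TP / (counts.TP + counts.FN) * 100 if counts.TP + counts.FN else math.nan
    sel = counts.TP / (counts.TP + counts.FP) * 100 if counts.TP + counts.FP else math.nan
    acc = (counts.TP + counts.TN) / counts.total * 100
    return sens, sel, acc


def confusion_for_class(pred_labels: np.ndarray, true_labels: np.ndarray,
                        positive: str) -> ConfusionCounts:
    pred_pos = np.asarray(pred_labels) == positive
    true_pos = np.asarray(true_labels) == positive
    return ConfusionCounts(
        TP=int(np.sum(pred_pos & true_pos)),
        TN=int(np.sum(~pred_pos & ~true_pos)),
        FP=int(np.sum(pred_pos & ~true_pos)),
        FN=int(np.sum(~pred_pos & true_pos)),
    )


def roc_curve(scores: np.ndarray, positive: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) over score thresholds, ties grouped.

    ``positive`` is a boolean array marking the positive class.  Both
    classes must be present.
    """
    scores = np.asarray(scores, dtype=np.float64)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = positive[order]
    tp = np.cumsum(p)
    fp = np.cumsum(~p)
    # keep only the last index of each tied-score run (threshold grouping)
    last_of_tie = np.append(np.diff(s) != 0, True)
    tpr = np.concatenate([[0.0], tp[last_of_tie] / n_pos])
    fpr = np.concatenate([[0.0], fp[last_of_tie] / n_neg])
    return fpr, tpr


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> dict[str, dict[str, object]]:
    """One ROC curve and trapezoidal AUC per class.

    ``scores`` has one column per class (order :data:`CLASSES`); the class
    score column ranks that class's positives.
    """
    labels = np.asarray(labels)
    out: dict[str, dict[str, object]] = {}
    for ci, cls in enumerate(CLASSES):
        fpr, tpr = roc_curve(scores[:, ci], labels == cls)
        auc = float(np.trapezoid(tpr, fpr))
        out[cls] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    return out


@dataclass
class EvalReport:
    """Per-fold and aggregate results of one configuration."""

    method: str
    map_kind: str
    n_levels: int
    group: int
    arch: str
    seed: int
    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)       # class -> mean AUC over folds
    roc: dict = field(default_factory=dict)       # class -> averaged ROC points

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["roc"] = {c: {k: list(v) for k, v in pts.items()}
                          for c, pts in self.roc.items()}
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def _featurize(cells, method: str, n_levels: int, group: int, **conventions):
    if method == "standard":
        return haralick.build_standard_dataset(cells, n_levels, group, **conventions)
    map_kind = {"gm-glcm": "GM", "gd-glcm": "GD", "intensity-glcm": "intensity"}[method]
    return glcm.build_dataset(cells, map_kind, n_levels, group, **conventions)


def _targets(labels: np.ndarray) -> np.ndarray:
    return np.column_stack([(labels == c).astype(float) for c in CLASSES])


def _fit_predict(arch: str, Xtr, Ytr, Xval, config: TrainConfig):
    if arch == "slp":
        model = slp_fit(Xtr, Ytr, learning_rate=0.1, epochs=20, seed=config.seed)
    else:
        n_hidden = 1 if arch == "mlp1" else 2
        model = mlp_fit(Xtr, Ytr, config, n_hidden_layers=n_hidden)
    return model, predict(model, Xval)


def evaluate_config(X: np.ndarray, labels: np.ndarray, cell_ids: np.ndarray,
                    arch: str, k: int = 5, seed: int = 0,
                    train_config: TrainConfig | None = None,
                    group_by_cell: bool = False,
                    zscore: bool = False,
                    meta: dict | None = None) -> EvalReport:
    """k-fold cross-validation of one (features, architecture) pairing.

    The early-stopping 80:20 split is carved from each training fold
    internally by the trainer; the held-out fold is never seen in
    training.  ``zscore`` standardises features with training-fold
    statistics only (used for the heterogeneous Haralick features).
    """
    meta = meta or {}
    report = EvalReport(method=meta.get("method", "?"),
                        map_kind=meta.get("map_kind", "?"),
                        n_levels=meta.get("n_levels", 0),
                        group=meta.get("group", 0), arch=arch, seed=seed)
    labels = np.asarray(labels)
    fpr_grid = np.linspace(0.0, 1.0, 101)
    tpr_acc = {c: [] for c in CLASSES}
    auc_acc = {c: [] for c in CLASSES}

    for fold_i, (tr, val) in enumerate(
            kfold_split(len(X), k=k, seed=seed, cell_ids=cell_ids,
                        group_by_cell=group_by_cell)):
        Xtr, Xval = X[tr], X[val]
        if zscore:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xval = (Xval - mu) / sd
        cfg = train_config or TrainConfig(seed=seed)
        cfg = TrainConfig(**{**asdict(cfg), "seed": seed + fold_i})
        try:
            model, scores = _fit_predict(arch, Xtr, _targets(labels[tr]), Xval, cfg)
        except FloatingPointError as exc:  # "classification failure" outcome
            log.warning("fold %d failed: %s", fold_i, exc)
            report.folds.append({"fold": fold_i, "failed": True, "error": str(exc)})
            continue
        pred = np.array([CLASSES[i] for i in np.argmax(scores, axis=1)])
        fold_rec: dict = {"fold": fold_i, "failed": False}
        for cls in CLASSES:
            sens, sel, acc = score_metrics(confusion_for_class(pred, labels[val], cls))
            fold_rec[f"sensitivity_{cls}"] = sens
            fold_rec[f"selectivity_{cls}"] = sel
            fold_rec["accuracy"] = acc  # argmax accuracy is class-symmetric
        rocs = roc_auc(scores, labels[val])
        for cls in CLASSES:
            fold_rec[f"auc_{cls}"] = rocs[cls]["auc"]
            auc_acc[cls].append(rocs[cls]["auc"])
            tpr_acc[cls].append(np.interp(fpr_grid, rocs[cls]["fpr"], rocs[cls]["tpr"]))
        report.folds.append(fold_rec)

    ok = [f for f in report.folds if not f.get("failed")]
    if ok:
        keys = [k_ for k_ in ok[0] if k_ not in ("fold", "failed")]
        for key in keys:
            vals = np.array([f[key] for f in ok], dtype=float)
            if np.isnan(vals).all():  # e.g. sensitivity never computable
                report.mean[key] = float("nan")
                report.sd[key] = float("nan")
            else:
                report.mean[key] = float(np.nanmean(vals))
                report.sd[key] = float(np.nanstd(vals))
        for cls in CLASSES:
            report.auc[cls] = float(np.mean(auc_acc[cls]))
            report.roc[cls] = {"fpr": fpr_grid,
                               "tpr": np.mean(tpr_acc[cls], axis=0)}
    return report


def run_experiment(cells, methods=METHODS, levels=(8, 16, 32, 64),
                   groups=(1, 2, 3), archs=ARCHS, k: int = 5, seed: int = 0,
                   group_by_cell: bool = False,
                   train_config: TrainConfig | None = None,
                   out_dir: str | Path | None = None,
                   **conventions) -> tuple[list[EvalReport], pd.DataFrame]:
    """Sweep methods x (levels, groups) x architectures with k-fold CV.

    Per-configuration failures are logged and recorded, not raised.
    Returns all reports plus a tidy summary DataFrame (one row per config);
    with ``out_dir`` the summary CSV and per-config JSON reports are
    written there.
    """
    cells = list(cells)
    reports: list[EvalReport] = []
    rows = []
    for method in methods:
        for n_levels in levels:
            for group in groups:
                try:
                    X, labels, cell_ids = _featurize(cells, method, n_levels, group)
                except Exception as exc:
                    log.warning("featurize failed for %s N=%d group=%d: %s",
                                method, n_levels, group, exc)
                    continue
                for arch in archs:
                    meta = {"method": method, "n_levels": n_levels, "group": group,
                            "map_kind": "intensity" if method == "standard"
                            else method.split("-")[0].upper()}
                    rep = evaluate_config(
                        X, labels, cell_ids, arch, k=k, seed=seed,
                        train_config=train_config, group_by_cell=group_by_cell,
                        zscore=(method == "standard"), meta=meta)
                    reports.append(rep)
                    row = {"method": method, "n_levels": n_levels,
                           "group": group, "arch": arch}
                    row.update({f"mean_{k_}": v for k_, v in rep.mean.items()})
                    row.update({f"sd_{k_}": v for k_, v in rep.sd.items()})
                    rows.append(row)
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False)
        for rep in reports:
            name = f"{rep.method}_N{rep.n_levels}_g{rep.group}_{rep.arch}.json"
            rep.to_json(out_dir / name)
    return reports, summary
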