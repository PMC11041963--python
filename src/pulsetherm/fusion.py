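"""Multimodal fusion: classifiers, Shapley attribution, quality sweep,
and cross-modal statistics.

Feature vectors from the cardiac (r-PPG) and thermal paths are joined
per subject and classified as baseline vs stimulus state with SVM or
random-forest models under stratified, subject-grouped cross-validation
with an inner grid search.  Early fusion concatenates the modalities'
features before one classifier; late fusion feeds per-modality class
probabilities to a shallow Gini decision tree.  Reporting operations
cover Monte-Carlo Shapley feature attribution, the MAE/HR quality-index
threshold sweep against a reference device, change-score t-tests and
the HRV-change x thermal-change correlation map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODALITIES = ("rppg", "thermal", "early_fusion", "late_fusion")

SVM_GRID = {"clf__C": [0.1, 1.0, 10.0, 100.0], "clf__gamma": ["scale", 0.01, 0.1, 1.0]}
# 100 trees are ample for the ~100-record studies this package targets;
# the grid searches the regularizing parameters (depth, leaf size) instead.
RF_GRID = {
    "clf__n_estimators": [100],
    "clf__max_depth": [None, 3, 5],
    "clf__min_samples_leaf": [1, 3],
}


@dataclass
class FusionDataset:
    """Per-record labeled feature table with modality tags.

    ``X`` holds one row per record (typically two records per subject:
    baseline state and stimulus state), ``y`` the binary label
    (0 = baseline, 1 = stimulus), ``subjects`` the subject id of each
    row — used to keep a subject's records in the same CV fold.
    """

    X: pd.DataFrame
    y: np.ndarray
    subjects: np.ndarray
    modality: Mapping[str, str]
    quality: pd.Series | None = None
    incomplete_subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.subjects = np.asarray(self.subjects)
        if len(self.X) != len(self.y) or len(self.X) != len(self.subjects):
            raise ValueError("X, y and subjects must align")
        if len(self.X) == 0:
            raise ValueError("empty dataset")
        if self.X.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        untagged = set(self.X.columns) - set(self.modality)
        if untagged:
            raise ValueError(f"features without a modality tag: {sorted(untagged)}")

    def feature_names(self, modality: str | None = None) -> list[str]:
        if modality is None or modality == "early_fusion":
            return list(self.X.columns)
        return [c for c in self.X.columns if self.modality[c] == modality]

    def features(self, modality: str | None = None) -> pd.DataFrame:
        return self.X[self.feature_names(modality)]


@dataclass
class EvalResult:
    """Cross-validated performance of one model/modality combination."""

    model: str
    modality: str
    avg_accuracy: float
    avg_f1: float
    fold_accuracies: list[float]
    fold_f1: list[float]
    fold_assignments: np.ndarray  # fold index per record
    chosen_params: list[dict]
    seed: int


@dataclass
class ImportanceReport:
    """Mean absolute Shapley attribution per feature, ranked descending."""

    table: pd.DataFrame  # columns: feature, mean_abs_shap, rank, modality

    @property
    def top_feature(self) -> str:
        return str(self.table.iloc[0]["feature"])


def assemble_features(
    rppg_features: pd.DataFrame,
    thermal_features: pd.DataFrame,
    labels: pd.Series,
    quality: pd.Series | None = None,
) -> FusionDataset:
    """Inner-join per-subject features from both modalities with labels.

    Indices are subject/record ids; subjects present in only one
    modality are excluded from the fused table (complete-case fusion).
    Standardization is deliberately deferred to training, where it is
    fit on training folds only.
    """
    for df, name in ((rppg_features, "rppg"), (thermal_features, "thermal")):
        if df.index.duplicated().any():
            raise ValueError(f"duplicate subject ids in {name} features")
    if len(labels) == 0:
        raise ValueError("empty label set")
    joined = rppg_features.join(thermal_features, how="inner", lsuffix="", rsuffix="_thermal")
    joined = joined.join(labels.rename("_label"), how="inner")
    dropped = sorted(
        set(rppg_features.index) ^ set(thermal_features.index)
    )
    if len(joined) == 0:
        raise ValueError("no subjects complete in both modalities")
    modality = {c: "rppg" for c in rppg_features.columns}
    modality |= {c: "thermal" for c in joined.columns if c not in modality and c != "_label"}
    y = joined.pop("_label").to_numpy()
    return FusionDataset(
        X=joined, y=y, subjects=joined.index.to_numpy(), modality=modality,
        quality=quality.loc[joined.index] if quality is not None else None,
        incomplete_subjects=dropped,  # flagged; still usable in unimodal analyses
    )


def _make_search(model: str, seed: int, inner_cv) -> GridSearchCV:
    if model == "svm":
        est = SVC(kernel="rbf", random_state=seed)
        grid = SVM_GRID
    elif model == "rf":
        est = RandomForestClassifier(random_state=seed)
        grid = RF_GRID
    else:
        raise ValueError(f"unknown model {model!r}; use 'svm' or 'rf'")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return GridSearchCV(pipe, grid, cv=inner_cv, scoring="accuracy", n_jobs=None)


def _probability_estimator(best_pipeline: Pipeline, model: str) -> Pipeline:
    """Version of a tuned pipeline that exposes class probabilities.

    The SVM's margin scores are mapped to probabilities by Platt-style
    calibration (cross-fitted); the random forest already provides
    probabilities.
    """
    if model != "svm":
        return clone(best_pipeline)
    svc = clone(best_pipeline.named_steps["clf"])
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", CalibratedClassifierCV(svc, ensemble=False, cv=3)),
    ])


def _outer_folds(ds: FusionDataset, cv_folds: int, seed: int):
    cv = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(ds.X, ds.y, groups=ds.subjects))
    for _, (tr, te) in enumerate(folds):
        if len(np.unique(ds.y[tr])) < 2 or len(np.unique(ds.y[te])) < 2:
            raise ValueError(
                "a CV fold contains a single class; use fewer folds or more subjects"
            )
    return folds


def train_eval(
    dataset: FusionDataset,
    modality: str = "early_fusion",
    model: str = "svm",
    cv_folds: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Stratified subject-grouped k-fold evaluation with inner grid search.

    Hyperparameters are grid-searched within each training fold (3-fold
    inner CV, also subject-grouped); accuracy and the stimulus-class F1
    are averaged over outer folds.  Fully deterministic given the seed.
    """
    classes, counts = np.unique(dataset.y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 records per class")
    X = dataset.features(modality).to_numpy(float)
    y = dataset.y
    folds = _outer_folds(dataset, cv_folds, seed)
    inner = StratifiedGroupKFold(n_splits=3, shuffle=True, random_state=seed)

    accs, f1s, params = [], [], []
    assign = np.full(len(y), -1)
    for k, (tr, te) in enumerate(folds):
        assign[te] = k
        search = _make_search(model, seed, inner)
        search.fit(X[tr], y[tr], groups=dataset.subjects[tr])
        pred = search.predict(X[te])
        accs.append(accuracy_score(y[te], pred))
        f1s.append(f1_score(y[te], pred, pos_label=1, zero_division=0))
        params.append({k_: v for k_, v in search.best_params_.items()})
    return EvalResult(
        model=model, modality=modality,
        avg_accuracy=float(np.mean(accs)), avg_f1=float(np.mean(f1s)),
        fold_accuracies=[float(a) for a in accs], fold_f1=[float(f) for f in f1s],
        fold_assignments=assign, chosen_params=params, seed=seed,
    )


def early_fusion_eval(
    dataset: FusionDataset, model: str = "rf", cv_folds: int = 5, seed: int = 0
) -> EvalResult:
    """Early fusion: concatenate both modalities' features, then classify."""
    for m in ("rppg", "thermal"):
        if not dataset.feature_names(m):
            raise ValueError(f"early fusion needs features from modality {m!r}")
    return train_eval(dataset, modality="early_fusion", model=model,
                      cv_folds=cv_folds, seed=seed)


def late_fusion_eval(
    dataset: FusionDataset,
    base_models: Mapping[str, str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    tree_max_depth: int = 2,
) -> EvalResult:
    """Late fusion: a Gini decision tree over per-modality predictions.

    Per outer fold, one base model per modality is grid-search-fitted on
    the training records; the fusion tree is trained on *out-of-fold*
    class probabilities of the training records (inner cross-fitting, so
    the tree never sees resubstitution scores) and evaluated on the test
    records' probabilities.
    """
    base_models = dict(base_models or {"rppg": "svm", "thermal": "rf"})
    for m in base_models:
        if not dataset.feature_names(m):
            raise ValueError(f"no features for modality {m!r}")
    y = dataset.y
    folds = _outer_folds(dataset, cv_folds, seed)
    inner = StratifiedGroupKFold(n_splits=3, shuffle=True, random_state=seed)

    accs, f1s, params = [], [], []
    assign = np.full(len(y), -1)
    for k, (tr, te) in enumerate(folds):
        assign[te] = k
        meta_tr = np.empty((len(tr), len(base_models)))
        meta_te = np.empty((len(te), len(base_models)))
        fold_params = {}
        for j, (mod, model) in enumerate(base_models.items()):
            Xm = dataset.features(mod).to_numpy(float)
            search = _make_search(model, seed, inner)
            search.fit(Xm[tr], y[tr], groups=dataset.subjects[tr])
            fold_params[mod] = dict(search.best_params_)
            proba_est = _probability_estimator(search.best_estimator_, model)
            oof = cross_val_predict(
                clone(proba_est), Xm[tr], y[tr], cv=inner,
                groups=dataset.subjects[tr], method="predict_proba",
            )
            meta_tr[:, j] = oof[:, 1]
            fitted = clone(proba_est).fit(Xm[tr], y[tr])
            meta_te[:, j] = fitted.predict_proba(Xm[te])[:, 1]
        tree = DecisionTreeClassifier(
            criterion="gini", max_depth=tree_max_depth, random_state=seed
        )
        tree.fit(meta_tr, y[tr])
        pred = tree.predict(meta_te)
        accs.append(accuracy_score(y[te], pred))
        f1s.append(f1_score(y[te], pred, pos_label=1, zero_division=0))
        params.append(fold_params)
    return EvalResult(
        model="late_fusion_tree", modality="late_fusion",
        avg_accuracy=float(np.mean(accs)), avg_f1=float(np.mean(f1s)),
        fold_accuracies=[float(a) for a in accs], fold_f1=[float(f) for f in f1s],
        fold_assignments=assign, chosen_params=params, seed=seed,
    )


def fit_model(
    dataset: FusionDataset, modality: str = "early_fusion", model: str = "rf",
    seed: int = 0,
) -> Pipeline:
    """Fit one grid-searched model on the full dataset (for attribution)."""
    inner = StratifiedGroupKFold(n_splits=3, shuffle=True, random_state=seed)
    search = _make_search(model, seed, inner)
    X = dataset.features(modality).to_numpy(float)
    search.fit(X, dataset.y, groups=dataset.subjects)
    return search.best_estimator_


def shapley_importance(
    model,
    X: pd.DataFrame,
    modality_tags: Mapping[str, str] | None = None,
    n_permutations: int = 24,
    n_background: int = 64,
    seed: int = 0,
    predict: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ImportanceReport:
    """Monte-Carlo Shapley feature attribution, ranked by mean |value|.

    Estimates per-instance Shapley values of the model's positive-class
    probability by sampling feature permutations: features are switched
    one at a time from a background record to the explained record, and
    each feature is credited the resulting change in model output,
    averaged over permutations and background draws.  The estimator is
    unbiased for the exact Shapley value and gives exactly zero to any
    feature the model's output never depends on.
    """
    feats = list(X.columns)
    Xv = X.to_numpy(float)
    n, d = Xv.shape
    rng = np.random.default_rng(seed)
    if predict is None:
        if hasattr(model, "predict_proba"):
            predict = lambda A: model.predict_proba(A)[:, 1]  # noqa: E731
        else:
            predict = model.decision_function
    bg = Xv[rng.choice(n, size=min(n_background, n), replace=False)]

    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        order = rng.permutation(d)
        z = bg[rng.integers(0, len(bg), size=n)]
        cur = z.copy()
        prev_out = predict(cur)
        for j in order:
            cur[:, j] = Xv[:, j]
            out = predict(cur)
            phi[:, j] += out - prev_out
            prev_out = out
    phi /= n_permutations

    mean_abs = np.abs(phi).mean(axis=0)
    table = pd.DataFrame({
        "feature": feats,
        "mean_abs_shap": mean_abs,
        "modality": [modality_tags.get(f, "") if modality_tags else "" for f in feats],
    })
    table = table.sort_values("mean_abs_shap", ascending=False, kind="stable")
    table["rank"] = np.arange(1, d + 1)
    return ImportanceReport(table=table.reset_index(drop=True))


def quality_sweep(
    paired: pd.DataFrame,
    thresholds: Sequence[float],
    measures: Sequence[str] = ("hr_mean_bpm", "rmssd_ms", "pnn50_pct", "sdnn_ms", "ln_hf", "ln_lf"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Agreement with the reference device as the quality threshold tightens.

    ``paired`` holds one row per recording with a ``quality`` column
    (the MAE/HR index) and ``rppg_<m>`` / ``ref_<m>`` columns per
    measure.  For each threshold, recordings with index <= threshold are
    retained and the Pearson r and p of each measure pair reported; a
    threshold retaining fewer than ``min_n`` recordings is marked
    insufficient (NaN statistics).
    """
    if "quality" not in paired.columns:
        raise ValueError("paired table needs a 'quality' column")
    rows = []
    for thr in thresholds:
        sub = paired[paired["quality"] <= thr]
        row: dict[str, float] = {"threshold": float(thr), "n": int(len(sub)),
                                 "insufficient": len(sub) < min_n}
        for m in measures:
            a = sub[f"rppg_{m}"].to_numpy(float)
            b = sub[f"ref_{m}"].to_numpy(float)
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_n or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                row[f"r_{m}"] = np.nan
                row[f"p_{m}"] = np.nan
            else:
                r, p = stats.pearsonr(a[ok], b[ok])
                row[f"r_{m}"] = float(r)
                row[f"p_{m}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_map(
    hrv_deltas: pd.DataFrame,
    thermal_changes: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every HRV change with every ROI change.

    Both tables are indexed by subject; only complete subjects enter.
    Returns (r, p, significant) DataFrames with HRV measures as rows and
    ROIs as columns; constant columns give missing r.  ``fdr=True``
    switches the significance mask to Benjamini-Hochberg at ``alpha``
    (off by default: the map reports raw p values).
    """
    common = hrv_deltas.index.intersection(thermal_changes.index)
    if len(common) < 3:
        raise ValueError("correlation map needs at least 3 complete subjects")
    A = hrv_deltas.loc[common]
    B = thermal_changes.loc[common]
    r = pd.DataFrame(np.nan, index=A.columns, columns=B.columns)
    p = pd.DataFrame(np.nan, index=A.columns, columns=B.columns)
    for m in A.columns:
        x = A[m].to_numpy(float)
        for roi in B.columns:
            yv = B[roi].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(yv)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(yv[ok]) == 0:
                continue
            rr, pp = stats.pearsonr(x[ok], yv[ok])
            r.loc[m, roi] = rr
            p.loc[m, roi] = pp
    if fdr:
        flat = p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        adj[ok] = stats.false_discovery_control(flat[ok])
        sig = pd.DataFrame(
            (adj < alpha).reshape(p.shape), index=p.index, columns=p.columns
        )
    else:
        sig = p < alpha
    return r, p, sig


def change_tests(deltas: pd.DataFrame) -> pd.DataFrame:
    """One-sample two-sided t-tests of per-subject change scores against 0.

    One row per column of ``deltas`` (an HRV measure or ROI change) with
    the mean change, t statistic and p value; zero-variance columns are
    reported with missing statistics.
    """
    if len(deltas) < 3:
        raise ValueError("change tests need at least 3 subjects")
    rows = []
    for col in deltas.columns:
        x = deltas[col].to_numpy(float)
        x = x[np.isfinite(x)]
        if len(x) < 3 or np.std(x) == 0:
            rows.append({"measure": col, "mean_delta": np.mean(x) if len(x) else np.nan,
                         "t": np.nan, "p": np.nan, "n": len(x)})
            continue
        t, p = stats.ttest_1samp(x, 0.0)
        rows.append({"measure": col, "mean_delta": float(np.mean(x)),
                     "t": float(t), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)
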