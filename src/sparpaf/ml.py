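"""Imbalance-aware ensemble classification with repeated random subsampling.

The classification protocol for the PAF-history problem:

* **ASUWO oversampling** — the minority (PAF) training sub-strips are grown
  to parity with the majority class by cluster-based adaptive
  semi-unsupervised weighted oversampling: the minority class is clustered
  (average-linkage agglomerative), clusters into which the majority class
  intrudes are trimmed, the remainder are weighted by boundary difficulty
  (inverse nearest-majority distance), and synthetic rows are drawn as
  convex combinations of same-cluster minority pairs.  Synthetic rows are
  used for training only; only real rows are ever scored.

* **Voting ensemble** — three classifiers with deliberately different
  inductive biases: k-nearest neighbours (k = 9, standardized Euclidean
  distance), a linear-kernel SVM on standardized features, and an
  RBF-kernel SVM on raw features (standardization can amplify feature noise
  under a nonlinear kernel).  Each member yields a posterior in [0, 1]; the
  sub-strip label is the majority of the three member labels at a 0.5
  threshold and the combined posterior (used for ROC curves) is the member
  mean.  A subject is classified by majority vote of its 9 sub-strips, the
  subject score being the fraction of sub-strips voted PAF.

* **SRRS cross-validation** — stratified repeated random sampling: subjects
  are repeatedly split into training/test sets with fixed per-class counts,
  enforcing unique training-set combinations across runs; metrics are
  aggregated as the mean with a 95% coverage interval (2.5th-97.5th
  percentile range across runs).

* **Feature selection** — sensitivity-weighted sequential forward
  selection: features are added greedily to maximize
  ``J = w * sensitivity + (1 - w) * specificity`` at the subject level
  (SRRS-averaged), stopping when J no longer improves by ``eps``.

PAF is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from ._rng import derive_rng, derive_seed
from .exceptions import ParameterError, SrrsError
from .features import FEATURE_NAMES, META_COLUMNS

__all__ = [
    "AsuwoConfig",
    "EnsembleConfig",
    "SrrsConfig",
    "CvResult",
    "EnsembleModel",
    "asuwo_oversample",
    "train_ensemble",
    "score_substrip",
    "classify_subject",
    "compute_metrics",
    "forward_feature_select",
    "srrs_crossvalidate",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "roc_auc", "f1_paf", "f1_ctr")


@dataclass(frozen=True)
class AsuwoConfig:
    """Minority-oversampling parameters."""

    target_ratio: float = 1.0  # minority grown to target_ratio x majority size
    n_clusters: int = 3
    seed: int = 0


@dataclass(frozen=True)
class EnsembleConfig:
    """Voting-ensemble parameters (k-NN + linear SVM + RBF SVM)."""

    k: int = 9
    substrip_threshold: float = 0.5
    subject_threshold: float = 0.5
    svm_c: float = 1.0
    posterior_method: str = "platt"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ParameterError("k must be odd and >= 1")
        if not (0 < self.substrip_threshold < 1 and 0 < self.subject_threshold < 1):
            raise ParameterError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class SrrsConfig:
    """Stratified repeated random sampling parameters.

    Per-class train/test subject counts must partition the cohort; the
    emulated full-scale protocol is 1000 runs with 108/15 training and
    12/4 test subjects for a 120/19 cohort.
    """

    n_runs: int = 1000
    train_control: int = 108
    train_paf: int = 15
    test_control: int = 12
    test_paf: int = 4
    enforce_unique_train: bool = True
    seed: int = 0


@dataclass
class CvResult:
    """Per-run and aggregated SRRS metrics with 95% coverage intervals."""

    per_run: pd.DataFrame  # columns: run, level, metric...
    aggregate: pd.DataFrame  # index (level, metric), columns mean/ci_lo/ci_hi
    subject_scores: pd.DataFrame  # per-subject mean vote score / posterior
    train_sets: list = None  # per-run frozensets of training subject ids


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        return (y == "paf").astype(int)
    return y.astype(int)


def asuwo_oversample(
    features: np.ndarray, labels, cfg: AsuwoConfig = AsuwoConfig()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance classes by adaptive cluster-based convex interpolation.

    Returns ``(X_aug, y_aug, synthetic_mask)`` where the original rows come
    first, unchanged, and every synthetic row lies on a segment between two
    real same-cluster minority rows.
    """
    X = np.asarray(features, dtype=np.float64)
    y = _as_binary(labels)
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    minority = 1 if n1 < n0 else 0
    n_min, n_maj = min(n0, n1), max(n0, n1)
    need = int(round(cfg.target_ratio * n_maj)) - n_min
    if need <= 0 or n0 == n1:
        return X, y, np.zeros(len(y), dtype=bool)
    if n_min < 2:
        raise ParameterError("cannot oversample from a single minority sample")

    Xmin = X[y == minority]
    Xmaj = X[y != minority]
    n_clusters = max(1, min(cfg.n_clusters, n_min // 2, n_min))
    if n_clusters > 1:
        clust = AgglomerativeClustering(n_clusters=n_clusters, linkage="average")
        cids = clust.fit_predict(Xmin)
    else:
        cids = np.zeros(n_min, dtype=int)

    # Boundary difficulty and intrusion trimming per cluster.
    d_maj = cdist(Xmin, Xmaj).min(axis=1)
    info = []
    for c in np.unique(cids):
        m = cids == c
        pts = Xmin[m]
        nearest = float(d_maj[m].min())
        spread = float(np.median(pdist(pts))) if m.sum() > 1 else 0.0
        intruded = m.sum() > 1 and nearest < spread
        info.append((c, int(m.sum()), nearest, intruded))
    kept = [t for t in info if not t[3]] or info  # keep all if every cluster trimmed

    eps = 1e-12
    weights = np.array([size / (nearest + eps) for _, size, nearest, _ in kept])
    weights = weights / weights.sum()
    alloc = np.floor(weights * need).astype(int)
    frac = weights * need - alloc
    for i in np.argsort(frac)[::-1][: need - alloc.sum()]:
        alloc[i] += 1

    rng = derive_rng(cfg.seed, "asuwo")
    synth = []
    for (c, size, _, _), k in zip(kept, alloc):
        pts = Xmin[cids == c]
        for _ in range(int(k)):
            if len(pts) >= 2:
                i, j = rng.choice(len(pts), size=2, replace=False)
            else:
                i = j = 0
            lam = rng.uniform()
            synth.append(pts[i] + lam * (pts[j] - pts[i]))
    X_aug = np.vstack([X, np.array(synth)]) if synth else X
    y_aug = np.concatenate([y, np.full(len(synth), minority, dtype=int)])
    mask = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(len(synth), dtype=bool)])
    return X_aug, y_aug, mask


@dataclass
class EnsembleModel:
    """Fitted voting ensemble; standardization parameters come from training only."""

    feature_names: tuple[str, ...]
    knn: KNeighborsClassifier
    knn_scale: np.ndarray
    svm_linear: CalibratedClassifierCV
    lin_mean: np.ndarray
    lin_scale: np.ndarray
    svm_rbf: CalibratedClassifierCV
    cfg: EnsembleConfig

    def member_posteriors(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) matrix of member PAF posteriors: k-NN, linear SVM, RBF SVM."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        cols = []
        for model, Z in (
            (self.knn, X / self.knn_scale),
            (self.svm_linear, (X - self.lin_mean) / self.lin_scale),
            (self.svm_rbf, X),
        ):
            proba = model.predict_proba(Z)
            idx = int(np.flatnonzero(model.classes_ == 1)[0])
            cols.append(proba[:, idx])
        return np.column_stack(cols)


def _safe_scale(sd: np.ndarray, what: str) -> np.ndarray:
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance feature(s) in {what}; scale set to 1")
        sd = sd.copy()
        sd[zero] = 1.0
    return sd


def train_ensemble(
    train_features: np.ndarray,
    train_labels,
    cfg: EnsembleConfig = EnsembleConfig(),
    selected_feature_names: tuple[str, ...] | None = None,
) -> EnsembleModel:
    """Fit the three-member ensemble on (oversampled) training sub-strips."""
    cfg.validate()
    X = np.asarray(train_features, dtype=np.float64)
    y = _as_binary(train_labels)
    if len(np.unique(y)) < 2:
        raise ParameterError("both classes must be present in the training data")
    if cfg.k > len(y):
        raise ParameterError(f"k={cfg.k} exceeds training size {len(y)}")

    knn_scale = _safe_scale(X.std(axis=0), "k-NN scaling")
    knn = KNeighborsClassifier(n_neighbors=cfg.k).fit(X / knn_scale, y)

    # Platt-style sigmoid posterior calibration fitted on training data only.
    lin_mean = X.mean(axis=0)
    lin_scale = _safe_scale(X.std(axis=0), "linear-SVM standardization")
    svm_lin = CalibratedClassifierCV(
        SVC(kernel="linear", C=cfg.svm_c), method="sigmoid", cv=5, ensemble=False
    ).fit((X - lin_mean) / lin_scale, y)

    sub = X if len(X) <= 256 else X[derive_rng(cfg.seed, "gamma").choice(len(X), 256, replace=False)]
    med = float(np.median(pdist(sub, "sqeuclidean")))
    gamma = 1.0 / med if med > 0 else "scale"
    svm_rbf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=cfg.svm_c, gamma=gamma), method="sigmoid", cv=5, ensemble=False
    ).fit(X, y)

    names = selected_feature_names if selected_feature_names is not None else tuple(
        f"f{i}" for i in range(X.shape[1])
    )
    return EnsembleModel(
        feature_names=tuple(names),
        knn=knn,
        knn_scale=knn_scale,
        svm_linear=svm_lin,
        lin_mean=lin_mean,
        lin_scale=lin_scale,
        svm_rbf=svm_rbf,
        cfg=cfg,
    )


def score_substrip(model: EnsembleModel, feature_row: np.ndarray):
    """Ensemble decision for sub-strip feature row(s).

    Each member votes via its posterior at the 0.5 threshold; the hard label
    is the member majority and the combined posterior (for ROC use) is the
    member mean.  A 1-D input returns scalars; a matrix returns arrays.
    """
    row = np.asarray(feature_row, dtype=np.float64)
    single = row.ndim == 1
    post = model.member_posteriors(row)
    member_labels = (post >= model.cfg.substrip_threshold).astype(int)
    label = (member_labels.sum(axis=1) >= 2).astype(int)
    combined = post.mean(axis=1)
    if single:
        return float(combined[0]), int(label[0])
    return combined, label


def classify_subject(substrip_labels) -> tuple[float, int]:
    """Majority vote over a subject's sub-strip labels.

    score = n_PAF / n_sub-strips (normally 9); label = PAF iff score > 0.5,
    so a full complement of 9 sub-strips can never tie.
    """
    lab = _as_binary(substrip_labels)
    if lab.size == 0:
        raise ParameterError("subject has no classified sub-strips")
    score = float(lab.mean())
    return score, int(score > 0.5)


def compute_metrics(true_labels, pred_labels, scores=None) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, per-class F1 (all %), and ROC AUC.

    PAF (label 1) is the positive class.  AUC uses the rank/trapezoid method
    and is reported as NaN when the truth is single-class or scores are
    absent.
    """
    from sklearn.metrics import f1_score, roc_auc_score

    y = _as_binary(true_labels)
    p = _as_binary(pred_labels)
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    out = {
        "accuracy": 100.0 * (tp + tn) / max(1, len(y)),
        "sensitivity": 100.0 * tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": 100.0 * tn / (tn + fp) if (tn + fp) else np.nan,
        "f1_paf": 100.0 * f1_score(y, p, pos_label=1, zero_division=0),
        "f1_ctr": 100.0 * f1_score(y, p, pos_label=0, zero_division=0),
    }
    if scores is not None and len(np.unique(y)) == 2:
        out["roc_auc"] = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    else:
        out["roc_auc"] = np.nan
    return out


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _subject_frame(table: pd.DataFrame) -> pd.DataFrame:
    subj = table[["subject_id", "label"]].drop_duplicates().reset_index(drop=True)
    return subj


def _draw_split(rng, ctrl_ids, paf_ids, cfg: SrrsConfig):
    tr_c = rng.choice(len(ctrl_ids), size=cfg.train_control, replace=False)
    tr_p = rng.choice(len(paf_ids), size=cfg.train_paf, replace=False)
    train = frozenset(ctrl_ids[i] for i in tr_c) | frozenset(paf_ids[i] for i in tr_p)
    test = (set(ctrl_ids) | set(paf_ids)) - train
    return frozenset(train), sorted(test)


def srrs_crossvalidate(
    table: pd.DataFrame,
    cfg: SrrsConfig,
    selected_features: list[str] | None = None,
    ens_cfg: EnsembleConfig = EnsembleConfig(),
    asuwo_cfg: AsuwoConfig = AsuwoConfig(),
) -> CvResult:
    """Stratified repeated random sampling cross-validation.

    ``table`` is a per-sub-strip feature table (one row per sub-strip with
    ``subject_id``/``label`` metadata).  Each run draws a stratified
    subject-level split with the configured per-class counts, oversamples
    the training sub-strips only, trains the ensemble and scores every real
    test sub-strip and subject.  Training subject sets are unique across
    runs when ``enforce_unique_train``.
    """
    feats = selected_features if selected_features is not None else _feature_columns(table)
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ParameterError(f"features not in table: {missing}")

    subj = _subject_frame(table)
    ctrl_ids = subj.loc[subj.label == "control", "subject_id"].to_numpy()
    paf_ids = subj.loc[subj.label == "paf", "subject_id"].to_numpy()
    if len(ctrl_ids) != cfg.train_control + cfg.test_control:
        raise SrrsError(
            f"{len(ctrl_ids)} control subjects cannot split "
            f"{cfg.train_control}/{cfg.test_control}"
        )
    if len(paf_ids) != cfg.train_paf + cfg.test_paf:
        raise SrrsError(
            f"{len(paf_ids)} PAF subjects cannot split {cfg.train_paf}/{cfg.test_paf}"
        )
    bound = comb(len(ctrl_ids), cfg.train_control) * comb(len(paf_ids), cfg.train_paf)
    if cfg.enforce_unique_train and cfg.n_runs > bound:
        raise SrrsError(
            f"n_runs={cfg.n_runs} exceeds the {bound} distinct training-set combinations"
        )

    rng = derive_rng(cfg.seed, "srrs-splits")
    by_subject = dict(tuple(table.groupby("subject_id", sort=False)))
    seen: set[frozenset] = set()
    train_sets: list[frozenset] = []
    rows = []
    subject_acc: dict[str, list] = {sid: [] for sid in subj.subject_id}
    subject_post: dict[str, list] = {sid: [] for sid in subj.subject_id}

    for run in range(cfg.n_runs):
        for _ in range(10000):
            train_set, test_ids = _draw_split(rng, ctrl_ids, paf_ids, cfg)
            if not cfg.enforce_unique_train or train_set not in seen:
                break
        else:  # pragma: no cover - guarded by the bound check above
            raise SrrsError("could not find an unseen training combination")
        seen.add(train_set)
        train_sets.append(train_set)

        train_tab = pd.concat([by_subject[s] for s in sorted(train_set)])
        X_tr = train_tab[feats].to_numpy(dtype=np.float64)
        y_tr = _as_binary(train_tab["label"])
        run_seed = derive_seed(cfg.seed, "run", run)
        X_aug, y_aug, _ = asuwo_oversample(
            X_tr, y_tr, AsuwoConfig(asuwo_cfg.target_ratio, asuwo_cfg.n_clusters, run_seed)
        )
        model = train_ensemble(
            X_aug,
            y_aug,
            EnsembleConfig(
                k=ens_cfg.k,
                substrip_threshold=ens_cfg.substrip_threshold,
                subject_threshold=ens_cfg.subject_threshold,
                svm_c=ens_cfg.svm_c,
                posterior_method=ens_cfg.posterior_method,
                seed=run_seed,
            ),
            tuple(feats),
        )

        test_tab = pd.concat([by_subject[s] for s in test_ids])
        X_te = test_tab[feats].to_numpy(dtype=np.float64)
        y_te = _as_binary(test_tab["label"])
        post, pred = score_substrip(model, X_te)
        m_sub = compute_metrics(y_te, pred, post)
        rows.append({"run": run, "level": "substrip", "n_scored": len(y_te), **m_sub})

        subj_true, subj_pred, subj_score = [], [], []
        for sid in test_ids:
            sel = (test_tab.subject_id == sid).to_numpy()
            score, label = classify_subject(pred[sel])
            subj_true.append(int(test_tab.loc[sel, "label"].iloc[0] == "paf"))
            subj_pred.append(label)
            subj_score.append(score)
            subject_acc[sid].append(score)
            subject_post[sid].append(float(post[sel].mean()))
        m_subj = compute_metrics(subj_true, subj_pred, subj_score)
        rows.append({"run": run, "level": "subject", **m_subj})

    per_run = pd.DataFrame(rows)
    agg_rows = []
    for level in ("substrip", "subject"):
        sub = per_run[per_run.level == level]
        for metric in METRIC_NAMES:
            vals = sub[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                agg_rows.append((level, metric, np.nan, np.nan, np.nan))
                continue
            agg_rows.append(
                (
                    level,
                    metric,
                    float(vals.mean()),
                    float(np.percentile(vals, 2.5)),
                    float(np.percentile(vals, 97.5)),
                )
            )
    aggregate = (
        pd.DataFrame(agg_rows, columns=["level", "metric", "mean", "ci_lo", "ci_hi"])
        .set_index(["level", "metric"])
        .sort_index()
    )

    subject_scores = pd.DataFrame(
        {
            "subject_id": subj.subject_id,
            "label": subj.label,
            "mean_vote_score": [
                float(np.mean(subject_acc[s])) if subject_acc[s] else np.nan
                for s in subj.subject_id
            ],
            "mean_posterior": [
                float(np.mean(subject_post[s])) if subject_post[s] else np.nan
                for s in subj.subject_id
            ],
            "n_runs_tested": [len(subject_acc[s]) for s in subj.subject_id],
        }
    )
    return CvResult(
        per_run=per_run,
        aggregate=aggregate,
        subject_scores=subject_scores,
        train_sets=train_sets,
    )


def forward_feature_select(
    table: pd.DataFrame,
    cfg: SrrsConfig,
    ens_cfg: EnsembleConfig = EnsembleConfig(),
    asuwo_cfg: AsuwoConfig = AsuwoConfig(),
    weight: float = 2.0 / 3.0,
    eps: float = 1e-3,
    max_features: int | None = None,
    candidates: list[str] | None = None,
) -> list[str]:
    """Sensitivity-weighted sequential forward feature selection.

    Greedily grows the feature subset maximizing
    ``J = weight * sensitivity + (1 - weight) * specificity`` (subject
    level, SRRS-averaged, as fractions), stopping once the best candidate
    fails to improve J by ``eps``.  The heavier sensitivity weight (default
    2/3) emphasizes correct classification of the PAF class.
    """
    cand = list(candidates) if candidates is not None else _feature_columns(table)
    if len(cand) < 2:
        raise ParameterError("need at least 2 candidate features")

    def J(subset: list[str]) -> float:
        res = srrs_crossvalidate(table, cfg, subset, ens_cfg, asuwo_cfg)
        sens = res.aggregate.loc[("subject", "sensitivity"), "mean"] / 100.0
        spec = res.aggregate.loc[("subject", "specificity"), "mean"] / 100.0
        if not np.isfinite(sens):
            sens = 0.0
        if not np.isfinite(spec):
            spec = 0.0
        return weight * sens + (1 - weight) * spec

    selected: list[str] = []
    best_j = -np.inf
    limit = max_features if max_features is not None else len(cand)
    while len(selected) < limit:
        trial = [(J(selected + [f]), f) for f in cand if f not in selected]
        j_new, f_new = max(trial)
        if j_new <= best_j + eps and selected:
            break
        if not selected and j_new <= best_j:
            break
        selected.append(f_new)
        best_j = j_new
    return selected
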