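"""Connectome-based prediction with suprathreshold edge selection.

Out-of-sample check of a network finding: inside each cross-validation
fold, a two-group statistic is computed per edge on the *training subjects
only*, edges above a primary F threshold form a graph, and the largest
connected component's edge values become the feature vector of a linear
discriminant classifier.  Leave-one-out folds are aggregated into
accuracy, precision, Cohen's kappa, AUC, sensitivity and specificity, each
with a bootstrap 95 % confidence interval over the fold-level predictions.

Because edge selection is refit within every training fold, the held-out
subject cannot influence which edges are used — the no-leakage property
tests assert exactly this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from sklearn import metrics as skm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut

from .io import CohortTable, FCBundle
from .nbs import edge_index_pairs

__all__ = [
    "CVConfig",
    "CVReport",
    "SuprathresholdEdgeClassifier",
    "loo_cv",
    "classification_metrics",
    "metric_ci",
]

METRICS = ("accuracy", "precision", "kappa", "auc", "sensitivity", "specificity")


@dataclass
class CVConfig:
    """Configuration of one cross-validated contrast."""

    contrast: tuple[str, str]          # (negative/reference, positive) labels
    f_threshold: float = 4.0
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast groups must differ")


@dataclass
class CVReport:
    """Aggregated leave-one-out results for one contrast/band."""

    metrics: dict                       # name -> (value, (ci_low, ci_high))
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray                  # decision scores for the positive class
    edge_frequency: np.ndarray          # fraction of folds selecting each edge
    config: CVConfig
    fallback_folds: list[int] = field(default_factory=list)


class SuprathresholdEdgeClassifier(ClassifierMixin, BaseEstimator):
    """Linear discriminant on the largest suprathreshold edge component.

    ``fit`` computes a two-sample F statistic (the squared pooled-variance
    t) per edge, keeps edges with F above ``f_threshold``, extracts the
    largest connected component of the resulting graph, standardizes the
    component's edge values with training statistics, and fits an LDA.
    When no edge passes the threshold the single highest-F edge is used as
    a fallback (recorded in ``used_fallback_``).

    Attributes
    ----------
    selected_edges_ : indices (into the upper-triangle edge ordering) of
        the features used by the discriminant.
    classes_ : the two class labels.
    """

    def __init__(self, f_threshold: float = 4.0):
        self.f_threshold = f_threshold

    def _edge_f(self, X: np.ndarray, y01: np.ndarray) -> np.ndarray:
        a, b = X[y01 == 0], X[y01 == 1]
        na, nb = len(a), len(b)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t2 = (a.mean(axis=0) - b.mean(axis=0)) ** 2 / (sp2 * (1 / na + 1 / nb))
        t2[~np.isfinite(t2)] = 0.0
        return t2

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary contrast required")
        y01 = (y == self.classes_[1]).astype(int)
        if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
            raise ValueError("each class needs >= 2 training subjects")
        e = X.shape[1]
        n_regions = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
        if n_regions * (n_regions - 1) // 2 != e:
            raise ValueError(f"{e} edge columns is not an upper triangle")
        f = self._edge_f(X, y01)
        mask = f > self.f_threshold
        self.used_fallback_ = not mask.any()
        if self.used_fallback_:
            sel = np.array([int(np.argmax(f))])
        else:
            iu_i, iu_j = edge_index_pairs(n_regions)
            idx = np.flatnonzero(mask)
            i, j = iu_i[idx], iu_j[idx]
            adj = coo_matrix((np.ones(idx.size), (i, j)),
                             shape=(n_regions, n_regions))
            _, labels = _cc(adj, directed=False)
            edge_labels = labels[i]
            best = np.bincount(edge_labels).argmax()
            sel = idx[edge_labels == best]
        self.selected_edges_ = sel
        feats = X[:, sel]
        self.mean_ = feats.mean(axis=0)
        sd = feats.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit((feats - self.mean_) / self.scale_, y01)
        return self

    def _features(self, X):
        X = np.asarray(X, dtype=float)
        return (X[:, self.selected_edges_] - self.mean_) / self.scale_

    def predict(self, X):
        y01 = self.lda_.predict(self._features(X))
        return self.classes_[y01]

    def decision_function(self, X):
        return self.lda_.decision_function(self._features(X))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._features(X))


def classification_metrics(y_true, y_pred, scores=None,
                           positive=None) -> dict[str, float]:
    """Binary metrics: accuracy, precision, Cohen's kappa, AUC (Mann-Whitney
    with ties counted half), sensitivity, specificity.

    Metrics whose denominator class is absent come back as NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if positive is None:
        positive = labels[-1]
    t = (y_true == positive).astype(int)
    p = (y_pred == positive).astype(int)
    tp = int(((t == 1) & (p == 1)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())

    def safe(num, den):
        return num / den if den > 0 else float("nan")

    out = {
        "accuracy": safe(tp + tn, len(t)),
        "precision": safe(tp, tp + fp),
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "kappa": float(skm.cohen_kappa_score(t, p)) if len(np.unique(t)) > 1 or len(np.unique(p)) > 1 else float("nan"),
        "auc": float("nan"),
    }
    if scores is not None and len(np.unique(t)) == 2:
        out["auc"] = float(skm.roc_auc_score(t, np.asarray(scores, dtype=float)))
    return out


def metric_ci(y_true, y_pred, scores, n_boot: int = 1000, seed: int = 0,
              positive=None) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap 95 % CIs over the fold-level prediction set."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    n = len(y_true)
    if n < 8:
        raise ValueError("need at least 8 folds for metric CIs")
    rng = np.random.default_rng(seed)
    samples = {m: [] for m in METRICS}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = classification_metrics(y_true[idx], y_pred[idx], scores[idx],
                                   positive=positive)
        for k, v in m.items():
            if np.isfinite(v):
                samples[k].append(v)
    out = {}
    for k, vals in samples.items():
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            out[k] = (float(lo), float(hi))
        else:
            out[k] = (float("nan"), float("nan"))
    return out


def loo_cv(bundle: FCBundle, band: str, cohort: CohortTable,
           cfg: CVConfig) -> CVReport:
    """Leave-one-out evaluation of the suprathreshold-edge classifier.

    Edge selection, feature standardization and the discriminant are refit
    on the training subjects of every fold; the held-out subject only ever
    passes through ``predict``.  Deterministic given ``cfg.seed``.
    """
    groups = cohort.groups()
    mask = groups.isin(cfg.contrast).to_numpy()
    subjects = [s for s, m in zip(cohort.subjects, mask) if m]
    y = groups.to_numpy()[mask]
    for g in cfg.contrast:
        if (y == g).sum() < 4:
            raise ValueError(f"group {g!r} needs >= 4 subjects for LOO")
    sub_bundle_rows = np.flatnonzero(
        np.isin(np.array(bundle.subjects), np.array(subjects))
    )
    X = bundle.edge_matrix(band)[sub_bundle_rows]
    # positive class = second contrast label
    base = SuprathresholdEdgeClassifier(f_threshold=cfg.f_threshold)
    n = len(y)
    y_pred = np.empty(n, dtype=object)
    scores = np.empty(n)
    freq = np.zeros(X.shape[1])
    fallback = []
    for fold, (tr, te) in enumerate(LeaveOneOut().split(X)):
        est = clone(base)
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        pos_col = int(np.flatnonzero(est.classes_ == cfg.contrast[1])[0]) \
            if cfg.contrast[1] in est.classes_ else 1
        scores[te] = est.predict_proba(X[te])[:, pos_col]
        freq[est.selected_edges_] += 1
        if est.used_fallback_:
            fallback.append(fold)
    freq /= n
    point = classification_metrics(y, y_pred.astype(str), scores,
                                   positive=cfg.contrast[1])
    cis = metric_ci(y, y_pred.astype(str), scores, n_boot=cfg.n_boot,
                    seed=cfg.seed, positive=cfg.contrast[1])
    report = CVReport(
        metrics={m: (point[m], cis[m]) for m in METRICS},
        y_true=y,
        y_pred=y_pred.astype(str),
        scores=scores,
        edge_frequency=freq,
        config=cfg,
        fallback_folds=fallback,
    )
    return report
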