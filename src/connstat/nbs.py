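"""Network-based statistic with covariate-adjusted edge-wise tests.

The network-based statistic (NBS) controls the family-wise error rate over
all edges of a connectivity graph by cluster-level inference: every edge is
tested with a k-group ANCOVA (general linear model with group dummies plus
nuisance covariates), edges whose F statistic exceeds a primary threshold
form a suprathreshold graph, and the size (edge count) of its largest
connected component is compared against a permutation null distribution of
maximum component sizes obtained by relabelling subjects across groups
(group sizes preserved, covariates staying attached to their subjects).

The primary threshold is chosen by an effect-size-guided scan: starting at
the smallest F on a fixed grid whose omega-squared effect size reaches the
"medium" bound (or at an explicit starting F), the threshold is increased
in fixed steps until the largest suprathreshold component is significant at
the FWER level.  A non-significant outcome is a valid result carrying the
scan trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from sklearn.base import BaseEstimator

from .io import CohortTable, FCBundle

__all__ = [
    "DesignSpec",
    "EdgewiseStats",
    "ThresholdPolicy",
    "Component",
    "NBSResult",
    "NetworkBasedStatistic",
    "edgewise_ancova",
    "omega_squared",
    "suprathreshold_components",
    "permutation_null",
    "fwer_pvalue",
    "run_nbs",
    "edge_index_pairs",
]


def edge_index_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (i, j) upper-triangle edge ordering shared package-wide."""
    return np.triu_indices(n_regions, 1)


@dataclass
class DesignSpec:
    """Group factor plus nuisance covariates for the edge-wise GLM.

    The full model per edge is ``intercept + (k-1) group dummies +
    covariates``; the reduced model drops the group dummies.  The design
    must be full rank and every group needs at least two subjects.
    """

    group: np.ndarray                      # (N,) string labels
    group_levels: list[str]
    covariates: np.ndarray | None = None   # (N, ncov)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.group = np.asarray(self.group)
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != len(self.group):
                raise ValueError("covariate rows must match subjects")
        if len(self.group_levels) < 2:
            raise ValueError("need at least two group levels")
        counts = {g: int((self.group == g).sum()) for g in self.group_levels}
        if any(c < 2 for c in counts.values()):
            raise ValueError(f"every group needs >= 2 subjects, got {counts}")

    @classmethod
    def from_cohort(cls, cohort: CohortTable, covariate_names: list[str] | None = None):
        covs = None
        names = list(covariate_names or [])
        if names:
            covs = cohort.covariate_matrix(names)
        return cls(
            group=cohort.groups().to_numpy(),
            group_levels=cohort.group_levels,
            covariates=covs,
            covariate_names=names,
        )

    @property
    def n(self) -> int:
        return len(self.group)

    @property
    def k(self) -> int:
        return len(self.group_levels)

    @property
    def ncov(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def df_between(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return self.n - self.k - self.ncov

    def dummies(self) -> np.ndarray:
        """(N, k-1) treatment-coded dummies, first level as reference."""
        return np.column_stack(
            [(self.group == g).astype(float) for g in self.group_levels[1:]]
        )

    def reduced_design(self) -> np.ndarray:
        """(N, 1 + ncov) intercept plus covariates."""
        cols = [np.ones(self.n)]
        if self.covariates is not None:
            cols.append(self.covariates)
        return np.column_stack(cols)


@dataclass
class EdgewiseStats:
    """Per-edge F statistics and effect sizes for the group factor."""

    F: np.ndarray          # (E,)
    omega2: np.ndarray     # (E,)
    df_between: int
    df_error: int
    n: int
    n_regions: int


@dataclass(frozen=True)
class ThresholdPolicy:
    """Effect-size-guided primary-threshold scan policy.

    ``f_initial`` overrides the derived grid start (the smallest multiple of
    ``step`` whose omega-squared effect size reaches ``omega2_min``).
    """

    step: float = 0.1
    omega2_min: float = 0.06
    alpha: float = 0.05
    f_initial: float | None = None

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.omega2_min < 1):
            raise ValueError("omega2_min must be in (0, 1)")

    def starting_f(self, df_between: int, n: int) -> float:
        if self.f_initial is not None:
            return float(self.f_initial)
        # invert omega2 = df_b (F-1) / (df_b (F-1) + N) >= omega2_min
        f_star = 1.0 + self.omega2_min * n / ((1.0 - self.omega2_min) * df_between)
        return round(math.ceil(f_star / self.step - 1e-9) * self.step, 10)


@dataclass
class Component:
    """A connected set of suprathreshold edges."""

    edges: list[tuple[int, int]]

    @property
    def nodes(self) -> list[int]:
        return sorted({v for e in self.edges for v in e})

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class NBSResult:
    """Outcome of one NBS run (significant or not)."""

    f_threshold: float
    component: Component | None
    p_fwer: float | None
    null_max_sizes: np.ndarray | None
    n_perm: int
    seed: int
    edgewise: EdgewiseStats
    significant: bool
    scan_trace: list[dict] = field(default_factory=list)


def omega_squared(F, df_between: int, n: int):
    """Omega-squared effect size for an ANOVA-family F, floored at 0.

    ``omega2 = df_b (F - 1) / (df_b (F - 1) + N)``; conventionally >= 0.06
    counts as a medium effect.
    """
    F = np.asarray(F, dtype=float)
    with np.errstate(invalid="ignore"):
        num = df_between * (F - 1.0)
        out = np.where(np.isinf(F), 1.0, num / (num + n))
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def _group_f_map(y_res: np.ndarray, dummies: np.ndarray, q_red: np.ndarray,
                 rss_red: np.ndarray, df_b: int, df_e: int) -> np.ndarray:
    """F per edge given reduced-model residualized responses.

    ``y_res`` is Y with the reduced design projected out, ``rss_red`` its
    per-edge squared norm.  The group sum of squares is the squared norm of
    the projection of ``y_res`` onto the residualized dummies.
    """
    d = dummies - q_red @ (q_red.T @ dummies)
    qd, rd = np.linalg.qr(d)
    # guard rank deficiency of the group block after residualization
    keep = np.abs(np.diag(rd)) > 1e-10 * max(1.0, np.abs(rd).max())
    qd = qd[:, keep]
    proj = qd.T @ y_res
    ss_group = np.einsum("ij,ij->j", proj, proj)
    rss_full = np.maximum(rss_red - ss_group, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_group / df_b) / (rss_full / df_e)
    f[~np.isfinite(f)] = np.inf
    # an edge with (numerically) no residual variance explains nothing
    f[rss_red <= 1e-24] = 0.0
    return f


class NetworkBasedStatistic(BaseEstimator):
    """Network-based statistic as a scikit-learn style estimator.

    ``fit(X, y, covariates=...)`` takes the (N_subjects, E) upper-triangle
    edge matrix, group labels and optional covariates, and performs the
    full procedure: edge-wise ANCOVA, threshold scan, suprathreshold
    component extraction, permutation null of maximum component size, and
    FWER p-value.

    Parameters
    ----------
    policy : ThresholdPolicy
        Primary-threshold scan rule (step, effect-size bound, FWER alpha,
        optional explicit starting F).
    n_perm : int
        Permutations for the null distribution (study-scale default 5000).
    scan : bool
        If False, test only the starting threshold instead of scanning
        upward to the first significant one.
    seed : int
        Seed for the permutation stream.

    Attributes
    ----------
    f_ : (E,) edge-wise ANCOVA F statistics.
    omega2_ : (E,) omega-squared effect sizes.
    result_ : NBSResult with threshold, component, p-value, null and trace.
    """

    def __init__(self, policy: ThresholdPolicy = ThresholdPolicy(),
                 n_perm: int = 5000, scan: bool = True, seed: int = 0):
        self.policy = policy
        self.n_perm = n_perm
        self.scan = scan
        self.seed = seed

    # -- core fitting --------------------------------------------------
    def fit(self, X, y, covariates=None, group_levels=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_subjects, n_edges)")
        y = np.asarray(y)
        levels = list(group_levels) if group_levels is not None else list(dict.fromkeys(y))
        design = DesignSpec(group=y, group_levels=levels, covariates=covariates,
                            covariate_names=[])
        self._fit_design(X, design)
        return self

    def _fit_design(self, X: np.ndarray, design: DesignSpec):
        e = X.shape[1]
        n_regions = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
        if n_regions * (n_regions - 1) // 2 != e:
            raise ValueError(f"{e} edge columns is not an upper triangle")
        stats = _edgewise_ancova_matrix(X, design, n_regions)
        self.f_ = stats.F
        self.omega2_ = stats.omega2
        self.design_ = design
        self.stats_ = stats
        policy = self.policy

        iu_i, iu_j = edge_index_pairs(n_regions)
        f_start = policy.starting_f(design.df_between, design.n)
        max_f = float(np.max(stats.F)) if e else 0.0

        perm_f = self._permuted_f_maps(X, design)

        trace: list[dict] = []
        f_thr = f_start
        result = None
        while True:
            obs_mask = stats.F > f_thr
            comps = _components_from_mask(obs_mask, iu_i, iu_j, n_regions)
            if not comps:
                trace.append({"f": f_thr, "max_size": 0, "p": None})
                result = NBSResult(f_thr, None, None, None, self.n_perm,
                                   self.seed, stats, False, trace)
                break
            largest = comps[0]
            null_sizes = _null_max_sizes(perm_f, f_thr, iu_i, iu_j, n_regions)
            p = fwer_pvalue(largest.size, null_sizes)
            trace.append({"f": f_thr, "max_size": largest.size, "p": p})
            if p < policy.alpha or not self.scan:
                result = NBSResult(f_thr, largest, p, null_sizes, self.n_perm,
                                   self.seed, stats, p < policy.alpha, trace)
                break
            f_thr = round(f_thr + policy.step, 10)
            if f_thr > max_f:
                result = NBSResult(f_thr, None, None, None, self.n_perm,
                                   self.seed, stats, False, trace)
                break
        self.result_ = result
        return self

    def _permuted_f_maps(self, X: np.ndarray, design: DesignSpec) -> np.ndarray:
        """(n_perm, E) F maps under group relabelling, float32, deterministic."""
        rng = np.random.default_rng(self.seed)
        c = design.reduced_design()
        q_red, _ = np.linalg.qr(c)
        y_res = X - q_red @ (q_red.T @ X)
        rss_red = np.einsum("ij,ij->j", y_res, y_res)
        dummies = design.dummies()
        out = np.empty((self.n_perm, X.shape[1]), dtype=np.float32)
        for p in range(self.n_perm):
            perm = rng.permutation(design.n)
            out[p] = _group_f_map(y_res, dummies[perm], q_red, rss_red,
                                  design.df_between, design.df_error)
        return out


# ---------------------------------------------------------------------
# functional wrappers (operate on FCBundle / DesignSpec per the pipeline)
# ---------------------------------------------------------------------

def _edgewise_ancova_matrix(X: np.ndarray, design: DesignSpec,
                            n_regions: int) -> EdgewiseStats:
    if design.n != X.shape[0]:
        raise ValueError("design rows must match subjects")
    if design.df_error < 1:
        raise ValueError("non-positive error degrees of freedom")
    c = design.reduced_design()
    full = np.column_stack([c, design.dummies()])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates/dummies)")
    q_red, _ = np.linalg.qr(c)
    y_res = X - q_red @ (q_red.T @ X)
    rss_red = np.einsum("ij,ij->j", y_res, y_res)
    f = _group_f_map(y_res, design.dummies(), q_red, rss_red,
                     design.df_between, design.df_error)
    om = omega_squared(f, design.df_between, design.n)
    return EdgewiseStats(F=f, omega2=om, df_between=design.df_between,
                         df_error=design.df_error, n=design.n, n_regions=n_regions)


def edgewise_ancova(bundle: FCBundle, band: str, design: DesignSpec) -> EdgewiseStats:
    """Edge-by-edge k-group ANCOVA F map for one band.

    Per edge, ``F = [(RSS_reduced - RSS_full)/(k-1)] / [RSS_full/(N-k-Ncov)]``
    where the full model is intercept + group dummies + covariates and the
    reduced model drops the dummies.  With no covariates this is the
    classical one-way ANOVA F.
    """
    X = bundle.edge_matrix(band)
    return _edgewise_ancova_matrix(X, design, bundle.n_regions)


def _components_from_mask(mask: np.ndarray, iu_i: np.ndarray, iu_j: np.ndarray,
                          n_regions: int) -> list[Component]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    g = nx.Graph()
    g.add_edges_from(zip(iu_i[idx].tolist(), iu_j[idx].tolist()))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = sorted(tuple(sorted(e)) for e in sub.edges)
        comps.append(Component(edges=edges))
    comps.sort(key=lambda comp: (-comp.size, comp.nodes[0]))
    return comps


def suprathreshold_components(stats: EdgewiseStats, f_threshold: float) -> list[Component]:
    """Connected components of edges with F strictly above the threshold.

    Sorted by edge count descending; ties broken by smallest node index.
    """
    iu_i, iu_j = edge_index_pairs(stats.n_regions)
    return _components_from_mask(stats.F > f_threshold, iu_i, iu_j, stats.n_regions)


def _max_component_size(mask: np.ndarray, iu_i: np.ndarray, iu_j: np.ndarray,
                        n_regions: int) -> int:
    """Edge count of the largest connected suprathreshold component."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    i, j = iu_i[idx], iu_j[idx]
    adj = coo_matrix((np.ones(idx.size), (i, j)), shape=(n_regions, n_regions))
    _, labels = _cc(adj, directed=False)
    edge_labels = labels[i]
    return int(np.bincount(edge_labels).max())


def _null_max_sizes(perm_f: np.ndarray, f_thr: float, iu_i, iu_j, n_regions) -> np.ndarray:
    sizes = np.empty(perm_f.shape[0], dtype=int)
    for p in range(perm_f.shape[0]):
        sizes[p] = _max_component_size(perm_f[p] > f_thr, iu_i, iu_j, n_regions)
    return sizes


def permutation_null(bundle: FCBundle, band: str, design: DesignSpec,
                     f_threshold: float, n_perm: int = 5000, seed: int = 0) -> np.ndarray:
    """Null distribution of maximum component size under group relabelling.

    Group labels are shuffled across subjects (group sizes preserved,
    covariates staying attached to their subjects), the edge-wise ANCOVA is
    recomputed, and the maximum suprathreshold component size recorded
    (0 when no edge passes).  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = NetworkBasedStatistic(n_perm=n_perm, seed=seed)
    X = bundle.edge_matrix(band)
    perm_f = est._permuted_f_maps(X, design)
    iu_i, iu_j = edge_index_pairs(bundle.n_regions)
    return _null_max_sizes(perm_f, f_threshold, iu_i, iu_j, bundle.n_regions)


def fwer_pvalue(observed_size: int, null_max_sizes: np.ndarray) -> float:
    """p = fraction of null maximum sizes >= the observed component size."""
    null_max_sizes = np.asarray(null_max_sizes)
    if null_max_sizes.size == 0:
        raise ValueError("empty null distribution")
    if observed_size < 1:
        raise ValueError("observed component must have at least one edge")
    return float(np.mean(null_max_sizes >= observed_size))


def run_nbs(bundle: FCBundle, band: str, design: DesignSpec,
            policy: ThresholdPolicy = ThresholdPolicy(), n_perm: int = 5000,
            seed: int = 0, scan: bool = True) -> NBSResult:
    """Full NBS procedure on one band of an FC bundle.

    Thin wrapper over :class:`NetworkBasedStatistic`.
    """
    est = NetworkBasedStatistic(policy=policy, n_perm=n_perm, scan=scan, seed=seed)
    est._fit_design(bundle.edge_matrix(band), design)
    return est.result_
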