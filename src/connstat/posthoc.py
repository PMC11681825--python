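"""Post-hoc characterization of significant networks.

Once a suprathreshold component survives permutation testing, three
descriptive/confirmatory layers follow:

* *mean network connectivity* (mNC) — per subject, the average FC over the
  component's edges — compared across groups with a one-way ANOVA and
  Tukey-Kramer pairwise post-hocs (studentized-range based, valid for
  unequal group sizes);
* *directional subnetworks* — per component edge, a Tukey-Kramer pairwise
  comparison across all groups; edges where a named group pair differs are
  collected, split by direction of the difference;
* *summary statistics* — node/link counts, percentage of the parent
  network's links, hemispheric lateralization (three variants, since the
  literature is not consistent about the base), node degrees, and lobe
  composition from the atlas metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import studentized_range

from .atlas import AtlasRegion
from .io import FCBundle
from .nbs import Component, DesignSpec

__all__ = [
    "MNCVector",
    "TukeyResult",
    "Subnetwork",
    "SubnetworkSummary",
    "mean_network_connectivity",
    "mnc_group_test",
    "extract_subnetwork",
    "summarize_subnetwork",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (47.65 -> 47.7), as in clinical reporting."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MNCVector:
    """Per-subject mean connectivity over a fixed edge set."""

    values: np.ndarray          # (N,)
    edges: list[tuple[int, int]]
    band: str
    subjects: list[str] = field(default_factory=list)


@dataclass
class TukeyResult:
    """All-pairs Tukey-Kramer comparisons.

    ``q_ij = |mean_i - mean_j| / sqrt((MSW/2) (1/n_i + 1/n_j))`` with
    adjusted p-values from the studentized range distribution with k groups
    and ``df_error = N - k``.
    """

    pairs: list[tuple[str, str]]
    mean_diff: np.ndarray
    q: np.ndarray
    p_adj: np.ndarray
    df_error: int
    degenerate: bool = False


def mean_network_connectivity(
    bundle: FCBundle, band: str, edges: list[tuple[int, int]]
) -> MNCVector:
    """Per-subject arithmetic mean of FC values over the given edges."""
    if not edges:
        raise ValueError("edge set must be nonempty")
    r = bundle.n_regions
    for i, j in edges:
        if not (0 <= i < j < r):
            raise ValueError(f"edge ({i}, {j}) invalid for {r} regions")
    rows = np.array([i for i, _ in edges])
    cols = np.array([j for _, j in edges])
    vals = np.array(
        [bundle.matrices[(s, band)][rows, cols].mean() for s in bundle.subjects]
    )
    return MNCVector(values=vals, edges=list(edges), band=band,
                     subjects=list(bundle.subjects))


def _tukey_kramer(y: np.ndarray, design: DesignSpec) -> TukeyResult:
    """Tukey-Kramer on a 1-D response (vectorized core used per edge too)."""
    res = _tukey_kramer_matrix(y[:, None], design)
    return TukeyResult(res.pairs, res.mean_diff[:, 0], res.q[:, 0],
                       res.p_adj[:, 0], res.df_error, res.degenerate)


@dataclass
class _TukeyMatrix:
    pairs: list[tuple[str, str]]
    mean_diff: np.ndarray   # (n_pairs, E)
    q: np.ndarray
    p_adj: np.ndarray
    df_error: int
    degenerate: bool


def _tukey_kramer_matrix(Y: np.ndarray, design: DesignSpec) -> _TukeyMatrix:
    levels = design.group_levels
    k = len(levels)
    n = Y.shape[0]
    df_e = n - k
    masks = [design.group == g for g in levels]
    ns = np.array([m.sum() for m in masks])
    means = np.stack([Y[m].mean(axis=0) for m in masks])          # (k, E)
    ssw = sum(((Y[m] - means[i]) ** 2).sum(axis=0) for i, m in enumerate(masks))
    msw = ssw / df_e
    degenerate = bool(np.any(msw <= 0))
    pairs, diffs, qs = [], [], []
    for a in range(k):
        for b in range(a + 1, k):
            pairs.append((levels[a], levels[b]))
            d = means[a] - means[b]
            se = np.sqrt((msw / 2.0) * (1.0 / ns[a] + 1.0 / ns[b]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.abs(d) / se
            q = np.where(se > 0, q, np.where(np.abs(d) > 0, np.inf, 0.0))
            diffs.append(d)
            qs.append(q)
    qmat = np.stack(qs)
    finite = np.isfinite(qmat)
    p = np.zeros_like(qmat)
    p[finite] = studentized_range.sf(qmat[finite], k, df_e)
    p = np.clip(p, 0.0, 1.0)
    return _TukeyMatrix(pairs, np.stack(diffs), qmat, p, df_e, degenerate)


def mnc_group_test(mnc: MNCVector, design: DesignSpec) -> tuple[float, float, TukeyResult]:
    """One-way ANOVA on mNC plus all-pairs Tukey-Kramer post-hocs.

    Returns ``(F, p_omnibus, TukeyResult)``.  Zero within-group variance is
    flagged as degenerate rather than raising.
    """
    from scipy.stats import f as f_dist

    y = np.asarray(mnc.values, dtype=float)
    levels = design.group_levels
    masks = [design.group == g for g in levels]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs >= 2 subjects")
    k, n = len(levels), len(y)
    grand = y.mean()
    ssb = sum(m.sum() * (y[m].mean() - grand) ** 2 for m in masks)
    ssw = sum(((y[m] - y[m].mean()) ** 2).sum() for m in masks)
    df_b, df_e = k - 1, n - k
    if ssw <= 0:
        f_stat = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_e)
        p = float(f_dist.sf(f_stat, df_b, df_e))
    return float(f_stat), p, _tukey_kramer(y, design)


@dataclass
class Subnetwork:
    """Edges of a parent component where one group pair differs.

    ``direction`` names the group with the higher mean FC; a mixed-direction
    result is split into one subnetwork per direction.
    """

    parent: Component
    edges: list[tuple[int, int]]
    contrast: tuple[str, str]
    direction: str


def extract_subnetwork(
    bundle: FCBundle,
    band: str,
    parent: Component,
    design: DesignSpec,
    contrast: tuple[str, str],
    alpha: float = 0.05,
) -> list[Subnetwork]:
    """Edge-level Tukey-Kramer post-hoc over a parent component.

    For every parent edge an all-pairs Tukey-Kramer comparison is run on
    the raw FC values across the k groups; the edge is retained when the
    named pair's adjusted p is below ``alpha``.  Retained edges are split
    by the sign of the mean difference into at most two directional
    subnetworks (empty list if nothing is retained).
    """
    if contrast[0] not in design.group_levels or contrast[1] not in design.group_levels:
        raise ValueError(f"contrast {contrast} not among groups {design.group_levels}")
    if not parent.edges:
        return []
    X = bundle.edge_matrix(band)
    r = bundle.n_regions
    iu_i, iu_j = np.triu_indices(r, 1)
    flat = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(iu_i, iu_j))}
    cols = [flat[e] for e in parent.edges]
    res = _tukey_kramer_matrix(X[:, cols], design)
    try:
        pair_idx = res.pairs.index(tuple(contrast))
        sign = 1.0
    except ValueError:
        pair_idx = res.pairs.index((contrast[1], contrast[0]))
        sign = -1.0
    keep = res.p_adj[pair_idx] < alpha
    diff = sign * res.mean_diff[pair_idx]
    out = []
    for direction, mask in ((contrast[0], keep & (diff > 0)),
                            (contrast[1], keep & (diff < 0))):
        edges = [parent.edges[e] for e in np.flatnonzero(mask)]
        if edges:
            out.append(Subnetwork(parent=parent, edges=edges,
                                  contrast=tuple(contrast), direction=direction))
    return out


@dataclass
class SubnetworkSummary:
    """Reporting-convention summary of a (sub)network."""

    n_nodes: int
    n_links: int
    pct_of_parent_links: float
    lateralization: dict            # three named variants, percentages
    degree: dict                    # region name -> degree, sorted desc
    lobe_composition: dict          # lobe -> pct of degree mass


def summarize_subnetwork(
    sub: Subnetwork | Component,
    parent: Component,
    atlas: list[AtlasRegion],
) -> SubnetworkSummary:
    """Node/link counts, parent-link percentage, lateralization, degrees.

    Percentages are rounded half-up to one decimal.  Lateralization is
    reported in three variants because published network descriptions mix
    the bases: ``node_share`` (percent of nodes per hemisphere),
    ``intra_link_share`` (percent of links with both endpoints in one
    hemisphere, cross-hemisphere links listed separately), and
    ``degree_mass_share`` (percent of edge-endpoint incidences per
    hemisphere, equivalently intra links + half-weighted cross links).
    """
    edges = list(sub.edges)
    n_regions = len(atlas)
    for i, j in edges:
        if not (0 <= i < n_regions and 0 <= j < n_regions):
            raise ValueError(f"edge ({i}, {j}) references nodes outside the atlas")
    n_links = len(edges)
    nodes = sorted({v for e in edges for v in e})
    pct = round_half_up(100.0 * n_links / parent.size, 1) if parent.size else 0.0

    hemi = {r.index: r.hemisphere for r in atlas}
    lobe = {r.index: r.lobe for r in atlas}
    name = {r.index: r.name for r in atlas}

    degree: dict[int, int] = {}
    for i, j in edges:
        degree[i] = degree.get(i, 0) + 1
        degree[j] = degree.get(j, 0) + 1

    def pct_of(x, total):
        return round_half_up(100.0 * x / total, 1) if total else 0.0

    n_left_nodes = sum(hemi[v] == "left" for v in nodes)
    intra_l = sum(hemi[i] == "left" and hemi[j] == "left" for i, j in edges)
    intra_r = sum(hemi[i] == "right" and hemi[j] == "right" for i, j in edges)
    cross = n_links - intra_l - intra_r
    mass_l = sum(d for v, d in degree.items() if hemi[v] == "left")
    total_mass = 2 * n_links

    lateralization = {
        "node_share": {"left": pct_of(n_left_nodes, len(nodes)),
                       "right": pct_of(len(nodes) - n_left_nodes, len(nodes))},
        "intra_link_share": {"left": pct_of(intra_l, n_links),
                             "right": pct_of(intra_r, n_links),
                             "cross": pct_of(cross, n_links)},
        "degree_mass_share": {"left": pct_of(mass_l, total_mass),
                              "right": pct_of(total_mass - mass_l, total_mass)},
    }

    lobe_mass: dict[str, int] = {}
    for v, d in degree.items():
        lobe_mass[lobe[v]] = lobe_mass.get(lobe[v], 0) + d
    lobe_composition = {
        lb: pct_of(m, total_mass)
        for lb, m in sorted(lobe_mass.items(), key=lambda kv: -kv[1])
    }

    degree_named = dict(
        sorted(((name[v], d) for v, d in degree.items()), key=lambda kv: (-kv[1], kv[0]))
    )
    return SubnetworkSummary(
        n_nodes=len(nodes),
        n_links=n_links,
        pct_of_parent_links=pct,
        lateralization=lateralization,
        degree=degree_named,
        lobe_composition=lobe_composition,
    )
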