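"""Long-range interaction analysis: desert tropism, signal partition,
viewpoint clustering.

Hox clusters sit at the boundary between two topologically associating
domains that extend into flanking gene deserts. A viewpoint's *tropism*
is the way its long-range signal splits between the centromeric and the
telomeric desert, computed on smoothed signal with the cluster itself
excluded. Viewpoints are compared by hierarchical clustering of their
pairwise Spearman correlations over the desert fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .chip import spearman_correlation
from .profiles import NormalizedProfile, exclude_interval, running_mean


@dataclass(frozen=True)
class DesertAnnotation:
    """Cluster and flanking gene-desert intervals in bp, 0-based half-open.

    The cluster must lie between the two deserts and the three intervals
    must not overlap; ``span`` is the full analysis extent.
    """

    centromeric: tuple[int, int]
    cluster: tuple[int, int]
    telomeric: tuple[int, int]
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        c, k, t = self.centromeric, self.cluster, self.telomeric
        for name, (s, e) in (("centromeric", c), ("cluster", k), ("telomeric", t)):
            if e <= s:
                raise ValueError(f"{name} interval is empty")
        if not (c[1] <= k[0] and k[1] <= t[0]):
            raise ValueError(
                "intervals must be ordered centromeric < cluster < telomeric "
                "without overlap"
            )
        span = self.span or (c[0], t[1])
        if span[0] > c[0] or span[1] < t[1]:
            raise ValueError("span must contain all three intervals")
        object.__setattr__(self, "span", tuple(span))


@dataclass(frozen=True)
class TropismSummary:
    """Fractions of long-range signal per flanking desert (and cluster)."""

    viewpoint_id: str
    p_cen: float
    p_tel: float
    p_cluster: float | None = None

    def __post_init__(self) -> None:
        parts = [self.p_cen, self.p_tel] + (
            [self.p_cluster] if self.p_cluster is not None else []
        )
        if any(not 0 <= p <= 1 for p in parts):
            raise ValueError("fractions must lie in [0, 1]")
        if not np.isclose(sum(parts), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1")


def _desert_sums(
    profile: NormalizedProfile, annotation: DesertAnnotation, window: int | None
) -> tuple[float, float]:
    masked = exclude_interval(profile, *annotation.cluster)
    if window is not None:
        masked = running_mean(masked, window)
    fmap = profile.fragment_map
    cen_idx = fmap.overlapping(*annotation.centromeric)
    tel_idx = fmap.overlapping(*annotation.telomeric)
    ok = masked.ok
    cen = float(masked.values[cen_idx][ok[cen_idx]].sum())
    tel = float(masked.values[tel_idx][ok[tel_idx]].sum())
    return cen, tel


def tropism(
    profile: NormalizedProfile,
    annotation: DesertAnnotation,
    window: int | None = 11,
) -> TropismSummary:
    """Split of desert signal between the centromeric and telomeric sides.

    The cluster interval is excluded before smoothing (the running mean
    skips excluded fragments, so no cluster signal leaks into the desert
    edges), then p_cen = desert-signal fraction on the centromeric side
    and p_tel = 1 - p_cen. Pass ``window=None`` for raw-signal mode.
    """
    cen, tel = _desert_sums(profile, annotation, window)
    total = cen + tel
    if total <= 0:
        raise ValueError("no desert signal; tropism undefined")
    return TropismSummary(
        viewpoint_id=profile.viewpoint_id,
        p_cen=cen / total,
        p_tel=tel / total,
    )


def cumulative_tropism(
    profile: NormalizedProfile,
    annotation: DesertAnnotation,
    window: int | None = 11,
) -> TropismSummary:
    """Desert fractions with the cluster kept as a third category."""
    cen, tel = _desert_sums(profile, annotation, window)
    fmap = profile.fragment_map
    clu_idx = fmap.overlapping(*annotation.cluster)
    clu = float(profile.values[clu_idx][profile.ok[clu_idx]].sum())
    total = cen + tel + clu
    if total <= 0:
        raise ValueError("no signal in any category")
    return TropismSummary(
        viewpoint_id=profile.viewpoint_id,
        p_cen=cen / total,
        p_tel=tel / total,
        p_cluster=clu / total,
    )


def signal_partition(
    profile: NormalizedProfile, categories: dict[str, tuple[int, int]]
) -> pd.Series:
    """Fraction of OK signal in each named interval category.

    The categories must not overlap; fragments outside every category are
    ignored, and the fractions are taken over the categorised signal so
    they sum to 1.
    """
    fmap = profile.fragment_map
    seen = np.zeros(fmap.n_fragments, dtype=bool)
    sums = {}
    for name, (start, end) in categories.items():
        idx = fmap.overlapping(start, end)
        if np.any(seen[idx]):
            raise ValueError(f"category {name!r} overlaps another category")
        seen[idx] = True
        ok = profile.ok[idx]
        sums[name] = float(profile.values[idx][ok].sum())
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("no OK signal in any category")
    return pd.Series({name: s / total for name, s in sums.items()})


@dataclass
class ViewpointDendrogram:
    """Average-linkage tree over viewpoints from 1 - Spearman rho distances."""

    correlation: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.correlation.index)

        def walk(node) -> str:
            if node.is_leaf():
                return names[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6f},{right}:{dr:.6f})"

        return walk(tree) + ";"


def cluster_viewpoints(
    profiles: dict[str, NormalizedProfile],
    annotation: DesertAnnotation,
    window: int | None = 11,
) -> ViewpointDendrogram:
    """Hierarchically cluster viewpoints by smoothed long-range profiles.

    Pairwise Spearman rho is computed over desert fragments (cluster
    excluded, window-11 running mean by default), converted to the
    distance 1 - rho, and clustered with average linkage. Leaf order
    follows scipy's deterministic ordering of the input order.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 viewpoints to cluster")
    names = list(profiles)
    vectors = []
    for name in names:
        profile = profiles[name]
        masked = exclude_interval(profile, *annotation.cluster)
        if window is not None:
            masked = running_mean(masked, window)
        fmap = profile.fragment_map
        idx = np.concatenate(
            [fmap.overlapping(*annotation.centromeric),
             fmap.overlapping(*annotation.telomeric)]
        )
        values = np.where(masked.ok[idx], masked.values[idx], np.nan)
        vectors.append(values)
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("profiles do not share common fragment support")
    corr = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            corr[i, j] = corr[j, i] = spearman_correlation(vectors[i], vectors[j])
    corr_df = pd.DataFrame(corr, index=names, columns=names)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(linkage)]
    return ViewpointDendrogram(correlation=corr_df, linkage=linkage, leaf_order=order)
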