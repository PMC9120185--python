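"""Three independent checks of strong-trust isolation.

1. Level-set average correlations: group the 15 vaccine attitudes into the
   five trust bands and average the cross-item phi between each pair of
   bands.  An isolated strong-trust band shows a negative row.
2. Ward hierarchical clustering of the 15 attitude indicator columns
   (attitudes as objects, respondents as features); isolation shows as a
   final merge separating the three strong-trust attitudes from the rest.
3. Neutral overlap: for each non-neutral band, the probability that a
   person holding at least one attitude of that band also holds at least
   one neutral vaccine attitude — a proxy for having something in common
   with a fully neutral person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .attitude_network import trust_band, vaccine_phi_matrix
from .survey_core import SurveyDataset, dummy_code

__all__ = [
    "LevelSetMatrix",
    "Dendrogram",
    "NeutralOverlap",
    "level_set_correlations",
    "ward_cluster",
    "neutral_overlap",
]

BANDS = ["strong-distrust", "weak-distrust", "neutral", "weak-trust", "strong-trust"]
_OVERLAP_BANDS = ["strong-distrust", "weak-distrust", "weak-trust", "strong-trust"]


@dataclass
class LevelSetMatrix:
    """5x5 symmetric table of mean cross-item phi between trust bands."""

    table: pd.DataFrame  # index/columns = BANDS
    n_pairs: pd.DataFrame

    def band_mean(self, a: str, b: str) -> float:
        return float(self.table.loc[a, b])


@dataclass
class Dendrogram:
    """Agglomerative merge tree over attitudes (SciPy linkage encoding)."""

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def final_split(self) -> tuple[set[str], set[str]]:
        """The two clusters present just before the last merge."""
        assignment = fcluster(self.linkage_matrix, t=2, criterion="maxclust")
        a = {lab for lab, c in zip(self.labels, assignment) if c == 1}
        b = {lab for lab, c in zip(self.labels, assignment) if c == 2}
        return a, b

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        root = to_tree(self.linkage_matrix)

        def rec(node, parent_h):
            length = parent_h - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(root.left, root.dist)},{rec(root.right, root.dist)});"

    def merges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage_matrix, columns=["cluster_a", "cluster_b", "height", "size"]
        )


@dataclass
class NeutralOverlap:
    """P(holds >= 1 neutral vaccine attitude | holds >= 1 attitude of band)."""

    proportions: dict[str, float]
    counts: dict[str, int]


def level_set_correlations(data: SurveyDataset) -> LevelSetMatrix:
    """Average cross-item phi between every pair of trust-band sets.

    The diagonal uses cross-item pairs within a band (within-item pairs are
    structurally undefined); bands with no defined pairs get NaN.
    """
    phi, idx = vaccine_phi_matrix(data)
    bands = [trust_band(lv, 5) for _, lv in idx]
    table = pd.DataFrame(np.nan, index=BANDS, columns=BANDS)
    npairs = pd.DataFrame(0, index=BANDS, columns=BANDS)
    for a in BANDS:
        for b in BANDS:
            vals = [
                phi[p, q]
                for p in range(len(idx))
                for q in range(len(idx))
                if p < q
                and {bands[p], bands[q]} == ({a, b} if a != b else {a})
                and not np.isnan(phi[p, q])
            ]
            if vals:
                table.loc[a, b] = table.loc[b, a] = float(np.mean(vals))
            npairs.loc[a, b] = npairs.loc[b, a] = len(vals)
    return LevelSetMatrix(table, npairs)


def ward_cluster(data: SurveyDataset, metric: str = "euclidean") -> Dendrogram:
    """Ward agglomerative clustering of the 15 vaccine attitude columns.

    Objects are the binary attitude indicator columns, features are
    respondents (complete vaccine cases).  Euclidean distance is the
    default (Ward's validity condition); ``metric="correlation"`` is
    available as a sensitivity check.
    """
    vax = [it.item_id for it in data.vaccine_items]
    if len(vax) != 3:
        raise ValueError(f"expected exactly 3 vaccine items, found {len(vax)}")
    complete = data.complete_mask(vax)
    dm = dummy_code(data, vax)
    x = dm.matrix[complete].T.astype(float)  # attitudes x respondents
    if x.shape[1] < 2:
        raise ValueError("need at least 2 complete respondents")
    dist = pdist(x, metric=metric)
    z = linkage(dist, method="ward")
    labels = [f"{i}:{lv}" for i, lv in dm.attitude_index]
    return Dendrogram(z, labels)


def neutral_overlap(data: SurveyDataset) -> NeutralOverlap:
    """Per-band probability of sharing an attitude with a fully neutral person.

    For each band except neutral: among complete-vaccine respondents
    holding at least one vaccine attitude of that band, the proportion who
    also hold at least one neutral (middle-level) vaccine attitude.  The
    neutral band itself is excluded (trivially 1).  Empty subgroups yield
    NaN.
    """
    vax = [it.item_id for it in data.vaccine_items]
    if len(vax) != 3:
        raise ValueError(f"expected exactly 3 vaccine items, found {len(vax)}")
    codes = data.codes(vax).dropna().to_numpy()
    band_level = {"strong-distrust": 1, "weak-distrust": 2, "weak-trust": 4, "strong-trust": 5}
    has_neutral = (codes == 3).any(axis=1)
    props, counts = {}, {}
    for band in _OVERLAP_BANDS:
        holders = (codes == band_level[band]).any(axis=1)
        n = int(holders.sum())
        counts[band] = n
        props[band] = float(has_neutral[holders].mean()) if n else float("nan")
    return NeutralOverlap(props, counts)
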