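"""Phi-correlation attitude networks, bootstrap significance, isolation.

Every response level of every item ("attitude") is a node; the edge weight
between two attitudes of *different* items is their phi coefficient — the
Pearson correlation of the two binary indicator columns.  Within-item pairs
are mutually exclusive by construction and carry no information about the
attitude space, so they are excluded.

Significance of the whole network is assessed with a permutation bootstrap:
each resample independently permutes every item's categorical response
column across respondents, which preserves each indicator column's number
of ones and the one-respondent-one-answer-per-item constraint while
destroying cross-item association.  The test statistic is the sum of
absolute edge weights.

Attitude-isolation is -1 times the average phi between the three
strong-trust vaccine attitudes and the remaining vaccine attitudes: high
values mean strong trust is rarely co-held with anything else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .survey_core import DummyMatrix, SurveyDataset, UndefinedResultError, dummy_code

__all__ = [
    "TRUST_BANDS_5",
    "TRUST_BANDS_4",
    "trust_band",
    "phi_edge",
    "AttitudeNetwork",
    "BootstrapResult",
    "IsolationResult",
    "build_network",
    "network_statistic",
    "permute_items",
    "bootstrap_test",
    "attitude_isolation",
    "export_graph",
]

logger = logging.getLogger(__name__)

TRUST_BANDS_5 = {
    1: "strong-distrust",
    2: "weak-distrust",
    3: "neutral",
    4: "weak-trust",
    5: "strong-trust",
}
TRUST_BANDS_4 = {1: "strong-distrust", 2: "weak-distrust", 3: "weak-trust", 4: "strong-trust"}

_BAND_COLORS = {
    "strong-trust": "#2ca02c",
    "weak-trust": "#9edae5",
    "neutral": "#1f3d7a",
    "weak-distrust": "#ff7f0e",
    "strong-distrust": "#d62728",
}


def trust_band(level: int, n_levels: int) -> str:
    """Map a level code to its trust band (4-level items have no neutral)."""
    table = TRUST_BANDS_5 if n_levels == 5 else TRUST_BANDS_4
    return table[level]


def phi_edge(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient of two binary columns on pairwise-complete rows.

    Equals the Pearson correlation of the indicators, or equivalently
    (n11*n00 - n10*n01) / sqrt(n1. * n0. * n.1 * n.0) from the 2x2
    contingency counts.  NaN entries are dropped pairwise; returns NaN if
    either column is constant on the complete rows (undefined edge).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("columns differ in length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 2:
        return float("nan")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _phi_block(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Cross-phi matrix between two one-hot blocks on complete rows.

    Inputs are (n, La) and (n, Lb) float blocks restricted to rows where
    both items are answered.  Columns with zero variance give NaN.
    """
    n = xa.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    ca, cb = xa - ma, xb - mb
    cov = ca.T @ cb / n
    sa = np.sqrt((ca * ca).mean(axis=0))
    sb = np.sqrt((cb * cb).mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = cov / np.outer(sa, sb)
    phi[~np.isfinite(phi)] = np.nan
    return phi


@dataclass
class AttitudeNetwork:
    """Attitude nodes plus phi-weighted cross-item edges.

    Wraps a :class:`networkx.Graph`; nodes are ``"item:level"`` strings with
    item / level / trust-band attributes, edges carry ``weight``.
    Zero-variance (undefined) edges are omitted and listed in
    ``dropped_edges``; within-item pairs in ``excluded_pairs``.
    """

    graph: nx.Graph
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}


@dataclass
class BootstrapResult:
    """Permutation-bootstrap test of the network against independence."""

    observed_stat: float
    null_stats: np.ndarray
    n_iter: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        assert len(self.null_stats) == self.n_iter


@dataclass
class IsolationResult:
    """Attitude-isolation: -1 x mean phi(strong-trust, other vaccine attitude)."""

    isolation: float
    n_pairs_used: int
    country: str | None = None


def _node_name(item_id: str, level: int) -> str:
    return f"{item_id}:{level}"


def build_network(dm: DummyMatrix) -> AttitudeNetwork:
    """Build the full cross-item phi network from a dummy matrix.

    Edges use pairwise-complete respondents per item pair; negative edges
    are retained.  Raises on a single-item matrix (no cross-item pairs).
    """
    if len(dm.items) < 2:
        raise ValueError("need at least 2 items to build a network")
    g = nx.Graph()
    for it in dm.items:
        for lv in it.levels:
            band = trust_band(lv, it.n_levels)
            g.add_node(
                _node_name(it.item_id, lv),
                item=it.item_id,
                level=lv,
                trust_band=band,
                color=_BAND_COLORS[band],
            )
    excluded, dropped = [], []
    for it in dm.items:
        for a in it.levels:
            for b in it.levels:
                if a < b:
                    excluded.append((_node_name(it.item_id, a), _node_name(it.item_id, b)))

    mat = dm.matrix.astype(float)
    answered = {it.item_id: ~dm.missing_mask(it.item_id) for it in dm.items}
    for i, ita in enumerate(dm.items):
        for itb in dm.items[i + 1 :]:
            rows = answered[ita.item_id] & answered[itb.item_id]
            xa = mat[np.ix_(rows, dm.item_groups[ita.item_id])]
            xb = mat[np.ix_(rows, dm.item_groups[itb.item_id])]
            phi = _phi_block(xa, xb) if rows.sum() >= 2 else np.full(
                (ita.n_levels, itb.n_levels), np.nan
            )
            for ai, a in enumerate(ita.levels):
                for bi, b in enumerate(itb.levels):
                    u, v = _node_name(ita.item_id, a), _node_name(itb.item_id, b)
                    w = phi[ai, bi]
                    if np.isnan(w):
                        dropped.append((u, v))
                        logger.debug("undefined edge omitted: %s -- %s", u, v)
                    else:
                        g.add_edge(u, v, weight=float(w))
    if dropped:
        logger.info("omitted %d undefined (zero-variance) edges", len(dropped))
    return AttitudeNetwork(g, excluded_pairs=excluded, dropped_edges=dropped)


def network_statistic(net: AttitudeNetwork) -> float:
    """Sum of absolute edge weights over the defined edges."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    return float(sum(abs(d["weight"]) for _, _, d in net.graph.edges(data=True)))


def _abs_phi_sum(codes: np.ndarray, n_levels: list[int]) -> float:
    """Fast sum of |phi| over all cross-item attitude pairs.

    ``codes`` is a (n, k) float matrix of level codes with NaN for missing.
    Undefined (zero-variance) edges contribute nothing, mirroring the
    omission rule of :func:`build_network`.
    """
    k = codes.shape[1]
    answered = ~np.isnan(codes)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            rows = answered[:, i] & answered[:, j]
            if rows.sum() < 2:
                continue
            ci, cj = codes[rows, i], codes[rows, j]
            xa = (ci[:, None] == np.arange(1, n_levels[i] + 1)).astype(float)
            xb = (cj[:, None] == np.arange(1, n_levels[j] + 1)).astype(float)
            phi = _phi_block(xa, xb)
            total += np.nansum(np.abs(phi))
    return float(total)


def permute_items(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap resample: permute each item's responses independently.

    Operating on the categorical codes (missing travels with its cell)
    preserves every dummy column's count of ones and the one-answer-per-
    item constraint by construction.
    """
    out = np.empty_like(codes)
    n = codes.shape[0]
    for j in range(codes.shape[1]):
        out[:, j] = codes[rng.permutation(n), j]
    return out


def bootstrap_test(
    data: SurveyDataset,
    item_subset: list[str] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Permutation-bootstrap test of the sum-of-|phi| network statistic.

    Each resample permutes every item's response column independently
    across respondents, preserving per-column counts of ones and zeros and
    the one-hot constraint, then recomputes the statistic.  The p-value
    uses the add-one estimator (1 + #{null >= observed}) / (1 + n_iter), so
    it is never exactly zero; ties count against the observed statistic.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ids = list(item_subset) if item_subset is not None else data.item_ids
    items = [data.item(i) for i in ids]
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    levels = [it.n_levels for it in items]
    codes = data.codes(ids).to_numpy(dtype=float)
    observed = _abs_phi_sum(codes, levels)

    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_iter)
    for b in range(n_iter):
        null_stats[b] = _abs_phi_sum(permute_items(codes, rng), levels)
    p = (1 + int((null_stats >= observed).sum())) / (1 + n_iter)
    return BootstrapResult(observed, null_stats, n_iter, p, seed)


def vaccine_phi_matrix(data: SurveyDataset) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Phi matrix over the 15 vaccine attitudes (NaN on the diagonal blocks).

    Returns the symmetric 15x15 matrix and the (item, level) index.  Entries
    for within-item pairs and undefined edges are NaN.
    """
    vax = data.vaccine_items
    if len(vax) != 3:
        raise ValueError(f"expected exactly 3 vaccine items, found {len(vax)}")
    dm = dummy_code(data, [it.item_id for it in vax])
    net = build_network(dm)
    idx = dm.attitude_index
    k = len(idx)
    phi = np.full((k, k), np.nan)
    pos = {_node_name(i, lv): p for p, (i, lv) in enumerate(idx)}
    for (u, v), w in net.weights().items():
        phi[pos[u], pos[v]] = phi[pos[v], pos[u]] = w
    return phi, idx


def attitude_isolation(
    data: SurveyDataset,
    country: str | None = None,
    include_within_item: bool = False,
) -> IsolationResult:
    """Isolation of the strong-trust vaccine attitudes.

    -1 times the mean phi between the three top-level (code 5) vaccine
    attitudes and the remaining vaccine attitudes.  By default within-item
    pairs are excluded (they are structurally exclusive, never computed in
    the network); ``include_within_item=True`` instead averages over all
    3 x 12 pairs, counting within-item pairs as undefined-and-dropped.
    Undefined pairs are dropped from the mean; positive values mean strong
    trust is isolated from the rest of the vaccine attitude system.
    """
    if country is not None:
        data = data.restrict(country)
    phi, idx = vaccine_phi_matrix(data)
    if include_within_item:
        # within-item pairs are excluded from the network by convention but
        # their phi is well defined; fill them in for this averaging mode
        dm = dummy_code(data, [it.item_id for it in data.vaccine_items])
        mat = dm.matrix.astype(float)
        mat[dm.recover_codes().isna().to_numpy().repeat(5, axis=1)] = np.nan
        for p in range(len(idx)):
            for q in range(p + 1, len(idx)):
                if idx[p][0] == idx[q][0]:
                    phi[p, q] = phi[q, p] = phi_edge(mat[:, p], mat[:, q])
    strong = [p for p, (i, lv) in enumerate(idx) if lv == 5]
    values = []
    for s in strong:
        s_item = idx[s][0]
        for q, (q_item, q_lv) in enumerate(idx):
            if q_lv == 5:
                continue
            if not include_within_item and q_item == s_item:
                continue
            if not np.isnan(phi[s, q]):
                values.append(phi[s, q])
    if not values:
        raise UndefinedResultError("no defined strong-trust pairs")
    return IsolationResult(float(-np.mean(values)), len(values), country)


def export_graph(
    net: AttitudeNetwork, path, dialect: str = "gexf", drop_negative: bool = False
) -> None:
    """Write the network as GEXF or GraphML.

    ``drop_negative=True`` removes negative edges, matching force-directed
    visualisation workflows that cannot handle them; all analyses keep them.
    """
    g = net.graph
    if drop_negative:
        g = g.copy()
        g.remove_edges_from(
            [(u, v) for u, v, d in g.edges(data=True) if d["weight"] < 0]
        )
    dialect = dialect.lower()
    if dialect == "gexf":
        nx.write_gexf(g, path)
    elif dialect == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'gexf' or 'graphml')")
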