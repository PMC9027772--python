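"""Correlation-threshold co-occurrence networks and their topology.

A molecular ecological network for one salinity group is built in three
steps: (1) Pearson correlation of log10 relative abundances across the
group's samples, after a prevalence filter; (2) threshold selection by a
random-matrix-theory spacing criterion — the cutoff is raised until the
nearest-neighbour spacing distribution of the thresholded matrix's
eigenvalues is consistent with Poisson statistics (the GOE→Poisson
transition that marks the removal of noise correlations); (3) an undirected
signed graph over the pairs whose |r| clears the threshold.

Topological indices (density, average degree, Freeman degree
centralization, transitivity, average geodesic distance, greedy-modularity
modules) are computed with networkx, and each is compared against a null
ensemble — degree-preserving double-edge-swap rewirings or Erdős–Rényi
G(n, m) graphs — by z-score and empirical permutation p.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from halosoil.community import OtuTable
from halosoil.exceptions import InputError

_MIN_SPACINGS = 10  # below this the Poisson hypothesis cannot be rejected


@dataclass
class EcoNetwork:
    """Thresholded signed correlation graph for one sample group."""

    graph: nx.Graph
    threshold: float
    group_label: str = ""
    isolated_nodes: list[str] = field(default_factory=list)


@dataclass
class NetworkTopology:
    n_nodes: int
    n_links: int
    density: float
    avg_degree: float
    degree_centralization: float
    transitivity: float
    avg_path_distance: float
    n_modules: int
    modularity: float
    positive_edge_fraction: float

    def as_series(self) -> pd.Series:
        return pd.Series(vars(self))


def correlation_matrix(
    table: OtuTable, prevalence_min: float = 0.5, pseudocount: float | None = None
) -> pd.DataFrame:
    """Pearson correlation of log10 relative abundances between OTUs.

    OTUs present in fewer than ``prevalence_min`` of the group's samples are
    discarded; the remaining relative abundances are shifted by a
    pseudocount (default: the smallest nonzero relative abundance in the
    table) before the log transform. Needs ≥ 4 samples; warns below 10
    retained OTUs.
    """
    if table.n_samples < 4:
        raise InputError(
            f"correlation over {table.n_samples} samples is meaningless; need ≥ 4"
        )
    totals = table.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise InputError("a sample has zero total count")
    rel = table.counts / totals[:, None]
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= prevalence_min
    if keep.sum() < 2:
        raise InputError("fewer than 2 OTUs pass the prevalence filter")
    if keep.sum() < 10:
        warnings.warn(
            f"only {int(keep.sum())} OTUs pass the prevalence filter; "
            "correlations will be unstable",
            stacklevel=2,
        )
    if pseudocount is None:
        nz = rel[rel > 0]
        pseudocount = float(nz.min())
    x = np.log10(rel[:, keep] + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)  # constant OTUs → r = 0
    np.fill_diagonal(corr, 1.0)
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return pd.DataFrame(corr, index=ids, columns=ids)


_ANCHOR_STEP = 5  # unfolding smoothness scale, in eigenvalue ranks


def _spacing_ks_p(mat: np.ndarray) -> float:
    """KS p-value of the unfolded eigenvalue spacings against Exp(1).

    Eigenvalues are collapsed to distinct values (thresholding creates
    large degenerate multiplicities which carry no spacing information)
    and unfolded through a smooth approximation of the spectral CDF — a
    monotone (PCHIP) spline through every 5th point of the empirical CDF.
    The resulting nearest-neighbour spacings, normalized to unit mean, are
    tested against the unit-rate exponential (Poisson statistics); GOE-like
    spectra show level repulsion and are rejected. Fewer than 10 spacings
    cannot reject the Poisson hypothesis and return p = 1.
    """
    eig = np.linalg.eigvalsh(mat)
    distinct = np.unique(np.round(eig, 8))
    m = len(distinct)
    if m - 1 < _MIN_SPACINGS:
        return 1.0
    ecdf = np.arange(1, m + 1) / m
    anchors = np.unique(np.r_[np.arange(0, m, _ANCHOR_STEP), m - 1])
    cdf = PchipInterpolator(distinct[anchors], ecdf[anchors])
    unfolded = m * cdf(distinct)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) < _MIN_SPACINGS:
        return 1.0
    spacings = spacings / spacings.mean()
    return float(stats.kstest(spacings, "expon").pvalue)


def select_threshold_rmt(
    corr, s_grid: np.ndarray | None = None, alpha: float = 0.05
) -> float:
    """Smallest threshold whose spacing statistics are Poisson-compatible.

    For each candidate s the matrix with |r| < s zeroed (diagonal kept) is
    tested by :func:`_spacing_ks_p`; the smallest s with KS p > ``alpha``
    is returned. If no grid value passes, the s with maximal p is returned
    with a warning.
    """
    mat = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, float)
    if mat.shape[0] < 20:
        raise InputError(
            f"matrix is {mat.shape[0]}×{mat.shape[0]}; spacing statistics need ≥ 20 OTUs"
        )
    if s_grid is None:
        s_grid = np.round(np.arange(0.30, 0.951, 0.01), 2)
    best_s, best_p = None, -1.0
    for s in s_grid:
        w = np.where(np.abs(mat) >= s, mat, 0.0)
        np.fill_diagonal(w, np.diag(mat))
        p = _spacing_ks_p(w)
        if p > alpha:
            return float(s)
        if p > best_p:
            best_s, best_p = float(s), p
    warnings.warn(
        f"no grid threshold reached KS p > {alpha}; returning the best "
        f"candidate s = {best_s} (p = {best_p:.3g})",
        stacklevel=2,
    )
    return best_s


def build_network(corr, threshold: float, group_label: str = "") -> EcoNetwork:
    """Signed graph over OTU pairs with |r| ≥ threshold.

    Isolated OTUs (no surviving edge) are removed from the graph and listed
    in ``isolated_nodes``.
    """
    if isinstance(corr, pd.DataFrame):
        ids = list(corr.index)
        mat = corr.to_numpy()
    else:
        mat = np.asarray(corr, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    g = nx.Graph()
    for i, j in zip(*np.nonzero(np.triu(np.abs(mat) >= threshold, k=1))):
        r = float(mat[i, j])
        g.add_edge(ids[i], ids[j], r=r, sign="+" if r >= 0 else "-")
    isolated = [o for o in ids if o not in g]
    return EcoNetwork(graph=g, threshold=float(threshold),
                      group_label=group_label, isolated_nodes=isolated)


def topology(net: EcoNetwork | nx.Graph) -> NetworkTopology:
    """Topological index suite of a co-occurrence network.

    ``avg_path_distance`` averages geodesic lengths over connected pairs
    only; ``n_modules`` counts greedy-modularity communities with ≥ 5
    nodes; ``positive_edge_fraction`` is NaN when edges carry no sign.
    """
    g = net.graph if isinstance(net, EcoNetwork) else net
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        warnings.warn("empty graph: all topology indices reported as 0", stacklevel=2)
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0, 0.0)

    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    avg_degree = 2.0 * m / n
    degrees = np.array([d for _, d in g.degree()])
    if n > 2:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    trans = nx.transitivity(g)

    total, pairs = 0.0, 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(comp) * (len(comp) - 1)
    avg_path = total / pairs if pairs else 0.0

    if m > 0:
        comms = list(nx.algorithms.community.greedy_modularity_communities(g))
        q = nx.algorithms.community.modularity(g, comms)
        n_modules = sum(1 for c in comms if len(c) >= 5)
    else:
        q, n_modules = 0.0, 0

    signs = [d.get("sign") for _, _, d in g.edges(data=True)]
    if m > 0 and all(s is not None for s in signs):
        pos_frac = sum(1 for s in signs if s == "+") / m
    else:
        pos_frac = float("nan")

    return NetworkTopology(
        n_nodes=n, n_links=m, density=density, avg_degree=avg_degree,
        degree_centralization=centralization, transitivity=float(trans),
        avg_path_distance=avg_path, n_modules=n_modules, modularity=float(q),
        positive_edge_fraction=pos_frac,
    )


# indices compared against the null ensemble (sign-free, structure-only)
_NULL_INDICES = [
    "density", "avg_degree", "degree_centralization", "transitivity",
    "avg_path_distance", "n_modules", "modularity",
]


def random_network_test(
    net: EcoNetwork,
    n_random: int = 100,
    seed: int | None = None,
    null_model: str = "degree_preserving",
) -> pd.DataFrame:
    """Compare topology indices against a random-network null ensemble.

    ``degree_preserving`` rewires the observed graph by double edge swaps
    (10 × links swaps per replicate), preserving the degree sequence
    exactly; ``er_gnm`` draws uniform graphs with the same node and edge
    counts. Returns a frame indexed by topology index with columns
    observed, null_mean, null_sd, z, p (two-sided empirical, +1
    correction). Falls back to ``er_gnm`` with a warning when the graph
    admits no valid swap.
    """
    if null_model not in ("degree_preserving", "er_gnm"):
        raise InputError(f"unknown null model {null_model!r}")
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0 or m == 0:
        raise InputError("cannot build a null ensemble for an empty graph")
    if n_random < 30:
        warnings.warn(
            "n_random < 30: null standard deviations will be unreliable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    obs = topology(net).as_series()

    model = null_model
    if model == "degree_preserving" and m < 2:
        warnings.warn(
            "graph too sparse to rewire; falling back to the G(n, m) null",
            stacklevel=2,
        )
        model = "er_gnm"

    null_vals = {ix: [] for ix in _NULL_INDICES}
    for _ in range(n_random):
        rep_seed = int(rng.integers(2**31))
        if model == "degree_preserving":
            h = nx.Graph()
            h.add_nodes_from(g.nodes())
            h.add_edges_from(g.edges())
            try:
                nx.double_edge_swap(h, nswap=10 * m, max_tries=1000 * m, seed=rep_seed)
            except nx.NetworkXError:
                warnings.warn(
                    "rewiring failed; falling back to the G(n, m) null",
                    stacklevel=2,
                )
                model = "er_gnm"
                h = nx.gnm_random_graph(n, m, seed=rep_seed)
        else:
            h = nx.gnm_random_graph(n, m, seed=rep_seed)
        tp = topology(h).as_series()
        for ix in _NULL_INDICES:
            null_vals[ix].append(tp[ix])

    rows = []
    for ix in _NULL_INDICES:
        arr = np.asarray(null_vals[ix], dtype=float)
        mean, sd = arr.mean(), arr.std(ddof=1)
        o = float(obs[ix])
        # indices fixed by the null (e.g. density under rewiring) show only
        # last-ulp jitter; treat those as exactly invariant
        tol = 1e-9 * max(1.0, abs(mean))
        if sd > tol:
            z = (o - mean) / sd
        else:
            z = 0.0 if abs(o - mean) <= tol else np.inf * np.sign(o - mean)
        ge = int(np.sum(arr >= o))
        le = int(np.sum(arr <= o))
        p = min(1.0, 2.0 * min(ge + 1, le + 1) / (n_random + 1))
        rows.append(
            {"index": ix, "observed": o, "null_mean": mean, "null_sd": sd,
             "z": z, "p": p}
        )
    out = pd.DataFrame(rows).set_index("index")
    out.attrs.update({"null_model": model, "n_random": n_random, "seed": seed})
    return out
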