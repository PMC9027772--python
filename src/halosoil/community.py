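"""Diversity and permutation statistics for OTU count tables.

Implements the community-level inference stack from first principles:
rarefaction (without-replacement subsampling to a common depth), per-sample
richness, Faith's phylogenetic diversity, Bray-Curtis dissimilarity,
PERMANOVA (Anderson's pseudo-F with a label-permutation null, global and
pairwise with Holm adjustment), the Mantel test, one-way ANOVA with Tukey
HSD compact letter display, and simple linear R². Permutation p-values use
the +1 correction, p = (1 + #{T_perm ≥ T_obs}) / (1 + n_perm), so p is
never 0 and has resolution 1/(n_perm + 1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from halosoil.exceptions import InputError


@dataclass
class OtuTable:
    """A samples × OTUs integer count matrix with optional taxonomy.

    ``taxonomy`` maps otu_id → semicolon-delimited lineage
    (domain;phylum;class;order;...).
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2-D samples × OTUs matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise InputError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise InputError("counts shape does not match id lists")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                raise InputError(f"{name} ids are not unique")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Samples × OTUs count frame (taxonomy not included)."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            self.counts[idx], list(sample_ids), list(self.otu_ids), self.taxonomy
        )


@dataclass
class TestResult:
    """Outcome of a permutation test (PERMANOVA, Mantel) or F-test."""

    statistic: float
    p_value: float
    n_perm: int = 0
    seed: int | None = None
    effect: float | None = None  # R² for PERMANOVA
    name: str = ""


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a
    warning; rarefying the same table with the same seed is bit-identical.
    """
    if depth < 1:
        raise InputError(f"depth must be ≥ 1, got {depth}")
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise InputError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    new = np.array(
        [rng.multivariate_hypergeometric(row, depth)
         for row in table.counts[keep]],
        dtype=np.int64,
    )
    return OtuTable(
        new,
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.otu_ids),
        table.taxonomy,
    )


def richness(table: OtuTable) -> pd.Series:
    """Number of OTUs observed (count > 0) per sample."""
    return pd.Series((table.counts > 0).sum(axis=1), index=table.sample_ids, name="richness")


def faith_pd(table: OtuTable, tree: TreeNode) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    PD is the total branch length of the minimal subtree connecting the
    OTUs present in a sample, including the path to the root (Faith's
    original definition). Every present OTU must be a leaf of ``tree``.
    """
    present_any = [o for o, c in zip(table.otu_ids, table.counts.sum(axis=0)) if c > 0]
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(set(present_any) - tip_names)
    if missing:
        raise InputError(f"OTUs absent from the tree: {missing}")

    col = {o: j for j, o in enumerate(table.otu_ids)}
    masks, lengths = [], []
    # postorder: each node's OTU-membership mask is the union of its children's
    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = np.zeros(table.n_otus, dtype=bool)
            if node.name in col:
                m[col[node.name]] = True
        else:
            m = np.zeros(table.n_otus, dtype=bool)
            for ch in node.children:
                m |= node_mask[id(ch)]
        node_mask[id(node)] = m
        if node.parent is not None:  # the root carries no branch
            masks.append(m)
            lengths.append(node.length if node.length is not None else 0.0)
    mask_mat = np.array(masks)  # (n_branches, n_otus)
    lengths = np.asarray(lengths, dtype=float)
    presence = table.counts > 0  # (n_samples, n_otus)
    spanned = mask_mat @ presence.T > 0  # (n_branches, n_samples)
    pd_vals = lengths @ spanned
    return pd.Series(pd_vals, index=table.sample_ids, name="faith_pd")


# ---------------------------------------------------------------------------
# beta diversity and permutation tests
# ---------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(i, j) = Σ_k |x_ik − x_jk| / Σ_k (x_ik + x_jk), computed on the counts
    as given (rarefy first so depths are equal).
    """
    x = table.counts.astype(float)
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = (x[i] + x[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(den > 0, num / den, 0.0)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DistanceMatrix(d, ids=table.sample_ids)


def _as_dist(d) -> tuple[np.ndarray, list[str]]:
    if isinstance(d, DistanceMatrix):
        return d.data, list(d.ids)
    arr = np.asarray(d, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Anderson's pseudo-F and R² from a squared distance matrix and labels."""
    n = len(codes)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
        r2 = ss_between / ss_total if ss_total > 0 else np.nan
    return float(f), float(r2)


def permanova(
    dist,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    pairwise: bool = False,
):
    """PERMANOVA on a distance matrix with a label-permutation null.

    The pseudo-F is computed from squared distances:
    SS_total = Σ_{i<j} d²_ij / N; SS_within sums the analogous within-group
    terms; F = (SS_between/(a−1)) / (SS_within/(N−a)). Significance comes
    from ``n_perm`` random permutations of the group labels with the +1
    correction. With ``pairwise=True`` each group pair is additionally
    tested on its sub-matrix and Holm-adjusted.

    Returns a :class:`TestResult` (global test), or
    ``(TestResult, DataFrame)`` when ``pairwise`` is requested.
    """
    d, ids = _as_dist(dist)
    labels = _align_grouping(grouping, ids)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise InputError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        bad = [str(uniq[i]) for i in np.nonzero(sizes < 2)[0]]
        raise InputError(f"singleton group(s): {bad}")
    if n_perm < 99:
        raise InputError(f"n_perm must be ≥ 99, got {n_perm}")

    d2 = d * d
    f_obs, r2 = _pseudo_f(d2, codes, len(uniq))
    if not np.isfinite(f_obs):
        # no variance to partition (e.g., all distances identical and tiny n)
        result = TestResult(np.nan, 1.0, n_perm, seed, effect=r2, name="PERMANOVA")
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            f_p, _ = _pseudo_f(d2, rng.permutation(codes), len(uniq))
            if f_p >= f_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        result = TestResult(f_obs, p, n_perm, seed, effect=r2, name="PERMANOVA")
    if not pairwise:
        return result

    from statsmodels.stats.multitest import multipletests

    rows = []
    rng = np.random.default_rng(seed)
    for ga, gb in itertools.combinations(range(len(uniq)), 2):
        idx = np.nonzero((codes == ga) | (codes == gb))[0]
        sub = DistanceMatrix(d[np.ix_(idx, idx)], ids=[ids[i] for i in idx])
        res = permanova(
            sub, labels[idx], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        rows.append(
            {"group_a": str(uniq[ga]), "group_b": str(uniq[gb]),
             "pseudo_F": res.statistic, "R2": res.effect, "p": res.p_value}
        )
    pw = pd.DataFrame(rows)
    pw["p_holm"] = multipletests(pw["p"], method="holm")[1]
    return result, pw


def _align_grouping(grouping, ids: list[str]) -> np.ndarray:
    if isinstance(grouping, dict):
        try:
            return np.asarray([grouping[i] for i in ids])
        except KeyError as e:
            raise InputError(f"grouping is missing sample {e.args[0]!r}") from e
    if isinstance(grouping, pd.Series):
        if set(ids) <= set(grouping.index):
            return grouping.loc[ids].to_numpy()
        return grouping.to_numpy()
    arr = np.asarray(grouping)
    if len(arr) != len(ids):
        raise InputError("grouping length does not match the distance matrix")
    return arr


def mantel(d1, d2, n_perm: int = 999, seed: int | None = None) -> TestResult:
    """Mantel test: Pearson correlation of two distance matrices.

    The observed r correlates the upper-triangle vectors; the null is built
    by simultaneously permuting rows and columns of the second matrix. The
    p-value is one-sided (greater) with the +1 correction.
    """
    a, ids_a = _as_dist(d1)
    b, ids_b = _as_dist(d2)
    if a.shape != b.shape:
        raise InputError("distance matrices differ in shape")
    if isinstance(d1, DistanceMatrix) and isinstance(d2, DistanceMatrix):
        if list(d1.ids) != list(d2.ids):
            raise InputError("distance matrices carry different sample ids")
    n = a.shape[0]
    if n < 3:
        raise InputError("Mantel needs at least 3 samples")
    iu = np.triu_indices(n, 1)
    va = a[iu]
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(va, b[np.ix_(perm, perm)][iu])[0, 1]
        if r_p >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(r_obs, p, n_perm, seed, name="Mantel")


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def anova_tukey(values, groups, alpha: float = 0.05):
    """One-way ANOVA with Tukey HSD compact letter display.

    Returns ``(F, p, letters)`` where ``letters`` maps group label → letter
    string; groups sharing a letter are not significantly different at
    ``alpha`` by the studentized-range (Tukey-Kramer) criterion. Letters are
    assigned in descending-mean order, so the highest-mean group gets "a".
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        return np.nan, np.nan, {g: "a" for g in uniq}
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise InputError("every group needs at least 2 observations")
    f, p = stats.f_oneway(*samples)

    n_total = len(values)
    k = len(uniq)
    dof = n_total - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / dof
    q_crit = stats.studentized_range.ppf(1 - alpha, k, dof)
    means = np.array([s.mean() for s in samples])
    ns = np.array([len(s) for s in samples])

    order = np.argsort(-means)  # descending mean
    sig = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            sig[i, j] = sig[j, i] = means[i] != means[j]
        else:
            sig[i, j] = sig[j, i] = abs(means[i] - means[j]) / se > q_crit
    letters = _compact_letters(sig, order)
    return float(f), float(p), {uniq[i]: letters[i] for i in range(k)}


def _compact_letters(sig: np.ndarray, order: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``sig`` is the boolean significance matrix; ``order`` ranks groups by
    descending mean and fixes both the processing order and the letter
    naming, making the display deterministic.
    """
    k = sig.shape[0]
    letter_sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for s in list(letter_sets):
            if i in s and j in s:
                letter_sets.remove(s)
                s1, s2 = s - {j}, s - {i}
                # absorb duplicates / subsets
                if not any(s1 <= t for t in letter_sets):
                    letter_sets.append(s1)
                if not any(s2 <= t for t in letter_sets):
                    letter_sets.append(s2)
        letter_sets = [
            s for s in letter_sets
            if not any(s < t for t in letter_sets if t is not s)
        ]
    rank = {g: r for r, g in enumerate(order)}
    # name letters by the best-ranked (highest-mean) group they contain
    letter_sets.sort(key=lambda s: min(rank[g] for g in s))
    out = [""] * k
    for li, s in enumerate(letter_sets):
        ch = chr(ord("a") + li)
        for g in sorted(s, key=lambda g: rank[g]):
            out[g] += ch
    return out


@dataclass
class LinearFit:
    r2: float
    slope: float
    p_value: float
    intercept: float = 0.0


def linear_r2(x, y) -> LinearFit:
    """Simple OLS regression: R² (= squared Pearson r), slope, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("x and y must be equal-length with n ≥ 3")
    res = stats.linregress(x, y)
    return LinearFit(
        r2=float(res.rvalue**2), slope=float(res.slope),
        p_value=float(res.pvalue), intercept=float(res.intercept),
    )


# ---------------------------------------------------------------------------
# taxonomy summaries
# ---------------------------------------------------------------------------

def taxonomy_summary(table: OtuTable, level: int) -> pd.DataFrame:
    """Per-sample relative abundance (%) aggregated at a lineage level.

    ``level`` indexes the semicolon-delimited lineage (0 = domain,
    1 = phylum, ...). Rows are lineages, columns samples; each column sums
    to 100.
    """
    if table.taxonomy is None:
        raise InputError("table has no taxonomy annotations")
    labels = []
    for o in table.otu_ids:
        parts = [p.strip() for p in table.taxonomy.get(o, "").split(";")]
        labels.append(parts[level] if level < len(parts) and parts[level] else "unclassified")
    totals = table.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise InputError("cannot normalize a sample with zero total count")
    rel = 100.0 * table.counts / totals[:, None]
    df = pd.DataFrame(rel.T, index=pd.Index(labels, name="lineage"),
                      columns=table.sample_ids)
    return df.groupby(level=0).sum()


def domain_fraction(table: OtuTable) -> dict[str, float]:
    """Percentage of OTUs per domain (first lineage field), 2 dp."""
    if table.taxonomy is None:
        raise InputError("table has no taxonomy annotations")
    domains = [
        table.taxonomy.get(o, "unclassified").split(";")[0].strip() or "unclassified"
        for o in table.otu_ids
    ]
    counts = pd.Series(domains).value_counts()
    total = counts.sum()
    return {d: round(100.0 * c / total, 2) for d, c in counts.items()}
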