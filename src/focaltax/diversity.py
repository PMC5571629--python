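"""Alpha/beta diversity, rarefaction, ordination and group tests.

Alpha metrics follow the QIIME-1 conventions the field's amplicon
pipelines used: Shannon in log base 2, Chao1 with the classic F1^2/(2 F2)
estimator (bias-corrected form when no doubletons exist), Faith PD
including the branch to the root.  Beta diversity covers unweighted
UniFrac and Bray-Curtis; ordination is classical PCoA with negative
eigenvalues reported; group tests are Welch/permutation t-tests and a
one-factor PERMANOVA with the +1 permutation correction.

Faith PD and UniFrac delegate to scikit-bio; the simple closed-form
metrics and the permutation machinery are implemented here for full
control over seeds and conventions.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .tables import CountTable

__all__ = [
    "rarefy",
    "alpha_diversity",
    "alpha_compare",
    "beta_distance",
    "pcoa",
    "permanova",
    "group_distance_compare",
    "parse_tree",
]


def parse_tree(newick: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(newick))
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity


def rarefy(counts_row: np.ndarray, depth: int, seed=0) -> np.ndarray:
    """Subsample a counts vector to ``depth`` reads without replacement."""
    counts_row = np.asarray(counts_row, dtype=np.int64)
    total = int(counts_row.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds available reads {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts_row, depth)


def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon(row: np.ndarray) -> float:
    total = row.sum()
    p = row[row > 0] / total
    return float(-(p * np.log2(p)).sum())


def alpha_diversity(
    table: CountTable,
    metric: str,
    tree: TreeNode | str | None = None,
    rarefaction_depth: int | None = None,
    seed=0,
) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Returns a frame with columns ``value`` and ``excluded`` (True for
    samples shallower than the rarefaction depth, which are flagged and
    skipped rather than raising).
    """
    metric = metric.lower()
    if metric not in ("observed_otus", "chao1", "shannon", "faith_pd"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        if isinstance(tree, str):
            tree = parse_tree(tree)
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxa if t not in tips]
        if missing:
            raise ValueError(f"tree missing tips for taxa: {missing[:10]}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = table.counts()
    taxa = table.taxa
    values, excluded = [], []
    for i, sample in enumerate(table.samples):
        row = counts[i]
        if rarefaction_depth is not None:
            if row.sum() < rarefaction_depth:
                values.append(np.nan)
                excluded.append(True)
                continue
            row = rarefy(row, rarefaction_depth, rng)
        excluded.append(False)
        if metric == "observed_otus":
            values.append(float((row > 0).sum()))
        elif metric == "chao1":
            values.append(_chao1(row))
        elif metric == "shannon":
            values.append(_shannon(row))
        else:
            # own tip/length validation above; skbio's validator additionally
            # rejects multifurcating roots (e.g. star trees), which are fine
            values.append(float(_skbio_faith_pd(row, taxa=taxa, tree=tree,
                                                validate=False)))
    return pd.DataFrame({"value": values, "excluded": excluded}, index=table.samples)


def _welch_t(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic for 2-D permuted groups."""
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx = X.var(axis=1, ddof=1) / X.shape[1]
    vy = Y.var(axis=1, ddof=1) / Y.shape[1]
    return (mx - my) / np.sqrt(vx + vy)


def _permutation_t_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided label-permutation p for the Welch t statistic, with the
    +1 correction (floor 1/(n_perm+1))."""
    obs = abs(stats.ttest_ind(x, y, equal_var=False).statistic)
    pooled = np.concatenate([x, y])
    nx = len(x)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    t = _welch_t(perms[:, :nx], perms[:, nx:])
    count = int((np.abs(t) >= obs - 1e-12).sum())
    return (count + 1) / (n_perm + 1)


def alpha_compare(
    values: pd.Series,
    groups: pd.Series,
    n_perm: int = 999,
    seed=0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise group comparisons of an alpha-diversity vector.

    Reports plain two-sample t-tests (Welch by default) and Monte-Carlo
    permutation t-tests, both Bonferroni-corrected over the number of
    pairwise comparisons.  Groups with n < 2 are skipped and flagged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = values.dropna()
    groups = groups.loc[values.index]
    levels = sorted(groups.unique(), key=str)
    if sum(len(values[groups == g]) > 0 for g in levels) < 2:
        raise ValueError("need at least two non-empty groups")
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        x = values[groups == a].to_numpy(dtype=float)
        y = values[groups == b].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            rows.append({"group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
                         "skipped": True, "t": np.nan, "p_t": np.nan,
                         "p_t_bonferroni": np.nan, "p_perm": np.nan,
                         "p_perm_bonferroni": np.nan})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        p_perm = _permutation_t_p(x, y, n_perm, rng)
        rows.append({
            "group_a": a, "group_b": b, "n_a": len(x), "n_b": len(y),
            "skipped": False, "t": float(t), "p_t": float(p),
            "p_t_bonferroni": min(1.0, float(p) * m),
            "p_perm": p_perm, "p_perm_bonferroni": min(1.0, p_perm * m),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]


def beta_distance(
    table: CountTable,
    metric: str = "bray_curtis",
    tree: TreeNode | str | None = None,
) -> DistanceMatrix:
    """Pairwise unweighted UniFrac or Bray-Curtis distances.

    Bray-Curtis is computed on raw counts (rarefy upstream if a common
    depth is wanted); UniFrac needs a rooted tree covering all taxa.
    """
    metric = metric.lower()
    counts = table.counts()
    if (counts.sum(axis=1) == 0).any():
        bad = [s for s, d in zip(table.samples, counts.sum(axis=1)) if d == 0]
        raise ValueError(f"all-zero samples: {bad[:5]}")
    if metric == "bray_curtis":
        dm = beta_diversity("braycurtis", counts, ids=table.samples)
    elif metric == "unweighted_unifrac":
        if tree is None:
            raise ValueError("unweighted_unifrac requires a tree")
        if isinstance(tree, str):
            tree = parse_tree(tree)
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxa if t not in tips]
        if missing:
            raise ValueError(f"tree missing tips for taxa: {missing[:10]}")
        # validate=False: skbio's validator rejects multifurcating roots
        dm = beta_diversity("unweighted_unifrac", counts, ids=table.samples,
                            taxa=table.taxa, tree=tree, validate=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data))


def pcoa(dist: DistanceMatrix) -> dict:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the double-centered squared-distance matrix;
    negative eigenvalues are reported, not dropped.  Coordinates span the
    positive-eigenvalue axes, ordered by decreasing eigenvalue.
    """
    D = dist.data
    n = len(dist.ids)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[eigvals > 0].sum()
    explained = np.where(eigvals > 0, eigvals / total, 0.0)
    return {
        "coordinates": pd.DataFrame(
            coords, index=dist.ids,
            columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
        "eigenvalues": eigvals,
        "proportion_explained": explained,
    }


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared distance matrix."""
    n = len(labels)
    k = len(levels)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in levels:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    return (ssa / (k - 1)) / (ssw / (n - k))


def permanova(dist: DistanceMatrix, groups: pd.Series, n_perm: int = 1000, seed=0) -> dict:
    """One-factor PERMANOVA with p = (#{F_perm >= F_obs} + 1)/(n_perm + 1)."""
    labels = groups.loc[dist.ids].to_numpy()
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs n >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d2 = dist.data ** 2
    f_obs = _pseudo_f(d2, labels, levels)
    count = 0
    for _ in range(n_perm):
        f = _pseudo_f(d2, rng.permutation(labels), levels)
        if f >= f_obs - 1e-12:
            count += 1
    return {"pseudo_F": float(f_obs), "p_value": (count + 1) / (n_perm + 1),
            "n_permutations": n_perm}


def group_distance_compare(
    dist: DistanceMatrix,
    groups: pd.Series,
    bootstrap_k: int | None = None,
    seed=0,
) -> dict:
    """Intra- vs inter-group pairwise distances.

    Returns mean +/- SEM per intra(g) and inter(g, g') set, Bonferroni-
    corrected Welch t-tests of each inter set against the corresponding
    intra sets, and (optionally) bootstrap distributions of intragroup
    mean distance (resampling samples within each group ``bootstrap_k``
    times).
    """
    labels = groups.loc[dist.ids]
    levels = sorted(labels.unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    idx_by = {g: np.flatnonzero(labels.to_numpy() == g) for g in levels}
    D = dist.data

    def _pair_values(ii, jj, same):
        if same:
            if len(ii) < 2:
                return np.array([])
            sub = D[np.ix_(ii, ii)]
            return sub[np.triu_indices(len(ii), 1)]
        return D[np.ix_(ii, jj)].ravel()

    sets = {}
    for g in levels:
        sets[("intra", g)] = _pair_values(idx_by[g], None, True)
    for a, b in itertools.combinations(levels, 2):
        sets[("inter", f"{a}|{b}")] = _pair_values(idx_by[a], idx_by[b], False)

    summary_rows = []
    flagged = []
    for (kind, name), vals in sets.items():
        if len(vals) == 0:
            flagged.append(name)
        summary_rows.append({
            "kind": kind, "set": name, "n_pairs": len(vals),
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sem": float(stats.sem(vals)) if len(vals) > 1 else np.nan,
        })
    summary = pd.DataFrame(summary_rows)

    tests = []
    comparisons = [
        (f"{a}|{b}", g)
        for a, b in itertools.combinations(levels, 2) for g in (a, b)
    ]
    m = sum(1 for inter_name, g in comparisons
            if len(sets[("inter", inter_name)]) and len(sets[("intra", g)]) > 1)
    for inter_name, g in comparisons:
        inter_vals = sets[("inter", inter_name)]
        intra_vals = sets[("intra", g)]
        if len(inter_vals) < 2 or len(intra_vals) < 2:
            continue
        t, p = stats.ttest_ind(inter_vals, intra_vals, equal_var=False)
        tests.append({"inter": inter_name, "intra": g, "t": float(t),
                      "p": float(p), "p_bonferroni": min(1.0, float(p) * m)})
    result = {"summary": summary, "tests": pd.DataFrame(tests), "flagged": flagged}

    if bootstrap_k:
        rng = np.random.default_rng(seed)
        boot = {}
        for g in levels:
            ii = idx_by[g]
            if len(ii) < 2:
                continue
            means = []
            for _ in range(bootstrap_k):
                samp = rng.choice(ii, size=len(ii), replace=True)
                uniq = np.unique(samp)
                if len(uniq) < 2:
                    means.append(np.nan)
                    continue
                sub = D[np.ix_(uniq, uniq)]
                means.append(float(np.mean(sub[np.triu_indices(len(uniq), 1)])))
            boot[g] = np.asarray(means)
        result["bootstrap_intragroup_means"] = boot
    return result
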