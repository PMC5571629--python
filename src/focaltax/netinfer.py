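"""Compositional microbial network inference.

Pipeline: aggregate OTU counts to species, keep species present in at
least 20% of samples, centered log-ratio (CLR) transform of pseudocounted
counts, Meinshausen-Buhlmann neighborhood selection (per-node L1-penalized
regression on standardized CLR columns) over a log-spaced penalty path,
StARS stability selection (instability of edge indicators over random
subsamples, threshold beta), and signed-edge extraction from the averaged
coefficient (beta) matrix.

Coefficients are reported on the standardized scale; the penalty grid
lives on the correlation scale of the CLR columns, so lambda >= lambda_max
(the largest absolute off-diagonal correlation) yields an empty graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .tables import CountTable

__all__ = [
    "ClrMatrix",
    "MBFit",
    "StarsResult",
    "SignedNetwork",
    "prepare_matrix",
    "lambda_grid",
    "mb_fit",
    "stars_select",
    "build_network",
    "infer_network",
]


@dataclass
class ClrMatrix:
    """Samples x species CLR-transformed matrix (rows sum to zero)."""

    df: pd.DataFrame
    pseudocount: float

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n(self) -> int:
        return len(self.df)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def prepare_matrix(
    table: CountTable,
    taxonomy: Mapping[str, str] | None = None,
    prevalence_min: float = 0.20,
    pseudocount: float = 1.0,
) -> ClrMatrix:
    """Species aggregation, prevalence filter, CLR.

    ``taxonomy`` maps each OTU to a species label (OTUs of the same
    species are summed); ``None`` means the table is already species
    level.  Species detected in at least ``prevalence_min`` of samples
    are retained (boundary inclusive); CLR is applied to count +
    pseudocount.
    """
    df = table.df
    if taxonomy is not None:
        missing = [t for t in df.columns if t not in taxonomy]
        if missing:
            raise KeyError(f"taxonomy missing OTUs: {missing[:10]}")
        df = df.T.groupby(df.columns.map(lambda c: taxonomy[c])).sum().T
    prevalence = (df > 0).mean(axis=0)
    keep = prevalence[prevalence >= prevalence_min - 1e-12].index
    if len(keep) == 0:
        raise ValueError("no species pass the prevalence filter")
    df = df.loc[:, keep]
    logged = np.log(df.to_numpy(dtype=float) + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(clr, index=df.index, columns=df.columns),
                     pseudocount)


def lambda_grid(clr: ClrMatrix, nlambda: int = 100, min_ratio: float = 0.2) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to lambda_max * min_ratio,
    where lambda_max is the largest absolute off-diagonal correlation of
    the CLR columns."""
    if nlambda < 2:
        raise ValueError("nlambda must be >= 2")
    X = clr.values()
    if X.shape[1] < 2:
        raise ValueError("need at least 2 species")
    corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    lam_max = float(np.nanmax(np.abs(corr)))
    if lam_max < 1e-8:
        warnings.warn("columns appear uncorrelated; lambda_max ~ 0")
        lam_max = 1e-8
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), nlambda)


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if (std == 0).any():
        raise ValueError(f"constant CLR column(s) at index {np.flatnonzero(std == 0)}")
    return (X - mean) / std


@dataclass
class MBFit:
    """Neighborhood-selection fit at one penalty."""

    lam: float
    beta: np.ndarray            # beta[j, i] = coefficient of i in regression of j
    species: list[str]

    @property
    def edges(self) -> set[frozenset]:
        """Union ("or") symmetrization: edge if either direction nonzero."""
        adj = (self.beta != 0) | (self.beta != 0).T
        out = set()
        p = len(self.species)
        for i in range(p):
            for j in range(i + 1, p):
                if adj[i, j]:
                    out.add(frozenset((self.species[i], self.species[j])))
        return out


def mb_fit(clr: ClrMatrix, lam: float) -> MBFit:
    """L1-penalized regression of each standardized CLR column on the rest."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    try:
        Z = _standardize(clr.values())
    except ValueError as exc:
        idx = np.flatnonzero(clr.values().std(axis=0) == 0)
        names = [clr.species[i] for i in idx]
        raise ValueError(f"constant CLR column for species {names}") from exc
    n, p = Z.shape
    beta = np.zeros((p, p))
    model = Lasso(alpha=lam, fit_intercept=False)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Z[:, others], Z[:, j])
        beta[j, others] = model.coef_
    return MBFit(lam=float(lam), beta=beta, species=clr.species)


def _edge_path(Z: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Boolean edge indicators along the penalty path.

    Returns array (L, p, p) of symmetrized (union-rule) adjacency per
    lambda, computed with per-node coordinate-descent paths.
    """
    n, p = Z.shape
    L = len(grid)
    nonzero = np.zeros((L, p, p), dtype=bool)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(Z[:, others], Z[:, j], alphas=grid)
        # lasso_path returns coefs for alphas in the given (descending) order
        nonzero[:, j, others] = (coefs != 0).T
    return nonzero | nonzero.transpose(0, 2, 1)


@dataclass
class StarsResult:
    selected_lambda: float
    selected_index: int
    grid: np.ndarray
    instability: np.ndarray            # D(lambda) along the grid
    instability_monotone: np.ndarray   # running max from sparsest to densest
    edge_stability: pd.DataFrame       # theta_e at the selected lambda
    rep_num: int
    subsample_size: int


def stars_select(
    clr: ClrMatrix,
    grid: np.ndarray,
    rep_num: int = 20,
    beta: float = 0.05,
    subsample_size: int | None = None,
    seed=0,
) -> StarsResult:
    """Stability Approach to Regularization Selection.

    For each lambda, edge-selection frequencies theta_e are estimated over
    ``rep_num`` random subsamples without replacement (default size
    floor(10 sqrt(n)), capped at n-1); the instability D(lambda) is the
    mean over node pairs of 2 theta (1 - theta).  D is monotonized from
    the sparsest end, and the densest lambda with monotonized instability
    <= beta is selected.
    """
    if rep_num < 2:
        raise ValueError("rep_num must be >= 2 (stability is undefined otherwise)")
    grid = np.asarray(grid, dtype=float)
    if not (np.diff(grid) < 0).all():
        raise ValueError("lambda grid must be strictly decreasing")
    n, p = clr.values().shape
    if subsample_size is None:
        subsample_size = min(int(10 * np.sqrt(n)), n - 1)
    if not 1 < subsample_size < n:
        raise ValueError("subsample size must be in (1, n)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    X = clr.values()
    L = len(grid)
    freq = np.zeros((L, p, p))
    for _ in range(rep_num):
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub = X[idx]
        std = sub.std(axis=0)
        if (std == 0).any():
            # degenerate subsample; redraw deterministically by skipping
            std[std == 0] = 1.0
        Z = (sub - sub.mean(axis=0)) / std
        freq += _edge_path(Z, grid)
    theta = freq / rep_num
    iu = np.triu_indices(p, k=1)
    n_pairs = p * (p - 1) / 2
    instability = np.array([
        (2.0 * theta[l][iu] * (1.0 - theta[l][iu])).sum() / n_pairs
        for l in range(L)
    ])
    mono = np.maximum.accumulate(instability)  # sparsest -> densest
    admissible = np.flatnonzero(mono <= beta)
    if len(admissible) == 0:
        # instability exceeds beta everywhere: no model meets the stability
        # target, so fall back to the sparsest (most conservative) penalty
        warnings.warn("all instabilities exceed beta; returning sparsest lambda")
        sel = 0
    else:
        sel = int(admissible.max())
    stab = pd.DataFrame(theta[sel], index=clr.species, columns=clr.species)
    return StarsResult(
        selected_lambda=float(grid[sel]), selected_index=sel, grid=grid,
        instability=instability, instability_monotone=mono,
        edge_stability=stab, rep_num=rep_num, subsample_size=subsample_size,
    )


@dataclass
class SignedNetwork:
    """Undirected species network with signed edges and stability scores."""

    graph: nx.Graph
    selected_lambda: float

    @property
    def species(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "sign": d["sign"],
             "stability": d["stability"], "mean_coefficient": d["mean_coefficient"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign",
                                           "stability", "mean_coefficient"])

    def write_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(fit: MBFit, stability: pd.DataFrame | None = None) -> SignedNetwork:
    """Signed network from an MB fit at the selected penalty.

    Edge sign is the sign of the mean of the two directional coefficients;
    when the mean is exactly zero (cancelling coefficients) the sign of
    the larger-magnitude coefficient is used.
    """
    g = nx.Graph()
    g.add_nodes_from(fit.species)
    p = len(fit.species)
    B = fit.beta
    for i in range(p):
        for j in range(i + 1, p):
            if B[i, j] == 0 and B[j, i] == 0:
                continue
            mean = (B[i, j] + B[j, i]) / 2.0
            if mean != 0:
                sign = "+" if mean > 0 else "-"
            else:
                larger = B[i, j] if abs(B[i, j]) >= abs(B[j, i]) else B[j, i]
                sign = "+" if larger > 0 else "-"
            si, sj = fit.species[i], fit.species[j]
            stab = float(stability.loc[si, sj]) if stability is not None else float("nan")
            g.add_edge(si, sj, sign=sign, stability=stab,
                       mean_coefficient=float(mean))
    return SignedNetwork(graph=g, selected_lambda=fit.lam)


def infer_network(
    table: CountTable,
    taxonomy: Mapping[str, str] | None = None,
    prevalence_min: float = 0.20,
    pseudocount: float = 1.0,
    nlambda: int = 100,
    min_ratio: float = 0.2,
    rep_num: int = 20,
    beta: float = 0.05,
    subsample_size: int | None = None,
    seed=0,
) -> tuple[SignedNetwork, StarsResult]:
    """Full pipeline: prepare -> grid -> StARS -> final fit -> signed network."""
    clr = prepare_matrix(table, taxonomy, prevalence_min, pseudocount)
    grid = lambda_grid(clr, nlambda=nlambda, min_ratio=min_ratio)
    stars = stars_select(clr, grid, rep_num=rep_num, beta=beta,
                         subsample_size=subsample_size, seed=seed)
    fit = mb_fit(clr, stars.selected_lambda)
    net = build_network(fit, stars.edge_stability)
    return net, stars
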