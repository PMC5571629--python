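"""Network robustness: centralities, natural connectivity, attacks.

Natural connectivity is a closed-walk robustness index derived from the
eigenvalues of the (unweighted, undirected) adjacency matrix.  Two modes
ship because the index appears in the literature in slightly different
normalizations:

* ``standard``: ln((1/N) sum_i exp(lambda_i)) / (N - ln N) — the mean
  eigenvalue-exponential; an edgeless graph scores exactly 0.
* ``literal``: ln(sum_i exp(lambda_i)) / (N - ln N) — the plain Estrada
  index numerator.

Comparisons between networks must use a single mode; ``standard`` is the
default everywhere.

Attack simulations remove nodes sequentially (highest degree, highest
betweenness, or uniformly at random), by default recomputing the ordering
metric after every removal, recording natural connectivity along the way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .netinfer import SignedNetwork, infer_network
from .screening import DetectionMatrix, rank_test
from .tables import CountTable

__all__ = [
    "centrality",
    "natural_connectivity",
    "attack_simulation",
    "AttackResult",
    "ConnectivityDistribution",
    "connectivity_distribution",
    "select_controls",
]


def _as_graph(net) -> nx.Graph:
    if isinstance(net, SignedNetwork):
        return net.graph
    if isinstance(net, nx.Graph):
        return net
    raise TypeError("expected a SignedNetwork or networkx Graph")


def centrality(net, metric: str = "degree") -> pd.Series:
    """Per-node centrality normalized by its theoretical maximum.

    degree / (N - 1); betweenness (unweighted shortest-path fraction)
    divided by (N - 1)(N - 2)/2.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if metric == "degree":
        if n < 2:
            raise ValueError("degree centrality needs N >= 2")
        vals = {v: d / (n - 1) for v, d in g.degree()}
    elif metric == "betweenness":
        if n < 3:
            raise ValueError("betweenness centrality needs N >= 3")
        vals = nx.betweenness_centrality(g, normalized=True)
    else:
        raise ValueError(f"unknown centrality metric {metric!r}")
    return pd.Series(vals).sort_index()


def natural_connectivity(net, mode: str = "standard") -> float:
    """Closed-walk robustness index from adjacency eigenvalues."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity is undefined for an empty graph")
    if mode not in ("standard", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    if n == 1:
        eig = np.zeros(1)
    else:
        A = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str), weight=None)
        eig = np.linalg.eigvalsh(A)
    denom = n - np.log(n)
    if mode == "standard":
        return float((logsumexp(eig) - np.log(n)) / denom)
    return float(logsumexp(eig) / denom)


@dataclass
class AttackResult:
    """Sequential node-removal trajectory.

    ``trajectory`` rows cover remaining network sizes N, N-1, ..., 1 (the
    initial network plus the state after each of the first N-1 removals).
    """

    ordering: str
    trajectory: pd.DataFrame     # columns: remaining, natural_connectivity, removed
    mode: str
    seed: int | None = None

    def curve(self) -> np.ndarray:
        return self.trajectory["natural_connectivity"].to_numpy()

    def auc(self) -> float:
        """Area under the connectivity-vs-remaining-size curve."""
        return float(np.trapezoid(self.curve()[::-1]))


def attack_simulation(
    net,
    ordering: str = "degree",
    seed=None,
    mode: str = "standard",
    adaptive: bool = True,
) -> AttackResult:
    """Remove nodes one at a time and track natural connectivity.

    ``ordering``: "degree" or "betweenness" (remove the current maximum,
    ties broken by lexicographic node label) or "random" (uniform,
    seed-reproducible).  With ``adaptive=False`` the removal order is
    fixed from the initial ranking.
    """
    if ordering not in ("degree", "betweenness", "random"):
        raise ValueError(f"unknown ordering {ordering!r}")
    g = _as_graph(net).copy()
    n0 = g.number_of_nodes()
    if n0 == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(seed)

    def _pick(h: nx.Graph) -> str:
        if ordering == "random":
            nodes = sorted(h.nodes, key=str)
            return nodes[rng.integers(len(nodes))]
        if ordering == "degree":
            scores = dict(h.degree())
        else:
            scores = nx.betweenness_centrality(h, normalized=False)
        best = max(scores.values())
        return min((v for v, s in scores.items() if s == best), key=str)

    fixed_order: list[str] = []
    if not adaptive and ordering != "random":
        scores = (dict(g.degree()) if ordering == "degree"
                  else nx.betweenness_centrality(g, normalized=False))
        fixed_order = [v for v, _ in sorted(scores.items(),
                                            key=lambda kv: (-kv[1], str(kv[0])))]

    rows = [{"remaining": n0, "natural_connectivity": natural_connectivity(g, mode),
             "removed": None}]
    for step in range(n0 - 1):
        victim = fixed_order[step] if fixed_order else _pick(g)
        g.remove_node(victim)
        rows.append({
            "remaining": g.number_of_nodes(),
            "natural_connectivity": natural_connectivity(g, mode),
            "removed": victim,
        })
    return AttackResult(ordering=ordering, trajectory=pd.DataFrame(rows),
                        mode=mode, seed=seed)


@dataclass
class ConnectivityDistribution:
    condition: str
    values: np.ndarray
    iterations: int
    subsample: int


def connectivity_distribution(
    table: CountTable,
    detection: DetectionMatrix | pd.Series,
    condition_taxon: str,
    iterations: int = 100,
    subsample: int = 1000,
    seed=0,
    mode: str = "standard",
    taxonomy=None,
    **netinfer_kwargs,
) -> dict:
    """Natural-connectivity distributions under taxon presence/absence.

    Per iteration, ``subsample`` samples are drawn without replacement
    from the taxon-positive and taxon-negative strata, the full network
    inference pipeline is run on each draw (the condition taxon itself is
    excluded from the inferred network), and natural connectivity of the
    resulting network is recorded.  The two distributions are compared
    with a one-sided Mann-Whitney test (alternative: presence greater).
    """
    if iterations < 2:
        raise ValueError("need iterations >= 2 for the rank test")
    if isinstance(detection, DetectionMatrix):
        if condition_taxon in detection.df.columns:
            positive = detection.df[condition_taxon]
        else:
            positive = detection.any_positive()
    else:
        positive = detection.astype(bool)
    positive = positive.loc[table.df.index]
    pos_ids = list(positive.index[positive])
    neg_ids = list(positive.index[~positive])
    for label, ids in (("positive", pos_ids), ("negative", neg_ids)):
        if len(ids) < subsample:
            raise ValueError(
                f"{label} condition has {len(ids)} samples; need >= {subsample}")

    work = table
    if condition_taxon in work.df.columns:
        work = CountTable(work.df.drop(columns=[condition_taxon]))

    rng = np.random.default_rng(seed)
    out = {}
    for label, ids in (("present", pos_ids), ("absent", neg_ids)):
        vals = []
        for _ in range(iterations):
            draw = rng.choice(len(ids), size=subsample, replace=False)
            sub = work.subset_samples([ids[i] for i in draw])
            net, _ = infer_network(sub, taxonomy=taxonomy,
                                   seed=rng.integers(2**31 - 1),
                                   **netinfer_kwargs)
            vals.append(natural_connectivity(net, mode))
        out[label] = ConnectivityDistribution(label, np.asarray(vals),
                                              iterations, subsample)
    _, p = rank_test(out["present"].values, out["absent"].values,
                     kind="mann_whitney_one_sided")
    return {"present": out["present"], "absent": out["absent"],
            "p_one_sided": float(p)}


def select_controls(
    table: CountTable,
    focal: str | Sequence[str],
    prevalence_range: tuple[float, float] = (0.30, 0.40),
    abundance_range: tuple[float, float] = (1e-3, 1e-2),
) -> list[str]:
    """Control taxa matched to the focal taxon's population parameters.

    Returns species whose detection rate lies within ``prevalence_range``
    and whose geometric-mean nonzero relative abundance lies within
    ``abundance_range``, excluding the focal taxa themselves.
    """
    focal_set = {focal} if isinstance(focal, str) else set(focal)
    rel = table.relative()
    prevalence = (table.df > 0).mean(axis=0)
    out = []
    for taxon in table.taxa:
        if taxon in focal_set:
            continue
        prev = float(prevalence[taxon])
        if not prevalence_range[0] <= prev <= prevalence_range[1]:
            continue
        vals = rel[taxon][table.df[taxon] > 0].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        geo = float(np.exp(np.mean(np.log(vals))))
        if abundance_range[0] <= geo <= abundance_range[1]:
            out.append(taxon)
    if not out:
        warnings.warn("no control taxa matched the requested ranges")
    return out
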