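"""Synthetic cohort generation with known ground truth.

Emulates an American-Gut-style 16S survey at desk scale: subjects providing
1-5 longitudinal fecal samples, categorical/continuous host covariates with
missing values, log-normal sequencing depths, 2-3 focal OTUs whose
detection and abundance follow a zero-inflated negative-binomial model with
log-depth offsets, and a background community whose latent log-abundances
follow a known sparse conditional-dependence (precision-matrix) graph,
observed as compositional counts.

Every generator takes an explicit seed (or numpy Generator) and is
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import CountTable

__all__ = [
    "CovariateSpec",
    "CohortSpec",
    "FocalModelTruth",
    "CommunityTruth",
    "default_cohort_spec",
    "default_focal_truths",
    "chain_precision",
    "hub_precision",
    "gen_metadata",
    "gen_focal_counts",
    "gen_community",
    "gen_tree",
    "assemble_dataset",
    "Dataset",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass
class CovariateSpec:
    """One host covariate.

    For categorical covariates ``levels`` and ``probs`` give the level set
    and sampling probabilities; for continuous covariates ``mean``/``sd``
    parameterize a normal draw.  ``missing_rate`` is the Bernoulli rate at
    which observed values are masked (the generative truth is untouched).
    """

    name: str
    kind: str  # "continuous" | "categorical"
    levels: Sequence[str] | None = None
    probs: Sequence[float] | None = None
    mean: float = 0.0
    sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical covariate {self.name} needs levels")
            if self.probs is None:
                self.probs = [1.0 / len(self.levels)] * len(self.levels)
            p = np.asarray(self.probs, dtype=float)
            self.probs = (p / p.sum()).tolist()


@dataclass
class CohortSpec:
    """Cohort layout: subjects, repeat sampling, covariates, depths."""

    n_subjects: int
    samples_per_subject_probs: Sequence[float] = (0.963, 0.020, 0.009, 0.005, 0.003)
    covariates: Sequence[CovariateSpec] = ()
    depth_log_mean: float = float(np.log(2e4))  # median 20,000 reads
    depth_log_sd: float = 0.55
    site_probs: Mapping[str, float] = field(
        default_factory=lambda: {"feces": 0.95, "skin": 0.02, "tongue": 0.03}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        p = np.asarray(self.samples_per_subject_probs, dtype=float)
        if len(p) != 5 or (p < 0).any() or p.sum() <= 0:
            raise ValueError("samples_per_subject_probs must be 5 non-negative weights")
        self.samples_per_subject_probs = (p / p.sum()).tolist()


@dataclass
class FocalModelTruth:
    """Generating parameters for one focal OTU.

    Coefficient mappings are keyed by ``"intercept"``, a continuous
    covariate name, or ``(covariate, level)`` for categorical dummies.
    The zero-inflation logit and the NB log-mean both receive the
    log-depth offset with coefficient 1.  ``coupling`` is the log-odds
    boost of detection contributed by a latent Bernoulli factor shared
    across focal OTUs (drives co-detection).
    """

    logit_coefficients: Mapping
    nb_coefficients: Mapping
    nb_dispersion: float
    coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class CommunityTruth:
    """Sparse Gaussian graphical model for latent log-abundances."""

    precision: np.ndarray
    base_log_abundance: np.ndarray | None = None
    names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("precision must be square")
        if not np.allclose(P, P.T):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("precision must be positive definite")
        self.precision = P
        p = P.shape[0]
        if self.base_log_abundance is None:
            self.base_log_abundance = np.zeros(p)
        self.base_log_abundance = np.asarray(self.base_log_abundance, dtype=float)
        if self.base_log_abundance.shape != (p,):
            raise ValueError("base_log_abundance length mismatch")
        if self.names is None:
            self.names = [f"sp{i:03d}" for i in range(p)]
        if len(set(self.names)) != p:
            raise ValueError("duplicate species names")

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def edges(self) -> set[frozenset]:
        """Edge set = off-diagonal non-zeros of the precision matrix."""
        out = set()
        P = self.precision
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if P[i, j] != 0:
                    out.add(frozenset((self.names[i], self.names[j])))
        return out


def chain_precision(p: int, strength: float = 0.3) -> np.ndarray:
    """Tridiagonal precision: species i conditionally depends on i-1, i+1."""
    P = np.eye(p)
    idx = np.arange(p - 1)
    P[idx, idx + 1] = P[idx + 1, idx] = -strength
    return P


def hub_precision(p: int, hub_size: int = 6, strength: float = 0.3) -> np.ndarray:
    """Union of star motifs: every block of ``hub_size`` nodes has a hub.

    A single hub of degree p-1 cannot keep useful partial-correlation
    strength and positive definiteness at the same time, so the hub
    topology is realized as several moderate-degree hubs.
    """
    P = np.eye(p)
    for start in range(0, p - hub_size + 1, hub_size):
        hub = start
        for leaf in range(start + 1, start + hub_size):
            P[hub, leaf] = P[leaf, hub] = -strength
    return P


def default_cohort_spec(n_subjects: int = 500, seed: int = 0) -> CohortSpec:
    """AGP-like defaults: age/sex/race/BMI/antibiotics/country covariates."""
    covs = [
        CovariateSpec("age", "continuous", mean=46.1, sd=17.3, missing_rate=0.05),
        CovariateSpec("sex", "categorical", ["Female", "Male"], [0.55, 0.45],
                      missing_rate=0.045),
        CovariateSpec("race", "categorical",
                      ["Caucasian", "Asian", "Hispanic", "AfricanAmerican", "Other"],
                      [0.88, 0.05, 0.02, 0.01, 0.04], missing_rate=0.016),
        CovariateSpec("bmi_cat", "categorical",
                      ["Underweight", "Normal", "Overweight", "Obese"],
                      [0.10, 0.59, 0.21, 0.10], missing_rate=0.066),
        CovariateSpec("antibiotic_history", "categorical",
                      [">365d", "<365d", "<180d", "<30d", "<7d"],
                      [0.68, 0.15, 0.12, 0.03, 0.02], missing_rate=0.025),
        CovariateSpec("country", "categorical",
                      ["USA", "UK", "Other"], [0.76, 0.17, 0.07], missing_rate=0.0),
    ]
    return CohortSpec(n_subjects=n_subjects, covariates=covs, seed=seed)


def default_focal_truths(coupling: float = 2.0) -> dict[str, FocalModelTruth]:
    """Two dominant focal OTUs plus one rare one, loosely mirroring the
    prevalence/abundance layering seen for the studied organism (a common
    OTU around 30% prevalence, a rarer one ~10x lower in abundance)."""
    common = {
        "intercept": -9.0, "age": -0.02, ("sex", "Male"): 0.4,
        ("bmi_cat", "Obese"): 0.8, ("country", "UK"): -1.2,
    }
    common_nb = {
        "intercept": -8.3, "age": 0.004, ("sex", "Male"): -0.12,
        ("bmi_cat", "Obese"): -0.7,
    }
    return {
        "focalA": FocalModelTruth(common, common_nb, nb_dispersion=0.7,
                                  coupling=coupling),
        "focalB": FocalModelTruth(
            {**common, "intercept": -7.8}, {**common_nb, "intercept": -10.0},
            nb_dispersion=0.7, coupling=coupling),
        "focalC": FocalModelTruth(
            {**common, "intercept": -6.5}, {**common_nb, "intercept": -11.5},
            nb_dispersion=0.7, coupling=coupling),
    }


# ---------------------------------------------------------------------------
# generators


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _gen_metadata_full(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (complete, observed) metadata; observed has missingness."""
    rng = np.random.default_rng(spec.seed)
    n_per = rng.choice(np.arange(1, 6), size=spec.n_subjects,
                       p=spec.samples_per_subject_probs)
    rows = []
    for s, k in enumerate(n_per):
        subject = f"subj{s:05d}"
        for order in range(1, k + 1):
            rows.append((f"{subject}.s{order}", subject, order))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "collection_order"])
    meta = meta.set_index("sample_id")
    n = len(meta)

    sites = list(spec.site_probs)
    site_p = np.asarray(list(spec.site_probs.values()), dtype=float)
    meta["body_site"] = rng.choice(sites, size=n, p=site_p / site_p.sum())

    # covariates are a subject-level property, shared across repeat samples
    subj_ids = meta["subject_id"].to_numpy()
    uniq, inverse = np.unique(subj_ids, return_inverse=True)
    for cov in spec.covariates:
        if cov.kind == "continuous":
            vals = rng.normal(cov.mean, cov.sd, size=len(uniq))
        else:
            vals = rng.choice(list(cov.levels), size=len(uniq), p=cov.probs)
        meta[cov.name] = vals[inverse]

    observed = meta.copy()
    for cov in spec.covariates:
        if cov.missing_rate > 0:
            mask = rng.random(len(uniq)) < cov.missing_rate
            observed.loc[mask[inverse], cov.name] = np.nan
    return meta, observed


def gen_metadata(spec: CohortSpec) -> pd.DataFrame:
    """Per-sample metadata table; missing values injected at the stated
    rates.  The complete (pre-masking) covariates are attached under
    ``result.attrs["complete"]`` so that count generation can condition on
    truth rather than on observed values."""
    complete, observed = _gen_metadata_full(spec)
    observed.attrs["complete"] = complete
    return observed


def _design_row_value(meta: pd.DataFrame, key) -> np.ndarray:
    if key == "intercept":
        return np.ones(len(meta))
    if isinstance(key, tuple):
        cov, level = key
        return (meta[cov].astype(object) == level).to_numpy(dtype=float)
    return meta[key].to_numpy(dtype=float)


def _linear_predictor(meta: pd.DataFrame, coefs: Mapping) -> np.ndarray:
    eta = np.zeros(len(meta))
    for key, c in coefs.items():
        eta = eta + c * _design_row_value(meta, key)
    return eta


def gen_focal_counts(
    meta: pd.DataFrame,
    truths: Mapping[str, FocalModelTruth],
    depths: np.ndarray,
    seed=0,
) -> CountTable:
    """Zero-inflated NB counts for the focal OTUs.

    For sample i the count is 0 with probability
    pi_i = logistic(x_i' gamma + log T_i - coupling * Z_i) and otherwise
    NB with mean T_i * exp(x_i' beta) and dispersion k, where Z_i is the
    shared Bernoulli(0.5) co-detection factor.
    """
    depths = np.asarray(depths, dtype=float)
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if len(depths) != len(meta):
        raise ValueError("depths length must match metadata")
    rng = _rng(seed)
    log_T = np.log(depths)
    shared = rng.binomial(1, 0.5, size=len(meta)).astype(float)
    cols = {}
    for name, truth in truths.items():
        eta0 = _linear_predictor(meta, truth.logit_coefficients) + log_T
        eta0 = eta0 - truth.coupling * shared
        pi = 1.0 / (1.0 + np.exp(-eta0))
        mu = depths * np.exp(_linear_predictor(meta, truth.nb_coefficients))
        k = truth.nb_dispersion
        structural_zero = rng.random(len(meta)) < pi
        counts = rng.negative_binomial(k, k / (k + mu))
        counts[structural_zero] = 0
        cols[name] = counts
    return CountTable(pd.DataFrame(cols, index=meta.index))


def gen_community(n: int, truth: CommunityTruth, depths: np.ndarray, seed=0) -> CountTable:
    """Logistic-normal-multinomial community counts.

    Latent vectors are multivariate normal with covariance equal to the
    inverse of the precision matrix (plus the base log-abundance mean);
    softmax maps them to proportions, and each sample is a multinomial
    draw at its depth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    depths = np.asarray(depths)
    if len(depths) != n:
        raise ValueError("depths length must equal n")
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    rng = _rng(seed)
    cov = np.linalg.inv(truth.precision)
    latent = rng.multivariate_normal(truth.base_log_abundance, cov, size=n,
                                     method="cholesky")
    latent -= latent.max(axis=1, keepdims=True)  # softmax stabilization
    props = np.exp(latent)
    props /= props.sum(axis=1, keepdims=True)
    counts = np.vstack([
        rng.multinomial(int(depths[i]), props[i]) for i in range(n)
    ])
    index = [f"s{i:05d}" for i in range(n)]
    return CountTable(pd.DataFrame(counts, index=index, columns=list(truth.names)))


def gen_tree(taxa: Sequence[str], seed=0, rate: float = 1.0) -> str:
    """Random rooted binary tree over ``taxa`` with exponential branch
    lengths; returned as a Newick string."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    rng = _rng(seed)
    nodes = [f"{t}:{rng.exponential(rate):.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")  # root: no branch above
        else:
            nodes.append(f"({a},{b}):{rng.exponential(rate):.6f}")
    return nodes[0] + ";"


@dataclass
class Dataset:
    """Assembled synthetic dataset plus its generating truth."""

    table: CountTable
    meta: pd.DataFrame
    tree_newick: str
    truth: dict


def assemble_dataset(
    spec: CohortSpec,
    focal_truths: Mapping[str, FocalModelTruth],
    community_truth: CommunityTruth,
) -> Dataset:
    """Community + focal counts on a shared cohort.

    Row sums equal the drawn community depth plus the focal counts (focal
    reads are appended on top of the community depth rather than carved
    out of it; focal taxa are rare, so the distortion is negligible and
    documented).
    """
    collision = set(focal_truths) & set(community_truth.names)
    if collision:
        raise ValueError(f"taxon name collision: {sorted(collision)}")
    meta = gen_metadata(spec)
    complete = meta.attrs["complete"]
    rng = np.random.default_rng(spec.seed + 1)
    n = len(meta)
    depths = np.maximum(
        1, np.round(rng.lognormal(spec.depth_log_mean, spec.depth_log_sd, size=n))
    ).astype(int)
    community = gen_community(n, community_truth, depths,
                              seed=np.random.default_rng(spec.seed + 2))
    community.df.index = meta.index
    focal = gen_focal_counts(complete, focal_truths, depths,
                             seed=np.random.default_rng(spec.seed + 3))
    table = CountTable(pd.concat([community.df, focal.df], axis=1))
    tree = gen_tree(table.taxa, seed=spec.seed + 4)
    truth = {
        "focal": {name: t for name, t in focal_truths.items()},
        "community": community_truth,
        "depths": depths,
    }
    return Dataset(table=table, meta=meta, tree_newick=tree, truth=truth)
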