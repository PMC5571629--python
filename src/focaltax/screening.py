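"""Sample filtering, focal-taxon detection and co-occurrence analysis.

Implements the screening stage of a focal-taxon survey: depth/site/repeat
filtering, presence calls, prevalence and abundance summaries (geometric
mean relative abundance over detected samples), a hypergeometric
co-occurrence overlap test, one-sided abundance-shift rank tests, and
longitudinal colonization grouping for subjects with repeat samples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable

__all__ = [
    "DetectionMatrix",
    "FilterResult",
    "OverlapResult",
    "LongitudinalResult",
    "filter_and_dedup",
    "detect_focal",
    "summarize_focal",
    "overlap_test",
    "codetection_shift",
    "longitudinal_groups",
    "rank_test",
]

#: combined sample size at or below which rank tests use exact enumeration
EXACT_N = 12


@dataclass
class DetectionMatrix:
    """Boolean samples x focal-taxa presence calls."""

    df: pd.DataFrame  # bool
    threshold: int

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    def any_positive(self) -> pd.Series:
        return self.df.any(axis=1)

    def n_detected(self) -> pd.Series:
        return self.df.sum(axis=1)


@dataclass
class FilterResult:
    table: CountTable
    meta: pd.DataFrame
    retention: dict  # step -> samples remaining


def filter_and_dedup(
    table: CountTable,
    meta: pd.DataFrame,
    min_depth: int = 10_000,
    site: str = "feces",
) -> FilterResult:
    """Keep samples with depth >= ``min_depth`` from ``site``; subjects
    with several retained samples are represented only by the earliest
    (smallest collection order).  Idempotent."""
    for col in ("subject_id", "collection_order", "body_site"):
        if col not in meta.columns:
            raise KeyError(f"metadata missing required column {col!r}")
    valid_sites = sorted(meta["body_site"].dropna().unique())
    if site not in valid_sites:
        raise ValueError(f"unknown body site {site!r}; valid sites: {valid_sites}")
    meta = meta.loc[table.samples]
    retention = {"initial": len(meta)}

    deep = table.depths >= min_depth
    keep = meta.index[deep.loc[meta.index]]
    retention["depth"] = len(keep)

    meta2 = meta.loc[keep]
    keep = meta2.index[meta2["body_site"] == site]
    retention["site"] = len(keep)

    meta3 = meta.loc[keep]
    first = meta3.sort_values("collection_order").groupby("subject_id").head(1)
    keep = meta.index[meta.index.isin(first.index)]  # original order
    retention["dedup"] = len(keep)

    return FilterResult(table.subset_samples(list(keep)), meta.loc[keep], retention)


def detect_focal(table: CountTable, focal_ids: Sequence[str], threshold: int = 1) -> DetectionMatrix:
    """Presence call: count >= threshold."""
    missing = [t for t in focal_ids if t not in table.df.columns]
    if missing:
        raise KeyError(f"focal taxa not in table: {missing}")
    sub = table.df.loc[:, list(focal_ids)]
    return DetectionMatrix(df=sub >= threshold, threshold=threshold)


def summarize_focal(table: CountTable, detection: DetectionMatrix) -> pd.DataFrame:
    """Per-focal-taxon prevalence and abundance summary.

    Columns: prevalence_pct (% samples detected), read_share_pct (% of the
    summed focal reads), geo_mean_rel_abund (geometric mean of relative
    abundance over DETECTED samples only; NaN when never detected),
    min/max_rel_abund over detected samples.
    """
    focal = list(detection.df.columns)
    rel = table.relative()[focal]
    counts = table.df[focal]
    total_focal_reads = counts.to_numpy().sum()
    rows = {}
    n = len(table.samples)
    for t in focal:
        det = detection.df[t]
        nd = int(det.sum())
        if nd:
            vals = rel.loc[det, t].to_numpy(dtype=float)
            geo = float(np.exp(np.mean(np.log(vals))))
            lo, hi = float(vals.min()), float(vals.max())
        else:
            geo = lo = hi = float("nan")
        share = 100.0 * counts[t].sum() / total_focal_reads if total_focal_reads else float("nan")
        rows[t] = {
            "prevalence_pct": 100.0 * nd / n,
            "n_detected": nd,
            "read_share_pct": share,
            "geo_mean_rel_abund": geo,
            "min_rel_abund": lo,
            "max_rel_abund": hi,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class OverlapResult:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    codetection_pct: float        # overlap as % of universe
    conditional_pct: float        # |A & B| / |B| x 100
    p_value: float                # hypergeometric upper tail


def overlap_test(detection: DetectionMatrix, taxon_a: str, taxon_b: str) -> OverlapResult:
    """One-sided hypergeometric test for co-detection overlap >= observed,
    conditioning on the marginal prevalences in the shared universe."""
    n = len(detection.df)
    if n == 0:
        raise ValueError("empty sample universe")
    a = detection.df[taxon_a].to_numpy()
    b = detection.df[taxon_b].to_numpy()
    na, nb = int(a.sum()), int(b.sum())
    k = int((a & b).sum())
    # P(X >= k) with X ~ Hypergeom(N=n, K=na, n=nb)
    p = float(stats.hypergeom.sf(k - 1, n, na, nb))
    cond = 100.0 * k / nb if nb else float("nan")
    return OverlapResult(n, na, nb, k, 100.0 * k / n, cond, p)


def codetection_shift(
    table: CountTable,
    detection: DetectionMatrix,
    taxon: str,
    other: str,
):
    """Is ``taxon`` more abundant when ``other`` is co-detected?

    One-sided Mann-Whitney comparing relative abundance of ``taxon`` in
    samples where only ``taxon`` is detected against samples where both
    are detected (alternative: co-detected greater).
    """
    det_t = detection.df[taxon]
    det_o = detection.df[other]
    only = det_t & ~det_o
    both = det_t & det_o
    if only.sum() == 0:
        raise ValueError(f"empty stratum: {taxon} detected without {other}")
    if both.sum() == 0:
        raise ValueError(f"empty stratum: {taxon} and {other} co-detected")
    rel = table.relative()[taxon]
    x = rel[only].to_numpy(dtype=float)   # taxon alone
    y = rel[both].to_numpy(dtype=float)   # co-detected
    stat, p = rank_test(y, x, kind="mann_whitney_one_sided")
    return {"U": stat, "p_value": p, "n_only": int(only.sum()), "n_both": int(both.sum())}


@dataclass
class LongitudinalResult:
    """Colonization groups for subjects with repeat samples.

    Group I: never positive; group III: positive in every sample;
    group II: intermediate.
    """

    groups: pd.Series                 # subject -> "I"/"II"/"III"
    positivity: pd.DataFrame          # per-sample: subject, order, positive
    comparisons: pd.DataFrame         # one-sided II-vs-III abundance tests
    depth_check_p: float              # two-sided depth MW between tested sets


def longitudinal_groups(
    table: CountTable,
    meta: pd.DataFrame,
    detection: DetectionMatrix,
) -> LongitudinalResult:
    """Partition multi-sample subjects by longitudinal positivity and test
    whether positive-sample abundance is lower in intermittently positive
    subjects (group II) than in always-positive subjects (group III)."""
    counts = meta.groupby("subject_id")["collection_order"].count()
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(
            f"subjects with a single sample included: {list(singletons.index[:5])}"
        )
    pos = detection.any_positive().loc[meta.index]
    positivity = pd.DataFrame({
        "subject_id": meta["subject_id"],
        "collection_order": meta["collection_order"],
        "positive": pos,
    }).sort_values(["subject_id", "collection_order"])

    frac = positivity.groupby("subject_id")["positive"].mean()
    groups = pd.Series(
        np.where(frac == 0, "I", np.where(frac == 1, "III", "II")),
        index=frac.index, name="group",
    )

    subj_group = meta["subject_id"].map(groups)
    rel = table.relative()[list(detection.df.columns)]
    rel = rel.assign(sum_focal=rel.sum(axis=1))

    rows = {}
    mask_ii = (subj_group == "II") & pos
    mask_iii = (subj_group == "III") & pos
    for col in rel.columns:
        # positive samples *for that taxon* within each group
        det_col = detection.df[col] if col in detection.df.columns else pos
        x = rel.loc[mask_iii & det_col, col].to_numpy(dtype=float)
        y = rel.loc[mask_ii & det_col, col].to_numpy(dtype=float)
        if len(x) and len(y):
            stat, p = rank_test(x, y, kind="mann_whitney_one_sided")
        else:
            stat, p = float("nan"), float("nan")
        rows[col] = {"U": stat, "p_one_sided": p,
                     "n_group_II": len(y), "n_group_III": len(x)}
    comparisons = pd.DataFrame.from_dict(rows, orient="index")

    depths = table.depths
    d2 = depths[mask_ii.index[mask_ii]].to_numpy(dtype=float)
    d3 = depths[mask_iii.index[mask_iii]].to_numpy(dtype=float)
    if len(d2) and len(d3):
        _, depth_p = rank_test(d2, d3, kind="mann_whitney_two_sided")
    else:
        depth_p = float("nan")
    return LongitudinalResult(groups, positivity, comparisons, float(depth_p))


# ---------------------------------------------------------------------------
# rank tests


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x vs y with mid-rank ties."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def _mw_exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation p for the Mann-Whitney U by full enumeration of
    group assignments (handles ties; feasible for combined n <= ~12)."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    observed = _mw_u(x, y)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _mw_u(pooled[mask], pooled[~mask])
        total += 1
        if alternative == "greater":
            count += u >= observed - 1e-12
        elif alternative == "less":
            count += u <= observed + 1e-12
        else:
            mean_u = nx * (n - nx) / 2.0
            count += abs(u - mean_u) >= abs(observed - mean_u) - 1e-12
    return count / total


def rank_test(x, y=None, kind: str = "mann_whitney_two_sided"):
    """Rank tests used throughout the screening stage.

    Mann-Whitney tests use exact permutation enumeration when the combined
    sample size is <= 12 and the tie-corrected normal approximation
    otherwise; ``spearman`` returns (rho, p) from the t approximation.
    """
    x = np.asarray(x, dtype=float)
    if kind == "spearman":
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("spearman needs paired vectors of length >= 2")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("constant vector passed to spearman")
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)

    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1 or len(x) + len(y) < 3:
        raise ValueError("mann-whitney needs non-empty groups")
    alternative = "greater" if kind == "mann_whitney_one_sided" else "two-sided"
    u = _mw_u(x, y)
    if len(x) + len(y) <= EXACT_N:
        p = _mw_exact_p(x, y, "greater" if alternative == "greater" else "two-sided")
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
    return u, float(p)
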