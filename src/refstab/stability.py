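"""The four reference-gene stability estimators.

Each estimator consumes a :class:`~refstab.cq_data.CollapsedCqTable` (one
column per biological replicate) and returns a :class:`StabilityResult`
with a per-gene stability value — lower is always more stable — and a rank
(1 = most stable, average ranks on ties).

Working scales follow each method's original formulation under the single
assumption of perfect PCR doubling (efficiency 2):

* comparative delta-Ct operates on Cq directly (pairwise Cq differences are
  log2 expression ratios up to gene constants);
* geNorm operates on log2 relative quantities 2^(minCq - Cq), whose pairwise
  log-ratios again reduce to Cq differences;
* BestKeeper describes raw Cq dispersion (its "SD[+-Cq]" is the mean absolute
  deviation) and correlates each gene against the per-sample geometric mean
  of all candidates' Cq (the BestKeeper index);
* NormFinder decomposes -Cq (a log-expression proxy) into intergroup
  deviation and intragroup variance after within-sample centering.

Missing values: delta-Ct and geNorm use pairwise-complete samples per gene
pair; BestKeeper uses each gene's complete samples; NormFinder requires
complete columns and drops (with a log warning) samples missing any gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CollapsedCqTable, CqTable
from .errors import EstimationError

logger = logging.getLogger(__name__)

METHODS = ("delta_ct", "genorm", "bestkeeper", "normfinder")


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks for one method on one subset."""

    method: str
    values: pd.Series          # gene -> stability value (lower = more stable)
    ranks: pd.Series           # gene -> rank, 1 = most stable, ties averaged
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if list(self.values.index) != list(self.ranks.index):
            raise ValueError("values and ranks must cover the same genes")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def to_frame(self) -> pd.DataFrame:
        """Report frame: gene, value, rank plus flat per-gene diagnostics."""
        out = pd.DataFrame({"gene": self.values.index,
                            "value": self.values.to_numpy(),
                            "rank": self.ranks.to_numpy()})
        for key, val in self.diagnostics.items():
            if isinstance(val, pd.Series) and list(val.index) == list(self.values.index):
                out[key] = val.to_numpy()
        return out


def _ascending_ranks(values: pd.Series) -> pd.Series:
    return pd.Series(stats.rankdata(values.to_numpy(), method="average"),
                     index=values.index)


def _matrix(t: CqTable) -> tuple[np.ndarray, list[str]]:
    return t.values.to_numpy(dtype=float), list(t.values.index)


def _pairwise_sd(arr: np.ndarray, genes: Sequence[str], min_shared: int = 3
                 ) -> np.ndarray:
    """Symmetric matrix of SD over shared samples of Cq_i - Cq_j (ddof=1).

    These pairwise SDs are the common computational core of the delta-Ct
    method and of geNorm's V_jk (constants cancel out of the log ratios).
    """
    n = len(genes)
    out = np.zeros((n, n))
    present = ~np.isnan(arr)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            k = int(shared.sum())
            if k < min_shared:
                raise EstimationError(
                    f"gene pair ({genes[i]!r}, {genes[j]!r}) shares only {k} "
                    f"samples with both Cq present (need >= {min_shared})")
            d = arr[i, shared] - arr[j, shared]
            out[i, j] = out[j, i] = float(np.std(d, ddof=1))
    return out


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------

def delta_ct_stability(t: CollapsedCqTable) -> StabilityResult:
    """Comparative delta-Ct stability.

    For every ordered gene pair the per-sample Cq difference is formed; a
    gene's stability is the mean, over all partner genes, of the SD of those
    differences across samples (units: cycles).
    """
    arr, genes = _matrix(t)
    if len(genes) < 2:
        raise EstimationError("delta-Ct needs at least 2 genes")
    sd = _pairwise_sd(arr, genes)
    n = len(genes)
    vals = (sd.sum(axis=1)) / (n - 1)
    values = pd.Series(vals, index=genes)
    diag = {"pairwise_sd": pd.DataFrame(sd, index=genes, columns=genes)}
    return StabilityResult("delta_ct", values, _ascending_ranks(values), diag)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def genorm_stability(t: CollapsedCqTable) -> StabilityResult:
    """geNorm expression-stability measure M with iterative exclusion.

    M_j is the mean over partners k of V_jk = SD across samples of
    log2(Q_j/Q_k); the gene with the highest M is excluded and M recomputed
    until two genes remain.  A gene's reported value is its M at the step it
    was excluded; the final two genes carry the final-step M and share the
    best (tied) rank, since the method cannot separate its last pair.

    ``diagnostics['exclusion_order']`` lists genes worst-first;
    ``diagnostics['V']`` holds the pairwise variations V_n/n+1 between
    normalization factors built from the top n and top n+1 genes.
    """
    arr, genes = _matrix(t)
    n = len(genes)
    if n < 2:
        raise EstimationError("geNorm needs at least 2 genes")
    sd = _pairwise_sd(arr, genes)
    idx = {g: i for i, g in enumerate(genes)}

    values = pd.Series(np.nan, index=genes, dtype=float)
    ranks = pd.Series(np.nan, index=genes, dtype=float)
    exclusion_order: list[str] = []
    active = list(genes)
    step_rank = n
    while len(active) > 2:
        rows = [idx[g] for g in active]
        sub = sd[np.ix_(rows, rows)]
        m = sub.sum(axis=1) / (len(active) - 1)
        worst_m = m.max()
        # deterministic tie-break: among equal-M genes exclude the
        # alphabetically last, so earlier symbols are preferred
        tied = [active[i] for i in np.flatnonzero(np.isclose(m, worst_m))]
        worst = max(tied)
        values[worst] = m[active.index(worst)]
        ranks[worst] = step_rank
        exclusion_order.append(worst)
        active.remove(worst)
        step_rank -= 1
    final_m = sd[idx[active[0]], idx[active[1]]]
    for g in active:
        values[g] = final_m
        ranks[g] = 1.5
    best_first = sorted(active) + exclusion_order[::-1]

    # V_n/n+1 series between successive normalization factors
    with np.errstate(invalid="ignore"):
        log2q = (np.nanmin(arr, axis=1, keepdims=True) - arr)  # log2 rel. quantity
    v_series: dict[str, float] = {}
    for top_n in range(2, n):
        rows_n = [idx[g] for g in best_first[:top_n]]
        rows_n1 = [idx[g] for g in best_first[:top_n + 1]]
        nf_n = np.nanmean(log2q[rows_n], axis=0)       # log2 geometric-mean NF
        nf_n1 = np.nanmean(log2q[rows_n1], axis=0)
        diff = nf_n - nf_n1
        diff = diff[~np.isnan(diff)]
        v_series[f"V{top_n}/{top_n + 1}"] = (
            float(np.std(diff, ddof=1)) if diff.size >= 2 else float("nan"))

    diag = {"exclusion_order": exclusion_order, "V": v_series,
            "ranking_best_first": best_first}
    return StabilityResult("genorm", values, ranks, diag)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper_stability(t: CollapsedCqTable) -> StabilityResult:
    """BestKeeper descriptive stability.

    A gene's value is its "SD[+-Cq]": the mean absolute deviation of Cq from
    the gene's arithmetic mean (cycles), the statistic the original tool
    prints as SD and judges against its 1-cycle acceptability bound.
    Diagnostics carry CV% (SD over mean x 100), the BestKeeper index (the
    per-sample geometric mean of all candidates' Cq) and each gene's Pearson
    r against the index with its two-sided p-value.
    """
    arr, genes = _matrix(t)
    if len(genes) < 2:
        raise EstimationError("BestKeeper needs at least 2 genes")
    mad = np.empty(len(genes))
    cv = np.empty(len(genes))
    for i, g in enumerate(genes):
        x = arr[i][~np.isnan(arr[i])]
        if x.size < 3:
            raise EstimationError(
                f"BestKeeper needs >= 3 samples with Cq present for gene {g!r} "
                f"(found {x.size})")
        mu = x.mean()
        mad[i] = np.abs(x - mu).mean()
        cv[i] = mad[i] / mu * 100.0 if mu != 0 else np.nan

    with np.errstate(all="ignore"):
        index = np.exp(np.nanmean(np.log(arr), axis=0))  # geometric mean of Cq
    r = np.full(len(genes), np.nan)
    r_p = np.full(len(genes), np.nan)
    r_warnings: list[str] = []
    for i, g in enumerate(genes):
        ok = ~np.isnan(arr[i]) & ~np.isnan(index)
        x, y = arr[i, ok], index[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            r_warnings.append(g)
            logger.warning("BestKeeper: Pearson r undefined for gene %s "
                           "(constant Cq or constant index)", g)
            continue
        res = stats.pearsonr(x, y)
        r[i], r_p[i] = float(res.statistic), float(res.pvalue)

    values = pd.Series(mad, index=genes)
    diag = {
        "cv_percent": pd.Series(cv, index=genes),
        "r": pd.Series(r, index=genes),
        "r_pvalue": pd.Series(r_p, index=genes),
        "index": pd.Series(index, index=t.values.columns),
        "r_warnings": r_warnings,
    }
    return StabilityResult("bestkeeper", values, _ascending_ranks(values), diag)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _resolve_groups(t: CqTable, groups, n_cols: np.ndarray) -> np.ndarray | None:
    if groups is None:
        return None
    if isinstance(groups, str):
        if groups not in t.samples.columns:
            raise EstimationError(f"no sample annotation column {groups!r}")
        lab = t.samples[groups].to_numpy()
    else:
        lab = np.asarray(list(groups))
        if lab.size != t.n_samples:
            raise EstimationError("groups must give one label per sample")
    return lab[n_cols]


def normfinder_stability(t: CollapsedCqTable, groups=None) -> StabilityResult:
    """NormFinder model-based stability value.

    The log-expression proxy -Cq is decomposed, after centering each sample
    across genes, into a per-group intergroup deviation d_ig and an
    intragroup variance sigma2_ig (estimated with the k/(k-2) bias
    correction, k = number of genes, truncated at zero).  Intergroup
    deviations are shrunk toward zero by tau/(tau + var(d_ig)), tau being the
    moment estimate of the variance of the true deviations, and the stability
    value is the mean over groups of |d_shrunk| + sqrt(sigma2_ig/n_g).  With
    no grouping the measure reduces to the single-group form sqrt(sigma2_i).

    ``groups`` may be None, the name of a sample-annotation column (for
    example ``"genotype"``), or an explicit per-sample label sequence.
    """
    arr, genes = _matrix(t)
    k = len(genes)
    if k < 3:
        raise EstimationError("NormFinder needs at least 3 genes "
                              "(within-sample centering requires >= 2 others)")
    complete = ~np.isnan(arr).any(axis=0)
    if not complete.all():
        logger.warning("NormFinder: dropping %d sample(s) with missing Cq",
                       int((~complete).sum()))
    if complete.sum() < 2:
        raise EstimationError("NormFinder needs >= 2 complete samples")
    cols = np.flatnonzero(complete)
    y = -arr[:, cols]
    lab = _resolve_groups(t, groups, cols)
    if lab is None:
        lab = np.zeros(cols.size, dtype=int)
    group_levels = list(dict.fromkeys(lab.tolist()))
    if groups is not None and len(group_levels) < 2:
        raise EstimationError("NormFinder with groups needs >= 2 group levels")

    r = y - y.mean(axis=0, keepdims=True)          # within-sample centering
    G = len(group_levels)
    z = np.empty((k, G))
    s2 = np.empty((k, G))
    n_g = np.empty(G)
    for gi, gl in enumerate(group_levels):
        sel = np.asarray(lab) == gl
        n = int(sel.sum())
        if n < 2:
            raise EstimationError(
                f"NormFinder group {gl!r} has {n} sample(s); need >= 2")
        n_g[gi] = n
        block = r[:, sel]
        z[:, gi] = block.mean(axis=1)
        s2[:, gi] = block.var(axis=1, ddof=1)

    gamma = s2.mean(axis=0) / (k - 1)              # (1/k^2) * sum of sigma2
    sigma2 = np.maximum((s2 - gamma[None, :]) * k / (k - 2), 0.0)

    if G == 1:
        values = pd.Series(np.sqrt(sigma2[:, 0]), index=genes)
        diag = {"intragroup_variance": pd.Series(sigma2[:, 0], index=genes),
                "intergroup_deviation": pd.DataFrame(
                    np.zeros((k, 1)), index=genes, columns=[group_levels[0]])}
        return StabilityResult("normfinder", values,
                               _ascending_ranks(values), diag)

    d = z - z.mean(axis=1, keepdims=True)          # intergroup deviations
    vard = sigma2 / n_g[None, :]
    tau = max(float(np.mean(d * d - vard)), 0.0)
    denom = tau + vard
    shrink = np.divide(tau, denom, out=np.zeros_like(denom), where=denom > 0)
    d_shrunk = d * shrink
    rho = np.abs(d_shrunk) + np.sqrt(vard)
    values = pd.Series(rho.mean(axis=1), index=genes)
    diag = {
        "intergroup_deviation": pd.DataFrame(d, index=genes, columns=group_levels),
        "intergroup_deviation_shrunk": pd.DataFrame(
            d_shrunk, index=genes, columns=group_levels),
        "intragroup_variance": pd.DataFrame(sigma2, index=genes,
                                            columns=group_levels),
        "group_sizes": dict(zip(group_levels, n_g.astype(int).tolist())),
    }
    return StabilityResult("normfinder", values, _ascending_ranks(values), diag)


def run_all(t: CollapsedCqTable, normfinder_groups=None
            ) -> dict[str, StabilityResult]:
    """Run all four estimators on one table; keys are the method names."""
    return {
        "delta_ct": delta_ct_stability(t),
        "genorm": genorm_stability(t),
        "bestkeeper": bestkeeper_stability(t),
        "normfinder": normfinder_stability(t, groups=normfinder_groups),
    }
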