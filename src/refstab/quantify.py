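"""Relative quantification against a reference panel and genotype contrasts.

Expression of a target gene is reported per biological replicate as
2^-dCq with dCq = Cq_target - mean(Cq of the panel genes); averaging panel
Cq arithmetically is equivalent to normalizing by the geometric mean of the
panel's linear quantities (the standard multi-reference normalization
factor) under perfect doubling per cycle.

Genotype contrasts use a two-sided unpaired t-test on the per-replicate
relative expressions (classical Student by default, Welch by flag), with
Shapiro-Wilk normality checks attached as diagnostics and significance
labels ns / * / ** / *** at p <= 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_data import CollapsedCqTable
from .errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class ExpressionResult:
    """Relative expression of one gene in one (region, genotype) condition."""

    gene: str
    region: str
    genotype: str
    rel_expr: pd.Series  # per biological replicate, index = bio_rep

    @property
    def n(self) -> int:
        return int(self.rel_expr.size)

    @property
    def mean(self) -> float:
        return float(self.rel_expr.mean())

    @property
    def sd(self) -> float:
        return float(self.rel_expr.std(ddof=1)) if self.n >= 2 else float("nan")


@dataclass
class GroupComparison:
    """Two-group contrast of relative expression for one gene and region."""

    gene: str
    region: str
    mean_a: float
    mean_b: float
    fold_change: float            # mean_b / mean_a
    normality_p: tuple[float, float]  # Shapiro-Wilk p per group (NaN if n < 3)
    p_value: float
    label: str
    t_statistic: float = float("nan")
    warnings: tuple[str, ...] = ()


def significance_label(p: float,
                       alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS
                       ) -> str:
    """Map a p-value to ns/*/**/*** under the declared thresholds."""
    a1, a2, a3 = alpha_levels
    if not (a1 > a2 > a3 > 0):
        raise ValidationError(f"alpha levels must decrease: {alpha_levels!r}")
    if np.isnan(p):
        return "ns"
    if p <= a3:
        return "***"
    if p <= a2:
        return "**"
    if p <= a1:
        return "*"
    return "ns"


def relative_expression(t: CollapsedCqTable, target: str,
                        panel: Sequence[str]) -> list[ExpressionResult]:
    """2^-dCq of ``target`` against the mean panel Cq, per condition.

    Returns one :class:`ExpressionResult` per (region, genotype) condition
    present in the table, in design order.  Replicates missing the target Cq
    (or every panel Cq) are dropped with a warning; a condition left with no
    usable replicate raises :class:`EstimationError`.
    """
    panel = list(panel)
    if target in panel:
        raise ValidationError(f"target {target!r} must not be in the panel")
    missing = [g for g in [target] + panel if g not in t.values.index]
    if missing:
        raise ValidationError(f"gene(s) not in table: {missing}")
    if not panel:
        raise ValidationError("panel must contain at least one gene")

    tgt = t.values.loc[target]
    pnl = t.values.loc[panel]
    panel_mean = pnl.mean(axis=0, skipna=True)  # arithmetic mean of panel Cq
    dcq = tgt - panel_mean
    rel = np.power(2.0, -dcq)

    results: list[ExpressionResult] = []
    conditions: list[tuple[str, str]] = []
    for region in t.design.regions:
        for genotype in t.design.genotypes:
            sel = ((t.samples["region"] == region)
                   & (t.samples["genotype"] == genotype))
            if sel.any():
                conditions.append((region, genotype))
    for region, genotype in conditions:
        sel = ((t.samples["region"] == region)
               & (t.samples["genotype"] == genotype))
        sub = rel[sel.to_numpy()]
        bio = t.samples.loc[sel, "bio_rep"]
        ok = sub.notna()
        if (~ok).any():
            logger.warning(
                "dropping %d replicate(s) of %s in (%s, %s) with missing Cq",
                int((~ok).sum()), target, region, genotype)
        if ok.sum() == 0:
            raise EstimationError(
                f"no usable replicate for {target!r} in ({region}, {genotype})")
        results.append(ExpressionResult(
            target, region, genotype,
            pd.Series(sub[ok].to_numpy(), index=bio[ok.to_numpy()].to_numpy())))
    return results


def compare_groups(a: ExpressionResult, b: ExpressionResult,
                   alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
                   equal_var: bool = True) -> GroupComparison:
    """Two-sided unpaired t-test between two conditions of the same gene/region.

    ``equal_var=True`` gives the classical Student test; ``False`` the Welch
    variant.  Shapiro-Wilk normality p-values are attached when each group
    has at least three replicates (a warning notes when they cannot be
    computed, or when a group fails normality at 0.05 — the test is not
    switched automatically).
    """
    if a.gene != b.gene or a.region != b.region:
        raise ValidationError(
            f"cannot compare ({a.gene}, {a.region}) with ({b.gene}, {b.region})")
    xa, xb = a.rel_expr.to_numpy(float), b.rel_expr.to_numpy(float)
    if xa.size < 2 or xb.size < 2:
        raise EstimationError("each group needs >= 2 replicates for a t-test")
    warn: list[str] = []
    norm_p = []
    for name, x in (("a", xa), ("b", xb)):
        if x.size >= 3 and np.ptp(x) > 0:
            p = float(stats.shapiro(x).pvalue)
            if p < 0.05:
                warn.append(f"group {name} fails Shapiro-Wilk (p={p:.3g})")
        else:
            p = float("nan")
            warn.append(f"normality not assessable for group {name} (n={x.size})")
        norm_p.append(p)
    if np.std(xa) == 0 and np.std(xb) == 0:
        p_value = 1.0 if np.isclose(xa.mean(), xb.mean()) else 0.0
        t_stat = float("nan")
        warn.append("zero variance in both groups; p set by mean equality")
    else:
        res = stats.ttest_ind(xb, xa, equal_var=equal_var)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    for w in warn:
        logger.warning("%s / %s: %s", a.gene, a.region, w)
    mean_a, mean_b = float(xa.mean()), float(xb.mean())
    return GroupComparison(
        gene=a.gene, region=a.region, mean_a=mean_a, mean_b=mean_b,
        fold_change=mean_b / mean_a, normality_p=(norm_p[0], norm_p[1]),
        p_value=p_value, label=significance_label(p_value, alpha_levels),
        t_statistic=t_stat, warnings=tuple(warn))


def isoform_profile(t: CollapsedCqTable, isoform_assays: Mapping[str, str] | Sequence[str],
                    panel: Sequence[str]) -> dict[str, list[ExpressionResult]]:
    """Batched :func:`relative_expression` over a set of named target assays.

    ``isoform_assays`` maps an assay name to the gene symbol carried in the
    table (a plain sequence is treated as symbols naming themselves), e.g.
    three assays measuring a total transcript and two splice isoforms.
    """
    if not isinstance(isoform_assays, Mapping):
        isoform_assays = {g: g for g in isoform_assays}
    absent = [sym for sym in isoform_assays.values() if sym not in t.values.index]
    if absent:
        raise ValidationError(f"assay gene(s) not in table: {absent}")
    return {name: relative_expression(t, sym, panel)
            for name, sym in isoform_assays.items()}


def expression_frame(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    """Tidy per-condition summary: gene, region, genotype, n, mean, sd."""
    return pd.DataFrame([
        {"gene": r.gene, "region": r.region, "genotype": r.genotype,
         "n": r.n, "mean": r.mean, "sd": r.sd}
        for r in results])


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tidy contrast table: fold change, p-value, label, normality flags."""
    return pd.DataFrame([
        {"gene": c.gene, "region": c.region, "mean_wt": c.mean_a,
         "mean_mut": c.mean_b, "fold_change": c.fold_change,
         "p_value": c.p_value, "label": c.label,
         "normality_p_wt": c.normality_p[0],
         "normality_p_mut": c.normality_p[1]}
        for c in comparisons])


def compare_by_region(t: CollapsedCqTable, target: str, panel: Sequence[str],
                      alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
                      equal_var: bool = True) -> list[GroupComparison]:
    """Contrast the two design genotypes per region for one target gene.

    The first genotype of the design is the baseline (group a)."""
    per_cond = {(r.region, r.genotype): r
                for r in relative_expression(t, target, panel)}
    base, other = t.design.genotypes[0], t.design.genotypes[1]
    out = []
    for region in t.design.regions:
        if (region, base) in per_cond and (region, other) in per_cond:
            out.append(compare_groups(per_cond[(region, base)],
                                      per_cond[(region, other)],
                                      alpha_levels=alpha_levels,
                                      equal_var=equal_var))
    return out
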