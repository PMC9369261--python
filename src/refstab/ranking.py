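"""Rank aggregation: comprehensive (geometric-mean) ranking, the two-axis
condition sweep over the factorial design, screening, and panel compilation.

The comprehensive ranking combines the four per-method stability ranks of a
gene by their geometric mean (fractional tied ranks enter unrounded), the
aggregation popularized by the RefFinder tool.  Stability is then assessed
along two axes of the design:

* within each genotype, across brain regions (how stable is a gene over the
  anatomy), and
* within each brain region, across the two genotypes (how stable is it over
  the genetic contrast);

and the final reference panel is the top-k genes of a weighted average
(default 50/50) of the two axis scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cq_data import CollapsedCqTable, subset_condition
from .errors import EstimationError, ValidationError
from .stability import METHODS, StabilityResult, run_all

Axis = Literal["within_genotype_across_regions", "within_region_across_genotypes"]
Mode = Literal["pooled", "per_cell_averaged"]

#: Report column headers, per method, in the conventional display order.
METHOD_LABELS: dict[str, str] = {
    "delta_ct": "Delta Ct",
    "bestkeeper": "BestKeeper",
    "normfinder": "Normfinder",
    "genorm": "Genorm",
}
AVG_LABEL = "Avg. ranking"


@dataclass
class ComprehensiveRanking:
    """Geometric-mean aggregation of the four per-method rankings.

    ``averaged`` marks rankings produced by averaging several per-condition
    rankings (e.g. a genotype's mean over its nine per-region rankings); for
    those, ``geomean_rank`` is the arithmetic mean of the per-condition
    geometric-mean ranks and is not reproducible from ``per_method_ranks``
    alone.
    """

    per_method_ranks: dict[str, pd.Series]
    geomean_rank: pd.Series
    final_order: list[str]
    averaged: bool = False
    cell_rankings: dict[str, "ComprehensiveRanking"] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.geomean_rank.index)

    def to_frame(self) -> pd.DataFrame:
        """One row per gene in final order, columns per method + average."""
        rows = []
        for g in self.final_order:
            row = {"gene": g}
            for m, label in METHOD_LABELS.items():
                row[label] = float(self.per_method_ranks[m][g])
            row[AVG_LABEL] = float(self.geomean_rank[g])
            rows.append(row)
        return pd.DataFrame(rows)


def _final_order(score: pd.Series) -> list[str]:
    return sorted(score.index, key=lambda g: (float(score[g]), g))


def comprehensive_rank(results: Iterable[StabilityResult] | Mapping[str, StabilityResult]
                       ) -> ComprehensiveRanking:
    """Aggregate exactly one result per method into a comprehensive ranking.

    The gene sets of the four results must agree; ties in the final ordering
    break alphabetically by gene symbol.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    else:
        results = list(results)
    by_method: dict[str, StabilityResult] = {}
    for res in results:
        if res.method in by_method:
            raise ValidationError(f"method {res.method!r} supplied twice")
        by_method[res.method] = res
    missing = [m for m in METHODS if m not in by_method]
    if missing:
        raise ValidationError(f"missing method result(s): {missing}")
    gene_sets = {m: set(r.genes) for m, r in by_method.items()}
    ref = gene_sets[METHODS[0]]
    for m, gs in gene_sets.items():
        if gs != ref:
            diff = sorted(gs ^ ref)
            raise ValidationError(
                f"gene sets differ between methods (symmetric difference "
                f"{diff})")
    genes = by_method[METHODS[0]].genes
    ranks = {m: by_method[m].ranks.loc[genes].astype(float) for m in METHODS}
    log_sum = sum(np.log(ranks[m].to_numpy()) for m in METHODS)
    geomean = pd.Series(np.exp(log_sum / len(METHODS)), index=genes)
    return ComprehensiveRanking(ranks, geomean, _final_order(geomean))


def rank_table(t: CollapsedCqTable, normfinder_groups=None) -> ComprehensiveRanking:
    """Run all four estimators on one table and aggregate."""
    return comprehensive_rank(run_all(t, normfinder_groups=normfinder_groups))


def _average_rankings(parts: dict[str, ComprehensiveRanking]) -> ComprehensiveRanking:
    """Arithmetic mean of per-condition rankings (per method and overall)."""
    keys = list(parts)
    genes = parts[keys[0]].genes
    for k in keys[1:]:
        if set(parts[k].genes) != set(genes):
            raise ValidationError("per-condition rankings cover different genes")
    per_method = {
        m: pd.Series(
            np.mean([parts[k].per_method_ranks[m].loc[genes].to_numpy()
                     for k in keys], axis=0), index=genes)
        for m in METHODS
    }
    geomean = pd.Series(
        np.mean([parts[k].geomean_rank.loc[genes].to_numpy() for k in keys],
                axis=0), index=genes)
    return ComprehensiveRanking(per_method, geomean, _final_order(geomean),
                                averaged=True, cell_rankings=dict(parts))


def condition_sweep(t: CollapsedCqTable, axis: Axis,
                    mode: Mode = "per_cell_averaged"
                    ) -> dict[str, ComprehensiveRanking]:
    """One comprehensive ranking per condition along the chosen axis.

    ``within_genotype_across_regions`` yields one ranking per genotype.  In
    ``pooled`` mode all of the genotype's samples (all regions) enter a
    single estimation; in ``per_cell_averaged`` mode a ranking is computed
    per region and the genotype's ranking is the arithmetic mean of its
    per-region rankings (the "average ranking position across the nine brain
    regions" reading).

    ``within_region_across_genotypes`` yields one ranking per region, always
    pooling the region's samples of both genotypes (a single-genotype cell
    cannot contrast genotypes, so ``mode`` does not apply); NormFinder runs
    with genotype as the group factor here.
    """
    if axis == "within_genotype_across_regions":
        out: dict[str, ComprehensiveRanking] = {}
        genotypes = [g for g in t.design.genotypes
                     if (t.samples["genotype"] == g).any()]
        if len(genotypes) < 2:
            raise EstimationError("need >= 2 genotype levels present for the "
                                  "within-genotype axis")
        for geno in genotypes:
            sub = subset_condition(t, genotype=geno)
            if mode == "pooled":
                try:
                    out[geno] = rank_table(sub)
                except EstimationError as exc:
                    raise EstimationError(f"condition genotype={geno}: {exc}") from exc
            else:
                parts: dict[str, ComprehensiveRanking] = {}
                regions = [r for r in t.design.regions
                           if (sub.samples["region"] == r).any()]
                for region in regions:
                    cell = subset_condition(sub, region=region)
                    try:
                        parts[region] = rank_table(cell)
                    except EstimationError as exc:
                        raise EstimationError(
                            f"condition genotype={geno}, region={region}: {exc}"
                        ) from exc
                out[geno] = _average_rankings(parts)
        return out
    if axis == "within_region_across_genotypes":
        out = {}
        regions = [r for r in t.design.regions
                   if (t.samples["region"] == r).any()]
        if not regions:
            raise EstimationError("no region levels present")
        for region in regions:
            sub = subset_condition(t, region=region)
            if sub.samples["genotype"].nunique() < 2:
                raise EstimationError(
                    f"condition region={region}: needs both genotypes present")
            try:
                out[region] = rank_table(sub, normfinder_groups="genotype")
            except EstimationError as exc:
                raise EstimationError(f"condition region={region}: {exc}") from exc
        return out
    raise ValidationError(f"unknown axis {axis!r}")


@dataclass
class PanelSpec:
    """Weighted two-axis combination and the resulting reference panel."""

    axis_region_rank: pd.Series    # within-genotype / across-regions scores
    axis_genotype_rank: pd.Series  # within-region / across-genotypes scores
    weights: tuple[float, float]
    combined_rank: pd.Series
    panel: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Rows regions/genotypes/combination, one column per gene (genes
        ordered by combined rank)."""
        order = sorted(self.combined_rank.index,
                       key=lambda g: (float(self.combined_rank[g]), g))
        return pd.DataFrame(
            [self.axis_region_rank.loc[order].to_numpy(),
             self.axis_genotype_rank.loc[order].to_numpy(),
             self.combined_rank.loc[order].to_numpy()],
            index=pd.Index(["regions", "genotypes", "combination"], name="axis"),
            columns=order)


def _axis_score(rankings: Mapping[str, ComprehensiveRanking]) -> pd.Series:
    keys = list(rankings)
    genes = rankings[keys[0]].genes
    for k in keys[1:]:
        if set(rankings[k].genes) != set(genes):
            raise ValidationError("axis rankings cover different gene sets")
    return pd.Series(
        np.mean([rankings[k].geomean_rank.loc[genes].to_numpy() for k in keys],
                axis=0), index=genes)


def compile_panel(region_axis: Mapping[str, ComprehensiveRanking],
                  genotype_axis: Mapping[str, ComprehensiveRanking],
                  weights: tuple[float, float] = (0.5, 0.5),
                  k: int = 3) -> PanelSpec:
    """Combine the two axes into a final panel of the k best genes.

    Each axis score is the arithmetic mean, over that axis's conditions, of
    the per-condition geometric-mean ranks; the combined score is the
    weighted average of the two axis scores (weights non-negative, summing
    to 1; default 0.5/0.5).  Ties break alphabetically.
    """
    w = tuple(float(x) for x in weights)
    if len(w) != 2 or min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
        raise ValidationError(
            f"weights must be two non-negative numbers summing to 1, got {weights!r}")
    score_r = _axis_score(region_axis)
    score_g = _axis_score(genotype_axis)
    if set(score_r.index) != set(score_g.index):
        diff = sorted(set(score_r.index) ^ set(score_g.index))
        raise ValidationError(f"axes cover different gene sets ({diff})")
    score_g = score_g.loc[score_r.index]
    if not (1 <= k <= len(score_r)):
        raise ValidationError(f"k must be in 1..{len(score_r)}, got {k}")
    combined = w[0] * score_r + w[1] * score_g
    order = sorted(combined.index, key=lambda g: (float(combined[g]), g))
    return PanelSpec(score_r, score_g, (w[0], w[1]), combined, order[:k])


def screen_candidates(r: ComprehensiveRanking, keep: int) -> list[str]:
    """The ``keep`` best genes by comprehensive rank, in final order."""
    if keep < 0 or keep > len(r.final_order):
        raise ValidationError(
            f"keep must be in 0..{len(r.final_order)}, got {keep}")
    return list(r.final_order[:keep])
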