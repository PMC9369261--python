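"""Model/Results facade over the functional pipeline.

Two estimator-style entry points mirror the common modelling idiom
(construct from data, call ``fit()``, inspect a Results object):

* :class:`ReferenceGenePanel` — fits the two-axis stability assessment and
  compiles the weighted reference panel;
* :class:`RelativeExpression` — fits per-condition 2^-dCq expression of
  target genes against a panel and the per-region genotype contrasts.

Both wrap the ``stability``/``ranking``/``quantify`` modules; nothing here
adds statistics, only presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .cq_data import (CollapsedCqTable, CqTable, Design, DEFAULT_DESIGN,
                      collapse_technical_replicates, read_cq_table,
                      subset_condition)
from .errors import ValidationError
from .quantify import (DEFAULT_ALPHA_LEVELS, comparison_frame,
                       compare_by_region, expression_frame,
                       relative_expression)
from .ranking import (ComprehensiveRanking, PanelSpec, compile_panel,
                      condition_sweep, rank_table, screen_candidates)


def _as_collapsed(table: CqTable, spread_warn: float) -> CollapsedCqTable:
    if isinstance(table, CollapsedCqTable):
        return table
    return collapse_technical_replicates(table, spread_warn=spread_warn)


@dataclass
class ReferenceGenePanelResults:
    """Fitted two-axis stability assessment and compiled panel."""

    model: "ReferenceGenePanel"
    region_axis: dict[str, ComprehensiveRanking]    # per genotype
    genotype_axis: dict[str, ComprehensiveRanking]  # per region
    panel_spec: PanelSpec
    screened_out: list[str] = field(default_factory=list)

    @property
    def panel(self) -> list[str]:
        return list(self.panel_spec.panel)

    def ranking_frame(self, condition: str) -> pd.DataFrame:
        """Per-method rank table for one condition (genotype or region)."""
        if condition in self.region_axis:
            return self.region_axis[condition].to_frame()
        if condition in self.genotype_axis:
            return self.genotype_axis[condition].to_frame()
        raise ValidationError(f"unknown condition {condition!r}")

    def summary(self) -> str:
        lines = ["Reference gene panel assessment",
                 "=" * 38]
        if self.screened_out:
            lines.append("screened out (unstable): "
                         + ", ".join(self.screened_out))
        w = self.panel_spec.weights
        lines.append(f"axis weights: regions {w[0]:.2f} / genotypes {w[1]:.2f}")
        lines.append("")
        frame = self.panel_spec.to_frame()
        lines.append(frame.round(3).to_string())
        lines.append("")
        lines.append("selected panel: " + ", ".join(self.panel))
        return "\n".join(lines)


class ReferenceGenePanel:
    """Reference-gene stability model for a Cq survey.

    Parameters
    ----------
    table
        A raw or collapsed Cq table covering the candidate genes (technical
        replicates are collapsed on construction if needed).
    candidates
        Candidate reference genes to assess; defaults to every gene in the
        table.
    spread_warn
        Technical-spread warning threshold (cycles) used when collapsing.
    """

    def __init__(self, table: CqTable, candidates: Sequence[str] | None = None,
                 spread_warn: float = 0.5) -> None:
        self.table = _as_collapsed(table, spread_warn)
        if candidates is not None:
            self.table = subset_condition(self.table, genes=list(candidates))
        self.candidates = list(self.table.values.index)

    @classmethod
    def from_dataframe(cls, long_df: pd.DataFrame, design: Design = DEFAULT_DESIGN,
                       **kwargs) -> "ReferenceGenePanel":
        """Build from a tidy long-format frame (same columns as the file
        format: sample_id, gene, cq, region, genotype, bio_rep, tech_rep)."""
        from .cq_data import table_from_long

        return cls(table_from_long(long_df, design=design), **kwargs)

    @classmethod
    def from_file(cls, path, design: Design = DEFAULT_DESIGN, *, wide: bool = False,
                  **kwargs) -> "ReferenceGenePanel":
        return cls(read_cq_table(path, design=design, wide=wide), **kwargs)

    def screen(self, keep: int, genotype: str | None = None,
               mode: str = "pooled") -> list[str]:
        """Initial screen: comprehensive ranking within one genotype
        (default: the design's first) and truncation to the ``keep`` best.

        Screening pools the genotype's samples across all regions into a
        single estimation by default — across-region instability (large
        region effects, high biological noise) is exactly what the screen
        must detect, and the pooled fit uses every sample."""
        geno = genotype or self.table.design.genotypes[0]
        sub = subset_condition(self.table, genotype=geno)
        if mode == "pooled":
            ranking = rank_table(sub)
        else:
            from .ranking import _average_rankings

            parts = {}
            for region in self.table.design.regions:
                if (sub.samples["region"] == region).any():
                    parts[region] = rank_table(subset_condition(sub, region=region))
            ranking = _average_rankings(parts)
        return screen_candidates(ranking, keep)

    def fit(self, mode: str = "per_cell_averaged",
            weights: tuple[float, float] = (0.5, 0.5), k: int = 3,
            screen_keep: int | None = None) -> ReferenceGenePanelResults:
        """Run the two-axis sweep and compile the weighted panel.

        With ``screen_keep`` given, an initial comprehensive screen in the
        first genotype truncates the candidate pool before the sweep.
        """
        table = self.table
        screened_out: list[str] = []
        if screen_keep is not None:
            kept = self.screen(screen_keep)
            screened_out = [g for g in self.candidates if g not in kept]
            table = subset_condition(table, genes=kept)
        region_axis = condition_sweep(table, "within_genotype_across_regions",
                                      mode=mode)
        genotype_axis = condition_sweep(table, "within_region_across_genotypes",
                                        mode=mode)
        spec = compile_panel(region_axis, genotype_axis, weights=weights, k=k)
        return ReferenceGenePanelResults(self, region_axis, genotype_axis,
                                         spec, screened_out)


@dataclass
class RelativeExpressionResults:
    """Fitted relative expression and genotype contrasts."""

    model: "RelativeExpression"
    expression: pd.DataFrame    # gene, region, genotype, n, mean, sd
    comparisons: pd.DataFrame   # gene, region, fold_change, p_value, label, ...

    def summary(self) -> str:
        lines = ["Relative expression (2^-dCq vs panel: "
                 + ", ".join(self.model.panel) + ")",
                 "=" * 54,
                 self.expression.round(4).to_string(index=False)]
        if len(self.comparisons):
            lines += ["", "Genotype contrasts (unpaired t-test)",
                      self.comparisons.round(4).to_string(index=False)]
        return "\n".join(lines)


class RelativeExpression:
    """Relative-quantification model for target genes against a panel."""

    def __init__(self, table: CqTable, targets: Sequence[str],
                 panel: Sequence[str], spread_warn: float = 0.5) -> None:
        self.table = _as_collapsed(table, spread_warn)
        self.targets = list(targets)
        self.panel = list(panel)
        overlap = sorted(set(self.targets) & set(self.panel))
        if overlap:
            raise ValidationError(f"target(s) {overlap} also in panel")

    @classmethod
    def from_file(cls, path, targets: Sequence[str], panel: Sequence[str],
                  design: Design = DEFAULT_DESIGN, *, wide: bool = False,
                  **kwargs) -> "RelativeExpression":
        return cls(read_cq_table(path, design=design, wide=wide),
                   targets, panel, **kwargs)

    def fit(self, alpha_levels: Sequence[float] = DEFAULT_ALPHA_LEVELS,
            equal_var: bool = True) -> RelativeExpressionResults:
        expr_rows = []
        comp_rows = []
        two_genotypes = self.table.samples["genotype"].nunique() >= 2
        for target in self.targets:
            expr_rows.extend(relative_expression(self.table, target, self.panel))
            if two_genotypes:
                comp_rows.extend(compare_by_region(
                    self.table, target, self.panel,
                    alpha_levels=alpha_levels, equal_var=equal_var))
        return RelativeExpressionResults(
            self, expression_frame(expr_rows), comparison_frame(comp_rows))
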