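"""Seeded generator of Cq datasets with the study's factorial structure.

The generator emulates an RT-qPCR survey of candidate reference genes and
target genes over nine brain regions x two genotypes x >= 3 biological
replicates x 3 technical replicates, with Gaussian noise on the Cq (log)
scale:

    Cq(g, sample) = base_cq + region_effect + genotype_effect[second genotype]
                    + eps_bio(bio_rep) + eps_tech(tech_rep)

eps_bio ~ N(0, bio_sd^2) is shared by a biological replicate's technical
triplicate; eps_tech ~ N(0, tech_sd^2) is per well; technical dropouts occur
independently with probability dropout_p.  A genotype effect of d cycles in
the second genotype corresponds to a true expression fold change of 2^-d.

Alongside the sampled table the generator returns a :class:`SimulationTruth`
— a deterministic function of the configuration alone — holding the designed
stability order (by a declared composite instability score) and the true
per-region fold changes, so that every downstream pipeline stage can be
tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cq_data import (CqTable, Design, GENOTYPES, NINE_REGIONS)
from .errors import ValidationError


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters of one gene.

    ``genotype_effect`` is the Cq offset applied in the second genotype,
    either a single number (same in every region) or a region -> cycles map
    (absent regions get 0); log2 fold change = -genotype_effect.
    """

    symbol: str
    base_cq: float
    region_effects: Mapping[str, float] = field(default_factory=dict)
    genotype_effect: float | Mapping[str, float] = 0.0
    bio_sd: float = 0.0
    tech_sd: float = 0.0
    dropout_p: float = 0.0

    def __post_init__(self) -> None:
        if not (5.0 < self.base_cq < 40.0):
            raise ValidationError(
                f"{self.symbol}: base_cq must lie in (5, 40), got {self.base_cq}")
        if self.bio_sd < 0 or self.tech_sd < 0:
            raise ValidationError(f"{self.symbol}: SDs must be >= 0")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValidationError(
                f"{self.symbol}: dropout_p must be in [0, 1), got {self.dropout_p}")

    def effect_in(self, region: str) -> float:
        if isinstance(self.genotype_effect, Mapping):
            return float(self.genotype_effect.get(region, 0.0))
        return float(self.genotype_effect)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study design plus per-gene generative parameters."""

    genes: tuple[GeneSpec, ...]
    regions: tuple[str, ...] = NINE_REGIONS
    genotypes: tuple[str, ...] = GENOTYPES
    n_bio: int = 3
    n_tech: int = 3
    n_bio_overrides: Mapping[tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes) != 2:
            raise ValidationError("generator requires exactly two genotypes")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("gene symbols must be unique")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValidationError("n_bio and n_tech must be >= 1")
        for (region, genotype), n in self.n_bio_overrides.items():
            if region not in self.regions or genotype not in self.genotypes:
                raise ValidationError(
                    f"override cell ({region!r}, {genotype!r}) outside the design")
            if n < 1:
                raise ValidationError("per-cell n_bio override must be >= 1")
        for g in self.genes:
            unknown = [r for r in (g.region_effects or {}) if r not in self.regions]
            if unknown:
                raise ValidationError(
                    f"{g.symbol}: region effect(s) for unknown region {unknown}")
            if isinstance(g.genotype_effect, Mapping):
                unknown = [r for r in g.genotype_effect if r not in self.regions]
                if unknown:
                    raise ValidationError(
                        f"{g.symbol}: genotype effect(s) for unknown region {unknown}")

    @property
    def design(self) -> Design:
        return Design(self.regions, self.genotypes)

    def n_bio_in(self, region: str, genotype: str) -> int:
        return int(self.n_bio_overrides.get((region, genotype), self.n_bio))

    def n_samples(self) -> int:
        """Total number of technical-replicate columns the design yields."""
        return sum(self.n_bio_in(r, g) for r in self.regions
                   for g in self.genotypes) * self.n_tech

    # -- text round trip -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "regions": list(self.regions),
            "genotypes": list(self.genotypes),
            "n_bio": self.n_bio,
            "n_tech": self.n_tech,
            "n_bio_overrides": [
                {"region": r, "genotype": g, "n_bio": n}
                for (r, g), n in self.n_bio_overrides.items()],
            "seed": self.seed,
            "genes": [
                {"symbol": g.symbol, "base_cq": g.base_cq,
                 "region_effects": dict(g.region_effects),
                 "genotype_effect": (dict(g.genotype_effect)
                                     if isinstance(g.genotype_effect, Mapping)
                                     else g.genotype_effect),
                 "bio_sd": g.bio_sd, "tech_sd": g.tech_sd,
                 "dropout_p": g.dropout_p}
                for g in self.genes],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        genes = tuple(
            GeneSpec(symbol=g["symbol"], base_cq=float(g["base_cq"]),
                     region_effects=g.get("region_effects", {}) or {},
                     genotype_effect=g.get("genotype_effect", 0.0),
                     bio_sd=float(g.get("bio_sd", 0.0)),
                     tech_sd=float(g.get("tech_sd", 0.0)),
                     dropout_p=float(g.get("dropout_p", 0.0)))
            for g in doc["genes"])
        overrides = {(o["region"], o["genotype"]): int(o["n_bio"])
                     for o in doc.get("n_bio_overrides", []) or []}
        return cls(genes=genes, regions=tuple(doc["regions"]),
                   genotypes=tuple(doc["genotypes"]),
                   n_bio=int(doc.get("n_bio", 3)),
                   n_tech=int(doc.get("n_tech", 3)),
                   n_bio_overrides=overrides, seed=int(doc.get("seed", 0)))


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth implied by a configuration (no sampling involved).

    The composite instability score declared for the truth ordering is
    sqrt(bio_sd^2 + var(region_effects) + mean(genotype_effect^2)), the
    population variance taken over all configured regions (absent regions
    contribute an offset of 0) and the genotype term averaged over regions
    for region-dependent effects.  It is used only as test ground truth.
    """

    instability_score: dict[str, float]
    true_stability_order: tuple[str, ...]
    true_fold_changes: dict[tuple[str, str], float]  # (gene, region) -> fold


def simulation_truth(config: GeneratorConfig) -> SimulationTruth:
    scores: dict[str, float] = {}
    folds: dict[tuple[str, str], float] = {}
    for g in config.genes:
        eff = np.array([float((g.region_effects or {}).get(r, 0.0))
                        for r in config.regions])
        gen = np.array([g.effect_in(r) for r in config.regions])
        scores[g.symbol] = float(np.sqrt(
            g.bio_sd ** 2 + eff.var(ddof=0) + np.mean(gen ** 2)))
        for r in config.regions:
            folds[(g.symbol, r)] = float(2.0 ** (-g.effect_in(r)))
    order = tuple(sorted(scores, key=lambda s: (scores[s], s)))
    return SimulationTruth(scores, order, folds)


def generate(config: GeneratorConfig) -> tuple[CqTable, SimulationTruth]:
    """Sample a CqTable from the configuration; reproducible from its seed.

    Randomness is split per gene from a single root seed sequence, so adding
    or removing genes does not perturb the draws of the others.
    """
    design = config.design
    cells: list[tuple[str, str, int]] = []   # (region, genotype, bio_rep)
    for region in config.regions:
        for genotype in config.genotypes:
            for b in range(1, config.n_bio_in(region, genotype) + 1):
                cells.append((region, genotype, b))
    sample_rows = []
    for region, genotype, b in cells:
        for tch in range(1, config.n_tech + 1):
            sid = f"{region.replace(' ', '-')}_{genotype}_b{b}_t{tch}"
            sample_rows.append({"sample_id": sid, "region": region,
                                "genotype": genotype, "bio_rep": b,
                                "tech_rep": tch})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    second = config.genotypes[1]
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.genes))
    rows = np.empty((len(config.genes), len(samples)))
    for gi, g in enumerate(config.genes):
        rng = np.random.default_rng(children[gi])
        col = 0
        for region, genotype, b in cells:
            mu = (g.base_cq
                  + float((g.region_effects or {}).get(region, 0.0))
                  + (g.effect_in(region) if genotype == second else 0.0))
            bio = rng.normal(0.0, g.bio_sd) if g.bio_sd > 0 else 0.0
            tech = (rng.normal(0.0, g.tech_sd, size=config.n_tech)
                    if g.tech_sd > 0 else np.zeros(config.n_tech))
            vals = mu + bio + tech
            if g.dropout_p > 0:
                drop = rng.random(config.n_tech) < g.dropout_p
                vals = np.where(drop, np.nan, vals)
            rows[gi, col:col + config.n_tech] = vals
            col += config.n_tech
    values = pd.DataFrame(rows, index=[g.symbol for g in config.genes],
                          columns=samples.index)
    return CqTable(values, samples, design), simulation_truth(config)


# ---------------------------------------------------------------------------
# ready-made study-like configuration
# ---------------------------------------------------------------------------

#: Candidate reference genes of the screening pool; the first three are
#: designed unstable (conventional housekeepers that fail across brain
#: regions), the remaining eight survive screening, and Alg5/Hmbs/Gusb are
#: the designed low-noise panel.
UNSTABLE_CANDIDATES = ("Sdha", "B2m", "Actb")
SURVIVOR_CANDIDATES = ("Alg5", "Mogs", "Hmbs", "Gusb", "Man2b2", "Cyc1",
                       "Snhg12", "Tfrc")
PANEL_GENES = ("Alg5", "Hmbs", "Gusb")
TARGET_GENES = ("Igfbp7", "Pcsk1", "Pcsk2", "Nhlh2",
                "Nlgn3_total", "Nlgn3_iso1", "Nlgn3_iso2")


def pws_brain_config(seed: int = 0, include_targets: bool = True
                     ) -> GeneratorConfig:
    """Configuration emulating the nine-region WT vs PWScr brain survey.

    Eleven candidate reference genes: three designed-unstable conventional
    housekeepers (large biological noise, regional and genotype effects),
    five moderately noisy survivors, and three designed panel genes with low
    noise and no genotype effect.  Optional target genes carry
    region-dependent genotype effects qualitatively mimicking the reported
    expression differences (Igfbp7 up in the mutant; Pcsk1 down in
    hypothalamus and pons; Pcsk2 up in four regions; Nhlh2 up in cerebellum,
    midbrain and hippocampus; all Nlgn3 isoforms mildly up).  Three
    biological replicates per cell (six for WT hypothalamus), technical
    triplicates.
    """
    tech = 0.15
    genes: list[GeneSpec] = [
        # designed panel: tight, effect-free
        GeneSpec("Alg5", 21.0, bio_sd=0.10, tech_sd=tech),
        GeneSpec("Hmbs", 24.5, bio_sd=0.10, tech_sd=tech),
        GeneSpec("Gusb", 26.0, bio_sd=0.10, tech_sd=tech),
        # moderate survivors
        GeneSpec("Mogs", 23.0, bio_sd=0.60, tech_sd=tech,
                 region_effects={"cerebellum": 0.2}),
        GeneSpec("Man2b2", 24.0, bio_sd=0.65, tech_sd=tech,
                 region_effects={"isocortex": -0.2}),
        GeneSpec("Cyc1", 19.5, bio_sd=0.70, tech_sd=tech),
        GeneSpec("Snhg12", 22.5, bio_sd=0.75, tech_sd=tech,
                 region_effects={"hippocampus": 0.3}),
        GeneSpec("Tfrc", 23.5, bio_sd=0.80, tech_sd=tech,
                 genotype_effect=0.10),
        # designed-unstable conventional housekeepers
        GeneSpec("Sdha", 22.0, bio_sd=1.40, tech_sd=tech,
                 region_effects={"cerebellum": 1.0, "hypothalamus": -0.8},
                 genotype_effect=0.5),
        GeneSpec("B2m", 20.0, bio_sd=1.50, tech_sd=tech,
                 region_effects={"olfactory bulb": 1.2, "medulla": -0.9},
                 genotype_effect=-0.5),
        GeneSpec("Actb", 17.0, bio_sd=1.60, tech_sd=tech,
                 region_effects={"isocortex": -1.0, "pons": 0.9},
                 genotype_effect=0.6),
    ]
    if include_targets:
        genes += [
            GeneSpec("Igfbp7", 22.0, bio_sd=0.15, tech_sd=tech,
                     region_effects={"hypothalamus": -0.5, "cerebellum": 0.5},
                     genotype_effect={"hippocampus": -0.5, "hypothalamus": -0.5,
                                      "cerebellum": -0.5, "olfactory bulb": -0.2,
                                      "isocortex": -0.2, "thalamus": -0.2,
                                      "midbrain": -0.2, "pons": -0.2,
                                      "medulla": -0.2}),
            GeneSpec("Pcsk1", 26.0, bio_sd=0.15, tech_sd=tech,
                     region_effects={"hypothalamus": -1.5, "olfactory bulb": -1.0,
                                     "isocortex": -0.8, "hippocampus": 1.0},
                     genotype_effect={"hypothalamus": 1.0, "pons": 0.4}),
            GeneSpec("Pcsk2", 24.0, bio_sd=0.15, tech_sd=tech,
                     region_effects={"isocortex": -1.2, "hippocampus": -0.6,
                                     "thalamus": -0.5, "olfactory bulb": 0.8,
                                     "cerebellum": 0.8, "pons": 0.8},
                     genotype_effect={"olfactory bulb": -0.4, "isocortex": -0.4,
                                      "hippocampus": -0.4, "medulla": -0.4}),
            GeneSpec("Nhlh2", 28.0, bio_sd=0.20, tech_sd=tech,
                     region_effects={"cerebellum": -2.0, "thalamus": -1.0,
                                     "hypothalamus": -1.0, "olfactory bulb": 2.0,
                                     "isocortex": 4.0},
                     genotype_effect={"cerebellum": -1.0, "midbrain": -1.0,
                                      "hippocampus": -0.7}),
            GeneSpec("Nlgn3_total", 23.0, bio_sd=0.12, tech_sd=tech,
                     region_effects={"hippocampus": -0.5, "isocortex": -0.4,
                                     "cerebellum": 0.6, "medulla": 0.6},
                     genotype_effect=-0.20),
            GeneSpec("Nlgn3_iso1", 25.0, bio_sd=0.12, tech_sd=tech,
                     region_effects={"thalamus": -0.5, "hippocampus": -0.4,
                                     "hypothalamus": 0.8},
                     genotype_effect=-0.26),
            GeneSpec("Nlgn3_iso2", 25.5, bio_sd=0.12, tech_sd=tech,
                     region_effects={"hippocampus": -0.5, "isocortex": -0.4},
                     genotype_effect=-0.20),
        ]
    return GeneratorConfig(
        genes=tuple(genes),
        n_bio=3, n_tech=3,
        n_bio_overrides={("hypothalamus", "WT"): 6},
        seed=seed)
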