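"""Cq-table data model, validated I/O and technical-replicate collapsing.

The central container is :class:`CqTable`: a genes x samples matrix of
quantification-cycle (Cq) values together with per-sample annotations
(brain region, genotype, biological and technical replicate).  Technical
replicates are collapsed by arithmetic mean of Cq into a
:class:`CollapsedCqTable` with one column per biological replicate; every
downstream stability or quantification routine consumes the collapsed form.

Missing Cq values (non-detects) are carried as NaN and propagate as missing;
nothing in this module imputes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: The nine anatomical brain regions of the study design, in rostro-caudal order.
NINE_REGIONS: tuple[str, ...] = (
    "olfactory bulb",
    "isocortex",
    "hippocampus",
    "thalamus",
    "hypothalamus",
    "midbrain",
    "cerebellum",
    "pons",
    "medulla",
)

#: Default genotypes: wild type and the PWS-critical-region deletion model.
GENOTYPES: tuple[str, ...] = ("WT", "PWScr")

ANNOTATION_COLUMNS = ("region", "genotype", "bio_rep", "tech_rep")
LONG_COLUMNS = ("sample_id", "gene", "cq") + ANNOTATION_COLUMNS


@dataclass(frozen=True)
class Design:
    """Declared factor levels of an experiment.

    Values outside the declared levels are rejected at read/validation time,
    so a typo in a region name fails loudly instead of silently creating a
    tenth region.
    """

    regions: tuple[str, ...] = NINE_REGIONS
    genotypes: tuple[str, ...] = GENOTYPES

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("duplicate region levels in design")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValidationError("duplicate genotype levels in design")
        if len(self.genotypes) < 1 or len(self.regions) < 1:
            raise ValidationError("design needs at least one region and one genotype")


DEFAULT_DESIGN = Design()


@dataclass(frozen=True)
class SampleAnnotation:
    """Annotation of a single measured well/column."""

    sample_id: str
    region: str
    genotype: str
    bio_rep: int
    tech_rep: int = 1

    def key(self) -> tuple[str, str, int, int]:
        return (self.region, self.genotype, self.bio_rep, self.tech_rep)


def _check_samples_frame(samples: pd.DataFrame, design: Design, *, collapsed: bool) -> None:
    required = ["region", "genotype", "bio_rep"] + ([] if collapsed else ["tech_rep"])
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample annotation missing columns: {missing}")
    if samples.index.has_duplicates:
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    bad_region = sorted(set(samples["region"]) - set(design.regions))
    if bad_region:
        raise ValidationError(
            f"unknown region level(s) {bad_region}; valid: {list(design.regions)}"
        )
    bad_geno = sorted(set(samples["genotype"]) - set(design.genotypes))
    if bad_geno:
        raise ValidationError(
            f"unknown genotype level(s) {bad_geno}; valid: {list(design.genotypes)}"
        )
    for col in ("bio_rep",) + (() if collapsed else ("tech_rep",)):
        vals = samples[col]
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError(f"{col} must be integer, got dtype {vals.dtype}")
        if (vals < 1).any():
            raise ValidationError(f"{col} must be >= 1")
    keycols = ["region", "genotype", "bio_rep"] + ([] if collapsed else ["tech_rep"])
    dup = samples.duplicated(subset=keycols)
    if dup.any():
        first = samples.loc[dup, keycols].iloc[0].tolist()
        raise ValidationError(
            f"(region, genotype, bio_rep{'' if collapsed else ', tech_rep'}) "
            f"not unique; duplicated key {first}"
        )


class CqTable:
    """Genes x samples matrix of Cq values with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample id.
        Entries are Cq in PCR cycles; NaN marks a non-detect.
    samples
        DataFrame indexed by sample id with columns ``region``, ``genotype``,
        ``bio_rep``, ``tech_rep``; column order must match ``values.columns``.
    design
        Declared factor levels; defaults to the nine-region, two-genotype
        study design.
    """

    _collapsed = False

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame,
                 design: Design = DEFAULT_DESIGN) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        if list(values.columns) != list(samples.index):
            raise ValidationError(
                "matrix columns and sample annotation rows do not match "
                f"({len(values.columns)} columns vs {len(samples)} annotations)"
            )
        _check_samples_frame(samples, design, collapsed=self._collapsed)
        arr = values.to_numpy()
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ValidationError("Cq values must be finite or missing (NaN)")
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("Cq values must be >= 0")
        self.values = values
        self.samples = samples
        self.design = design

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<{type(self).__name__} {self.n_genes} genes x "
                f"{self.n_samples} samples>")

    # -- long-format views ---------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Tidy long-format frame with one row per (gene, sample)."""
        long = (self.values.rename_axis(index="gene", columns="sample_id")
                .stack(future_stack=True).rename("cq").reset_index())
        ann_cols = [c for c in ANNOTATION_COLUMNS if c in self.samples.columns]
        ann = self.samples[list(ann_cols)].rename_axis("sample_id").reset_index()
        out = long.merge(ann, on="sample_id", how="left")
        return out[["sample_id", "gene", "cq"] + list(ann_cols)]

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write the table in canonical long format (UTF-8, header row)."""
        self.to_long().to_csv(path, sep=sep, index=False, float_format="%.10g")

    def _replace(self, values: pd.DataFrame, samples: pd.DataFrame) -> "CqTable":
        return type(self)(values, samples, self.design)


class CollapsedCqTable(CqTable):
    """A CqTable with technical replicates averaged: one column per
    (region, genotype, bio_rep) cell.

    ``tech_spread`` holds the per-cell sample SD (cycles) of the technical
    replicates that were averaged; NaN where fewer than two replicates were
    present.  ``spread_warnings`` lists (gene, sample_id, spread) triples that
    exceeded the collapse threshold — flagged, never removed.
    """

    _collapsed = True

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame,
                 design: Design = DEFAULT_DESIGN,
                 tech_spread: pd.DataFrame | None = None,
                 spread_warnings: list[tuple[str, str, float]] | None = None) -> None:
        super().__init__(values, samples, design)
        if tech_spread is None:
            tech_spread = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
        if (tech_spread.shape != values.shape
                or list(tech_spread.index) != list(values.index)
                or list(tech_spread.columns) != list(values.columns)):
            raise ValidationError("tech_spread must mirror the Cq matrix layout")
        with np.errstate(invalid="ignore"):
            if np.nanmin(tech_spread.to_numpy(), initial=0.0) < 0:
                raise ValidationError("tech_spread must be >= 0")
        self.tech_spread = tech_spread.astype(float)
        self.spread_warnings = list(spread_warnings or [])

    def _replace(self, values: pd.DataFrame, samples: pd.DataFrame) -> "CollapsedCqTable":
        spread = self.tech_spread.loc[values.index, values.columns]
        return CollapsedCqTable(values, samples, self.design, spread,
                                self.spread_warnings)

    def condition_of(self, sample_id: str) -> tuple[str, str]:
        row = self.samples.loc[sample_id]
        return (str(row["region"]), str(row["genotype"]))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_cq_table(path: str | Path, design: Design = DEFAULT_DESIGN,
                  *, wide: bool = False, sep: str | None = None) -> CqTable:
    """Read a delimited-text Cq table.

    The canonical layout is long format with header columns
    ``sample_id, gene, cq, region, genotype, bio_rep, tech_rep``; empty or
    ``NA`` Cq cells become missing values.  With ``wide=True`` the file has
    one row per sample (annotation columns plus one column per gene).
    Delimiter is auto-detected among comma/tab unless given.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    if sep is None:
        sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                         encoding="utf-8", skipinitialspace=True)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"could not parse {path}: {exc}") from exc

    if wide:
        id_cols = ["sample_id"] + list(ANNOTATION_COLUMNS)
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: wide format missing columns {missing}")
        gene_cols = [c for c in df.columns if c not in id_cols]
        if not gene_cols:
            raise ParseError(f"{path}: wide format has no gene columns")
        df = df.melt(id_vars=id_cols, value_vars=gene_cols,
                     var_name="gene", value_name="cq")

    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required columns {missing_cols}")

    def _num(col: str, line_offset: int = 2) -> pd.Series:
        raw = df[col].str.strip()
        blank = raw.isin(("", "NA", "NaN", "nan", "na"))
        out = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = out.isna() & ~blank
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: malformed {col} value {raw.iloc[i]!r} at data line {i + line_offset}"
            )
        return out

    cq = _num("cq")
    reps = {}
    for col in ("bio_rep", "tech_rep"):
        vals = _num(col)
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ParseError(f"{path}: empty {col} at data line {i + 2}")
        if (vals % 1 != 0).any():
            raise ParseError(f"{path}: {col} must be integer")
        reps[col] = vals.astype(int)

    tidy = pd.DataFrame({
        "sample_id": df["sample_id"].str.strip(),
        "gene": df["gene"].str.strip(),
        "cq": cq,
        "region": df["region"].str.strip(),
        "genotype": df["genotype"].str.strip(),
        "bio_rep": reps["bio_rep"],
        "tech_rep": reps["tech_rep"],
    })
    return table_from_long(tidy, design)


def table_from_long(long_df: pd.DataFrame, design: Design = DEFAULT_DESIGN
                    ) -> CqTable:
    """Build a CqTable from a tidy long-format frame.

    Expects the canonical columns ``sample_id, gene, cq, region, genotype,
    bio_rep, tech_rep``; first-appearance order of genes and samples is
    preserved.
    """
    missing_cols = [c for c in LONG_COLUMNS if c not in long_df.columns]
    if missing_cols:
        raise ValidationError(f"long frame missing columns {missing_cols}")
    tidy = long_df.copy()
    tidy["sample_id"] = tidy["sample_id"].astype(str)
    tidy["gene"] = tidy["gene"].astype(str)
    tidy["cq"] = pd.to_numeric(tidy["cq"], errors="coerce")
    for col in ("bio_rep", "tech_rep"):
        tidy[col] = pd.to_numeric(tidy[col]).astype(int)

    dup = tidy.duplicated(subset=["gene", "sample_id"])
    if dup.any():
        g, s = tidy.loc[dup, ["gene", "sample_id"]].iloc[0]
        raise ValidationError(f"duplicate (gene, sample) pair: ({g!r}, {s!r})")

    ann = (tidy.drop_duplicates("sample_id")
           .set_index("sample_id")[list(ANNOTATION_COLUMNS)])
    # consistency of annotations across rows of one sample
    chk = tidy.groupby("sample_id")[list(ANNOTATION_COLUMNS)].nunique()
    inconsistent = chk[(chk > 1).any(axis=1)]
    if len(inconsistent):
        raise ValidationError(
            f"inconsistent annotations for sample(s): {list(inconsistent.index)}"
        )

    values = tidy.pivot(index="gene", columns="sample_id", values="cq")
    # preserve first-appearance order of genes and samples
    gene_order = tidy["gene"].drop_duplicates().tolist()
    sample_order = tidy["sample_id"].drop_duplicates().tolist()
    values = values.loc[gene_order, sample_order]
    ann = ann.loc[sample_order]
    return CqTable(values, ann, design)


# ---------------------------------------------------------------------------
# collapsing and subsetting
# ---------------------------------------------------------------------------

def collapse_technical_replicates(t: CqTable, spread_warn: float = 0.5
                                  ) -> CollapsedCqTable:
    """Average technical replicates into one column per biological replicate.

    Per-cell Cq is the arithmetic mean of the non-missing technical
    replicates; a cell is missing iff all its technical replicates are
    missing.  Cells whose technical SD exceeds ``spread_warn`` cycles are
    flagged in ``spread_warnings`` (and logged) but never removed.
    Idempotent: collapsing an already-collapsed table returns it unchanged.
    """
    if isinstance(t, CollapsedCqTable):
        return t
    keys = list(zip(t.samples["region"], t.samples["genotype"], t.samples["bio_rep"]))
    order: list[tuple[str, str, int]] = []
    seen = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    cols, anns, means, spreads = [], [], [], []
    arr = t.values.to_numpy()
    key_arr = np.array([order.index(k) for k in keys])
    for i, (region, genotype, bio) in enumerate(order):
        block = arr[:, key_arr == i]
        n_present = np.sum(~np.isnan(block), axis=1)
        sums = np.nansum(block, axis=1)
        mean = np.divide(sums, n_present, out=np.full(block.shape[0], np.nan),
                         where=n_present > 0)
        sd = np.full(block.shape[0], np.nan)
        for g in np.flatnonzero(n_present >= 2):
            present = block[g][~np.isnan(block[g])]
            sd[g] = np.std(present, ddof=1)
        sid = f"{region}|{genotype}|b{bio}"
        cols.append(sid)
        anns.append({"region": region, "genotype": genotype, "bio_rep": int(bio)})
        means.append(mean)
        spreads.append(sd)
    values = pd.DataFrame(np.column_stack(means), index=t.values.index, columns=cols)
    spread = pd.DataFrame(np.column_stack(spreads), index=t.values.index, columns=cols)
    samples = pd.DataFrame(anns, index=pd.Index(cols, name="sample_id"))
    warnings_list: list[tuple[str, str, float]] = []
    hit = spread.to_numpy() > spread_warn
    for gi, ci in zip(*np.nonzero(hit)):
        trip = (str(values.index[gi]), cols[ci], float(spread.iat[gi, ci]))
        warnings_list.append(trip)
        logger.warning("technical spread %.3f cycles > %.3f for gene %s, sample %s",
                       trip[2], spread_warn, trip[0], trip[1])
    return CollapsedCqTable(values, samples, t.design, spread, warnings_list)


def subset_condition(t: CqTable, region: str | None = None,
                     genotype: str | None = None,
                     genes: Sequence[str] | None = None) -> CqTable:
    """Restrict a table to one region and/or genotype and/or a gene subset.

    Ordering of the retained genes and samples is preserved.  Unknown levels
    raise :class:`ValidationError`; a selection matching nothing raises
    :class:`EmptySelectionError`.
    """
    mask = np.ones(t.n_samples, dtype=bool)
    if region is not None:
        if region not in t.design.regions:
            raise ValidationError(
                f"unknown region {region!r}; valid: {list(t.design.regions)}")
        mask &= (t.samples["region"] == region).to_numpy()
    if genotype is not None:
        if genotype not in t.design.genotypes:
            raise ValidationError(
                f"unknown genotype {genotype!r}; valid: {list(t.design.genotypes)}")
        mask &= (t.samples["genotype"] == genotype).to_numpy()
    values = t.values.loc[:, mask]
    samples = t.samples.loc[mask]
    if genes is not None:
        missing = [g for g in genes if g not in t.values.index]
        if missing:
            raise ValidationError(f"genes not in table: {missing}")
        values = values.loc[list(genes)]
    if values.shape[1] == 0 or values.shape[0] == 0:
        raise EmptySelectionError(
            f"selection (region={region!r}, genotype={genotype!r}, genes={genes!r}) "
            "matches no data")
    return t._replace(values, samples)
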