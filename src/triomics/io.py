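"""Central data types and readers/writers for the tab-delimited interchange formats.

All tables are UTF-8, tab-delimited; floats are written with 6 significant
digits.  Gene and sample identifiers are case-preserved everywhere, but
matching against gene-set collections (GMT / MSigDB symbols, conventionally
uppercase) is case-insensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("triomics")

LOCUS_TYPES = ("coding", "multiple_complex", "noncoding", "other")
GROUPS = ("proband", "father", "mother", "HC")
MODELS = ("PBMC", "plasma", "THP1_mono", "THP1_macro")
CFTR_CLASSES = ("I_II_III", "IV", "NA")
PANCREATIC = ("PI", "PS", "NA")
PA_INFECTION = ("pos", "neg", "NA")

METADATA_COLUMNS = [
    "sample_id", "group", "family_id", "model", "cftr_class",
    "pancreatic", "pa_infection", "sweat_chloride", "fev1_pct",
]

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A malformed input file (bad structure, duplicate or invalid values)."""


class ValidationError(ValueError):
    """Inputs violate a domain invariant (mismatched samples, bad contrast...)."""


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        if np.isnan(x):
            return "NA"
        return FLOAT_FMT % x
    return str(x)


# ---------------------------------------------------------------------------
# Expression matrix


class ExpressionMatrix:
    """Genes x samples log2 expression with a per-gene locus-type annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene IDs), samples in columns, log2 units.
    locus_type : pandas.Series
        Per-gene category, one of ``coding``, ``multiple_complex``,
        ``noncoding``, ``other``; indexed like ``values``.
    """

    def __init__(self, values: pd.DataFrame, locus_type: pd.Series):
        values = values.astype(float)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID: {dup!r}")
        if not np.isfinite(values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
            raise FormatError(
                f"non-finite expression value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        locus_type = locus_type.reindex(values.index)
        if locus_type.isna().any():
            missing = locus_type.index[locus_type.isna()][0]
            raise FormatError(f"gene {missing!r} has no locus type")
        unknown = ~locus_type.isin(LOCUS_TYPES)
        if unknown.any():
            for g in locus_type.index[unknown]:
                logger.warning("unknown locus type %r for gene %r mapped to 'other'",
                               locus_type[g], g)
            locus_type = locus_type.where(~unknown, "other")
        self.values = values
        self.locus_type = locus_type.rename("locus_type")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], self.locus_type.loc[genes])

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(self.values, other.values, rtol=1e-5, atol=1e-8)
            and (self.locus_type == other.locus_type).all()
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV with columns (gene_id, locus_type, <sample>...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected gene_id, locus_type and >=1 sample column")
    gene_col, locus_col = df.columns[0], df.columns[1]
    dup = df[gene_col][df[gene_col].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene ID {dup.iloc[0]!r}")
    sample_cols = list(df.columns[2:])
    vals = {}
    for c in sample_cols:
        try:
            vals[c] = pd.to_numeric(df[c], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()][0]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[bad, c]!r} at row "
                f"{bad + 2}, column {c!r}"
            ) from None
    values = pd.DataFrame(vals, index=pd.Index(df[gene_col], name="gene_id"))
    locus = pd.Series(df[locus_col].to_numpy(), index=values.index, name="locus_type")
    em = ExpressionMatrix(values, locus)
    logger.info("read expression %s: %d genes x %d samples", path, *em.shape)
    return em


def write_expression(em: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tlocus_type\t" + "\t".join(em.sample_ids) + "\n")
        arr = em.values.to_numpy()
        for i, g in enumerate(em.gene_ids):
            row = "\t".join(FLOAT_FMT % v for v in arr[i])
            fh.write(f"{g}\t{em.locus_type.iloc[i]}\t{row}\n")


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample metadata table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[METADATA_COLUMNS].copy()
    for col in ("sweat_chloride", "fev1_pct"):
        df[col] = pd.to_numeric(df[col].mask(df[col] == "NA"), errors="coerce")
    validate_metadata(df)
    logger.info("read metadata %s: %d samples, %d families", path, len(df),
                df.loc[df["group"] != "HC", "family_id"].nunique())
    return df


def validate_metadata(df: pd.DataFrame) -> None:
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        raise ValidationError(f"unknown group {df.loc[bad_group, 'group'].iloc[0]!r}")
    if not df["model"].isin(MODELS).all():
        bad = df.loc[~df["model"].isin(MODELS), "model"].iloc[0]
        raise ValidationError(f"unknown model {bad!r}")
    non_hc = df[df["group"] != "HC"]
    no_fam = non_hc["family_id"].isin(["", "NA"])
    if no_fam.any():
        sid = non_hc.loc[no_fam, "sample_id"].iloc[0]
        raise ValidationError(f"non-HC sample {sid!r} lacks a family_id")
    dup = non_hc.duplicated(subset=["family_id", "group", "model"])
    if dup.any():
        row = non_hc[dup].iloc[0]
        raise ValidationError(
            f"family {row['family_id']!r} has more than one {row['group']!r} "
            f"sample in model {row['model']!r}"
        )
    for col in ("sweat_chloride", "fev1_pct"):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"negative {col} value")


def write_metadata(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as tab-delimited UTF-8, 6-significant-digit floats,
    missing values as the literal ``NA``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Contrasts


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison; ``paired`` pairs on family_id (trio members)."""

    name: str
    case_group: str
    reference_group: str
    paired: bool = False

    def __post_init__(self):
        if self.case_group == self.reference_group:
            raise ValidationError(f"contrast {self.name!r}: case equals reference")
        if self.paired:
            trio = {"proband", "father", "mother"}
            if not ({self.case_group, self.reference_group} <= trio):
                raise ValidationError(
                    f"contrast {self.name!r}: paired contrasts require trio groups"
                )


# ---------------------------------------------------------------------------
# Gene set collections (GMT)


@dataclass
class GeneSetCollection:
    name: str
    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for sname, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {sname!r} is empty")
            self.sets[sname] = set(genes)

    def __len__(self):
        return len(self.sets)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: set-name TAB description TAB gene TAB gene ..."""
    sets, desc = {}, {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets[fields[0]] = set(fields[2:])
            desc[fields[0]] = fields[1]
    return GeneSetCollection(name or str(path), sets, desc)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sname in coll.sets:
            genes = sorted(coll.sets[sname])
            fh.write("\t".join([sname, coll.descriptions.get(sname, "")] + genes) + "\n")


def match_genes(query, reference) -> set:
    """Case-insensitive intersection, returning members of ``query`` spelling."""
    ref_upper = {g.upper() for g in reference}
    return {g for g in query if g.upper() in ref_upper}


# ---------------------------------------------------------------------------
# Marker panels


@dataclass
class MarkerPanel:
    """Cell-subset marker genes: a (subset, gene_id, panel_group) table.

    ``stage`` is ``candidate`` before and ``selected`` after the
    pairwise-correlation selection step; after selection ``record`` holds the
    per-gene mean pairwise r, its p value and the keep decision.
    """

    table: pd.DataFrame
    stage: str = "candidate"
    record: pd.DataFrame | None = None

    def __post_init__(self):
        need = {"subset", "gene_id", "panel_group"}
        if not need <= set(self.table.columns):
            raise FormatError(f"marker panel needs columns {sorted(need)}")
        if self.stage not in ("candidate", "selected"):
            raise ValidationError(f"unknown panel stage {self.stage!r}")

    @property
    def subsets(self) -> list[str]:
        return list(dict.fromkeys(self.table["subset"]))

    def genes(self, subset: str) -> list[str]:
        return list(self.table.loc[self.table["subset"] == subset, "gene_id"])


def read_marker_panel(path, stage: str = "candidate") -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "panel_group" not in df.columns:
        df["panel_group"] = "main"
    return MarkerPanel(df, stage=stage)


def write_marker_panel(panel: MarkerPanel, path) -> None:
    write_table(panel.table, path)


# ---------------------------------------------------------------------------
# Cross-input validation


def check_samples_match(em: ExpressionMatrix, meta: pd.DataFrame) -> None:
    """Reject an expression/metadata pair whose sample-ID sets differ."""
    e, m = set(em.sample_ids), set(meta["sample_id"])
    if e != m:
        raise ValidationError(
            "expression and metadata sample sets differ: "
            f"expression-only={sorted(e - m)}, metadata-only={sorted(m - e)}"
        )
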