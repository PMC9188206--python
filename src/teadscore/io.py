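"""Readers and writers for the pipeline's external formats.

Formats handled
---------------
* expression matrices — TSV, genes-as-rows on disk by default (the
  dominant convention), samples-as-rows in memory;
* two-part gene-set signatures — GMT with a ``NAME_POS`` / ``NAME_NEG``
  line pair (a single-direction GMT line cannot carry a signed signature);
* mutation tables — minimal MAF-like TSV (sample, gene, variant class);
* thresholded copy-number tables — GISTIC ``all_thresholded.by_genes``
  style TSV with integer calls in {-2..+2};
* differential-expression tables — TSV with ``gene``, ``logFC``,
  ``pvalue`` columns.

Every reader validates the domain invariants on entry and every
reader/writer pair round-trips content exactly (to 1e-12 for floats).
Gene identifiers are case-sensitive exact strings; no alias resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError
from .signature import DEExperiment, Signature

__all__ = [
    "ExpressionMatrix",
    "MutationTable",
    "CopyNumberTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_mutation_table",
    "write_mutation_table",
    "read_copy_number_table",
    "write_copy_number_table",
    "read_de_table",
    "write_de_table",
    "MAF_NONSYNONYMOUS",
    "MAF_CLASSES",
]

logger = logging.getLogger("teadscore")

# MAF Variant_Classification vocabulary.  The non-synonymous subset is the
# package's declared reading of "protein-altering"; everything else in the
# dialect (and anything unknown) is treated as not protein-altering.
MAF_NONSYNONYMOUS = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
})
_MAF_NEUTRAL = frozenset({
    "Silent", "Splice_Region", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
    "Intron", "IGR", "RNA", "Targeted_Region",
})
MAF_CLASSES = MAF_NONSYNONYMOUS | _MAF_NEUTRAL
_MAF_CANONICAL = {c.lower(): c for c in MAF_CLASSES}


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes abundance matrix.

    Values are any monotone abundance unit (counts, TPM, normalized
    intensity) — downstream scoring is rank-based and therefore
    scale-free.  Missing values are NaN and are dropped per sample at
    scoring time.
    """

    data: pd.DataFrame = field(compare=False)

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene ids: {dups[:5]}")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=1 sample and >=2 genes, got shape {df.shape}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass(frozen=True)
class MutationTable:
    """Long-format somatic mutation calls (one row per mutation event).

    Duplicates are allowed: a gene may carry several mutations in the
    same sample.  ``samples`` is the set of samples covered by mutation
    profiling (a sample with zero rows is wildtype, not unprofiled);
    it defaults to the samples present in the rows.
    """

    rows: pd.DataFrame = field(compare=False)
    samples: frozenset = frozenset()

    def __post_init__(self):
        need = {"sample_id", "gene_symbol", "variant_classification"}
        missing = need - set(self.rows.columns)
        if missing:
            raise ValidationError(f"mutation table missing columns {sorted(missing)}")
        covered = frozenset(self.samples) | frozenset(self.rows["sample_id"])
        object.__setattr__(self, "samples", covered)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CopyNumberTable:
    """Samples x genes GISTIC-thresholded copy-number calls.

    Entries are integers in {-2, -1, 0, +1, +2} (deep deletion to
    amplification) or missing (NaN).
    """

    data: pd.DataFrame = field(compare=False)

    def __post_init__(self):
        df = self.data.astype(float)
        vals = df.to_numpy()
        finite = np.isfinite(vals)
        bad = finite & ~np.isin(vals, (-2.0, -1.0, 0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"copy-number value {vals[i, j]!r} outside {{-2..+2}} at "
                f"sample {df.index[i]!r}, gene {df.columns[j]!r}"
            )
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValidationError("duplicated sample or gene ids in copy-number table")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _read_numeric_tsv(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw = raw.replace("", np.nan)
    try:
        return raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for col in raw.columns:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric value {raw.loc[row, col]!r} at "
                    f"row {row!r}, column {col!r}"
                ) from None
        raise  # pragma: no cover - unreachable


def read_expression_matrix(path, orientation: str = "genes-as-rows") -> ExpressionMatrix:
    """Read a TSV abundance matrix.

    ``orientation`` names what the *rows on disk* are; in memory the
    matrix is always samples x genes.  Blank cells become missing.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_numeric_tsv(path)
    if orientation == "genes-as-rows":
        df = df.T
    logger.info("read expression matrix %s: %d samples x %d genes",
                path, df.shape[0], df.shape[1])
    return ExpressionMatrix(df)


def write_expression_matrix(mat: ExpressionMatrix, path,
                            orientation: str = "genes-as-rows") -> None:
    df = mat.data.T if orientation == "genes-as-rows" else mat.data
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# GMT signatures
# ---------------------------------------------------------------------------

def read_gmt(path) -> Signature:
    """Read a two-part signature from GMT.

    The file must contain exactly one ``<NAME>_POS`` and one
    ``<NAME>_NEG`` line with the same stem; extra sets are rejected so a
    signature file cannot silently carry unrelated gene sets.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs NAME<TAB>description<TAB>gene..."
                )
            sets[parts[0]] = set(g for g in parts[2:] if g)
    pos_names = [n for n in sets if n.endswith("_POS")]
    neg_names = [n for n in sets if n.endswith("_NEG")]
    if len(pos_names) != 1 or len(neg_names) != 1:
        raise FormatError(
            f"{path}: expected exactly one *_POS and one *_NEG set, "
            f"found {sorted(sets)}"
        )
    stem_p, stem_n = pos_names[0][:-4], neg_names[0][:-4]
    if stem_p != stem_n:
        raise FormatError(
            f"{path}: set name stems disagree: {pos_names[0]!r} vs {neg_names[0]!r}"
        )
    return Signature(frozenset(sets[pos_names[0]]),
                     frozenset(sets[neg_names[0]]), name=stem_p)


def write_gmt(sig: Signature, path) -> None:
    if not sig.positive or not sig.negative:
        raise ValidationError(
            "refusing to write a signature with an empty effector set "
            f"(|pos|={len(sig.positive)}, |neg|={len(sig.negative)})"
        )
    with open(path, "w") as fh:
        fh.write("\t".join([f"{sig.name}_POS", "positive effectors",
                            *sorted(sig.positive)]) + "\n")
        fh.write("\t".join([f"{sig.name}_NEG", "negative effectors",
                            *sorted(sig.negative)]) + "\n")


# ---------------------------------------------------------------------------
# Mutation tables (MAF-minimal dialect)
# ---------------------------------------------------------------------------

_MAF_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene_symbol",
    "Variant_Classification": "variant_classification",
}


def normalize_variant_classification(value: str) -> str:
    """Map a classification string to its canonical dialect spelling.

    Matching is case-insensitive; unknown classes are returned
    underscore-joined in their original casing (the non-synonymous test
    later treats them, with a warning, as not protein-altering).
    """
    return _MAF_CANONICAL.get(str(value).strip().lower(), str(value).strip())


def read_mutation_table(path, dialect: str = "maf-minimal") -> MutationTable:
    if dialect != "maf-minimal":
        raise ValueError(f"unknown mutation dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_MAF_ALIASES)
    missing = {"sample_id", "gene_symbol", "variant_classification"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {sorted(missing)} "
            "(MAF names Tumor_Sample_Barcode/Hugo_Symbol/Variant_Classification accepted)"
        )
    df = df[["sample_id", "gene_symbol", "variant_classification"]].copy()
    df["variant_classification"] = df["variant_classification"].map(
        normalize_variant_classification
    )
    logger.info("read mutation table %s: %d rows", path, len(df))
    return MutationTable(df)


def write_mutation_table(tbl: MutationTable, path) -> None:
    out = tbl.rows.rename(columns={v: k for k, v in _MAF_ALIASES.items()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number tables
# ---------------------------------------------------------------------------

def read_copy_number_table(path) -> CopyNumberTable:
    """Read a GISTIC-style thresholded table (gene rows, sample columns)."""
    df = _read_numeric_tsv(path)
    return CopyNumberTable(df.T)


def write_copy_number_table(tbl: CopyNumberTable, path) -> None:
    out = tbl.data.T
    # keep integer rendering where nothing is missing
    with open(path, "w") as fh:
        fh.write("\t".join(["Gene Symbol", *map(str, out.columns)]) + "\n")
        for gene, row in out.iterrows():
            cells = ["" if not np.isfinite(v) else str(int(v)) for v in row]
            fh.write("\t".join([str(gene), *cells]) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def read_de_table(path, experiment_id: str, perturbation_sign: int,
                  tissue: str = "") -> DEExperiment:
    """Read one contrast's DE results (columns gene, logFC, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    aliases = {"logFC": "effect", "pvalue": "p", "log_fc": "effect",
               "p_value": "p", "effect": "effect", "p": "p", "gene": "gene"}
    df = df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})
    missing = {"gene", "effect", "p"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: DE table missing column(s) {sorted(missing)} "
            "(accepted: gene, logFC/effect, pvalue/p)"
        )
    return DEExperiment(experiment_id=experiment_id,
                        perturbation_sign=perturbation_sign,
                        table=df[["gene", "effect", "p"]],
                        tissue=tissue)


def write_de_table(exp: DEExperiment, path) -> None:
    out = exp.table.rename(columns={"effect": "logFC", "p": "pvalue"})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
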