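"""Readers, writers and validated containers for the on-disk tables.

The package works with three inputs: a protein quantity matrix
(proteins x samples, raw or log2 intensities, missing values allowed), a
clinical sample table (histotype, FIGO stage, age, overall and
disease-specific survival), and a protein -> GO biological-process
annotation. Two matrix dialects are supported: a plain wide TSV (first
column protein id, one column per sample) and a Spectronaut-style long
export carrying ``PG.ProteinGroups`` / ``PG.Genes`` /
``PG.ProteinDescriptions`` annotation columns followed by per-sample
intensity columns.

All result tables written by the package are TSV with a fixed column
order so diffs are stable. Missing cells are written as empty fields and
read back from either empty fields or ``NA``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("strataprot")

HISTOTYPES = ("HGSC", "EC", "MC", "CCC")
STAGES = ("I", "II", "III", "IV")
EARLY_STAGES = frozenset({"I", "II"})

_STAGE_ALIASES = {"1": "I", "2": "II", "3": "III", "4": "IV",
                  "I": "I", "II": "II", "III": "III", "IV": "IV"}

SPECTRONAUT_ID = "PG.ProteinGroups"
SPECTRONAUT_GENE = "PG.Genes"
SPECTRONAUT_DESC = "PG.ProteinDescriptions"

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """A file does not match the expected dialect."""


class ValidationError(ValueError):
    """A table violates a domain invariant."""


def stage_group(stage: str) -> str:
    """Early (I/II) vs late (III/IV) stage group; pure function of stage."""
    if stage not in STAGES:
        raise ValidationError(f"unknown FIGO stage {stage!r}")
    return "early" if stage in EARLY_STAGES else "late"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein x sample quantity table with explicit missingness.

    Parameters
    ----------
    values : pandas.DataFrame
        Proteins in rows (index = protein ids), samples in columns.
        ``NaN`` marks a missing (undetected) cell.
    scale : {"raw", "log2"}
        Raw intensities must be strictly positive where present; on the
        log2 scale zero is a legitimate value and never a missing marker.
    gene_symbols, descriptions : optional per-protein annotation, aligned
        with ``values.index``.
    """

    values: pd.DataFrame
    scale: str = "raw"
    gene_symbols: pd.Series | None = None
    descriptions: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        idx = self.values.index
        if len(idx) == 0 or len(self.values.columns) == 0:
            raise ValidationError("matrix must have at least one protein and one sample")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)
        if self.scale == "raw":
            present = self.values.to_numpy()
            if np.any(present[~np.isnan(present)] <= 0):
                raise ValidationError("raw-scale values must be > 0 where present")
        for attr in ("gene_symbols", "descriptions"):
            s = getattr(self, attr)
            if s is not None and not s.index.equals(idx):
                raise ValidationError(f"{attr} index must match protein ids")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[:, list(sample_ids)], scale=self.scale,
                               gene_symbols=self.gene_symbols,
                               descriptions=self.descriptions)

    def subset_proteins(self, protein_ids: Sequence[str]) -> "AbundanceMatrix":
        ids = list(protein_ids)
        return AbundanceMatrix(
            self.values.loc[ids],
            scale=self.scale,
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[ids],
            descriptions=None if self.descriptions is None else self.descriptions.loc[ids],
        )


_META_COLUMNS = ["histotype", "stage", "stage_group", "age",
                 "os_time", "os_event", "dss_time", "dss_event"]


@dataclass
class SampleMetadata:
    """Per-sample clinical record, indexed by sample id.

    Columns: histotype (HGSC/EC/MC/CCC), FIGO stage (I-IV), derived
    stage_group (early/late), age in years, overall- and disease-specific
    survival time in days with 0/1 event indicators. A disease-specific
    death is a death, so ``dss_event == 1`` implies ``os_event == 1``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        missing = [c for c in _META_COLUMNS if c != "stage_group" and c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        bad_h = sorted(set(df["histotype"]) - set(HISTOTYPES))
        if bad_h:
            raise ValidationError(f"unknown histotype labels: {bad_h}")
        df["stage"] = [_normalise_stage(s) for s in df["stage"]]
        df["stage_group"] = [stage_group(s) for s in df["stage"]]
        for c in ("os_time", "dss_time"):
            df[c] = df[c].astype(float)
            if (df[c] < 0).any():
                bad = df.index[df[c] < 0].tolist()
                raise ValidationError(f"negative {c} for samples {bad}")
        for c in ("os_event", "dss_event"):
            vals = set(pd.unique(df[c]))
            if not vals <= {0, 1}:
                raise ValidationError(f"{c} must be 0/1, found {sorted(vals - {0, 1})}")
            df[c] = df[c].astype(int)
        offenders = df.index[(df["dss_event"] == 1) & (df["os_event"] == 0)].tolist()
        if offenders:
            raise ValidationError(
                "dss_event = 1 implies os_event = 1 (a disease-specific death is a "
                f"death); violated by samples {offenders}")
        df["age"] = df["age"].astype(float)
        self.df = df[_META_COLUMNS]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def select(self, histotype: str | None = None, stage_group: str | None = None,
               stage: str | None = None) -> list[str]:
        """Sample ids matching the given strata (None = no restriction)."""
        mask = pd.Series(True, index=self.df.index)
        if histotype is not None:
            mask &= self.df["histotype"] == histotype
        if stage_group is not None:
            mask &= self.df["stage_group"] == stage_group
        if stage is not None:
            mask &= self.df["stage"] == stage
        return list(self.df.index[mask])


def _normalise_stage(s) -> str:
    key = str(s).strip().upper()
    if key not in _STAGE_ALIASES:
        raise ValidationError(f"unknown FIGO stage {s!r} (expected I-IV or 1-4)")
    return _STAGE_ALIASES[key]


@dataclass
class AnnotationTable:
    """Protein -> GO biological-process annotation (de-duplicated pairs)."""

    df: pd.DataFrame  # columns: protein_id, go_id, description
    term_to_proteins: dict[str, frozenset[str]] = field(init=False)
    protein_to_terms: dict[str, frozenset[str]] = field(init=False)
    descriptions: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        df = self.df.drop_duplicates(subset=["protein_id", "go_id"]).reset_index(drop=True)
        self.df = df[["protein_id", "go_id", "description"]]
        t2p: dict[str, set[str]] = {}
        p2t: dict[str, set[str]] = {}
        for p, t in zip(df["protein_id"], df["go_id"]):
            t2p.setdefault(t, set()).add(p)
            p2t.setdefault(p, set()).add(t)
        self.term_to_proteins = {t: frozenset(v) for t, v in t2p.items()}
        self.protein_to_terms = {p: frozenset(v) for p, v in p2t.items()}
        self.descriptions = dict(
            df.drop_duplicates(subset="go_id")[["go_id", "description"]].itertuples(index=False))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_abundance(path: str | Path, format: str = "wide",
                   scale: str = "raw") -> AbundanceMatrix:
    """Read a protein quantity matrix.

    ``format="wide"``: first column = protein id, remaining columns =
    samples. ``format="spectronaut_long"``: one row per protein group with
    the PG.* annotation columns followed by per-sample intensity columns.
    Empty cells and ``NA``/``NaN``/``Filtered`` are treated as missing.
    """
    path = Path(path)
    if format not in ("wide", "spectronaut_long"):
        raise ValueError(f"unknown matrix format {format!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    genes = descs = None
    if format == "spectronaut_long":
        if SPECTRONAUT_ID not in df.columns:
            raise FormatError(f"{path}: missing required column {SPECTRONAUT_ID!r}")
        annot_cols = [c for c in (SPECTRONAUT_ID, SPECTRONAUT_GENE, SPECTRONAUT_DESC)
                      if c in df.columns]
        ids = df[SPECTRONAUT_ID]
        sample_cols = [c for c in df.columns if c not in annot_cols]
        if SPECTRONAUT_GENE in df.columns:
            genes = pd.Series(df[SPECTRONAUT_GENE].to_numpy(), index=ids.to_numpy())
        if SPECTRONAUT_DESC in df.columns:
            descs = pd.Series(df[SPECTRONAUT_DESC].to_numpy(), index=ids.to_numpy())
    else:
        ids = df.iloc[:, 0]
        sample_cols = list(df.columns[1:])
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise FormatError(f"{path}: duplicate protein ids: {dups}")

    values = np.full((len(ids), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        raw = df[col].str.strip()
        present = ~raw.isin(["", "NA", "NaN", "nan", "Filtered"])
        try:
            values[present.to_numpy(), j] = raw[present].astype(float).to_numpy()
        except ValueError as exc:
            bad = raw[present][pd.to_numeric(raw[present], errors="coerce").isna()]
            row = bad.index[0]
            raise FormatError(
                f"{path}: non-numeric intensity {bad.iloc[0]!r} at row {row}, "
                f"column {col!r}") from exc
    vdf = pd.DataFrame(values, index=pd.Index(ids.to_numpy(), name="protein_id"),
                       columns=sample_cols)
    logger.info("read_abundance: %d proteins x %d samples from %s",
                vdf.shape[0], vdf.shape[1], path)
    return AbundanceMatrix(vdf, scale=scale, gene_symbols=genes, descriptions=descs)


def write_abundance(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a wide matrix TSV; missing cells become empty fields."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the clinical sample table (TSV with header, first column = sample id)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a header and at least two columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.df.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a 3-column protein/GO-term/description TSV.

    Rows whose GO id does not match ``GO:`` + 7 digits are skipped with a
    warning; exact duplicate (protein, term) pairs are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (protein_id, go_id, description)")
    df = df.iloc[:, :3]
    df.columns = ["protein_id", "go_id", "description"]
    ok = df["go_id"].map(lambda g: bool(_GO_ID_RE.match(str(g)))).astype(bool)
    n_bad = int((~ok).sum())
    if n_bad:
        bad_ids = df.loc[~ok, "go_id"].unique()[:5].tolist()
        logger.warning("read_annotation: skipped %d rows with malformed GO ids (e.g. %s)",
                       n_bad, bad_ids)
    return AnnotationTable(df[ok].reset_index(drop=True))


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def join_matrix_metadata(matrix: AbundanceMatrix,
                         metadata: SampleMetadata) -> tuple[AbundanceMatrix, SampleMetadata]:
    """Strictly join matrix samples to metadata.

    Every matrix sample must have a metadata record (downstream
    stratification is label-driven, so silent exclusion would corrupt the
    group definitions); metadata rows without a matrix column are dropped.
    """
    missing = [s for s in matrix.sample_ids if s not in metadata.df.index]
    if missing:
        raise ValidationError(f"matrix samples without metadata: {missing}")
    meta = SampleMetadata(metadata.df.loc[matrix.sample_ids])
    return matrix, meta


def write_table(df: pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV with a fixed column order."""
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
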