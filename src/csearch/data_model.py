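"""Cohort representation and readers for clinical tables and mutation matrices.

A :class:`Cohort` couples a per-patient clinical table (covariates, binary
treatment, right-censored survival outcome) with a binary gene-alteration
matrix aligned by sample id.  Alignment is always by id, never by position:
silent misalignment between the clinical and genetic files is the worst
failure mode for a discovery method, so any id mismatch is a hard error that
names the offending samples.

Missing clinical values are preserved as NaN by the readers and only removed
by :func:`filter_complete_cases`, which reports how many records were
dropped.  Missing genetic values are not allowed: the discovery algorithm
has no missing-genotype pathway, so a gene absent for a sample is an error,
never a silent 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical names used internally for the non-covariate clinical columns
TREATMENT, TIME, EVENT = "treatment", "time", "event"
RESERVED = (TREATMENT, TIME, EVENT)


class SchemaError(ValueError):
    """A mandatory column is absent or a value cannot be coded."""


class AlignmentError(ValueError):
    """Clinical and genetic sample ids do not match."""


class EmptyCohortError(ValueError):
    """Every record was removed by filtering."""


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored survival outcome: observed time and event indicator.

    ``event`` is 1 when the endpoint (death) was observed at ``time`` and 0
    when follow-up ended at ``time`` with the patient still alive.
    """

    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"survival time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class Individual:
    """One patient: clinical covariates V, binary genotype G, treatment T, outcome Y."""

    id: str
    V: np.ndarray
    G: np.ndarray
    T: int
    Y: SurvivalOutcome


@dataclass
class ColumnMap:
    """Declared mapping from source-file columns to the cohort schema.

    ``event_map``/``treatment_map`` translate source codings (for example the
    cBioPortal-style ``"1:DECEASED"``/``"0:LIVING"``) to {0, 1}.  Plain 0/1
    integers are always accepted; any other value without a declared mapping
    is a parse error — codings are declared, never guessed.
    """

    id_col: str = "patient_id"
    time_col: str = "time"
    event_col: str = "event"
    treatment_col: str = "treatment"
    covariate_cols: Sequence[str] = ("age", "sex")
    event_map: Mapping[str, int] | None = None
    treatment_map: Mapping[str, int] | None = None


class Cohort:
    """Aligned clinical + genetic data for N individuals.

    Parameters
    ----------
    clinical:
        DataFrame indexed by unique sample id with the covariate columns
        plus ``treatment``, ``time`` and ``event``.
    genes:
        DataFrame indexed by the same sample ids (any order), one binary
        column per gene.  May be ``None`` for a clinical-only partial cohort.
    """

    def __init__(self, clinical: pd.DataFrame, genes: pd.DataFrame | None = None):
        if not clinical.index.is_unique:
            dupes = clinical.index[clinical.index.duplicated()].unique().tolist()
            raise AlignmentError(f"duplicate sample ids: {dupes}")
        for col in RESERVED:
            if col not in clinical.columns:
                raise SchemaError(f"clinical table lacks mandatory column '{col}'")
        self.clinical = clinical.copy()
        self.clinical.index = self.clinical.index.astype(str)
        # canonical dtypes so cohorts compare equal across write/read cycles
        for col in self.clinical.columns:
            self.clinical[col] = pd.to_numeric(self.clinical[col])
        self.clinical = self.clinical.astype(float)
        if genes is not None:
            genes = genes.copy()
            genes.index = genes.index.astype(str)
            missing = self.clinical.index.difference(genes.index)
            extra = genes.index.difference(self.clinical.index)
            if len(missing) or len(extra):
                raise AlignmentError(
                    "clinical/genetic sample id mismatch; "
                    f"missing from genetic: {sorted(missing)[:10]}, "
                    f"unknown to clinical: {sorted(extra)[:10]}"
                )
            genes = genes.loc[self.clinical.index]
            if genes.isna().any().any():
                bad = genes.columns[genes.isna().any()].tolist()
                raise AlignmentError(f"missing genetic values in genes {bad[:10]}")
            vals = genes.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("gene matrix entries must be binary {0,1}")
            genes = genes.astype(np.int8)
        self.genes = genes

    # ------------------------------------------------------------------ views

    @property
    def ids(self) -> np.ndarray:
        return self.clinical.index.to_numpy()

    @property
    def n(self) -> int:
        return len(self.clinical)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.clinical.columns if c not in RESERVED]

    @property
    def gene_names(self) -> list[str]:
        return [] if self.genes is None else list(self.genes.columns)

    @property
    def treatment(self) -> np.ndarray:
        return self.clinical[TREATMENT].to_numpy(dtype=int)

    @property
    def time(self) -> np.ndarray:
        return self.clinical[TIME].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical[EVENT].to_numpy(dtype=int)

    @property
    def V(self) -> pd.DataFrame:
        """Clinical covariate block (no treatment/outcome columns)."""
        return self.clinical[self.covariate_names]

    @property
    def G(self) -> pd.DataFrame:
        if self.genes is None:
            raise ValueError("cohort has no genetic data attached")
        return self.genes

    def individuals(self) -> Iterator[Individual]:
        V = self.V.to_numpy(dtype=float)
        G = self.genes.to_numpy() if self.genes is not None else None
        for k, sid in enumerate(self.ids):
            yield Individual(
                id=str(sid),
                V=V[k],
                G=G[k] if G is not None else np.empty(0, dtype=np.int8),
                T=int(self.clinical[TREATMENT].iloc[k]),
                Y=SurvivalOutcome(
                    float(self.clinical[TIME].iloc[k]),
                    int(self.clinical[EVENT].iloc[k]),
                ),
            )

    def subset(self, ids: Sequence[str] | np.ndarray) -> "Cohort":
        """Row subset by sample id, preserving this cohort's id order."""
        keep = self.clinical.index[self.clinical.index.isin(np.asarray(ids, dtype=str))]
        genes = self.genes.loc[keep] if self.genes is not None else None
        return Cohort(self.clinical.loc[keep], genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        same_clin = self.clinical.sort_index().equals(other.clinical.sort_index())
        if self.genes is None or other.genes is None:
            return same_clin and (self.genes is None) == (other.genes is None)
        return same_clin and self.genes.sort_index().equals(other.genes.sort_index())

    def __repr__(self) -> str:  # pragma: no cover
        ng = len(self.gene_names)
        return f"Cohort(n={self.n}, covariates={self.covariate_names}, n_genes={ng})"


# ---------------------------------------------------------------------- readers


def _numeric(values) -> np.ndarray:
    """Parse strings to float with correctly-rounded round-trip semantics.

    Unparseable or empty cells become NaN (an explicit missing marker).
    """
    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        s = str(v).strip()
        if s == "" or s.upper() in ("NA", "NAN", "NONE", "NULL"):
            return np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    return np.array([conv(v) for v in values], dtype=float)


def _code_binary(series: pd.Series, mapping: Mapping[str, int] | None, what: str) -> pd.Series:
    """Code a column to {0,1} using a declared mapping; NaN passes through."""
    out = pd.Series(np.nan, index=series.index, dtype=float)
    for row, val in series.items():
        if pd.isna(val) or (isinstance(val, str) and val.strip() == ""):
            continue
        key = str(val).strip()
        if mapping is not None and key in mapping:
            out[row] = int(mapping[key])
        else:
            try:
                num = float(key)
            except ValueError:
                raise SchemaError(
                    f"cannot code {what} value {val!r} at row {row}; declare a mapping"
                ) from None
            if num not in (0.0, 1.0):
                raise SchemaError(f"{what} value {val!r} at row {row} is not binary")
            out[row] = num
    return out


def read_clinical_table(path, column_map: ColumnMap | None = None, sep: str = "\t") -> Cohort:
    """Read a delimited clinical table into a clinical-only partial cohort.

    Missing values (empty cells, NA) are preserved as NaN in the covariate
    columns — dropping incomplete records is the job of
    :func:`filter_complete_cases`, so the returned partial cohort may contain
    missing covariates but must have codable treatment/event columns.
    """
    cmap = column_map or ColumnMap()
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    needed = [cmap.id_col, cmap.time_col, cmap.event_col, cmap.treatment_col]
    for col in needed + list(cmap.covariate_cols):
        if col not in raw.columns:
            raise SchemaError(f"clinical table lacks mandatory column '{col}'")
    clin = pd.DataFrame(index=raw[cmap.id_col].astype(str))
    clin.index.name = "sample_id"
    for cov in cmap.covariate_cols:
        clin[cov] = _numeric(raw[cov].values)
    clin[TREATMENT] = _code_binary(raw[cmap.treatment_col], cmap.treatment_map, "treatment").values
    clin[TIME] = _numeric(raw[cmap.time_col].values)
    clin[EVENT] = _code_binary(raw[cmap.event_col], cmap.event_map, "event").values
    return Cohort(clin)


def read_mutation_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes-in-rows mutation matrix; returns samples x genes DataFrame.

    The on-disk layout is the usual genes x samples TSV (first column gene
    symbol, remaining columns sample ids); it is transposed on load to match
    the cohort row order convention.  Entries > 0 are coerced to 1 with a
    warning (some exports count mutations per gene).
    """
    mat = pd.read_csv(path, sep=sep, index_col=0)
    mat.columns = mat.columns.astype(str)
    vals = mat.to_numpy()
    if np.isnan(vals.astype(float)).any():
        raise ValueError(f"mutation matrix {path} contains missing entries")
    if (vals < 0).any():
        raise ValueError("mutation matrix entries must be >= 0")
    if (vals > 1).any():
        warnings.warn(
            f"{int((vals > 1).sum())} mutation-matrix entries > 1 coerced to 1",
            stacklevel=2,
        )
    binary = (mat > 0).astype(np.int8)
    return binary.T  # samples x genes


def maf_to_matrix(
    records: Iterable[tuple[str, str]], samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Collapse (sample_id, gene_symbol) mutation records to a binary matrix.

    Entry is 1 iff at least one record exists for the (gene, sample) pair;
    duplicates are idempotent.  ``samples`` extends the column space to
    samples with zero records.  Malformed rows are skipped and counted.
    """
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    for rec in records:
        try:
            sid, gene = rec
            if not str(sid).strip() or not str(gene).strip():
                raise ValueError
        except (TypeError, ValueError):
            skipped += 1
            continue
        pairs.add((str(sid).strip(), str(gene).strip()))
    if not pairs and samples is None:
        raise ValueError("no valid mutation records")
    if skipped:
        logger.warning("skipped %d malformed mutation records", skipped)
    all_samples = sorted({s for s, _ in pairs} | set(map(str, samples or ())))
    all_genes = sorted({g for _, g in pairs})
    mat = pd.DataFrame(0, index=all_samples, columns=all_genes, dtype=np.int8)
    for sid, gene in pairs:
        mat.loc[sid, gene] = 1
    mat.index.name = "sample_id"
    return mat  # samples x genes


def read_maf(path, sep: str = "\t") -> pd.DataFrame:
    """Read a MAF-like TSV (Tumor_Sample_Barcode, Hugo_Symbol) to a binary matrix."""
    maf = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for col in ("Tumor_Sample_Barcode", "Hugo_Symbol"):
        if col not in maf.columns:
            raise SchemaError(f"MAF file lacks mandatory column '{col}'")
    return maf_to_matrix(zip(maf["Tumor_Sample_Barcode"], maf["Hugo_Symbol"]))


@dataclass(frozen=True)
class CompleteCaseCounts:
    n_input: int
    n_omitted: int
    n_retained: int


def filter_complete_cases(cohort: Cohort) -> tuple[Cohort, CompleteCaseCounts]:
    """Drop every individual with any missing clinical field.

    Returns the retained cohort and the (input, omitted, retained) counts;
    input = omitted + retained always holds.  Raises
    :class:`EmptyCohortError` if nothing survives.
    """
    complete = cohort.clinical.notna().all(axis=1)
    n_in, n_keep = len(complete), int(complete.sum())
    if n_keep == 0:
        raise EmptyCohortError("complete-case filter removed every record")
    clin = cohort.clinical.loc[complete]
    genes = cohort.genes.loc[complete[complete].index] if cohort.genes is not None else None
    counts = CompleteCaseCounts(n_in, n_in - n_keep, n_keep)
    logger.info(
        "complete-case filter: %d in, %d omitted, %d retained",
        counts.n_input, counts.n_omitted, counts.n_retained,
    )
    return Cohort(clin, genes), counts


# ---------------------------------------------------------------------- writers


def write_cohort(cohort: Cohort, clinical_path, mutations_path=None, sep: str = "\t") -> None:
    """Write the cohort back to the same formats the readers accept."""
    clin = cohort.clinical.copy()
    clin.index.name = "sample_id"
    clin.to_csv(clinical_path, sep=sep)
    if mutations_path is not None and cohort.genes is not None:
        mat = cohort.genes.T  # genes x samples on disk
        mat.index.name = "gene"
        mat.to_csv(mutations_path, sep=sep)


def read_cohort(clinical_path, mutations_path=None, column_map: ColumnMap | None = None,
                sep: str = "\t") -> Cohort:
    """Load and align a clinical table and optional mutation matrix."""
    cmap = column_map or ColumnMap(id_col="sample_id")
    partial = read_clinical_table(clinical_path, cmap, sep=sep)
    if mutations_path is None:
        return partial
    genes = read_mutation_matrix(mutations_path, sep=sep)
    return Cohort(partial.clinical, genes)
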