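"""Readers and writers for probe matrices, sample annotation and DER tables.

All files are tab-delimited UTF-8 text.  The probe matrix layout is::

    probe_id  chrom  position  <sample1> ... <sampleN>

with one row per probe, ``position`` the 1-based probe start in bp, and the
body holding normalized intensity values (log-ratio / M values).  ``NA`` is
accepted as a missing-value token in the body.  The annotation layout is::

    sample_id  <phenotype_name>  [covariate ...]

Two-level text columns are coded 0/1 with the lexicographically smaller label
mapped to 0, so the coding is reproducible regardless of row order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMatrix",
    "SampleTable",
    "read_probe_matrix",
    "read_annotation",
    "align_samples",
    "write_der_table",
    "read_der_table",
    "write_bed",
]

#: fixed column order of the DER result table
DER_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_probes",
    "direction",
    "mean_diff",
    "max_diff",
    "Q",
    "p",
    "q_fdr",
]


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ProbeMatrix:
    """Normalized probe signals, strictly sorted by (chrom, position).

    Parameters
    ----------
    probe_ids, chrom, position
        Per-probe identifiers and 1-based genomic start coordinates.
    values
        Array of shape ``(n_probes, n_samples)``; may contain NaN.
    sample_ids
        Column labels, unique, in the same order as ``values`` columns.
    """

    probe_ids: np.ndarray
    chrom: np.ndarray
    position: np.ndarray
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.probe_ids)
        if n < 1:
            raise ValidationError("probe matrix must contain at least one probe")
        if self.values.shape != (n, len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids are not unique")
        if len(self.sample_ids) < 4:
            raise ValidationError(
                "at least 4 samples are required (minimum for a slope "
                "standard error with a binary phenotype)"
            )
        key = list(zip(self.chrom.tolist(), self.position.tolist()))
        if any(key[i] >= key[i + 1] for i in range(n - 1)):
            if len(set(key)) != n:
                raise ValidationError("duplicate (chrom, position) pairs")
            raise ValidationError(
                "probes are not sorted by (chrom, position); "
                "use read_probe_matrix or sort before constructing"
            )
        if len(set(key)) != n:
            raise ValidationError("duplicate (chrom, position) pairs")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProbeMatrix":
        """Return a copy restricted to (and ordered by) ``sample_ids``."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ProbeMatrix(
            self.probe_ids.copy(),
            self.chrom.copy(),
            self.position.copy(),
            self.values[:, idx].copy(),
            list(sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "position", self.position)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "probe_id", self.probe_ids)
        return df


@dataclass
class SampleTable:
    """Per-sample phenotype and covariates, numerically coded.

    ``data`` is indexed by sample id; every column is numeric after coding.
    ``codings`` records, for each originally two-level text column, the
    label -> {0, 1} mapping that was applied.
    """

    data: pd.DataFrame
    codings: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def column(self, name: str, sample_order: Sequence[str] | None = None) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"column {name!r} not present in annotation")
        series = self.data[name]
        if sample_order is not None:
            series = series.reindex(list(sample_order))
            if series.isna().any() and not self.data[name].isna().any():
                missing = sorted(set(sample_order) - set(self.sample_ids))
                raise ValidationError(
                    f"annotation is missing samples: {', '.join(missing)}"
                )
        return series.to_numpy(dtype=float)


def _code_two_level(series: pd.Series) -> tuple[pd.Series, dict | None]:
    """Code a two-level text column 0/1 (lexicographically smaller -> 0)."""
    numeric = pd.to_numeric(series, errors="coerce")
    if not numeric.isna().all():
        return numeric, None
    levels = sorted(series.dropna().astype(str).unique())
    if len(levels) > 2:
        raise ValidationError(
            f"text column {series.name!r} has {len(levels)} levels; "
            "only two-level labels can be coded 0/1"
        )
    mapping = {lev: i for i, lev in enumerate(levels)}
    return series.astype(str).map(mapping).astype(float), mapping


def read_probe_matrix(path) -> ProbeMatrix:
    """Read and validate a tab-delimited probe matrix.

    Rows out of coordinate order are re-sorted with a warning; duplicate
    (chrom, position) pairs, non-numeric body cells, and fewer than four
    sample columns are errors.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.shape[1] < 7:
        raise ValidationError(
            f"{path}: expected probe_id, chrom, position plus >=4 sample "
            f"columns, found {df.shape[1]} columns"
        )
    probe_col, chrom_col, pos_col = df.columns[:3]
    df[probe_col] = df[probe_col].astype(str)
    df[chrom_col] = df[chrom_col].astype(str)
    sample_cols = list(df.columns[3:])
    try:
        positions = pd.to_numeric(df[pos_col], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-integer position column: {exc}") from exc
    values = np.empty((len(df), len(sample_cols)), dtype=float)
    for j, col in enumerate(sample_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} at data "
                f"row {row + 1}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)
    order = np.lexsort((positions.to_numpy(), df[chrom_col].to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        warnings.warn(
            f"{path}: probe rows were not sorted by (chrom, position); sorting",
            stacklevel=2,
        )
        df = df.iloc[order].reset_index(drop=True)
        positions = positions.iloc[order].reset_index(drop=True)
        values = values[order]
    return ProbeMatrix(
        df[probe_col].to_numpy(dtype=object),
        df[chrom_col].to_numpy(dtype=object),
        positions.to_numpy(),
        values,
        sample_cols,
    )


def read_annotation(path, phenotype: str | None = None) -> SampleTable:
    """Read a sample annotation table and code two-level text columns 0/1.

    ``phenotype`` defaults to the first column after ``sample_id``; it must be
    non-constant and free of missing values.  Numeric columns (e.g. a dose)
    pass through unchanged as continuous variables.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: need sample_id plus at least one column")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    df = df.set_index(id_col)
    codings: dict = {}
    for col in df.columns:
        coded, mapping = _code_two_level(df[col])
        df[col] = coded
        if mapping is not None:
            codings[col] = mapping
    if phenotype is None:
        phenotype = df.columns[0]
    if phenotype not in df.columns:
        raise ValidationError(f"{path}: phenotype column {phenotype!r} not found")
    pheno = df[phenotype]
    if pheno.isna().any():
        raise ValidationError(f"{path}: missing values in phenotype {phenotype!r}")
    if pheno.nunique() < 2:
        raise ValidationError(
            f"{path}: phenotype {phenotype!r} is constant across samples"
        )
    return SampleTable(df, codings)


def align_samples(matrix: ProbeMatrix, annot: SampleTable) -> None:
    """Check matrix and annotation describe the same sample set (set equality)."""
    m, a = set(matrix.sample_ids), set(annot.sample_ids)
    if m != a:
        diff = sorted(m.symmetric_difference(a))
        raise ValidationError(
            "matrix and annotation sample ids differ; symmetric difference: "
            + ", ".join(diff)
        )


def write_der_table(ders, path, bed_path=None) -> pd.DataFrame:
    """Write scored DERs as a tab-delimited table (and optional BED6 file).

    Rows are sorted by p ascending, then Q descending, then \\|mean_diff\\|
    descending, then coordinates.  Returns the frame that was written.
    """
    from .pipeline import scored_to_frame  # late import to avoid a cycle

    df = scored_to_frame(ders)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    if bed_path is not None:
        write_bed(df, bed_path)
    return df


def read_der_table(path) -> pd.DataFrame:
    """Re-read a table written by :func:`write_der_table`."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_truth_table(truth, path, bed_path=None) -> None:
    """Write a hidden-DMR truth set as TSV (and optional BED, 0-based half-open)."""
    df = pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "first_probe": t.first,
                "last_probe": t.last,
                "n_probes": t.n_probes,
                "effect": t.effect,
                "direction": t.direction,
            }
            for t in truth
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "first_probe",
            "last_probe",
            "n_probes",
            "effect",
            "direction",
        ],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    if bed_path is not None:
        with open(bed_path, "w", encoding="utf-8") as fh:
            for i, t in enumerate(truth, start=1):
                fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\tdmr{i}\t0\t"
                         f"{'+' if t.direction > 0 else '-'}\n")


def read_truth_table(path) -> list:
    """Read a truth set written by :func:`write_truth_table`."""
    from .simulate import HiddenDMR  # late import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        HiddenDMR(
            chrom=row.chrom,
            first=int(row.first_probe),
            last=int(row.last_probe),
            start=int(row.start),
            end=int(row.end),
            n_probes=int(row.n_probes),
            effect=float(row.effect),
            direction=int(row.direction),
        )
        for row in df.itertuples(index=False)
    ]


def write_bed(der_frame: pd.DataFrame, path) -> None:
    """Write DERs as BED6: 0-based half-open, name=rank, score=-10*log10(p).

    Scores are capped at 1000 per the BED convention.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rank, row in enumerate(der_frame.itertuples(index=False), start=1):
            score = min(1000, int(round(-10.0 * math.log10(row.p))))
            strand = "+" if row.direction > 0 else "-"
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{rank}\t{score}\t{strand}\n"
            )
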