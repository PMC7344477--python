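"""Core tabular containers and delimited-text I/O for qPCR panels.

The canonical on-disk layout is wide: one small RNA per row, one sample per
column, quantification cycles (Cq) in the cells.  Tab is the canonical
delimiter on output; tab and comma are auto-detected on input.  Empty cells
and the token ``NA`` are missing values and propagate as NaN.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, VocabularyError

#: Closed five-label region vocabulary: adjacent normal tissue (N), tumor
#: border (B), tumor center (C) and the two opposite tumor peripheries.
REGIONS: tuple[str, ...] = ("N", "B", "C", "P1", "P2")

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what} name: {lab!r}")
        seen.add(lab)


class CqMatrix:
    """Gene-by-sample matrix of quantification cycles.

    Parameters
    ----------
    values
        DataFrame indexed by gene name with sample identifiers as columns.
        Present values must be finite and strictly positive (PCR cycles);
        NaN marks a missing measurement.
    """

    _positive_required = True
    _value_kind = "Cq"

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        _check_unique([str(g) for g in values.index], "gene")
        _check_unique([str(s) for s in values.columns], "sample")
        try:
            df = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric {self._value_kind} value: {exc}") from exc
        arr = df.to_numpy()
        present = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[present])):
            raise FormatError(f"non-finite {self._value_kind} value present")
        if self._positive_required and np.any(arr[present] <= 0):
            bad = np.argwhere(present & ~(arr > 0))[0]
            raise FormatError(
                f"non-positive {self._value_kind} value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self._df = df

    @classmethod
    def from_arrays(
        cls, genes: Sequence[str], samples: Sequence[str], values
    ) -> "CqMatrix":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(genes), len(samples)):
            raise FormatError(
                f"value table shape {arr.shape} does not match "
                f"({len(genes)}, {len(samples)})"
            )
        return cls(pd.DataFrame(arr, index=list(genes), columns=list(samples)))

    # -- container protocol -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        """The underlying gene x sample DataFrame (a live view)."""
        return self._df

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def row(self, gene: str) -> pd.Series:
        if gene not in self._df.index:
            raise ValueError(f"unknown gene: {gene!r}")
        return self._df.loc[gene]

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "CqMatrix":
        df = self._df
        if genes is not None:
            genes = list(genes)
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise ValueError(f"unknown genes: {missing}")
            df = df.loc[genes]
        if samples is not None:
            samples = list(samples)
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise ValueError(f"unknown samples: {missing}")
            df = df[samples]
        return type(self)(df.copy())

    def to_numpy(self) -> np.ndarray:
        return self._df.to_numpy(copy=True)

    def equals(self, other: "CqMatrix", tol: float = 1e-9) -> bool:
        if self.genes != other.genes or self.samples != other.samples:
            return False
        a, b = self._df.to_numpy(), other._df.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=0.0, atol=tol)
        return bool(np.all(both_nan | close))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<{type(self).__name__} {self.shape[0]} genes x "
                f"{self.shape[1]} samples>")


class ExpressionMatrix(CqMatrix):
    """Gene-by-sample relative expression on the linear 2^-dCt scale.

    Rows for the reference genes are excluded by construction; the genes
    used to form the per-sample reference Cq are recorded in
    ``reference_genes``.
    """

    _value_kind = "expression"

    def __init__(self, values: pd.DataFrame,
                 reference_genes: Sequence[str] = ()):
        super().__init__(values)
        ref = [str(g) for g in reference_genes]
        overlap = [g for g in ref if g in self._df.index]
        if overlap:
            raise FormatError(
                f"reference genes must not appear as output rows: {overlap}")
        self.reference_genes: list[str] = ref


class SampleSheet:
    """Per-sample patient identifier and intratumor region label.

    Wraps a DataFrame with columns ``sample_id``, ``patient_id`` and
    ``region``; region labels are normalized to uppercase and must come
    from the closed vocabulary :data:`REGIONS`.
    """

    REQUIRED = ("sample_id", "patient_id", "region")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = frame.copy()
        for col in self.REQUIRED:
            df[col] = df[col].astype(str)
        df["region"] = df["region"].str.strip().str.upper()
        bad = sorted(set(df["region"]) - set(REGIONS))
        if bad:
            raise VocabularyError(
                f"unknown region label(s) {bad}; expected one of {list(REGIONS)}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample_id: {dup.iloc[0]!r}")
        pr = df[["patient_id", "region"]].apply(tuple, axis=1)
        dup_pr = pr[pr.duplicated()]
        if len(dup_pr):
            raise FormatError(
                f"duplicate (patient_id, region) pair: {dup_pr.iloc[0]}")
        self._df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "SampleSheet":
        return cls(pd.DataFrame(list(records)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df["sample_id"])

    def samples_in_region(self, region: str) -> list[str]:
        region = region.strip().upper()
        if region not in REGIONS:
            raise VocabularyError(f"unknown region label {region!r}")
        mask = self._df["region"] == region
        return list(self._df.loc[mask, "sample_id"])

    def region_of(self, sample_id: str) -> str:
        hit = self._df.loc[self._df["sample_id"] == sample_id, "region"]
        if hit.empty:
            raise ValueError(f"unknown sample: {sample_id!r}")
        return hit.iloc[0]

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<SampleSheet {len(self)} samples>"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_wide_matrix(path, delimiter: str | None) -> pd.DataFrame:
    sep = delimiter or _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "sample")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(list(raw.index), "gene")
    out = pd.DataFrame(np.nan, index=raw.index,
                       columns=[str(c) for c in raw.columns])
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            token = cell.strip()
            if token in _MISSING_TOKENS:
                continue
            try:
                out.iloc[i, j] = float(token)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {token!r} at gene {raw.index[i]!r}, "
                    f"sample {col!r}") from None
    return out


def read_cq_matrix(path, delimiter: str | None = None) -> CqMatrix:
    """Read a wide-format Cq matrix (genes as rows, samples as columns)."""
    return CqMatrix(_read_wide_matrix(path, delimiter))


def read_expression_matrix(path, delimiter: str | None = None,
                           reference_genes: Sequence[str] = ()
                           ) -> ExpressionMatrix:
    """Read a wide-format relative-expression matrix."""
    return ExpressionMatrix(_read_wide_matrix(path, delimiter),
                            reference_genes=reference_genes)


def read_sample_sheet(path, delimiter: str | None = None) -> SampleSheet:
    """Read a sample sheet with columns sample_id, patient_id, region."""
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return SampleSheet(df)


def write_table(table, path, index_label: str = "gene") -> None:
    """Write any rectangular result as round-trippable tab-delimited text.

    Floating values are printed with 12 significant digits so that a
    write/read cycle preserves them to well below 1e-9.
    """
    if isinstance(table, CqMatrix):  # covers ExpressionMatrix too
        df = table.values
    elif isinstance(table, SampleSheet):
        table.frame.to_csv(path, sep="\t", index=False)
        return
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        raise TypeError(f"cannot write object of type {type(table).__name__}")
    _check_unique([str(i) for i in df.index], "row")
    _check_unique([str(c) for c in df.columns], "column")
    df.to_csv(path, sep="\t", float_format="%.12g", na_rep="NA",
              index_label=index_label)


def write_cq_matrix(cq: CqMatrix, path) -> None:
    write_table(cq, path, index_label="gene")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    write_table(sheet, path)
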