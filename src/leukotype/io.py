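"""Tabular data containers and readers/writers.

The pipeline's primary container is :class:`ExpressionMatrix`: a genes x
samples table of non-negative expression values in arbitrary units, tagged
with the platform that produced it (microarray, AFA, ...).  Values are never
imputed: a gene a fragment-analysis assay did not detect must arrive as an
explicit 0, and missing or negative cells are rejected with the offending
gene and sample named.

Subtype labels come from a closed seven-class vocabulary covering the main
molecular subtypes of pediatric acute lymphoblastic leukemia (fusion genes,
ploidy, lineage) plus a catch-all "Others" class for samples with no known
lesion.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError, VocabularyError

#: The closed subtype vocabulary, in canonical reporting order.
SUBTYPES: tuple[str, ...] = (
    "BCR-ABL1",
    "TCF3-PBX1",
    "MLL rearrangement",
    "T-ALL",
    "ETV6-RUNX1",
    "hyperdiploid >50",
    "Others",
)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    values
        DataFrame with gene (or probe) identifiers as the index and sample
        identifiers as columns.  All cells must be finite and >= 0.
    platform
        Free-text tag recording the measurement platform.
    """

    values: pd.DataFrame
    platform: str = ""

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene/probe identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        for g in df.index:
            if not isinstance(g, str) or not g:
                raise ValidationError(f"gene identifier {g!r} is not a non-empty string")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            _raise_first_bad_cell(df)
        if not np.all(np.isfinite(arr)):
            _raise_first_bad_cell(df)
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value {arr[gi, si]!r} for gene "
                f"{df.index[gi]!r}, sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _raise_first_bad_cell(df: pd.DataFrame) -> None:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy().astype(float))
    if bad.any():
        gi, si = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-numeric or missing expression value {df.iloc[gi, si]!r} "
            f"for gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    raise ValidationError("expression matrix contains non-finite values")


@dataclass
class SampleLabels:
    """Mapping sample_id -> subtype, restricted to the 7-class vocabulary."""

    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, sub in self.labels.items():
            if sub not in SUBTYPES:
                raise VocabularyError(
                    f"unknown subtype {sub!r} for sample {sid!r}; "
                    f"allowed: {list(SUBTYPES)}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, sample_id: str) -> str:
        return self.labels[sample_id]

    def subset(self, sample_ids: Iterable[str]) -> "SampleLabels":
        return SampleLabels({s: self.labels[s] for s in sample_ids})

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, name="subtype")


class ProbeMap(dict):
    """Many-to-one probe_id -> gene_id mapping."""


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_matrix(
    path: str | Path, format: str = "tsv", platform: str = ""
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV/CSV file or a GEO series-matrix.

    The header row holds sample identifiers; the first column holds gene or
    probe identifiers.  For ``format="series_matrix"`` only the block between
    the ``!series_matrix_table_begin`` / ``!series_matrix_table_end``
    sentinels is parsed.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        except Exception as exc:  # pandas raises a zoo of parse errors
            raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
    elif format == "series_matrix":
        df = _read_series_matrix_block(path)
    else:
        raise FormatError(f"unknown expression matrix format {format!r}")
    if df.columns.size == 0:
        raise FormatError(f"{path}: header row holds no sample identifiers")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        _raise_first_bad_cell(df)
    return ExpressionMatrix(numeric.astype(float), platform=platform)


def _read_series_matrix_block(path: Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    try:
        start = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
        )
    except StopIteration:
        raise FormatError(
            f"{path}: no !series_matrix_table_begin/_end block found"
        ) from None
    block = "\n".join(lines[start + 1 : end])
    df = pd.read_csv(_io.StringIO(block), sep="\t", index_col=0, dtype=str)
    df.index = df.index.map(lambda s: str(s).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        raise FormatError(f"unknown expression matrix format {format!r}")
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, float_format="%.10g")


def collapse_probes(m: ExpressionMatrix, pm: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by arithmetic mean.

    Every probe row must be covered by the map; gene rows appear in order of
    first probe occurrence and sample order is preserved.
    """
    unmapped = [p for p in m.values.index if p not in pm]
    if unmapped:
        raise ValidationError(f"probes missing from the probe map: {unmapped}")
    genes = m.values.index.map(lambda p: pm[p])
    first_seen = list(dict.fromkeys(genes))
    collapsed = m.values.groupby(genes, sort=False).mean().loc[first_seen]
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(collapsed, platform=m.platform)


def read_labels(path: str | Path) -> SampleLabels:
    """Read a two-column (sample_id, subtype) CSV, with or without header."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as labels CSV: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (sample_id, subtype)")
    if list(df.iloc[0].str.lower()) == ["sample_id", "subtype"]:
        df = df.iloc[1:]
    labels: dict[str, str] = {}
    for sid, sub in df.itertuples(index=False):
        if sid in labels:
            raise ValidationError(f"duplicate sample identifier {sid!r} in {path}")
        labels[str(sid)] = str(sub)
    return SampleLabels(labels)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id,subtype\n")
        for sid, sub in labels.labels.items():
            fh.write(f"{sid},{sub}\n")
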