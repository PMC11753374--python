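"""Readers and writers for abundance matrices, sample metadata and GMT sets.

All tabular formats are plain delimited text.  Abundance values are taken as
already log2-transformed intensities; an optional ``log2_transform`` switch
applies log2(x + 1) for raw-intensity tables.  Missing cells are preserved as
NaN and never imputed here — downstream analyses are pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Ome = Literal["protein", "lipid"]

#: cell contents treated as missing in addition to a configured sentinel
DEFAULT_MISSING = ("", "NA", "NaN", "nan", "NAN", "null", "None")


@dataclass
class AbundanceMatrix:
    """Feature x sample matrix of log2 intensities for one ome.

    ``values`` is float with NaN for missing entries; rows follow
    ``feature_ids`` and columns follow ``sample_ids``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    ome: Ome

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.isinf(self.values).any():
            raise ValueError("abundance values must be finite or missing (NaN)")
        if self.ome not in ("protein", "lipid"):
            raise ValueError(f"unknown ome {self.ome!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, ome: Ome) -> "AbundanceMatrix":
        return cls(
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            ome=ome,
        )

    def subset_features(self, keep: Sequence[str]) -> "AbundanceMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return AbundanceMatrix(list(keep), list(self.sample_ids), self.values[rows], self.ome)


@dataclass
class AnnotationMap:
    """One annotation term (e.g. a GO cellular-component set) and its members."""

    term_id: str
    term_name: str
    feature_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.feature_ids = set(self.feature_ids)
        if not self.feature_ids:
            raise ValueError(f"term {self.term_id!r} has an empty feature set")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    ome: Ome,
    orientation: Literal["features_in_rows", "features_in_columns"] = "features_in_rows",
    delimiter: str | None = None,
    missing: Sequence[str] = DEFAULT_MISSING,
    log2_transform: bool = False,
) -> AbundanceMatrix:
    """Read a delimited feature x sample table into an :class:`AbundanceMatrix`.

    The first row is a header of sample ids (or feature ids when
    ``orientation="features_in_columns"``) and the first column holds the
    other axis.  Cells matching ``missing`` become NaN.  Duplicate ids and
    non-numeric cells are hard errors naming the offender and its
    coordinates.  With ``log2_transform`` the values are treated as raw
    intensities and mapped through log2(x + 1).
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    missing_set = set(missing)

    with open(path, "rt") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")

    header = lines[0].split(sep)
    col_ids = [c.strip() for c in header[1:]]
    row_ids: list[str] = []
    data = np.empty((len(lines) - 1, len(col_ids)), dtype=float)
    for r, ln in enumerate(lines[1:]):
        cells = ln.split(sep)
        if len(cells) != len(col_ids) + 1:
            raise ValueError(
                f"{path}: row {r + 2} has {len(cells)} fields, expected {len(col_ids) + 1}"
            )
        row_ids.append(cells[0].strip())
        for c, cell in enumerate(cells[1:]):
            cell = cell.strip()
            if cell in missing_set:
                data[r, c] = np.nan
            else:
                try:
                    data[r, c] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at row id "
                        f"{cells[0].strip()!r}, column id {col_ids[c]!r}"
                    ) from None

    if orientation == "features_in_columns":
        data = data.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    if log2_transform:
        if np.nanmin(data) < 0:
            raise ValueError("log2_transform requires nonnegative raw intensities")
        data = np.log2(data + 1.0)

    return AbundanceMatrix(feature_ids=row_ids, sample_ids=col_ids, values=data, ome=ome)


def write_abundance_table(
    matrix: AbundanceMatrix,
    path: str | Path,
    delimiter: str | None = None,
    missing_sentinel: str = "",
    float_format: str = "%.10g",
) -> None:
    """Write a matrix in the same dialect :func:`read_abundance_table` accepts."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path, "wt") as fh:
        fh.write("feature_id" + sep + sep.join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            cells = [
                missing_sentinel if np.isnan(v) else float_format % v for v in row
            ]
            fh.write(fid + sep + sep.join(cells) + "\n")


META_COLUMNS = ("sample_id", "genotype", "condition", "replicate")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (TSV: sample_id, genotype, condition, replicate)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "condition": str})
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"{path}: missing metadata column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate numbers must be positive")
    return meta[list(META_COLUMNS)]


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta[list(META_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_meta(matrix: AbundanceMatrix, meta: pd.DataFrame) -> None:
    """Every matrix sample must have exactly one metadata row."""
    known = set(meta["sample_id"])
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")


def read_annotation_gmt(path: str | Path) -> list[AnnotationMap]:
    """Read a GMT file: per line ``term_id<TAB>term_name<TAB>member...``.

    Lines with fewer than three fields are hard errors (with the line
    number); terms whose member list is empty after stripping are dropped
    with a warning.
    """
    terms: list[AnnotationMap] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            members = {f.strip() for f in fields[2:] if f.strip()}
            if not members:
                warnings.warn(
                    f"{path}: line {lineno} term {fields[0]!r} has no members; dropped"
                )
                continue
            terms.append(AnnotationMap(fields[0], fields[1], members))
    return terms


def write_annotation_gmt(terms: Sequence[AnnotationMap], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.feature_ids)]) + "\n")
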