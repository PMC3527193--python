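"""Reading and writing GWAS summary-statistic text files.

Two table formats are supported:

* the plain summary format with columns ``CHR, POSITION, SNP`` followed by
  1-100 trait columns (P-values or raw variables such as allele
  frequencies), and
* single-locus test result files carrying, per SNP, the sample size and
  P-values for the genotypic, additive and dominance effects.

A generic column-selection converter bridges output of arbitrary GWAS
software into the summary format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    MappingError,
    ParseError,
    TraitCapError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MAX_TRAITS = 100
#: chromosome labels treated as "unknown chromosome" (displayed by marker order)
UNKNOWN_CHROM_ALIASES = ("0", "Un", "UN", "un", "unknown")

_DELIMS = {"whitespace": None, "comma": ",", "tab": "\t"}


@dataclass(frozen=True)
class Dialect:
    """How a delimited text file is tokenised.

    Parameters
    ----------
    delimiter_policy:
        One of ``"whitespace"``, ``"comma"``, ``"tab"``.
    has_header:
        Whether the first line names the columns.
    missing_tokens:
        Ordered tokens that denote a missing value; the first one is used
        when writing.
    """

    delimiter_policy: Literal["whitespace", "comma", "tab"] = "whitespace"
    has_header: bool = True
    missing_tokens: tuple[str, ...] = ("NA", ".", "")

    def __post_init__(self) -> None:
        if self.delimiter_policy not in _DELIMS:
            raise ValueError(
                f"delimiter_policy must be one of {sorted(_DELIMS)}, "
                f"got {self.delimiter_policy!r}"
            )
        if not self.missing_tokens:
            raise ValueError("missing_tokens must be non-empty")

    @property
    def delimiter(self) -> str | None:
        """Field separator character, or None for any-whitespace."""
        return _DELIMS[self.delimiter_policy]

    def split(self, line: str) -> list[str]:
        if self.delimiter is None:
            return line.split()
        return line.rstrip("\n").split(self.delimiter)

    def join(self, fields: Sequence[str]) -> str:
        return (self.delimiter or " ").join(fields)


@dataclass(frozen=True)
class SnpRecord:
    """One marker row: identity, location and its per-trait values."""

    snp_id: str
    chrom: str
    position: int
    values: tuple[float, ...]  # NaN encodes missing

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"negative position {self.position} for {self.snp_id}")


@dataclass
class GwasTable:
    """Per-SNP records plus named trait columns.

    Backed by a :class:`pandas.DataFrame` with columns ``snp``, ``chrom``
    (string labels), ``position`` (int bp) and one float column per trait
    (NaN = missing). ``column_kinds`` marks each trait as ``"pvalue"``
    (validated to [0, 1], log-transformed for plotting) or ``"raw"``
    (plotted untransformed, e.g. minor allele frequency on a Y2 axis).
    """

    frame: pd.DataFrame
    trait_names: tuple[str, ...]
    column_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trait_names:
            raise FormatError("a table needs at least one trait column")
        if len(set(self.trait_names)) != len(self.trait_names):
            raise FormatError("trait names must be unique")
        if len(self.trait_names) > MAX_TRAITS:
            raise TraitCapError(
                f"{len(self.trait_names)} trait columns exceed the maximum of "
                f"{MAX_TRAITS} traits"
            )
        if len(self.frame) == 0:
            raise FormatError("a table needs at least one record")
        for t in self.trait_names:
            self.column_kinds.setdefault(t, "pvalue")
        self.frame = self.frame.reset_index(drop=True)
        self.frame["chrom"] = self.frame["chrom"].astype(str)
        self.frame["position"] = self.frame["position"].astype(np.int64)
        if (self.frame["position"] < 0).any():
            raise ValidationError("positions must be >= 0")
        for t in self.trait_names:
            col = self.frame[t].to_numpy(dtype=float)
            if self.column_kinds[t] == "pvalue":
                bad = np.isfinite(col) & ((col < 0) | (col > 1))
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise ValidationError(
                        f"P-value {col[i]!r} outside [0, 1] in trait {t!r} "
                        f"(record {i + 1})"
                    )

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        """Distinct chromosome labels in file order."""
        return list(dict.fromkeys(self.frame["chrom"]))

    def records(self) -> Iterator[SnpRecord]:
        vals = self.frame[list(self.trait_names)].to_numpy(dtype=float)
        for i, (sid, ch, pos) in enumerate(
            zip(self.frame["snp"], self.frame["chrom"], self.frame["position"])
        ):
            yield SnpRecord(str(sid), str(ch), int(pos), tuple(vals[i]))

    def trait_values(self, trait: str) -> np.ndarray:
        from .errors import LookupError_

        if trait not in self.trait_names:
            raise LookupError_(f"unknown trait {trait!r}; have {list(self.trait_names)}")
        return self.frame[trait].to_numpy(dtype=float)

    def equals(self, other: "GwasTable") -> bool:
        return (
            self.trait_names == other.trait_names
            and self.column_kinds == other.column_kinds
            and self.frame.shape == other.frame.shape
            and (self.frame["snp"].tolist() == other.frame["snp"].tolist())
            and (self.frame["chrom"].tolist() == other.frame["chrom"].tolist())
            and (self.frame["position"].tolist() == other.frame["position"].tolist())
            and all(
                np.array_equal(
                    self.frame[t].to_numpy(dtype=float),
                    other.frame[t].to_numpy(dtype=float),
                    equal_nan=True,
                )
                for t in self.trait_names
            )
        )


@dataclass(frozen=True)
class ColumnMap:
    """1-based selection of columns from a delimited file."""

    total_columns: int
    selected: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.total_columns < 1:
            raise MappingError("total_columns must be positive")
        if not self.selected:
            raise MappingError("selected column list must be non-empty")
        for idx in self.selected:
            if not 1 <= idx <= self.total_columns:
                raise MappingError(
                    f"selected column {idx} outside [1, {self.total_columns}]"
                )


@dataclass
class EpisnpTable:
    """Single-locus test results: per-SNP sample size and three P-values.

    Columns of ``frame``: ``snp``, ``chrom``, ``position``, ``n_obs`` and
    ``p_genotypic``, ``p_additive``, ``p_dominance`` (NaN = missing).
    """

    frame: pd.DataFrame

    EFFECTS = ("genotypic", "additive", "dominance")

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise FormatError("single-locus table must be non-empty")
        self.frame = self.frame.reset_index(drop=True)
        self.frame["chrom"] = self.frame["chrom"].astype(str)
        self.frame["position"] = self.frame["position"].astype(np.int64)
        n = self.frame["n_obs"].to_numpy()
        if (n < 1).any():
            raise ValidationError("n_obs must be >= 1 for every marker")
        for eff in self.EFFECTS:
            p = self.frame[f"p_{eff}"].to_numpy(dtype=float)
            bad = np.isfinite(p) & ((p < 0) | (p > 1))
            if bad.any():
                raise ValidationError(f"p_{eff} outside [0, 1]")

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))


#: role order the single-locus ColumnMap assigns source columns to
EPISNP_ROLES = (
    "snp_id",
    "chrom",
    "position",
    "n_obs",
    "p_genotypic",
    "p_additive",
    "p_dominance",
)

#: default layout: the seven roles in the seven first columns
DEFAULT_EPISNP_MAP = ColumnMap(total_columns=7, selected=tuple(range(1, 8)))


def _read_frame(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    """Tokenise a delimited file into a string DataFrame (no type coercion)."""
    sep = r"\s+" if dialect.delimiter is None else dialect.delimiter
    try:
        frame = pd.read_csv(
            path,
            sep=sep,
            header=0 if dialect.has_header else None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=True,
            engine="python",
        )
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    return frame


def _to_missing(frame: pd.DataFrame, cols: Sequence[str], dialect: Dialect) -> int:
    """Replace missing tokens by NaN in-place; return how many were replaced."""
    n_missing = 0
    for c in cols:
        mask = frame[c].isin(dialect.missing_tokens)
        n_missing += int(mask.sum())
        frame.loc[mask, c] = np.nan
    return n_missing


def _parse_positions(raw: pd.Series, has_header: bool) -> np.ndarray:
    pos = pd.to_numeric(raw, errors="coerce")
    bad = pos.isna() | (pos != np.floor(pos.fillna(0)))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        line_no = i + 1 + (1 if has_header else 0)
        raise ParseError(
            f"line {line_no}: POSITION {raw.iloc[i]!r} is not an integer"
        )
    return pos.to_numpy(dtype=np.int64)


def read_snpevg(
    path: str | Path,
    dialect: Dialect = Dialect(),
    column_kinds: dict[str, str] | None = None,
    on_invalid_p: Literal["error", "drop"] = "error",
) -> GwasTable:
    """Read a summary-statistic file with columns CHR, POSITION, SNP, traits.

    Trait names come from the header (columns after SNP); with
    ``has_header=False`` they are auto-named ``Trait1..TraitK``. Missing
    tokens become NaN. ``on_invalid_p="drop"`` demotes out-of-range
    P-values to missing with a warning instead of raising.
    """
    frame = _read_frame(path, dialect)
    if frame.shape[1] < 4:
        raise FormatError(
            f"{path}: expected at least 4 columns (CHR, POSITION, SNP, one "
            f"trait), found {frame.shape[1]}"
        )
    n_traits = frame.shape[1] - 3
    if n_traits > MAX_TRAITS:
        raise TraitCapError(
            f"{path}: {n_traits} trait columns exceed the maximum of "
            f"{MAX_TRAITS} traits"
        )
    if dialect.has_header:
        trait_names = tuple(str(c) for c in frame.columns[3:])
    else:
        trait_names = tuple(f"Trait{i + 1}" for i in range(n_traits))
    frame.columns = ["chrom", "position", "snp", *trait_names]

    n_missing = _to_missing(frame, trait_names, dialect)
    if n_missing:
        logger.info("%s: %d missing trait values", path, n_missing)

    positions = _parse_positions(frame["position"], dialect.has_header)
    columns: dict[str, object] = {
        "snp": frame["snp"].astype(str),
        "chrom": frame["chrom"].astype(str),
        "position": positions,
    }
    kinds = dict(column_kinds or {})
    for t in trait_names:
        # to_numeric only detects bad tokens; astype(float) parses exactly
        # (round-trip identity needs full double precision)
        probe = pd.to_numeric(frame[t], errors="coerce").to_numpy(dtype=float)
        was_token_missing = frame[t].isna().to_numpy()
        unparseable = np.isnan(probe) & ~was_token_missing
        if unparseable.any():
            i = int(np.flatnonzero(unparseable)[0])
            line_no = i + 1 + (1 if dialect.has_header else 0)
            raise ParseError(f"line {line_no}: value {frame[t].iloc[i]!r} in "
                             f"trait {t!r} is not numeric")
        vals = frame[t].astype(float).to_numpy()
        if kinds.get(t, "pvalue") == "pvalue" and on_invalid_p == "drop":
            bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
            if bad.any():
                logger.warning(
                    "%s: dropped %d out-of-range P-values in trait %s",
                    path, int(bad.sum()), t,
                )
                vals = np.where(bad, np.nan, vals)
        columns[t] = vals
    out = pd.DataFrame(columns)
    return GwasTable(frame=out, trait_names=trait_names, column_kinds=kinds)


def write_snpevg(table: GwasTable, path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write a table so that :func:`read_snpevg` reproduces it exactly.

    Floats are printed with ``repr`` (shortest round-trip form); missing
    values use the dialect's first missing token.
    """
    missing = dialect.missing_tokens[0]

    def fmt(v: float) -> str:
        return missing if np.isnan(v) else repr(float(v))

    lines = []
    if dialect.has_header:
        lines.append(dialect.join(["CHR", "POSITION", "SNP", *table.trait_names]))
    vals = table.frame[list(table.trait_names)].to_numpy(dtype=float)
    for i in range(table.n_markers):
        row = table.frame.iloc[i]
        fields = [str(row["chrom"]), str(int(row["position"])), str(row["snp"])]
        fields.extend(fmt(v) for v in vals[i])
        lines.append(dialect.join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_episnp(
    path: str | Path,
    column_map: ColumnMap = DEFAULT_EPISNP_MAP,
    dialect: Dialect = Dialect(),
) -> EpisnpTable:
    """Read a single-locus result file via an explicit column map.

    ``column_map.selected`` assigns source columns, in order, to the roles
    ``snp_id, chrom, position, n_obs, p_genotypic, p_additive,
    p_dominance``. The column layout of single-locus output files varies
    between producers, so the mapping is always explicit (the default
    assumes the seven roles occupy the first seven columns).
    """
    if len(column_map.selected) != len(EPISNP_ROLES):
        raise MappingError(
            f"single-locus column map must select {len(EPISNP_ROLES)} columns "
            f"({', '.join(EPISNP_ROLES)}), got {len(column_map.selected)}"
        )
    frame = _read_frame(path, dialect)
    if frame.shape[1] != column_map.total_columns:
        raise MappingError(
            f"{path}: file has {frame.shape[1]} columns but the map declares "
            f"{column_map.total_columns}"
        )
    frame.columns = [str(i) for i in range(1, frame.shape[1] + 1)]
    picked = frame[[str(i) for i in column_map.selected]].copy()
    picked.columns = list(EPISNP_ROLES)

    pcols = [f"p_{e}" for e in EpisnpTable.EFFECTS]
    n_missing = _to_missing(picked, pcols, dialect)
    if n_missing:
        logger.info("%s: %d missing P-values", path, n_missing)

    positions = _parse_positions(picked["position"], dialect.has_header)
    n_obs = pd.to_numeric(picked["n_obs"], errors="coerce")
    if n_obs.isna().any() or (n_obs < 1).any():
        raise ValidationError(f"{path}: n_obs must be a positive integer")
    out = pd.DataFrame(
        {
            "snp": picked["snp_id"].astype(str),
            "chrom": picked["chrom"].astype(str),
            "position": positions,
            "n_obs": n_obs.to_numpy(dtype=np.int64),
        }
    )
    for c in pcols:
        probe = pd.to_numeric(picked[c], errors="coerce")
        if (probe.isna() & ~picked[c].isna()).any():
            raise ParseError(f"{path}: non-numeric value in column {c}")
        out[c] = picked[c].astype(float).to_numpy()
    n_zero = int((out[pcols].to_numpy() == 0.0).sum())
    if n_zero:
        logger.info("%s: %d exact-zero P-values (transform policy applies at "
                    "plot time)", path, n_zero)
    return EpisnpTable(frame=out)


def write_episnp(table: EpisnpTable, path: str | Path, dialect: Dialect = Dialect()) -> None:
    """Write a single-locus table in the default seven-column layout."""
    missing = dialect.missing_tokens[0]

    def fmt(v: float) -> str:
        return missing if np.isnan(v) else repr(float(v))

    lines = []
    if dialect.has_header:
        lines.append(dialect.join(list(EPISNP_ROLES)))
    for _, row in table.frame.iterrows():
        fields = [
            str(row["snp"]), str(row["chrom"]), str(int(row["position"])),
            str(int(row["n_obs"])),
            fmt(row["p_genotypic"]), fmt(row["p_additive"]), fmt(row["p_dominance"]),
        ]
        lines.append(dialect.join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class ConversionSummary:
    lines_read: int
    lines_written: int
    lines_skipped: int = 0


def convert_columns(
    path_in: str | Path,
    column_map: ColumnMap,
    path_out: str | Path,
    dialect: Dialect = Dialect(),
    on_bad_line: Literal["error", "skip"] = "error",
) -> ConversionSummary:
    """Project selected columns of a delimited file, preserving line order.

    Every non-blank line (header included) is reduced to the selected
    columns in the selected order. A line whose field count differs from
    ``column_map.total_columns`` raises a :class:`ParseError` naming the
    line, or is skipped and logged with ``on_bad_line="skip"``.
    """
    n_read = n_written = n_skipped = 0
    out_lines: list[str] = []
    with open(path_in) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_read += 1
            fields = dialect.split(line)
            if len(fields) != column_map.total_columns:
                msg = (
                    f"line {line_no}: expected {column_map.total_columns} "
                    f"fields, found {len(fields)}"
                )
                if on_bad_line == "error":
                    raise ParseError(msg)
                logger.debug("skipping %s", msg)
                n_skipped += 1
                continue
            out_lines.append(dialect.join([fields[i - 1] for i in column_map.selected]))
            n_written += 1
    Path(path_out).write_text("\n".join(out_lines) + ("\n" if out_lines else ""))
    summary = ConversionSummary(n_read, n_written, n_skipped)
    logger.info(
        "%s -> %s: %d lines read, %d written, %d skipped",
        path_in, path_out, n_read, n_written, n_skipped,
    )
    return summary


def is_unknown_chrom(label: str, aliases: Sequence[str] = UNKNOWN_CHROM_ALIASES) -> bool:
    """True when the label marks markers without a mapped chromosome."""
    return str(label) in aliases


__all__ = [
    "Dialect", "SnpRecord", "GwasTable", "ColumnMap", "EpisnpTable",
    "ConversionSummary", "EPISNP_ROLES", "DEFAULT_EPISNP_MAP", "MAX_TRAITS",
    "UNKNOWN_CHROM_ALIASES", "read_snpevg", "write_snpevg", "read_episnp",
    "write_episnp", "convert_columns", "is_unknown_chrom",
]
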