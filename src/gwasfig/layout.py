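"""Genome coordinate layout and value transforms for Manhattan plots.

Chromosomes are tiled left-to-right at their true size — the span between
the first and the last marker on the chromosome — with cumulative offsets
(plus an optional cosmetic gap). Markers on the unknown chromosome
(label "0" or aliases) carry no usable position and are placed in
sequential file order, one marker per x unit, after the last known
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import LookupError_, OptionError, ValidationError
from .io import GwasTable, UNKNOWN_CHROM_ALIASES, is_unknown_chrom


@dataclass(frozen=True)
class ChromosomeSpan:
    """One chromosome's block on the global x axis.

    ``start_pos``/``end_pos`` are the first and last marker positions (bp).
    For the unknown chromosome the x unit is the marker rank, so its block
    length is ``n_markers - 1`` rather than the bp span.
    """

    chrom: str
    start_pos: int
    end_pos: int
    offset: float
    n_markers: int
    is_unknown: bool = False

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValidationError(
                f"chromosome {self.chrom}: start {self.start_pos} > end {self.end_pos}"
            )

    @property
    def length(self) -> float:
        """Block length in global x units (bp span, or rank span if unknown)."""
        if self.is_unknown:
            return float(self.n_markers - 1)
        return float(self.end_pos - self.start_pos)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome spans with cumulative global offsets."""

    spans: tuple[ChromosomeSpan, ...]
    gap: float

    def __post_init__(self) -> None:
        # strictly increasing except in the degenerate zero-length,
        # zero-gap case, where blocks may legitimately coincide
        offsets = [s.offset for s in self.spans]
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            raise ValidationError("span offsets must be non-decreasing")

    @property
    def c(self) -> int:
        """Number of chromosome blocks (the unknown block counts as one)."""
        return len(self.spans)

    @property
    def total_length(self) -> float:
        last = self.spans[-1]
        return last.offset + last.length

    def span(self, chrom: str) -> ChromosomeSpan:
        for s in self.spans:
            if s.chrom == str(chrom):
                return s
        raise LookupError_(
            f"chromosome {chrom!r} not in layout; have "
            f"{[s.chrom for s in self.spans]}"
        )

    @property
    def chrom_order(self) -> list[str]:
        return [s.chrom for s in self.spans]


def chromosome_sort_key(label: str):
    """Numeric labels first in numeric order, then others lexically."""
    s = str(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


def order_chromosomes(
    labels: Sequence[str],
    unknown_aliases: Sequence[str] = UNKNOWN_CHROM_ALIASES,
) -> list[str]:
    """Deduplicate and order labels: numeric, then lexical, unknown last."""
    uniq = list(dict.fromkeys(str(x) for x in labels))
    known = sorted(
        (x for x in uniq if not is_unknown_chrom(x, unknown_aliases)),
        key=chromosome_sort_key,
    )
    unknown = [x for x in uniq if is_unknown_chrom(x, unknown_aliases)]
    return known + unknown


def compute_layout(
    table: GwasTable,
    gap_fraction: float = 0.005,
    unknown_aliases: Sequence[str] = UNKNOWN_CHROM_ALIASES,
) -> GenomeLayout:
    """Build the global x layout from the marker map of a table.

    The gap inserted between consecutive chromosomes is
    ``gap_fraction × (sum of block lengths)``; 0 reproduces strict
    true-size tiling. Offsets satisfy, exactly,
    ``offset[k+1] = offset[k] + length[k] + gap``.
    """
    if gap_fraction < 0:
        raise ValidationError("gap_fraction must be >= 0")
    chroms = table.frame["chrom"].to_numpy()
    positions = table.frame["position"].to_numpy()
    order = order_chromosomes(chroms, unknown_aliases)

    raw: list[tuple[str, int, int, int, bool]] = []
    for ch in order:
        mask = chroms == ch
        pos = positions[mask]
        raw.append(
            (ch, int(pos.min()), int(pos.max()), int(mask.sum()),
             is_unknown_chrom(ch, unknown_aliases))
        )
    lengths = [
        float(n - 1) if unk else float(end - start)
        for (_, start, end, n, unk) in raw
    ]
    gap = gap_fraction * float(sum(lengths))
    spans = []
    offset = 0.0
    for (ch, start, end, n, unk), length in zip(raw, lengths):
        spans.append(ChromosomeSpan(ch, start, end, offset, n, unk))
        offset = offset + length + gap
    return GenomeLayout(spans=tuple(spans), gap=gap)


def global_x(
    layout: GenomeLayout, chrom: str, position: int, marker_index: int = 0
) -> float:
    """Global x of one marker.

    Known chromosome: ``offset + (position - start_pos)``. Unknown
    chromosome: ``offset + marker_index`` — the 0-based sequential rank of
    the marker within the unknown block, ignoring its position.
    """
    span = layout.span(chrom)
    if span.is_unknown:
        return span.offset + float(marker_index)
    return span.offset + float(position - span.start_pos)


def global_x_array(layout: GenomeLayout, table: GwasTable) -> np.ndarray:
    """Vectorised :func:`global_x` over every marker of a table (file order)."""
    chroms = table.frame["chrom"].to_numpy()
    positions = table.frame["position"].to_numpy()
    x = np.empty(len(chroms), dtype=float)
    for span in layout.spans:
        mask = chroms == span.chrom
        if span.is_unknown:
            x[mask] = span.offset + np.arange(int(mask.sum()), dtype=float)
        else:
            x[mask] = span.offset + (positions[mask] - span.start_pos)
    return x


@dataclass(frozen=True)
class TransformPolicy:
    """What to do with P = 0, whose -log10 is undefined.

    ``clamp`` replaces -log10(0) by ``clamp_ceiling`` (with a logged
    warning at transform time); ``drop`` removes the marker.
    """

    zero_p_mode: Literal["clamp", "drop"] = "clamp"
    clamp_ceiling: float = 50.0

    def __post_init__(self) -> None:
        if self.zero_p_mode not in ("clamp", "drop"):
            raise OptionError(f"unknown zero_p_mode {self.zero_p_mode!r}")
        if self.clamp_ceiling <= 0:
            raise ValidationError("clamp_ceiling must be > 0")


def neglog10(p: float, policy: TransformPolicy = TransformPolicy()) -> float | None:
    """-log10 of one P-value; ``None`` means the value was dropped."""
    if np.isnan(p):
        return None
    if p < 0 or p > 1:
        raise ValidationError(f"P-value {p} outside [0, 1]")
    if p == 0:
        return policy.clamp_ceiling if policy.zero_p_mode == "clamp" else None
    return float(-np.log10(p))


def neglog10_array(
    p: np.ndarray, policy: TransformPolicy = TransformPolicy()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised transform.

    Returns ``(y, keep)``: ``y`` has -log10 values (clamped zeros included),
    and ``keep`` flags entries that survive the policy (finite, and not
    dropped as zero or missing).
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValidationError("P-values outside [0, 1]")
    zero = finite & (p == 0)
    with np.errstate(divide="ignore"):
        y = -np.log10(np.where(finite & (p > 0), p, np.nan))
    keep = finite.copy()
    if policy.zero_p_mode == "clamp":
        y = np.where(zero, policy.clamp_ceiling, y)
    else:
        keep &= ~zero
    return y, keep


def apply_cutoff(pvalues: np.ndarray, cutoff_p: float) -> np.ndarray:
    """Boolean retention mask for a display cut-off.

    Only markers at least as significant as the cut-off (``p <= cutoff_p``)
    are drawn; the rest are eliminated from the figure. Missing values are
    never retained. Order is preserved (a mask, not a reordering).
    """
    if not 0 < cutoff_p <= 1:
        raise ValidationError(f"cutoff_p must be in (0, 1], got {cutoff_p}")
    p = np.asarray(pvalues, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(p) & (p <= cutoff_p)


@dataclass(frozen=True)
class MarkerSizeRule:
    """Fixed or significance-proportional marker pixel sizes."""

    mode: Literal["fixed", "proportional"] = "fixed"
    size_min: float = 2.0
    size_max: float = 8.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "proportional"):
            raise OptionError(f"unknown size mode {self.mode!r}")
        if not 0 < self.size_min <= self.size_max:
            raise ValidationError("need 0 < size_min <= size_max")


def marker_size(
    p: float | np.ndarray,
    rule: MarkerSizeRule,
    neglog_min: float,
    neglog_max: float,
    policy: TransformPolicy = TransformPolicy(),
) -> np.ndarray:
    """Pixel size per marker.

    Proportional mode maps -log10(p) linearly from
    ``[neglog_min, neglog_max]`` (the plotted trait's observed range) onto
    ``[size_min, size_max]``, so the most significant marker is drawn
    largest. A degenerate range yields ``size_min`` everywhere.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if rule.mode == "fixed":
        return np.full(p.shape, rule.size_min)
    if neglog_min > neglog_max:
        raise ValidationError("neglog_min must be <= neglog_max")
    y, _ = neglog10_array(p, policy)
    if neglog_max == neglog_min:
        return np.full(p.shape, rule.size_min)
    frac = np.clip((y - neglog_min) / (neglog_max - neglog_min), 0.0, 1.0)
    return rule.size_min + frac * (rule.size_max - rule.size_min)


def count_graphs(n: int, c: int) -> int:
    """Total figures one batch run produces: ``n * (c + 2)``.

    ``n`` traits each get one Manhattan plot, one Q-Q plot and one figure
    per chromosome block (``c`` of them, the unknown block included).
    """
    if not 0 < n <= 100:
        raise ValidationError(f"number of traits must be in (0, 100], got {n}")
    if c < 0:
        raise ValidationError(f"number of chromosomes must be >= 0, got {c}")
    return n * (c + 2)


__all__ = [
    "ChromosomeSpan", "GenomeLayout", "TransformPolicy", "MarkerSizeRule",
    "chromosome_sort_key", "order_chromosomes", "compute_layout", "global_x",
    "global_x_array", "neglog10", "neglog10_array", "apply_cutoff",
    "marker_size", "count_graphs",
]
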