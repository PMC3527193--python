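"""Declarative figure specifications and batch rendering.

Every plot type is first built as a :class:`FigureSpec` — a
renderer-independent description of series, axes, reference lines and
shaded bands — and only then rasterized through matplotlib. All plotting
logic (which markers survive the cut-off, where threshold lines sit, how
series map to the Y1/Y2 axes) is therefore assertable on plain arrays
without decoding images.

Plot types:

* Manhattan plot: all chromosomes side by side at true size, one colored
  series per chromosome.
* Q-Q plot: observed vs expected -log10 P with the identity line.
* Chromosome plot: one trait on one chromosome, lines or symbols.
* Multi-trait plot: several traits overlaid on one chromosome, each on a
  chosen Y1/Y2 axis with per-axis thresholds and cut-offs.
* Effect plot: genotypic/additive/dominance P-values on Y1 and the
  per-marker sample size on Y2, optionally re-ordered by a sorted effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    LookupError_,
    OptionError,
    ValidationError,
)
from .io import EpisnpTable, GwasTable
from .layout import (
    GenomeLayout,
    MarkerSizeRule,
    TransformPolicy,
    apply_cutoff,
    compute_layout,
    global_x_array,
    marker_size,
    neglog10_array,
)
from .qq import QqSeries, qq_series

logger = logging.getLogger(__name__)

#: two-color alternation across chromosomes
TEMPLATE1 = ("#1f497d", "#c0504d")
#: distinct qualitative color per chromosome (cycled)
TEMPLATE2 = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)
PALETTES = {"template1": TEMPLATE1, "template2": TEMPLATE2}

#: default colors for the three single-locus effects + sample size
EFFECT_COLORS = {
    "genotypic": "#1f77b4",
    "additive": "#d62728",
    "dominance": "#2ca02c",
    "n_obs": "#7f7f7f",
}

DEFAULT_ASPECT = {"manhattan": (2, 1), "qq": (1, 1), "chromosome": (4, 3),
                  "multitrait": (4, 3), "effects": (4, 3)}


# ---------------------------------------------------------------------------
# figure specification types

@dataclass(frozen=True)
class Series:
    """One plotted data series bound to a declared axis."""

    label: str
    x: np.ndarray
    y: np.ndarray
    axis: Literal["Y1", "Y2"] = "Y1"
    color: str = "#1f77b4"
    sizes: np.ndarray | None = None
    mode: Literal["symbols", "connected_lines"] = "symbols"

    @property
    def n_points(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class RefLine:
    """Horizontal reference line on one axis (e.g. a threshold P line)."""

    axis: Literal["Y1", "Y2"]
    y: float
    style: str = "dashed"
    color: str = "#444444"
    label: str = ""


@dataclass(frozen=True)
class Band:
    """Shaded horizontal band on one axis."""

    axis: Literal["Y1", "Y2"]
    y_lo: float
    y_hi: float
    color: str = "#bdd7ee"
    alpha: float = 0.5


@dataclass(frozen=True)
class AxisDesc:
    label: str = ""
    scale: Literal["neglog10", "raw"] = "neglog10"
    range: tuple[float, float] | None = None


@dataclass(frozen=True)
class XAxisDesc:
    kind: Literal["genome", "chromosome_bp", "rank"] = "genome"
    label: str = ""
    #: (tick label, tick x) pairs, e.g. chromosome names at block centers
    ticks: tuple[tuple[str, float], ...] = ()


@dataclass
class FigureSpec:
    """Complete, renderer-independent description of one figure."""

    title: str
    xaxis: XAxisDesc
    y1: AxisDesc
    y2: AxisDesc | None = None
    series: list[Series] = field(default_factory=list)
    ref_lines: list[RefLine] = field(default_factory=list)
    bands: list[Band] = field(default_factory=list)
    aspect: tuple[int, int] = (4, 3)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        declared = {"Y1"} | ({"Y2"} if self.y2 is not None else set())
        for s in self.series:
            if s.axis not in declared:
                raise ValidationError(
                    f"series {s.label!r} references undeclared axis {s.axis}"
                )
            if len(s.x) != len(s.y):
                raise ValidationError(f"series {s.label!r}: x/y length mismatch")
            if s.sizes is not None and len(s.sizes) != len(s.x):
                raise ValidationError(f"series {s.label!r}: sizes length mismatch")
        for r in self.ref_lines:
            if r.axis not in declared:
                raise ValidationError(f"reference line on undeclared axis {r.axis}")
        for b in self.bands:
            if b.axis not in declared:
                raise ValidationError(f"band on undeclared axis {b.axis}")

    @property
    def n_points(self) -> int:
        return sum(s.n_points for s in self.series)


# ---------------------------------------------------------------------------
# style / options types

@dataclass(frozen=True)
class StyleOptions:
    """Display options shared by the single-trait plot builders.

    ``chrom_colors`` is a named palette ("template1" two-color alternation,
    "template2" distinct qualitative colors) or an explicit color tuple
    cycled over chromosomes. ``threshold_p`` draws a horizontal
    significance line (optionally shading everything below it);
    ``cutoff_p`` *eliminates* markers with p > cutoff from the figure.
    """

    chrom_colors: str | tuple[str, ...] = "template1"
    size_rule: MarkerSizeRule = MarkerSizeRule()
    threshold_p: float | None = None
    cutoff_p: float | None = None
    shade_below_threshold: bool = False
    connect_lines: bool = False

    def palette(self) -> tuple[str, ...]:
        if isinstance(self.chrom_colors, str):
            try:
                return PALETTES[self.chrom_colors]
            except KeyError:
                raise OptionError(
                    f"unknown palette {self.chrom_colors!r}; "
                    f"have {sorted(PALETTES)}"
                ) from None
        if not self.chrom_colors:
            raise ValidationError("explicit palette must be non-empty")
        return tuple(self.chrom_colors)

    def __post_init__(self) -> None:
        if self.threshold_p is not None and not 0 < self.threshold_p < 1:
            raise ValidationError("threshold_p must be in (0, 1)")
        if self.cutoff_p is not None and not 0 < self.cutoff_p <= 1:
            raise ValidationError("cutoff_p must be in (0, 1]")
        self.palette()


@dataclass(frozen=True)
class TraitAxis:
    """Per-trait display assignment for the multi-trait plot."""

    axis: Literal["Y1", "Y2"] = "Y1"
    color: str | None = None
    enabled: bool = True


@dataclass(frozen=True)
class AxisOptions:
    """Per-axis scale and its own threshold / cut-off P-values."""

    scale: Literal["neglog10", "raw"] = "neglog10"
    threshold_p: float | None = None
    cutoff_p: float | None = None


@dataclass(frozen=True)
class AxisAssignment:
    """Which trait goes on which axis, with per-axis options."""

    traits: dict[str, TraitAxis]
    y1: AxisOptions = AxisOptions()
    y2: AxisOptions = AxisOptions()

    def enabled_traits(self) -> list[str]:
        return [t for t, ta in self.traits.items() if ta.enabled]

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValidationError("axis assignment needs at least one trait")


@dataclass(frozen=True)
class BatchOptions:
    """What a batch run produces and where."""

    outdir: str | Path
    kinds: frozenset[str] = frozenset({"manhattan", "qq", "chromosome"})
    traits: tuple[str, ...] | None = None  # None = all table traits
    image_format: Literal["png", "svg", "pdf"] = "png"
    width_px: int = 800
    height_px: int | None = None  # from the per-kind aspect when None

    def __post_init__(self) -> None:
        valid = {"manhattan", "qq", "chromosome"}
        if not self.kinds:
            raise ValidationError("at least one plot kind must be enabled")
        if not self.kinds <= valid:
            raise OptionError(f"unknown plot kinds {sorted(self.kinds - valid)}")


# ---------------------------------------------------------------------------
# spec builders

def _trait_pvalues(table: GwasTable, trait: str) -> np.ndarray:
    values = table.trait_values(trait)  # raises for unknown traits
    if table.column_kinds.get(trait) != "pvalue":
        raise OptionError(f"trait {trait!r} is not a P-value column")
    return values


def _threshold_artifacts(
    style: StyleOptions, axis: str = "Y1"
) -> tuple[list[RefLine], list[Band]]:
    lines: list[RefLine] = []
    bands: list[Band] = []
    if style.threshold_p is not None:
        ty = float(-np.log10(style.threshold_p))
        lines.append(RefLine(axis=axis, y=ty, label=f"P = {style.threshold_p:g}"))
        if style.shade_below_threshold:
            bands.append(Band(axis=axis, y_lo=0.0, y_hi=ty))
    return lines, bands


def _sizes_for(
    p: np.ndarray, style: StyleOptions, policy: TransformPolicy
) -> np.ndarray | None:
    """Per-point pixel sizes, or None when the rule is a fixed size."""
    if style.size_rule.mode == "fixed":
        return None
    y, keep = neglog10_array(p, policy)
    y = y[keep]
    lo, hi = (float(y.min()), float(y.max())) if y.size else (0.0, 0.0)
    return marker_size(p, style.size_rule, lo, hi, policy)


def build_manhattan_spec(
    table: GwasTable,
    trait: str,
    layout: GenomeLayout | None = None,
    style: StyleOptions = StyleOptions(),
    policy: TransformPolicy = TransformPolicy(),
) -> FigureSpec:
    """Genome-wide -log10 P scatter, one colored series per chromosome."""
    if layout is None:
        layout = compute_layout(table)
    p_all = _trait_pvalues(table, trait)
    x_all = global_x_array(layout, table)
    y_all, keep = neglog10_array(p_all, policy)
    if style.cutoff_p is not None:
        keep &= apply_cutoff(p_all, style.cutoff_p)
    sizes_all = _sizes_for(p_all, style, policy)

    palette = style.palette()
    chroms = table.frame["chrom"].to_numpy()
    series = []
    ticks = []
    for k, span in enumerate(layout.spans):
        ticks.append((span.chrom, span.offset + span.length / 2.0))
        mask = (chroms == span.chrom) & keep
        series.append(
            Series(
                label=f"chr{span.chrom}",
                x=x_all[mask],
                y=y_all[mask],
                color=palette[k % len(palette)],
                sizes=None if sizes_all is None else sizes_all[mask],
                mode="connected_lines" if style.connect_lines else "symbols",
            )
        )
    ref_lines, bands = _threshold_artifacts(style)
    return FigureSpec(
        title=f"{trait} - Manhattan plot",
        xaxis=XAxisDesc(kind="genome", label="Chromosome", ticks=tuple(ticks)),
        y1=AxisDesc(label="-log10 P", scale="neglog10"),
        series=series,
        ref_lines=ref_lines,
        bands=bands,
        aspect=DEFAULT_ASPECT["manhattan"],
    )


def build_qq_spec(
    series: QqSeries, style: StyleOptions = StyleOptions(), title: str = "Q-Q plot"
) -> FigureSpec:
    """Observed vs expected -log10 P scatter with the identity line."""
    if series.n == 0:
        raise EmptyInputError("empty Q-Q series")
    m = float(series.expected.max())
    identity = Series(
        label="identity", x=np.array([0.0, m]), y=np.array([0.0, m]),
        color="#999999", mode="connected_lines",
    )
    points = Series(
        label="observed", x=series.expected, y=series.observed,
        color=style.palette()[0], mode="symbols",
    )
    return FigureSpec(
        title=title,
        xaxis=XAxisDesc(kind="rank", label="Expected -log10 P"),
        y1=AxisDesc(label="Observed -log10 P", scale="neglog10"),
        series=[identity, points],
        aspect=DEFAULT_ASPECT["qq"],
    )


def _chrom_subset(table: GwasTable, chrom: str) -> np.ndarray:
    mask = (table.frame["chrom"] == str(chrom)).to_numpy()
    if not mask.any():
        raise LookupError_(f"chromosome {chrom!r} not present in the table")
    return mask


def build_chromosome_spec(
    table: GwasTable,
    trait: str,
    chrom: str,
    style: StyleOptions = StyleOptions(),
    policy: TransformPolicy = TransformPolicy(),
) -> FigureSpec:
    """One trait on one chromosome, bp on x, lines or separate symbols."""
    mask = _chrom_subset(table, chrom)
    p = _trait_pvalues(table, trait)[mask]
    pos = table.frame["position"].to_numpy()[mask]
    y, keep = neglog10_array(p, policy)
    if style.cutoff_p is not None:
        keep &= apply_cutoff(p, style.cutoff_p)
    if not keep.any():
        raise EmptyInputError(
            f"chromosome {chrom!r} has no plottable markers for trait {trait!r}"
        )
    sizes = _sizes_for(p, style, policy)
    ref_lines, bands = _threshold_artifacts(style)
    return FigureSpec(
        title=f"{trait} - chromosome {chrom}",
        xaxis=XAxisDesc(kind="chromosome_bp", label=f"Position on {chrom} (bp)"),
        y1=AxisDesc(label="-log10 P", scale="neglog10"),
        series=[
            Series(
                label=trait,
                x=pos[keep].astype(float),
                y=y[keep],
                color=style.palette()[0],
                sizes=None if sizes is None else sizes[keep],
                mode="connected_lines" if style.connect_lines else "symbols",
            )
        ],
        ref_lines=ref_lines,
        bands=bands,
        aspect=DEFAULT_ASPECT["chromosome"],
    )


def build_multitrait_spec(
    table: GwasTable,
    chrom: str,
    assignment: AxisAssignment,
    policy: TransformPolicy = TransformPolicy(),
    connect_lines: bool = False,
) -> FigureSpec:
    """Several traits overlaid on one chromosome, across the Y1/Y2 axes.

    Each enabled trait is drawn on its assigned axis in its assigned
    color. Each axis carries its own optional threshold and cut-off
    P-values; an axis in raw scale (e.g. allele frequency on Y2) plots
    values untransformed and ignores P-value threshold/cut-off semantics
    for raw-kind columns.
    """
    enabled = assignment.enabled_traits()
    if not enabled:
        raise OptionError("all traits are disabled; nothing to plot")
    mask = _chrom_subset(table, chrom)
    pos = table.frame["position"].to_numpy()[mask].astype(float)

    axis_opts = {"Y1": assignment.y1, "Y2": assignment.y2}
    palette = TEMPLATE2
    series = []
    used_axes = set()
    for k, trait in enumerate(enabled):
        ta = assignment.traits[trait]
        opts = axis_opts[ta.axis]
        vals = table.trait_values(trait)[mask]
        kind = table.column_kinds.get(trait, "pvalue")
        if kind == "pvalue" and opts.scale == "neglog10":
            y, keep = neglog10_array(vals, policy)
            if opts.cutoff_p is not None:
                keep &= apply_cutoff(vals, opts.cutoff_p)
        else:
            y = vals
            keep = np.isfinite(vals)
        used_axes.add(ta.axis)
        series.append(
            Series(
                label=trait,
                x=pos[keep],
                y=y[keep],
                axis=ta.axis,
                color=ta.color or palette[k % len(palette)],
                mode="connected_lines" if connect_lines else "symbols",
            )
        )
    ref_lines = []
    for axis_name, opts in axis_opts.items():
        if opts.threshold_p is not None and axis_name in used_axes:
            ref_lines.append(
                RefLine(
                    axis=axis_name,
                    y=float(-np.log10(opts.threshold_p)),
                    label=f"{axis_name} P = {opts.threshold_p:g}",
                )
            )
    y2 = (
        AxisDesc(label="Y2", scale=assignment.y2.scale)
        if "Y2" in used_axes or any(r.axis == "Y2" for r in ref_lines)
        else None
    )
    return FigureSpec(
        title=f"chromosome {chrom} - {len(enabled)} traits",
        xaxis=XAxisDesc(kind="chromosome_bp", label=f"Position on {chrom} (bp)"),
        y1=AxisDesc(label="-log10 P" if assignment.y1.scale == "neglog10" else "Y1",
                    scale=assignment.y1.scale),
        y2=y2,
        series=series,
        ref_lines=ref_lines,
        aspect=DEFAULT_ASPECT["multitrait"],
    )


def build_episnp_spec(
    table: EpisnpTable,
    chrom: str | None = None,
    connect_lines: bool = True,
    sort_by: Literal["additive", "dominance", "genotypic"] | None = None,
    policy: TransformPolicy = TransformPolicy(),
) -> FigureSpec:
    """Three effect P-value series on Y1 plus sample size on Y2.

    Default mode plots one chromosome against bp position. With
    ``sort_by`` the figure spans the whole table (or the chromosome if one
    is given): markers are ordered by ascending P of the chosen effect and
    x is that rank, all four series re-ordered consistently, so the sorted
    effect decreases monotonically in -log10 P along x.
    """
    if sort_by is not None and sort_by not in EpisnpTable.EFFECTS:
        raise OptionError(
            f"sort_by must be one of {EpisnpTable.EFFECTS}, got {sort_by!r}"
        )
    if sort_by is None and chrom is None:
        raise OptionError("either a chromosome or sort_by mode is required")

    frame = table.frame
    if chrom is not None:
        mask = (frame["chrom"] == str(chrom)).to_numpy()
        if not mask.any():
            raise LookupError_(f"chromosome {chrom!r} not present")
        frame = frame[mask].reset_index(drop=True)

    if sort_by is not None:
        order = np.argsort(frame[f"p_{sort_by}"].to_numpy(), kind="stable")
        frame = frame.iloc[order].reset_index(drop=True)
        x = np.arange(len(frame), dtype=float)
        x_desc = XAxisDesc(kind="rank", label=f"Marker rank by {sort_by} P")
    else:
        x = frame["position"].to_numpy(dtype=float)
        x_desc = XAxisDesc(kind="chromosome_bp", label=f"Position on {chrom} (bp)")

    mode = "connected_lines" if connect_lines else "symbols"
    series = []
    for eff in EpisnpTable.EFFECTS:
        y, keep = neglog10_array(frame[f"p_{eff}"].to_numpy(dtype=float), policy)
        series.append(
            Series(label=eff, x=x[keep], y=y[keep], axis="Y1",
                   color=EFFECT_COLORS[eff], mode=mode)
        )
    series.append(
        Series(label="sample size", x=x,
               y=frame["n_obs"].to_numpy(dtype=float), axis="Y2",
               color=EFFECT_COLORS["n_obs"], mode=mode)
    )
    where = f"chromosome {chrom}" if chrom is not None else "all markers"
    return FigureSpec(
        title=f"single-locus effects - {where}"
              + (f" (sorted by {sort_by})" if sort_by else ""),
        xaxis=x_desc,
        y1=AxisDesc(label="-log10 P", scale="neglog10"),
        y2=AxisDesc(label="Sample size", scale="raw"),
        series=series,
        aspect=DEFAULT_ASPECT["effects"],
    )


# ---------------------------------------------------------------------------
# rasterization

def rasterize(
    spec: FigureSpec,
    path: str | Path,
    image_format: Literal["png", "svg", "pdf"] | None = None,
    width_px: int = 800,
    height_px: int | None = None,
    dpi: int = 100,
    _fig=None,
) -> Path:
    """Render a spec to PNG, SVG or PDF; byte-stable for identical inputs.

    ``height_px`` defaults to the spec's aspect ratio. ``_fig`` lets batch
    callers reuse one matplotlib Figure across many renders.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    fmt = image_format or path.suffix.lstrip(".").lower()
    if fmt not in ("png", "svg", "pdf"):
        raise OptionError(f"unsupported image format {fmt!r}")
    if width_px <= 0 or (height_px is not None and height_px <= 0):
        raise ValidationError("figure dimensions must be positive")
    if height_px is None:
        w, h = spec.aspect
        height_px = max(1, round(width_px * h / w))

    own_fig = _fig is None
    fig = _fig if _fig is not None else plt.figure()
    fig.clf()
    fig.set_size_inches(width_px / dpi, height_px / dpi)
    try:
        ax1 = fig.add_subplot(111)
        axes = {"Y1": ax1}
        if spec.y2 is not None:
            axes["Y2"] = ax1.twinx()
        for band in spec.bands:
            axes[band.axis].axhspan(band.y_lo, band.y_hi, color=band.color,
                                    alpha=band.alpha, lw=0)
        for s in spec.series:
            ax = axes[s.axis]
            if s.mode == "connected_lines":
                ax.plot(s.x, s.y, color=s.color, lw=0.8, label=s.label or None)
            else:
                sz = 9.0 if s.sizes is None else np.asarray(s.sizes) ** 2
                ax.scatter(s.x, s.y, s=sz, c=s.color, edgecolors="none",
                           label=s.label or None)
        for r in spec.ref_lines:
            axes[r.axis].axhline(r.y, ls=r.style, color=r.color, lw=0.8)
        if spec.xaxis.ticks:
            ax1.set_xticks([t for _, t in spec.xaxis.ticks])
            ax1.set_xticklabels([n for n, _ in spec.xaxis.ticks], fontsize=7)
        ax1.set_xlabel(spec.xaxis.label)
        ax1.set_ylabel(spec.y1.label)
        if spec.y1.range:
            ax1.set_ylim(*spec.y1.range)
        if spec.y2 is not None:
            axes["Y2"].set_ylabel(spec.y2.label)
            if spec.y2.range:
                axes["Y2"].set_ylim(*spec.y2.range)
        ax1.set_title(spec.title, fontsize=9)

        if path.exists():
            logger.warning("overwriting %s", path)
        path.parent.mkdir(parents=True, exist_ok=True)
        save_kw: dict = {"dpi": dpi}
        if fmt == "svg":
            # strip the volatile date and pin hashed ids for byte stability
            save_kw["metadata"] = {"Date": None}
            with matplotlib.rc_context({"svg.hashsalt": "gwasfig"}):
                fig.savefig(path, format=fmt, **save_kw)
        elif fmt == "pdf":
            save_kw["metadata"] = {"CreationDate": None}
            fig.savefig(path, format=fmt, **save_kw)
        else:
            fig.savefig(path, format=fmt, **save_kw)
    finally:
        if own_fig:
            plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# batch runner

@dataclass(frozen=True)
class ManifestEntry:
    path: str
    kind: str
    trait: str
    chrom: str  # "all" for genome-wide figures


def _safe(name: str) -> str:
    return "".join(c if (c.isalnum() or c in "-._") else "_" for c in str(name))


def plan_batch(
    table: GwasTable, options: BatchOptions, layout: GenomeLayout | None = None
) -> list[tuple[str, str, str]]:
    """Planned (trait, kind, chrom) jobs of a batch run, without rendering."""
    if layout is None:
        layout = compute_layout(table)
    traits = options.traits if options.traits is not None else table.trait_names
    unknown = [t for t in traits if t not in table.trait_names]
    if unknown:
        raise LookupError_(f"traits not in table: {unknown}")
    if not traits:
        raise ValidationError("empty trait selection")
    jobs = []
    for trait in traits:
        if "manhattan" in options.kinds:
            jobs.append((trait, "manhattan", "all"))
        if "qq" in options.kinds:
            jobs.append((trait, "qq", "all"))
        if "chromosome" in options.kinds:
            for span in layout.spans:
                jobs.append((trait, "chromosome", span.chrom))
    return jobs


def batch_run(
    table: GwasTable,
    layout: GenomeLayout | None = None,
    options: BatchOptions = BatchOptions(outdir="gwasfig_out"),
    style: StyleOptions = StyleOptions(),
    policy: TransformPolicy = TransformPolicy(),
) -> list[ManifestEntry]:
    """Produce every enabled figure for every selected trait.

    With all three kinds enabled over n traits and c chromosome blocks the
    run writes exactly n Manhattan + n Q-Q + n*c chromosome figures =
    n*(c+2) files, named ``trait__kind__chrom.ext``, plus a MANIFEST.txt
    index. Existing files are overwritten with a warning.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if layout is None:
        layout = compute_layout(table)
    outdir = Path(options.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jobs = plan_batch(table, options, layout)
    manifest: list[ManifestEntry] = []
    fig = plt.figure()
    try:
        for trait, kind, chrom in jobs:
            if kind == "manhattan":
                spec = build_manhattan_spec(table, trait, layout, style, policy)
            elif kind == "qq":
                p = table.trait_values(trait)
                spec = build_qq_spec(qq_series(p, policy), style,
                                     title=f"{trait} - Q-Q plot")
            else:
                spec = build_chromosome_spec(table, trait, chrom, style, policy)
            fname = f"{_safe(trait)}__{kind}__{_safe(chrom)}.{options.image_format}"
            path = outdir / fname
            rasterize(spec, path, options.image_format,
                      width_px=options.width_px, height_px=options.height_px,
                      _fig=fig)
            manifest.append(ManifestEntry(str(path), kind, trait, chrom))
    finally:
        plt.close(fig)

    index = outdir / "MANIFEST.txt"
    lines = [f"{e.kind}\t{e.trait}\t{e.chrom}\t{Path(e.path).name}"
             for e in manifest]
    index.write_text("\n".join(lines) + "\n")
    logger.info("batch: %d figures written to %s", len(manifest), outdir)
    return manifest


__all__ = [
    "Series", "RefLine", "Band", "AxisDesc", "XAxisDesc", "FigureSpec",
    "StyleOptions", "TraitAxis", "AxisOptions", "AxisAssignment",
    "BatchOptions", "ManifestEntry", "TEMPLATE1", "TEMPLATE2", "PALETTES",
    "build_manhattan_spec", "build_qq_spec", "build_chromosome_spec",
    "build_multitrait_spec", "build_episnp_spec", "rasterize", "plan_batch",
    "batch_run",
]
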