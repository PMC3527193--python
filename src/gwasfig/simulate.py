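"""Synthetic GWAS fixtures with known structure.

Two generators:

* :func:`simulate_pvalue_table` draws a multi-chromosome marker map with
  uniform null P-values per trait and optional spiked signal windows, for
  exercising the Manhattan/Q-Q machinery with a known truth.
* :func:`simulate_genotype_study` draws Hardy-Weinberg genotypes and a
  quantitative phenotype with chosen additive/dominance effects, from
  which :func:`single_locus_tests` actually computes the genotypic (2-df),
  additive and dominance single-locus tests — producing structurally
  valid single-locus result tables without any external analysis run.

All randomness flows through one integer seed, bit-reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import (
    Dialect,
    EpisnpTable,
    GwasTable,
    write_episnp,
    write_snpevg,
)


@dataclass(frozen=True)
class Signal:
    """A spiked association: markers of one chromosome window get
    P = 10^-u with u ~ uniform(strength range), per trait."""

    chrom: str
    window: tuple[int, int]  # bp, inclusive
    strength: tuple[float, float]  # -log10 units

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValidationError("signal window start > end")
        if not 0 < self.strength[0] <= self.strength[1]:
            raise ValidationError("signal strength range must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Marker-map / P-value simulation settings.

    Defaults give a mid-density map (20 chromosomes x 500 markers over
    100 Mb each) with two spiked loci per genome — small enough to plot
    in seconds, large enough for the Q-Q null band to be tight.
    """

    n_chrom: int = 20
    markers_per_chrom: int = 500
    chrom_length_bp: int = 100_000_000
    n_traits: int = 1
    signals: tuple[Signal, ...] = ()
    include_unknown_chrom: bool = False
    unknown_markers: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.markers_per_chrom < 1:
            raise ValidationError("need >= 1 chromosome and >= 1 marker each")
        if not 1 <= self.n_traits <= 100:
            raise ValidationError("n_traits must be in 1..100")
        for s in self.signals:
            if not 0 <= s.window[0] <= s.window[1] <= self.chrom_length_bp:
                raise ValidationError(
                    f"signal window {s.window} outside chromosome length "
                    f"{self.chrom_length_bp}"
                )


def simulate_pvalue_table(config: SimConfig) -> GwasTable:
    """Draw a marker map with null P-values and spiked signal windows.

    Positions are sorted uniform draws per chromosome; the unknown
    chromosome (label "0"), when included, gets deliberately *unsorted*
    positions so the sequential-order display path is exercised.
    """
    rng = np.random.default_rng(config.seed)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for c in range(1, config.n_chrom + 1):
        pos = np.sort(
            rng.integers(1, config.chrom_length_bp + 1,
                         size=config.markers_per_chrom)
        )
        chroms.extend([str(c)] * config.markers_per_chrom)
        positions.append(pos)
    if config.include_unknown_chrom:
        pos = rng.integers(1, config.chrom_length_bp + 1,
                           size=config.unknown_markers)  # unsorted on purpose
        chroms.extend(["0"] * config.unknown_markers)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    m = len(pos_all)
    chrom_arr = np.array(chroms)

    frame = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(m)],
            "chrom": chrom_arr,
            "position": pos_all.astype(np.int64),
        }
    )
    trait_names = tuple(f"Trait{i + 1}" for i in range(config.n_traits))
    for t in trait_names:
        p = rng.uniform(0.0, 1.0, size=m)
        for sig in config.signals:
            in_win = (
                (chrom_arr == str(sig.chrom))
                & (pos_all >= sig.window[0])
                & (pos_all <= sig.window[1])
            )
            k = int(in_win.sum())
            if k:
                u = rng.uniform(sig.strength[0], sig.strength[1], size=k)
                p[in_win] = 10.0 ** (-u)
        frame[t] = p
    return GwasTable(frame=frame, trait_names=trait_names)


@dataclass(frozen=True)
class CausalEffect:
    """Additive effect a and dominance deviation d of one causal marker."""

    marker: int  # column index into the genotype matrix
    a: float
    d: float = 0.0


@dataclass(frozen=True)
class GenoSimConfig:
    """Genotype/phenotype simulation settings.

    n=200 individuals and 5,000 markers match a small association study;
    allele frequencies are uniform over ``maf_range`` and genotypes are in
    Hardy-Weinberg proportions.
    """

    n_individuals: int = 200
    n_markers: int = 5_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal: tuple[CausalEffect, ...] = ()
    residual_sd: float = 1.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 3:
            raise ValidationError("need at least 3 individuals")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.residual_sd <= 0:
            raise ValidationError("residual_sd must be > 0")
        for c in self.causal:
            if not 0 <= c.marker < self.n_markers:
                raise ValidationError(f"causal marker {c.marker} out of range")


def simulate_genotype_study(
    config: GenoSimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (genotypes, phenotype).

    Genotypes are 0/1/2 minor-allele counts, Binomial(2, maf) per marker.
    The phenotype is ``y = mu + sum_causal [a*(g-1) + d*1{g=1}] + e`` with
    e ~ Normal(0, residual_sd^2) — the standard biallelic single-locus
    parameterisation (additive dosage centred at the heterozygote,
    dominance as heterozygote deviation).
    """
    rng = np.random.default_rng(config.seed)
    maf = rng.uniform(*config.maf_range, size=config.n_markers)
    geno = rng.binomial(2, maf, size=(config.n_individuals, config.n_markers))
    y = np.full(config.n_individuals, config.mean, dtype=float)
    for c in config.causal:
        g = geno[:, c.marker]
        y += c.a * (g - 1.0) + c.d * (g == 1)
    y += rng.normal(0.0, config.residual_sd, size=config.n_individuals)
    return geno.astype(np.int8), y


def single_locus_tests(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    positions: np.ndarray | None = None,
    chrom_labels: Sequence[str] | None = None,
    snp_ids: Sequence[str] | None = None,
) -> EpisnpTable:
    """Per-marker genotypic, additive and dominance tests of a phenotype.

    For each marker the individuals are grouped by genotype class
    (0/1/2 copies of the minor allele) and tested against the pooled
    within-class variance:

    * genotypic — one-way ANOVA F test across the classes present
      (2 numerator df when all three occur);
    * additive — the allele-dosage contrast (mean(g=2) - mean(g=0))/2;
    * dominance — the heterozygote deviation
      mean(g=1) - (mean(g=0) + mean(g=2))/2.

    Contrasts are two-sided t tests on the within-class df. A marker with
    fewer than two classes (or, for the contrasts, missing one of the
    three classes) gets missing P-values rather than an error. Fully
    vectorised across markers.
    """
    geno = np.asarray(genotypes)
    y = np.asarray(phenotype, dtype=float)
    n, m = geno.shape
    if len(y) != n:
        raise ValidationError("phenotype length must match genotype rows")

    counts = np.empty((3, m))
    sums = np.empty((3, m))
    sqsums = np.empty((3, m))
    for g in range(3):
        mask = geno == g
        counts[g] = mask.sum(axis=0)
        sums[g] = mask.T @ y
        sqsums[g] = mask.T @ (y * y)

    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / counts
    ss_within = (sqsums - np.where(counts > 0, sums**2 / np.where(counts > 0, counts, 1), 0.0)).sum(axis=0)
    k = (counts > 0).sum(axis=0)
    df_within = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = ss_within / df_within

    grand_mean = y.mean()
    ss_between = (np.where(counts > 0, counts * (means - grand_mean) ** 2, 0.0)).sum(axis=0)

    p_geno = np.full(m, np.nan)
    ok = (k >= 2) & (df_within > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / mse
    zero_var = ok & (mse == 0)
    f_ok = ok & (mse > 0)
    p_geno[f_ok] = stats.f.sf(f[f_ok], k[f_ok] - 1, df_within[f_ok])
    # no residual variance: all class means equal -> F = 0/0, define P = 1
    p_geno[zero_var & (ss_between == 0)] = 1.0

    all3 = (counts > 0).all(axis=0) & (df_within > 0)

    def contrast_p(L: np.ndarray, var_coef: np.ndarray) -> np.ndarray:
        p = np.full(m, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse * var_coef)
            t = L / se
        good = all3 & (mse > 0)
        p[good] = 2.0 * stats.t.sf(np.abs(t[good]), df_within[good])
        p[all3 & (mse == 0) & (L == 0)] = 1.0
        return p

    with np.errstate(divide="ignore", invalid="ignore"):
        L_add = (means[2] - means[0]) / 2.0
        v_add = (1.0 / counts[2] + 1.0 / counts[0]) / 4.0
        L_dom = means[1] - (means[0] + means[2]) / 2.0
        v_dom = 1.0 / counts[1] + (1.0 / counts[0] + 1.0 / counts[2]) / 4.0
    p_add = contrast_p(L_add, v_add)
    p_dom = contrast_p(L_dom, v_dom)

    frame = pd.DataFrame(
        {
            "snp": list(snp_ids) if snp_ids is not None
                   else [f"rs{i + 1}" for i in range(m)],
            "chrom": list(chrom_labels) if chrom_labels is not None
                     else ["1"] * m,
            "position": np.asarray(positions, dtype=np.int64)
                        if positions is not None
                        else np.arange(1, m + 1, dtype=np.int64),
            "n_obs": np.full(m, n, dtype=np.int64),
            "p_genotypic": p_geno,
            "p_additive": p_add,
            "p_dominance": p_dom,
        }
    )
    return EpisnpTable(frame=frame)


def simulate_episnp_table(
    config: GenoSimConfig,
    n_chrom: int = 5,
    chrom_length_bp: int = 50_000_000,
) -> EpisnpTable:
    """End-to-end: simulate a study and run the three single-locus tests,
    spreading the markers over a map of ``n_chrom`` chromosomes."""
    geno, y = simulate_genotype_study(config)
    m = config.n_markers
    rng = np.random.default_rng(config.seed + 1)  # map independent of study
    per = -(-m // n_chrom)  # ceil
    chroms = [str(c + 1) for i in range(m) for c in [i // per]][:m]
    positions = np.empty(m, dtype=np.int64)
    for c in set(chroms):
        idx = [i for i, ch in enumerate(chroms) if ch == c]
        positions[idx] = np.sort(rng.integers(1, chrom_length_bp + 1, size=len(idx)))
    return single_locus_tests(geno, y, positions, chroms)


def write_fixtures(
    tables: dict[str, GwasTable | EpisnpTable],
    directory: str | Path,
    dialect: Dialect = Dialect(),
    seed: int | None = None,
) -> dict[str, Path]:
    """Write tables to ``directory`` in their on-disk formats.

    GwasTables become summary files, EpisnpTables the seven-column
    single-locus layout; a ``fixtures.json`` sidecar records file names,
    formats and the seed for provenance.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    meta: dict[str, dict] = {}
    for name, table in tables.items():
        path = directory / f"{name}.txt"
        if isinstance(table, GwasTable):
            write_snpevg(table, path, dialect)
            fmt = "snpevg"
        elif isinstance(table, EpisnpTable):
            write_episnp(table, path, dialect)
            fmt = "episnp"
        else:
            raise ValidationError(f"unsupported table type {type(table).__name__}")
        written[name] = path
        meta[name] = {"file": path.name, "format": fmt,
                      "n_markers": table.n_markers}
    sidecar = {"seed": seed, "dialect": dialect.delimiter_policy, "tables": meta}
    (directory / "fixtures.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return written


__all__ = [
    "Signal", "SimConfig", "CausalEffect", "GenoSimConfig",
    "simulate_pvalue_table", "simulate_genotype_study", "single_locus_tests",
    "simulate_episnp_table", "write_fixtures",
]
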