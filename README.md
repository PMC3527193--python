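# gwasfig

Headless, scriptable batch visualization of genome-wide association study
(GWAS) summary statistics.

A GWAS produces one P-value per SNP marker per trait — often millions of
tests across dozens of traits — and digesting them is largely a graphical
task: a Manhattan plot per trait for the global view, a Q-Q plot to judge
test calibration, and per-chromosome figures for local inspection.
Producing those figures one by one in interactive tools does not scale.
`gwasfig` generates all of them in one batch run from plain-text input,
with every plotting decision (cut-offs, thresholds, axis assignments)
represented as testable structure rather than pixels. It is aimed at
quantitative geneticists and analysis pipelines that need publication-ready
figures from any association software's output.

## What it computes

**Genome layout.** Chromosomes are tiled on the x axis at *true size*: the
span of chromosome $k$ is $\mathrm{end}_k - \mathrm{start}_k$, the first
and last marker positions, and the block offsets satisfy exactly

$$\mathrm{offset}_{k+1} = \mathrm{offset}_k + \mathrm{span}_k + g,$$

with $g$ an optional cosmetic gap. A marker at base-pair position $p$ maps
to $x = \mathrm{offset}_k + (p - \mathrm{start}_k)$. Markers on the
*unknown chromosome* (label `0`) carry no usable position and are placed
in sequential file order, one marker per x unit, after the last known
chromosome.

**Q-Q series.** With $N$ P-values sorted ascending, rank $i$ is plotted at
expected $-\log_{10}\!\left(\frac{i-0.5}{N}\right)$ against observed
$-\log_{10} p_{(i)}$; under the uniform null the points track the identity
line. The alternative $i/(N+1)$ convention is available behind a flag.

**Batch size.** One run over $n$ traits and $c$ chromosome blocks with all
plot kinds enabled produces $n(c+2)$ figures: $n$ Manhattan, $n$ Q-Q and
$nc$ chromosome figures (30 traits × 30 chromosomes → 960 files).

**Display semantics.** A *threshold* P-value draws a horizontal reference
line at $-\log_{10} p_T$ (optionally shading below it); a *cut-off*
P-value eliminates markers with $p > p_C$ from the figure entirely. Marker
pixel size can scale linearly with $-\log_{10} p$ between the trait's
least and most significant markers. Multi-trait figures assign each trait
to a left (Y1) or right (Y2) axis, each axis with its own scale (log or
raw), threshold and cut-off.

**Single-locus effect figures.** From effect-test tables (or from its own
genotype/phenotype simulator) it plots the genotypic (2-df ANOVA F),
additive (allele-dosage contrast $(\bar y_{2} - \bar y_{0})/2$) and
dominance (heterozygote deviation $\bar y_1 - (\bar y_0 + \bar y_2)/2$)
test P-values on Y1 with per-marker sample size on Y2, optionally ordered
by a sorted effect.

## Input format

A simple delimited text file (whitespace, comma or tab) with a header:

```
CHR POSITION SNP Trait1 Trait2 ...
1   100      rs1 0.05   0.50
```

1–100 trait columns are supported; `NA`, `.` or empty fields are missing.
Effect tables carry `snp chrom position n_obs p_genotypic p_additive
p_dominance` (any column order, via an explicit column map). The
`convert` subcommand projects columns out of any other software's output
into this format.

## Worked example

```
$ gwasfig simulate --outdir fixtures --seed 7 --n-chrom 5 \
    --markers-per-chrom 200 --n-traits 3 --kind both
wrote pvalues: fixtures/pvalues.txt
wrote single_locus: fixtures/single_locus.txt

$ gwasfig -v batch --input fixtures/pvalues.txt --outdir figures --threshold-p 5e-8
INFO gwasfig: loaded fixtures/pvalues.txt: 1000 markers, 3 traits, 5 chromosomes
INFO gwasfig.figures: batch: 21 figures written to figures
21 figures written to figures

$ head -3 figures/MANIFEST.txt
manhattan	Trait1	all	Trait1__manhattan__all.png
qq	Trait1	all	Trait1__qq__all.png
chromosome	Trait1	1	Trait1__chromosome__1.png

$ gwasfig effects --input fixtures/single_locus.txt --chrom 1 --out effects_chr1.png
```

The batch produced $3(5+2) = 21$ figures: one Manhattan and one Q-Q plot
per trait (5e-8 drawn as the genome-wide significance line) plus one
figure per trait per chromosome, all indexed in `MANIFEST.txt`. The
`effects` figure overlays the three single-locus effect P-values for
chromosome 1 with the sample size on the right-hand axis. The same
figures are available from Python via `build_manhattan_spec`,
`build_qq_spec`, `build_chromosome_spec`, `build_multitrait_spec`,
`build_episnp_spec` and `batch_run`; the intermediate `FigureSpec`
objects expose every plotted point for inspection before rasterization.

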