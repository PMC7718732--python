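# Methods

`cnvpop` implements a population-genomic analysis of copy-number variation
for a two-population cohort of diploid (or dikaryotic, hence diploid-like)
individuals: windowed copy-number calling from read depth, CNV segmentation
and summary, a V_ST differentiation scan with empirical top-1% outlier
selection, CNV-based ordination and clustering, GO-term enrichment, and
per-gene exact tests of copy-state differentiation. A synthetic cohort
generator with known ground truth makes every stage testable end to end.

## Coordinate model

All intervals are 0-based half-open internally. GFF3 (1-based closed) is
converted on read and write; BED passes through. Two intervals overlap iff
they share at least one base; no minimum-overlap fraction is applied.
Scaffolds are stored largest-first, so "the first K scaffolds" of a
size-ranked draft assembly is exactly the K largest (K defaults to 100).
The window grid tiles each scaffold with non-overlapping 250 bp windows;
the trailing window of a scaffold may be shorter and is kept rather than
dropped, flagged as partial downstream.

## Copy-number calling

Copy number per window is estimated from read counts alone:

    ratio_w = count_w / median(count over all windows of the sample)
    CN_w    = round_half_away_from_zero(2 * ratio_w), clipped at 0

The per-sample median is a robust normalizer as long as CNVs affect a
minority of windows; a sample whose median count is zero cannot be
normalized and is rejected with an error. GC-content and mappability
corrections are deliberately out of scope: the statistical pipeline is
isolated from alignment artifacts, and the simulator emits unbiased depths.

**Segmentation surrogate.** Full read-depth callers follow per-window
ratios with a segmentation step (HMMs, LASSO, circular binary
segmentation) that pools information across neighboring windows. `cnvpop`
keeps the caller contract purely per-window (`median_filter=1`, the
default for `call_copy_number`) but exposes a per-scaffold running median
of width 3 on the ratio track, and the end-to-end pipeline uses it
(`median_filter=3`). The reason is quantitative: with Poisson depth noise
at 50 reads per window, a neutral window is called non-neutral whenever
its count leaves [37.5, 62.5), which happens with probability ~7.6%, so
purely per-window calls top out near 92% class accuracy. The width-3
median removes isolated single-window flips while preserving any run of
two or more windows, lifting accuracy to ~99% at the cost of erasing
genuine single-window events (rare under the default event sizes). This
is the package's minimal stand-in for segmentation, and the main place it
diverges from heavier callers.

Gains are CN > 2; losses (absences) are CN <= 1; CN = 2 is neutral.
Segments are maximal same-class runs of windows within a scaffold; the
representative CN is the mode of member windows with ties broken toward
the smaller value. Segments containing a partial trailing window are
called normally but excluded from mean-size statistics and flagged.

Per-population CNV counts are totals across individuals, mean sizes are
means across segments, reported for the whole genome and for segments
overlapping predicted genes. Population comparisons use the Wilcoxon
rank-sum test with per-individual segment count and per-individual mean
segment size as the units of replication (the only choice that yields a
two-sample test). The exact null distribution is used for combined n <=
20 without ties; otherwise the normal approximation with continuity
correction. All-tied inputs return p = 1 directly, since the
tie-corrected z-statistic is 0/0 there.

## V_ST scan

For each window, with population variances (denominator n) V1, V2 of the
two populations' copy numbers, pooled variance V_T, and

    V_S  = (n1*V1 + n2*V2) / (n1 + n2)
    V_ST = (V_T - V_S) / V_T

the law of total variance gives V_S <= V_T, so V_ST lies in [0, 1]; using
sample variances (ddof=1, exposed as an option) loses that guarantee,
which is why denominator n is the default. Windows with V_T = 0 carry no
information and are undefined (NaN) rather than 0: counting them as 0
would drag the outlier quantile toward 0 on mostly-monomorphic genomes.
V_ST is computed on called integer copy numbers, not raw depth ratios.

The scan restricts to the K largest scaffolds *before* any quantile is
computed. The outlier threshold is the ceil(q * n_defined)-th largest
defined value (q = 0.01); every window at or above it is flagged, so ties
at the threshold all flag and slightly more than q of windows may be
selected — preferable to arbitrary tie-breaking among equal statistics.
Flagged windows are intersected with the annotation to produce per-type
overlap tallies (CDS, exon, start/stop codon) and the top-outlier gene
set. A per-gene aggregation (max window V_ST over a gene's CDS) is
exposed for users who prefer ranking genes directly; window-level
selection is the default.

## Population structure

Four filter schemes build the sample-by-region matrices: `all_cds`
(CDS-overlapping windows where any sample deviates from CN 2),
`top1pct_cds` (intersected with V_ST outlier flags), `any_gain` (>= 1
sample with CN > 2), `any_zero` (>= 1 sample with CN 0). Windows are the
default unit; per-gene aggregation (mean CN over a gene's CDS windows) is
an option. Distances are Euclidean on CN vectors (the upstream
ecosystem's default, stated here as an assumption; Manhattan available).

PCoA is classical scaling: double-center -1/2 D^2, eigendecompose, scale
eigenvectors by sqrt(eigenvalue). Axes with negative eigenvalues are
dropped with their total magnitude reported, with no Cailliez/Lingoes
correction — Euclidean input guarantees none beyond floating noise. The
cluster tree is neighbor-joining (negative branch lengths clamped to 0)
with UPGMA as an option.

The source analysis judged population clustering by eye; a testable
artifact needs a number, so `label_concordance` reports the mean
silhouette of the population labels on the distance matrix plus a
permutation p-value: the fraction of label permutations with silhouette
at least the observed, with +1 smoothing, so p is in [1/(B+1), 1] and is
uniform on that grid under exchangeable labels.

## Enrichment and candidate genes

GO enrichment of the top-outlier gene set uses a two-sided hypergeometric
test by the point-probability method — the sum of point probabilities over
the support not exceeding that of the observed overlap (a 1 + 1e-7
relative tolerance absorbs float noise, the standard device in two-sided
exact tests) — with Benjamini–Hochberg correction across terms. The
universe defaults to all genes in the supplied GO map (switchable);
tail-doubling is not used.

Candidate genes come from a case-insensitive literal substring search
over annotation descriptions (e.g. "Na+", "sodium"; "+" is not a pattern
operator). Per gene, copy number is the overlap-length-weighted mean of
the windows it intersects, rounded half away from zero, then scored gain
/ absence / neutral with the same thresholds as the global calls. The
per-gene test is Fisher's exact test on population x {variant, neutral},
where variant pools gains and absences — the minimal 2x2 reading of a
three-state scoring; gain-only, absence-only, and a 2x3 Freeman–Halton
variant are exposed as options. Odds ratios are conditional-MLE with 95%
CI. Bonferroni uses the number of non-degenerate tested genes by default
(genes with all samples in one state are flagged degenerate, p = 1), with
an override for a fixed panel size and a parallel column using the full
panel count, since either convention is defensible.

The heatmap export orders samples by population, clips CN to the 0–12
color scale (values above are recorded), and can flag one highlighted
gene row.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, not its
biology:

- **Genome**: log-normal scaffold lengths (descending), non-overlapping
  genes of 0.6–3 kb with exon/CDS/start/stop children, 0–3 GO terms per
  gene from a configurable vocabulary, and product descriptions sampled
  from a vocabulary that includes sodium-transport entries so keyword
  searches have realistic targets.
- **Truth**: baseline CN 2 everywhere; per sample, loss and gain events
  are independent Poisson processes along the genome with exponential
  sizes. Defaults (1.3 losses/Mb of ~60 kb; 0.22 gains/Mb of ~4 kb)
  reproduce the broad shape of the real cohort summary: losses ~6x more
  numerous and ~15x larger than gains. Losses draw CN uniformly from
  {0, 1}, gains uniformly from {3..12} (no empirical per-event CN
  distribution being available, uniform over allowed states is stated
  rather than hidden). Planted regions overwrite the baseline with
  independent per-sample draws from a population-specific CN
  distribution; differentiation exists only where planted.
- **Depths**: Poisson with mean coverage * CN/2, scaled by window-length
  fraction; default 50 reads per full window at CN 2. An optional
  negative-binomial dispersion knob exists and defaults off.

Deliberately absent: shared ancestry/haplotype structure (events are
independent per sample), GC/mappability bias, read-level artifacts,
linked SNPs. Passing tests therefore demonstrate the statistical pipeline
is correct and well calibrated under its own assumptions, not that the
caller is robust to alignment artifacts in real data.

Everything is deterministic given the seed: identical (spec, seed) pairs
give byte-identical emitted files.

## Validation experiments and problem sizes

`cnvpop.experiments` runs the replicated studies the test suite and
`scripts/acceptance.py` use. Replicates run on a reduced genome (3
scaffolds, ~0.25 Mb, ~1000 windows, 27 samples) so that 100 cohorts
complete in seconds. Event sizes are scaled with the genome (6 losses/Mb
of ~4 kb, 1 gain/Mb of ~1 kb) to keep the per-sample fraction of genome
inside CNVs at a few percent as in the full-scale conditions — unscaled
60 kb losses on a 0.25 Mb genome can cover most of a sample's windows and
break median normalization.

- **Power**: a region planted over a gene at CN 2 (population 1, n=11)
  vs CN 4 (population 2, n=16) lands in the V_ST top 1% and its gene is
  Bonferroni-significant at m=83 in >= 95% of 100 replicates (observed:
  100%).
- **Null**: with no planted differentiation, concordance permutation
  p-values are uniform (KS test), no gene passes Bonferroni and no GO
  term reaches BH q < 0.05 in >= 95% of replicates.
- **Caller closure**: >= 95% per-window class accuracy at 50 reads per
  window with the pipeline's median_filter=3 (observed ~99%; ~92% with
  purely per-window calls, as the Poisson arithmetic above predicts).

## Numerical conventions

- Rounding is half away from zero everywhere a real-valued CN estimate
  becomes an integer (2.5 -> 3), not banker's rounding.
- Exact tests compare point probabilities with a 1 + 1e-7 relative
  tolerance.
- Silhouette and permutation tests consume precomputed distance matrices;
  permutation p-values use +1 smoothing.
- NJ negative branch lengths are clamped to zero after tree construction.

## Known limitations

- The caller cannot distinguish tandem from dispersed duplications, and a
  read-depth method never can.
- No GC or mappability correction: adapters feeding real depth files
  should pre-correct them.
- The 2x2 Fisher collapse discards the gain-vs-absence direction; use the
  Freeman–Halton option when that distinction matters.
- GO annotations are used as given (no ontology-graph propagation).
- Single-window CNVs are suppressed by the width-3 median filter; set
  `median_filter=1` when they matter more than neutral-window precision.
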