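# Methods

## The metagene enrichment statistic

All genomic copies of a named repeat (RepeatMasker `repName`) form one
*TE type*. Coverage is assumed to arrive RPKM-normalized (bigWig or
bedGraph); internally a track is one float64 value per base. For a type's
observed signal, each copy is partitioned into consecutive 500-bp bins
anchored at the copy's 5′ end — minus-strand copies are reversed first,
so bin 0 is always the 5′-most — with the final partial bin kept at its
per-base mean and copies shorter than one bin contributing a single bin.
Bin *b* of the metagene is the mean over all copies long enough to have
bin *b*; the observed value is the maximum bin. The expected value is
the identical computation over a size-matched random background: one
region per copy, of the same length, drawn uniformly over the genome
(chromosomes weighted by length, with optional exclusion regions honored
by rejection sampling). Enrichment is `log2((obs + c)/(exp + c))`,
pseudocount `c = 0.01` RPKM, which bounds the fold when a background
draw is empty; a (type, mark) cell with zero observed *and* zero
expected is reported as fold 0 and flagged low-information.

Two designs here were genuinely open:

* **Metagene mean before max, not max per copy.** Binning each copy and
  then taking the maximum of the copy-averaged profile is less noisy
  than aggregating per-copy maxima and matches the metagene treatment of
  a TE type; the per-copy-max variant would systematically inflate the
  observed value for high-copy types.
* **One background draw per (type, seed), shared across marks.** All
  marks in a run are compared against the same null regions, so
  between-mark contrasts are not confounded by different background
  draws. The seed is recorded in the outputs. Each type's stream is
  salted with the type name (via `SeedSequence` entropy), so types never
  replay one another's draws — and never replay the synthetic
  generator's placement stream when both are handed the same integer
  seed.

Threshold comparisons are strict (`fold > 2`, relaxed `> 1.5`)
everywhere, including the network; a `strict=False` comparator is
available since "at least 2-fold" phrasing also has currency. High/Low
partitions take High as the types above threshold for a mark and Low as
equally many types from the bottom of the fold ranking; the call errors
out rather than letting the sets overlap.

Numerical note: bin sums are computed with `np.sum` over contiguous
array slices in small explicit loops (not `reduceat`/`cumsum`), so the
statistic is bit-for-bit reproducible and can be compared *exactly*
against an independent per-base reference implementation. At the
megabase scales this package targets, the loops are negligible.

## Replicate QC

Replicates are compared on their per-copy mean-RPKM vectors over all TE
copies; a replicate is kept when its Pearson correlation with at least
one other replicate exceeds 0.6, and kept replicates are merged by mean
(preserving the RPKM scale). If every pair is discordant the
highest-coverage replicate is kept with a warning — dropping everything
would silently remove the assay.

## TE ages

Per type, the proportion of divergent sites is `p = mean(milliDiv)/1000`
(unweighted mean over copies; a length-weighted variant is a flag), the
Jukes–Cantor distance is `d = -(3/4)·ln(1 − 4p/3)`, and the age is
`T = d / r` with `r = 4.5e-9` substitutions/base/year. The
single-lineage convention (`d/r`, no factor 2) treats milliDiv as
divergence from the consensus ≈ ancestral state; because the pairwise
convention (`d/2r`) is also published, it is exposed as
`doubled_rate=True` rather than guessed. Types at or beyond the JC
domain boundary (`p ≥ 0.75`) are flagged with undefined age, never
silently dropped.

## Catalog filtering and the LINE split

Copies shorter than 300 bp are removed first; then types whose
*remaining* copy count is below 50 are dropped entirely. The order
matters (a type can lose enough short copies to fall under the copy
threshold) and is fixed: length first. LINE types may be split into
pseudo-types at 5 kb; "long" is strict (`> 5000`), so a copy of exactly
5,000 bp is short. The split is reversible (`merge_split_types`).

## Differential expression

The package does not re-implement a published DE tool; it provides a
deliberately simple, documented negative-binomial Wald engine, because
the scientific content at this layer is the thresholds and the TE-level
summaries, not test internals (the engine is one function and can be
swapped).

* Raw counts are full-quantile normalized by default: each sample's
  sorted values are replaced by the across-sample mean of sorted values.
  Ties take consecutive quantile values in stable input order, which
  makes the transform exactly idempotent. Genes and TE metafeatures are
  normalized together in one matrix.
* Per feature, NB dispersion α (variance = μ + αμ²) is estimated by
  method of moments from within-group residual variance, then shrunk
  toward the across-feature median with 20 pseudo-degrees of freedom —
  at two or three replicates the per-feature estimate is far too noisy
  to use alone.
* The Wald statistic is the natural-log fold over its delta-method
  standard error `sqrt(Σ_groups 1/(n·μ) + α/n)`; two-sided normal
  p-values; Benjamini–Hochberg over genes and TEs jointly (the step-up
  is implemented directly so it agrees exactly with its definition);
  `up` means adjusted *P* < 0.05 **and** linear fold > 2 on normalized
  counts with pseudocount 1 (`down` symmetric). All-zero features are
  excluded and reported.

A caveat the tests make explicit: rank-based full-quantile
normalization assumes a large, mostly-null feature space. On a small
matrix where a sizable fraction of features truly changes, the rank
displacement injects spurious shifts into the normalized values; the
parameter-recovery fixture therefore runs the engine with
`normalize=False` (its simulated samples share one expected library size
by construction), while real multi-thousand-feature matrices go through
the default normalized path.

Counting from alignments (`count_features`) follows the
random-best-alignment convention: each primary alignment is counted once
at its reported position; reads touching both a gene exon and a TE copy
go to the gene (flag to invert); mitochondrial and unassigned contigs
are discarded; TE counts aggregate to the type, never the copy.

## Accessibility

TE accessibility per sample is the length-weighted mean per-base RPKM
over all the type's copies — an overall-accessibility measure, distinct
from the max-bin enrichment statistic (a max-bin variant is a flag).
States follow the 20 % rule against the control sample: opened at fold
≥ 1.2, closed at ≤ 0.8, pseudocount 0.01 applied to both sides of the
ratio. Mark enrichment among opened types is a two-sided Fisher exact
test (point-probability method, via scipy) on the opened × enriched 2×2
table, significant at *P* < 0.01; tables with an empty margin are
reported NA. Peaks link to every gene whose body lies within 10 kb
(edge-to-edge distance, 0 when overlapping, boundary inclusive).

## 2C-like signatures

The signature is the top-200 genes by reference fold-change (2C-like vs
ESC, pseudocount 1), restricted to upregulated genes (fold > 1), ties
broken by gene id. Scoring a knockdown reports the median (and mean —
both, since either convention is defensible) log2 fold of signature
genes and a one-sided Mann–Whitney *U* p-value against non-signature
genes. The reverse direction takes a knockdown's top upregulated genes
and measures them across reference stages the same way. MERVL proximity
labels a gene `same_ori`/`opposite_ori` when any `MERVL-int` or `MT2_Mm`
copy lies within 10 kb of the gene body (inclusive, overlap = 0);
`same_ori` wins when both orientations qualify, because the biological
signal of interest — same-strand splicing into the gene — only needs a
same-strand element to exist.

## Synthetic data: what it emulates, and what it does not

The generator produces a coordinates-only toy genome (no sequence):
chromosome sizes, non-overlapping TE copies placed by rejection sampling
(bounded retries, then an explicit capacity error), per-copy milliDiv ~
Normal(type mean, 30) clipped to [0, 1000], coverage tracks at
background 1.0 RPKM with truncated-Gaussian noise drawn per 25-bp step
(so planted magnitude equals expected fold and emitted bedGraphs stay
compact), planted folds applied multiplicatively (optionally only over
the 5′ 500 bp), negative-binomial count matrices (dispersion 0 degrades
to Poisson), a two-condition expression table with a planted top gene
set, and toy genes — some placed near MERVL-like copies in both
orientations. Everything is deterministic per seed, byte-for-byte for
the text outputs, and each bundle carries a ground-truth JSON plus a
sha256 manifest.

The demo fixture's defaults are chosen so each statistic operates in the
regime the method assumes: six TE types across the four classes with
copy numbers of 70–150 and compact copy lengths (0.3–1.5 kb), so each
planted mark's elevated territory stays near 1 % of the 5-Mb genome and
every metagene bin averages many copies — at mammalian genome scale
enriched TEs are a vanishing genome fraction, and this is the desk-scale
proxy for that; 2,000 gene baselines drawn lognormal (σ = 1.5) around
100 with TE metafeatures an order of magnitude higher (they aggregate
all copies of a type), giving the rank-based normalization a realistic
distribution; planted knockdown TE folds of 6–8, the robust derepression
regime, since quantile normalization suppresses fold magnitudes;
knockdown replicates n = 3 at NB dispersion 0.1.

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: sequence content (no mappability
structure, no GC bias, no real multimapper ambiguity — the random-best
convention is assumed to have been applied upstream); fragment-level
read structure (coverage is painted directly, so there is no Tn5 or
sonication bias); nested or fragmented TE copies (copies never overlap);
biological covariance between marks (each track's noise is independent);
and library-composition effects between samples (counts are drawn with
equal expected library size).

## Pipeline

Stages (`synth → annotate → {enrich → network, express → signature,
atac}`) run as CLI subcommands or via `run_stage`; each writes under
`outdir/<stage>/`, echoes the config, and refuses to run before its
prerequisites. All defaults in `PipelineConfig` are the analysis
constants listed in the README; all randomness flows from the single
`seed`. `run_demo` generates the bundle, runs every stage, and writes a
report comparing each planted effect with what the pipeline recovered
(enrichment within ±0.25 log2; expression called up; accessibility state
matching the planted fold's side of the 1.2/0.8 rule; signature set
equality; responder detection at *P* < 0.05).

## Known limitations

* The enrichment background is genome-uniform; it does not model
  assembly gaps or blacklists unless an exclusion set is supplied.
* The NB engine's common-dispersion shrinkage is coarse compared to
  modern trended/shrunken estimators; it is calibrated for the simple
  designs here (two groups, few replicates).
* GC correction is a lowess detrend, optional and off by default; with
  TE metafeatures the meaning of "the" GC of a feature is already an
  average over copies.
* Accessibility uses aggregate signal, not peak-overlap counts; the
  peak-based variant of the 20 % rule is not implemented beyond the
  max-bin flag.
* The problem sizes used throughout (megabase genomes, hundreds of
  copies, tens of simulation replicates) are the package's chosen
  desk-scale study conditions; the statistics themselves scale linearly
  in genome size and copy number.
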