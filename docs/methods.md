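# Methods

This note documents the statistical model, the defaults and why they are
set as they are, the simulator's scope, and the numerical choices. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Methylation calling

Per-cytosine input is (m, n): methylated (unconverted) and total mapped
reads, pooled over read mappers. Sites are retained when more than 5 reads
were aligned by at least 2 mappers (both thresholds configurable;
single-mapper inputs, e.g. the simulator's, use `min_mappers=1`). X/Y
chromosomes are removed by default to avoid sex-linked bias.

- **Level.** Me = m/n − R, clamped to [0, 1]. R is the non-conversion rate
  (required input, typically 0.002–0.01); clamping precedes all
  threshold comparisons. Subtraction can produce small negatives at
  unmethylated sites, hence the clamp.
- **CpG calls.** Me > 0.8, strict; 0.5 in low-methylation mode (samples
  whose global mCpG level is strongly reduced, e.g. DNMT-rescued ES
  cells). A threshold works because CpG methylation is bimodal.
- **CpH calls.** CpH levels are ~10× lower and unimodal near zero, so a
  threshold on Me cannot separate signal from conversion failure. Instead
  the upper-tail binomial p-value P(X ≥ m), X ~ Binomial(n, R) is used,
  called at p < 1e-5 (strict; ties at the cutoff are not called). The tail
  is exact (regularized incomplete beta via `scipy.stats.binom.sf`), never
  a normal approximation; the point mass alone is not a p-value.
- **FDR calibration.** Null counts m ~ Binomial(n, R) are drawn once per
  site with a recorded seed (a replicate option exists for variance
  estimates); empirical FDR = null calls / real calls per cutoff over the
  descending grid 1e-2 … 1e-6, with 0/0 defined as 0 (no discoveries imply
  no false discoveries). The loosest cutoff with FDR < 0.01 is
  recommended. At depth ~10 and R = 0.005 a null site needs m ≥ 4 to pass
  1e-5 (per-site probability ~1.3e-7), so the FDR at 1e-5 is essentially 0
  on any table with a few thousand true calls.
- **Region levels.** mCpG level of a region = mean Me over CpG sites (both
  strands, dyads not collapsed); mCpH level = methylated CpHs / CpH sites.
  Zero-denominator levels are reported missing, never 0.

## The three-state HMM

Bins of 180 bp tile each chromosome from coordinate 0 (all internal
coordinates are 0-based half-open; only file boundaries convert). The bin
size matches the nucleosomal periodicity of de-novo methylation, which is
also why neighboring bins are informative about each other — the point of
using an HMM rather than per-bin classification.

**Emissions** (fixed, not re-estimated). Detected bins
(CpG reads > 10 and CpH reads > 10, strict) emit their CpH
methylated-read count under Binomial(n_CpH, θ̂_state), with

- θ̂_U = Σ m_CpH / Σ n_CpH over detected bins (genome-wide ratio);
- θ̂_P/N = (m_CpH + α)/(n_CpH + n_CpG), α = n_CpG·M, β = n_CpG − α,
  M_P/N = θ̂_U ± SD_mH·(mG − MED_mG)/SD_mG.

MED_mG/SD_mG are the median and sample SD (ddof=1) of the per-bin CpG
ratio over detected bins; SD_mH the sample SD of the per-bin CpH ratio.
M and θ̂ are clamped to [1e-6, 1−1e-6] (the linear M formula can leave
[0, 1]; the binomial PMF needs θ ∈ (0, 1)). Undetected bins inside a chain
are retained with log-emission 0 for every state so that bin distance
equals genomic distance (keeps the 540-bp linking and 100-kb split rules
in one coordinate system); they are decoded from context alone.

*Information content.* Because θ̂ is a posterior mean dominated by the
observed CpH ratio p̂ when n_CpH ≫ n_CpG, the per-bin P-vs-N log-likelihood
ratio is second order:

LLR ≈ (n_CpG²/n_CpH) · (M_P − M_N)(M̄ − p̂) / (2 p̂(1 − p̂)).

State evidence therefore grows with CpG coverage squared, and at shallow
CpG coverage single bins are only weakly informative — the practical
reason decoding accuracy depends so strongly on CpG density and depth
(see Limitations).

**Chains.** A chromosome is split wherever a run of consecutive undetected
bins spans strictly more than 100,000 bp (≥ 556 bins); leading/trailing
undetected runs are trimmed. Chains never cross chromosomes.

**Transition fitting.** Baum–Welch restricted to the 3×3 transition
matrix and initial distribution, pooled over all chains of a sample (one
model per sample). Stopping rule: max |Δa_jk| < 5e-4, max 500 iterations
(logged if hit). All recursions are in log space (products over 10^5 bins
underflow otherwise) and are numba-compiled. The per-iteration data
log-likelihood is recorded and non-decreasing (EM guarantee, asserted in
tests). Initialization is a sticky diagonal (self-transition 0.9,
off-diagonal split evenly), uniform initial law. A uniform transition
matrix is deliberately *not* the default: with fixed emissions, a uniform
start yields row-identical (iid) expected counts whose correlations decay
too slowly for the 5e-4 tolerance, so EM terminates at the degenerate
iid solution and Viterbi collapses to the majority state. Both the
initialization and the tolerance are exposed.

**Decoding.** Viterbi, exact in log space, with deterministic tie-breaks
toward the earlier state in (P, N, U) everywhere (reproducibility). An
emission-argmax mode (state of highest per-bin emission, undetected bins
unassigned) exists as the baseline the validation compares against.
Posterior (forward–backward marginal) decoding is not implemented.

**Linking and DMRs.** Same-state runs separated by fewer than 3 bins
(i.e. ≤ 2 bins, 540 bp at default bin size) are merged greedily
left-to-right; gap bins are counted (`n_gap_bins_absorbed`) but keep
their decoded per-bin state. Left-to-right greediness makes composite
gaps (mixed other-state/unassigned bins) deterministic and keeps segments
non-overlapping. Linking treats all states uniformly; N segments are the
CpG–CpH DMRs.

## DMR analysis

- Fold change uses the genome-wide mCpH level over called sites; a
  non-positive denominator falls back to +0.0001 (the same guard used for
  log-FC display). Hyper: FC > 2; hypo: FC < 0.5; both strict; everything
  else "neither".
- Annotation overlap is merged base-pair arithmetic (duplicated or
  overlapping DMRs never double-count); the whole-genome row is total DMR
  bp / genome size. Interval intersection is a sorted sweep with an active
  window, checked against a quadratic oracle in tests.
- The proximity profile averages CpH Me by signed offset from
  (un)methylated CpG centers, same strand only, minus-strand centers
  mirrored so offsets read 5'→3' on the center's strand. The 50-bp window
  is centered, offsets [d−25, d+25), sliding at step 1 (the finest
  consistent step). Offsets with no observed CpH are missing, not 0.

## Simulator

`plant_truth`/`simulate_methylome` build an artificial chromosome in
180-bp bins: a configurable number of non-overlapping N regions with
lengths uniform on [1, 100] bins at uniform positions, all other bins P;
per-bin Me_CpG ~ Uniform(0, 1); CpH level 0.1·Me_CpG in P bins and
0.1·(1 − Me_CpG) in N bins (the tenfold scale mirrors real CpH levels).
Sites are placed at distinct uniform offsets within bins (defaults: 2 CpG
and 21 CpH sites per bin, genome-average dinucleotide frequencies, all on
the + strand), per-site depth ~ Poisson(10) (a fixed-depth mode aids exact
tests), methylated reads ~ Binomial(depth, level), plus optional
non-conversion noise Binomial(n − m, R). Zero-depth sites are absent from
the output, as in real count tables. Everything is bit-reproducible from
(config, seed).

What it does **not** emulate: real sequence context (an optional
FASTA-backed path exists only through `annotate_context` on user data),
strand asymmetry, mappability and coverage autocorrelation, PCR
duplicates, per-motif methylation preferences, and between-mapper
disagreement. Passing validation on it shows the segmentation machinery is
correct under the stated generative model, not that real-brain DMR calls
at a given depth are equally accurate.

`simulate_hmm_bins` is a separate bin-level generator for
transition-matrix recovery experiments: states follow a known Markov
chain and per-bin counts follow the P/N/U coupling with two-point CpG
levels (0.02/0.98). Its default coverage (CpG reads ~1000, CpH reads
~500 per bin) is deliberately deep and CpG-dominated so that, per the
information analysis above, emissions identify states and the transition
matrix is statistically recoverable; at the shallow coverage of the
site-level simulator no estimator can recover it to the tested 0.05
tolerance. Recovery there is
a check of the EM machinery, not a statement about shallow data.

`make_null_calibration_input` generates the FDR-calibration table: CpH
sites only, a chosen fraction truly methylated at a chosen level, the
rest pure non-conversion noise.

Benchmarking (`run_benchmark`) scores bin-level N-state detection —
TP/FP/FN over bins, precision = TP/(TP+FP), recall = TP/(TP+FN), 0/0
reported missing — for emission-argmax and full-HMM callers over
replicate sets with seeds spawned from a master seed. Bin-level counting
is used because a region-matching criterion would need an arbitrary
overlap definition.

## Known limitations

- At the simulator's default shallow coverage (depth 10, 2 CpG sites/bin)
  per-bin state evidence is ~0.2 nats, so Viterbi decoding is very precise
  but conservative: only regions whose cumulative evidence exceeds the
  learned transition penalty (~14 nats) are called N, and bin-level recall
  trails the over-calling emission-argmax baseline even though precision
  improves several-fold (the suite's study-scale validation test measures
  exactly this, and the README example shows it: precision 0.98 at recall
  0.25). In information-rich regimes (deeper reads, denser CpGs) full
  decoding dominates the baseline on both axes (asserted as a unit test).
- One transition matrix per sample; no per-chromosome models.
- R is a required input; no estimation from spike-in reads.
- No FASTQ/alignment handling and no microarray parsing; analysis starts
  at count tables.
- Enrichment analyses beyond interval overlap (TF motifs, GO/KEGG) are out
  of scope; outputs are BED/TSV tables ready for external tools.
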