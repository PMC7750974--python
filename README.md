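# cphmm

Detection of genomic regions where CpG and non-CpG (CpH) methylation are
differentially correlated, from whole-genome bisulfite sequencing (WGBS)
read counts.

In most mammalian cells methylated CpH sites (mCpH; H = A, C or T)
colocalize with methylated CpGs, but in brain tissue CpHs are *depleted*
near mCpGs. `cphmm` finds the loci behind this signal: it calls methylated
cytosines from bisulfite counts, segments the genome with a three-state
hidden Markov model into bins where CpG and CpH methylation correlate
positively (P), negatively (N) or not at all (U), and reports N-state runs
as **CpG–CpH DMRs** (differentially methylated regions), with downstream
hyper-/hypo-mCpH classification and annotation-overlap summaries. A
simulator with planted N-state structure supports validation by
precision/recall.

Intended users: epigenomics groups analysing WGBS of brain or stem-cell
samples, downstream of read mapping (the input is per-cytosine count
tables, e.g. Bismark cytosine/CX reports).

## Model

**Methylation calling.** For a cytosine with pooled methylated/total read
counts *m*, *n* and bisulfite non-conversion rate *R* (from spiked-in
unmethylated lambda DNA), the level is Me = m/n − R, clamped to [0, 1].
CpGs are methylated if Me > 0.8 (0.5 in globally hypomethylated samples).
CpHs, whose levels are roughly tenfold lower, are tested against
conversion failure: p = P(X ≥ m), X ~ Binomial(n, R), called at p < 1e-5 —
a cutoff checked by an empirical false-discovery-rate procedure
(calls on simulated null counts / calls on the data) over the grid
1e-2 … 1e-6.

**Segmentation.** The genome is tiled into 180-bp bins (the periodicity of
de-novo DNA methylation along nucleosomes). A bin is *detected* when both
its CpG and CpH read totals exceed 10. Each bin emits its CpH
methylated-read count under Binomial(n_CpH, θ̂_j) with state-specific θ̂:

- θ̂_U = genome-wide CpH methylated-read ratio θ̂_w;
- for P and N, θ̂ is the beta-posterior mean
  θ̂ = (m_CpH + α)/(n_CpH + n_CpG) with pseudo-counts α = n_CpG · M,
  β = n_CpG − α, whose prior mean is shifted from θ̂_w by the bin's
  CpG-methylation z-score:
  M_P/N = θ̂_w ± SD_mH · (mG − MED_mG)/SD_mG,
  where mG is the bin's CpG methylated-read ratio.

Chains are split at undetected stretches longer than 100 kb. Transition
probabilities (and the initial law) are the only free parameters, fitted by
Baum–Welch to a change tolerance of 5e-4; decoding is Viterbi. Same-state
runs separated by fewer than 3 bins (540 bp) are linked; N segments are the
DMRs. A DMR is hyper-mCpH if its mCpH level exceeds twice the genome-wide
level, hypo-mCpH below half (level = methylated CpHs / CpH sites).

## Worked example

Simulate a 20,000-bin chromosome with 30 planted N regions, segment it,
and score the result against the planted truth:

```
$ cphmm simulate --bins 20000 --regions 30 --seed 7 --out sim
simulated 460243 sites in 20000 bins, 30 planted N regions

$ cphmm segment --methylome sim.methylome.tsv --out seg
5 DMRs in 11 segments; EM iterations: 14

$ cphmm evaluate --pred seg.bins.tsv --truth sim.truth.bed
TP=405  FP=7    FN=1206 precision=0.9830        recall=0.2514

$ cphmm classify --methylome sim.methylome.tsv --dmrs seg.dmrs.bed --out cls.tsv
classified 5 DMRs against genome level 0.00761852
```

The learned transition matrix (`seg.model.txt`) is strongly diagonal — the
P and N states persist across many bins, as planted:

```
# transition matrix (rows/cols P N U)
0.999031    0.000967993  9.34151e-07
0.0168787   0.983121     5.60977e-07
0.966329    0.0333551    0.00031603
```

Decoded N bins are almost always truly planted (precision 0.98); recall is
limited at these read depths because short or weakly contrasting planted
regions carry too little evidence to out-weigh the learned state
persistence — see `docs/methods.md` for the information analysis. The same
library is usable without the CLI; `HmmSegmenter` and `MethylationCaller`
are scikit-learn-style estimators:

```python
from cphmm import HmmSegmenter, make_bins, read_cytosine_report, call_sites

table = read_cytosine_report("sample.CX_report.txt", "bismark_cx",
                             nonconversion_rate=0.005)
calls = call_sites(table)
bins = make_bins(table)
seg = HmmSegmenter().fit(bins)
states = seg.predict(bins)
segments, dmrs = seg.extract_dmrs(bins, states)
```

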