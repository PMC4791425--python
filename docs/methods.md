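# Methods

## Electrophysiological feature extraction

All features derive from current-clamp sweep families (500 ms square
pulses, 2 pA increments from −10 to +70 pA by default) and two
voltage-clamp recordings per cell.

**Spike detection.** A spike is a dV/dt upcrossing of the onset criterion
(default 10 mV/ms, configurable) followed within 5 ms by a local voltage
maximum at least 20 mV above the crossing point; peaks closer than 2 ms
merge to the larger one. dV/dt is the forward difference; the height and
refractory guards make detection robust to band-limited recording noise
without any pre-filtering.

**AP threshold.** The onset search anchors at the maximal-slope point of
the upstroke and walks backward to the last sample below the slope
criterion; the crossing is linearly interpolated between samples (both in
slope and voltage). Interpolation matters: at a 5 kHz acquisition rate one
sample spans 0.2 ms, or ~2 mV at threshold-level slopes. The same
interpolation is used for the half-amplitude crossings that define
halfwidth, and for the threshold-voltage crossing that defines rise time.

**Which AP is measured.** Threshold, rise time, halfwidth and amplitude
come from the first spike of the rheobase sweep (the lowest current step
that elicits a spike inside the stimulus window), where the waveform is
least distorted by adaptation. Firing rate is the maximum over sweeps of
(spike count in the stimulus window)/(pulse duration). Rin is
|mean voltage deflection| / |first current level|, with the deflection
averaged over a 50–200 ms post-onset window against a 50 ms pre-pulse
baseline; the window is late enough that membrane charging (τ = Rin·Cm)
has settled for any plausible Rin, and the ratio is reported as a positive
MΩ value.

**Spontaneous PSCs.** The voltage-clamp trace is median-baselined and
lightly smoothed (1 ms); deflections exceeding the amplitude threshold
(default 10 pA) and separated by ≥ 10 ms are events. Two guards control
retriggering on slow decay tails: a minimum inter-event interval, and a
decay envelope (τ 30 ms plus half the detection threshold) that a later,
smaller candidate must clear. Events are classed excitatory/inhibitory by
decay time to 1/e of the peak (default split 10 ms) — a documented
stand-in for pharmacological identification, since fast AMPA-mediated
EPSCs decay in a few ms while GABA_A IPSCs decay over tens of ms.

**Sodium current.** The ramp response is detrended with a 60 ms rolling
median to locate the largest inward transient; the local baseline is then
re-fit as a straight line on the flanking ±25 ms with the central ±6 ms
excluded (the rolling median alone is biased when the transient occupies
a nontrivial fraction of its window). ND unless the deflection exceeds 5
robust standard deviations of the residual noise.

**ND handling.** Unmeasurable entries are NaN in memory and the literal
token `ND` in CSV, never silently zero. A cell with no spikes anywhere
gets ND for the four AP-shape parameters and 0 Hz firing rate; an
explicitly flagged unexcitable cell gets ND firing rate as well.

## Maturity PCA

Parameters have heterogeneous units (Hz, mV, MΩ, pA), so the PCA is on
the correlation matrix: columns standardized to zero mean and unit
variance (ddof = 1), eigendecomposition, scores = Z·V. Before PCA, ND
entries are imputed as "too immature to measure": the observed column
maximum for maturation-negative parameters (halfwidth, Rin, rise time,
threshold) and the observed column minimum for maturation-positive ones
(firing rate, amplitude, Na current, PSC frequencies). The eigenvector
sign is arbitrary, so Dim1 is negated if it correlates positively with
firing rate; after orientation higher Dim1 = less mature. The variable
factor map reports each raw parameter's Pearson correlation with each
score vector.

Grouping uses a deterministic 1-D k-means on Dim1 (k = 3): centers start
at the k quantile midpoints and Lloyd iterations run to convergence, which
removes initialization randomness; ties that would empty a cluster fall
back to a tertile split with a warning. Clusters ordered by mean Dim1 map
to matured < maturing < immature.

## Expression handling

FPKM matrices load from TSV or MatrixMarket (+ row/col sidecars);
duplicate gene rows collapse by elementwise max (warned) so symbol-level
cross-referencing is well defined. The detection filter (keep a gene iff
FPKM ≥ 0.1 in at least one sample, inclusive boundary) applies to raw
FPKM, before the log2(x+1) transform used everywhere downstream; the
transform choice (base 2, pseudocount 1) is the field default for FPKM.
Technical-replicate QC is the Pearson correlation of two log-scale
columns.

## Signed co-expression network

Correlations are Pearson on log2(FPKM+1) across all samples (neurons and
contrast). The signed soft-threshold adjacency ((1+r)/2)^β preserves sign
information; β is the smallest value in 1..20 whose scale-free topology
fit reaches R² ≥ 0.8 (log10 p(k) regressed on log10 k over 10 equal-width
connectivity bins, slope required negative), falling back with a warning
to the argmax-R² β when nothing passes. On strongly block-structured data
(such as the synthetic study, whose correlation structure is two planted
blocks rather than a scale-free hierarchy) the fallback is the expected
path. TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) with unit
diagonal; 1−TOM is the clustering distance.

Module detection is a simplified dynamic cut: average-linkage dendrogram,
cut at a deep-split-dependent fraction of the merge-height range (0.99 −
0.02·deep_split; default deep_split 2), clusters under min_module_size
(default 30) to grey, followed by eigengene-membership pruning: a member
stays only if its correlation with the module eigengene (first PC of the
standardized module submatrix) is significant after Bonferroni correction
across all genes. The pruning matters at realistic sample sizes: with ~40
samples, genes correlate with a large module's eigengene at |kME| ≈
0.3–0.45 by sampling chance alone and would otherwise chain into the
module. An optional PAM-like stage can instead re-assign grey genes to
their closest module. Exact reproduction of any particular third-party
dynamic-cut implementation is not attempted. Module labels follow the
size-ordered color convention (turquoise, blue, brown, …); centrality is
the summed within-module adjacency, with hub ranks breaking ties
lexicographically; edge export writes the k strongest within-module edges
(default 100) as tab-delimited node–node–weight.

The neuron-specific module is identified operationally as the module with
the largest mean log-expression difference between neuron and contrast
samples — no ground-truth knowledge is used.

## Maturation programs and biomarkers

Gene–Dim1 correlations use the neuron samples only, on log scale, with
the exact two-sided p from t = r·√((n−2)/(1−r²)), n−2 df; constant genes
get r = 0, p = 1. Cluster thresholds are strict (r > 0.4, r < −0.4,
p < 0.05) and intentionally uncorrected for multiple testing — the
selection rule is a raw-p threshold, so under a pure-noise null the
expected selection rate per tail equals α/2 by construction (verified by
simulation in the tests). Set intersections sort their output for
determinism; external cross-referencing upper-cases symbols and accepts an
optional synonym map.

## Enrichment

One-sided (over-representation) Fisher exact test per GMT term, on the
2×2 table built inside a stated universe (default: all genes passing the
expression filter — the tested background is configurable). Raw p and
−log10 p are reported; Benjamini–Hochberg q-values are an optional column.

## Synthetic study generator

The generator emulates the study design, not biophysics. Each cell is a
passive RC membrane (resting −65 mV, Cm 25 pF, planted Rin) with
stereotyped AP waveforms stamped at deterministic spike times. The
waveform's upstroke is a linear + half-cosine blend whose slope starts at
8 mV/ms and rises monotonically, so the 10 mV/ms onset criterion is
crossed exactly once at a closed-form voltage — the planted threshold; the
downstroke is a half-cosine back to threshold, placing the half-amplitude
downcrossing at a known time; threshold, amplitude, rise time and
halfwidth are therefore analytically known per cell and serve as ground
truth for the extractors. Maturity m ∈ [0,1] interpolates Rin 800→150 MΩ,
amplitude 40→90 mV, halfwidth 4→1 ms, threshold −30→−45 mV, maximal
firing 2→40 Hz, Na current 200→2000 pA, total sPSC rate 0.1→2 Hz, rise
time 2→0.5 ms (AP rise is much faster than the fall in real spikes), and
rheobase 40→10 pA, each with ~5% per-cell jitter. The F-I curve is a
monotone staircase saturating at the planted maximal count by the top
current step. Cells with m < 0.1 may draw an unexcitable phenotype (no
spikes, ND AP shape). Recording noise is 0.05 mV Gaussian band-limited at
2 kHz, matching a filtered acquisition chain; sweeps are synthesized at
20 kHz so waveform geometry is represented accurately (the acquisition-
matched 5 kHz is available via the config). PSC events are difference-of-
exponential templates (rise 1 ms; decay 5 ms excitatory, 20 ms
inhibitory; amplitudes 20–40 pA on 4 pA noise, SNR ≈ 5) on a jittered
even grid, so planted counts are exact; the sodium transient is a
Gaussian dip on a linear outward ramp.

Expression: log2 values = baseline U(1,6) + 4·1{neuron sample} for the
300 neuron-specific genes + 2·m for the 120 mature-program genes +
2·(1−m) for the 60 immature-program genes + N(0, 0.25) noise,
back-transformed to FPKM; contrast ("blood-like") samples carry none of
the neuron programs, and 5% of genes sit below 0.1 FPKM everywhere to
exercise the filter. The default 20 neurons span m = linspace(0, 1), with
21 contrast samples and 2000 genes — a desk-scale rendering of the study
design. Effect size 2 (log2) with noise 0.25 puts planted gene–maturity
correlations near |r| ≈ 0.85 at n = 20, comfortably but not trivially
above the 0.4 threshold. The bundle also includes a technical-replicate
pair of one library with noise calibrated by the attenuation formula
r = var/(var+σ²) to an expected Pearson r of 0.99, a GMT whose first term
equals the planted neuron-module union (plus random decoy terms), an
external gene list built to share exactly 39 genes with the planted
candidate set, and a ground-truth JSON. Everything is reproducible from
one seed; HDF5 timestamps are disabled so identical seeds give
byte-identical bundles.

What the generator does **not** model — and what passing tests therefore
do not show about real data: conductance-based spike dynamics (adaptation,
bursting, depolarization block), seal/access-resistance artifacts,
correlated or heavy-tailed expression noise, dropout, batch effects,
doublets, and any genuinely scale-free co-expression topology. In
particular the planted module structure is far cleaner than real
transcriptomes; recovery rates here are upper bounds on real-data
behavior.

## Numerical choices and degenerate inputs

Half-amplitude and onset crossings are linearly interpolated; eigenvector
sign is fixed by the firing-rate anchor; k-means initialization is
quantile-based (no RNG anywhere in the analysis path); module colors and
hub ranks break ties lexicographically; edge export sorts by (−weight,
node pair). Zero-variance columns abort the PCA with the column named;
an all-ND column cannot be imputed and errors; an empty post-filter
matrix, an empty module, β < 1, TOM inputs outside [0,1], and a query
outside the enrichment universe all raise with specifics. Enrichment
p-values are floored at the smallest positive double so −log10 p is
always finite.

## Problem sizes

The shipped validation runs at the study's own scale: 20 neurons + 21
contrast samples, 2000 genes (1900 past the filter), 41-sweep protocols
per cell, 50 simulated cells for extractor-recovery checks, and 200
simulated null matrices for the calibration check. All of it executes in
well under a minute on one CPU; the network stage is dense linear algebra
and scales as O(genes²·samples + genes³) in time and O(genes²) in memory,
comfortable to ~25k genes on a desktop.

## Known limitations

The soft-power estimator's choice is only weakly tied to any "true"
generative exponent — on block-structured data the scale-free criterion
legitimately fails and the argmax fallback engages; treat β as a tuning
output, not an inference. The dynamic cut is a simplified height-based
rule plus membership pruning, not a reimplementation of any specific
published cutter; strongly nested module structure may split or merge
differently. EPSC/IPSC classification by decay kinetics is heuristic.
The 1-D k-means grouping reproduces clearly separated maturity groups but
any 3-binning of a continuum is convention where separation is weak.
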