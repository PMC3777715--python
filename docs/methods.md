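# Methods

This note documents the models, conventions and numerical choices behind
`slgraph`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the limitations a user
should know about.

## Synthetic cohort model

Each simulated channel is a convex mixture of band-limited latent
sources,

    x_c(t) = Σ_b a_b [ c_{b,c} s_b(t) + (1 − c_{b,c}) p_{b,c}(t) ],

where `s_b` is one shared Gaussian source per frequency band (white
noise band-passed with a zero-phase 4th-order Butterworth filter and
scaled to unit RMS), `p_{b,c}` an independent private source of the same
construction, `c_{b,c} ∈ [0,1]` the coupling strength, and `a_b` a fixed
band-amplitude profile (δ 1.0, θ 0.8, α 1.3, β 0.6, γ 0.3 — an
eyes-closed, alpha-dominant shape). Channels are scaled to 30 µV RMS, a
conventional resting-EEG amplitude chosen so that the ±150 µV artifact
rule is rarely triggered by clean data. Two correlated channels with
couplings `c₁, c₂` have in-band correlation
`c₁c₂ / √((c₁²+(1−c₁)²)(c₂²+(1−c₂)²))`, so coupling is a monotone dial
for the downstream synchronization likelihood.

Default couplings are 0.4 in all bands (0.3 in gamma) for both groups,
except alpha: 0.6 for controls and 0.3 for patients **restricted to the
effect channels** F4, FC3, FC4, Cz, CPz. This is the planted ground
truth the statistics must recover: a fronto-central/centro-parietal
alpha-band desynchronization. A per-subject coupling jitter
(SD 0.08, one draw per band) provides between-subject variability; the
patients' jittered alpha coupling is the latent severity to which the
synthetic MADRS score is anti-correlated (default target correlation
0.35; MADRS marginal mean 13.0, SD 11.1, rounded and clipped at zero).
YMRS and the demographic covariates (age, sex, IQ, education) are drawn
from the study-table group summaries. Controls score zero on both
clinical scales.

EOG channels are low-passed noise plus ~10 blink pulses per minute
(300 ms raised cosines, ~250 µV); they leak into every scalp channel
with propagation coefficients 0.12 (vertical) and 0.06 (horizontal), so
the EOG-regression stage has real work to do. Artifact epochs are
planted as 200-ms raised-cosine pulses of 400 µV on one random scalp
channel, centred in Poisson(rate)-many randomly chosen 2-s epochs —
unambiguous threshold crossings whose positions are recorded so tests
can compare the rejection mask against ground truth.

Randomness: one master seed spawns independent per-subject
`SeedSequence` streams, so cohorts are bit-identical under a fixed seed
and individual subjects do not interact.

What the generator does **not** emulate: 1/f background spectra, volume
conduction and field spread, non-stationarity, heavy-tailed artifact
distributions, medication effects. Passing tests therefore demonstrate
that the pipeline recovers *planted band-limited coupling structure
under Gaussian conditions*, not that it is robust to every property of
clinical EEG.

## Preprocessing chain

Order: EOG regression → epoching/rejection → selection of the first
clean epochs → decimation → band-pass. Choices:

- **EOG correction** is ordinary least-squares regression of each scalp
  channel on VEOG and HEOG (plus intercept) over the whole recording;
  the fitted EOG contribution is subtracted and the coefficients kept
  for inspection. Blink/saccade-separated variants are an extension
  point; the whole-record regression captures the propagation
  coefficients to well under 1 % on recordings of a few minutes.
- **Rejection** applies the ±150 µV rule to scalp channels only,
  before baseline correction; any single crossing rejects the 2-s
  epoch. Baseline correction subtracts each channel's within-epoch
  mean.
- **Decimation** (1000 → 250 Hz by default) low-passes at 0.4× the
  target rate (100 Hz) with a zero-phase Butterworth filter before
  taking every 4th sample; a unit factor is a no-op.
- **Band filters** are zero-phase (forward–backward) 4th-order
  Butterworth band-passes at δ 1–4, θ 4–8, α 8–12, β 12–30, γ 30–50 Hz.
  Zero-phase filtering matters because SL is phase-sensitive.

## Synchronization likelihood

Per channel, the time-delay embedding uses band-specific parameters
from a frequency prior: lag `l = round(fs/3·HF)` (a third of the fastest
period), dimension `m = round(3·HF/LF)+1` (the embedding spans the
slowest period), Theiler window `w1 = 2l(m−1)` (clears the
autocorrelation time), outer window `w2 = w1 + round(n_ref/p_ref)` (so
each reference sees about `n_ref` recurrences at recurrence probability
`p_ref`). Rounding is half-up. `p_ref = 0.01` and `n_ref = 10` are the
package defaults; they are conventions of this implementation,
configurable per analysis.

For reference vector `i` with `n_cand(i)` candidates in the window, the
critical distance is realized as the `k`-th smallest candidate distance
with `k = max(1, round(p_ref · n_cand))`; the hit set is exactly those
`k` nearest candidates, ties at the `k`-th distance admitted by
ascending partner time. The instantaneous SL of a channel pair is the
shared-hit count divided by `k`, averaged over references. Normalizing
by the realized `k` rather than the idealized `p_ref · n_cand` makes two
identities exact — SL = 1 for identical or affinely rescaled signals
and SL ≤ 1 always — at the cost of a rounding-level departure from the
idealized normalization. Distances are Euclidean by default (squared
internally; the quantile selection is order-invariant), Chebyshev as an
option. Constant signals are rejected: their recurrence distances are
degenerate.

**Epoch handling.** Embedding vectors never span epoch boundaries, but
references and candidates pair across the retained epochs on the
concatenated time grid. This matches the study design (ten 2-s epochs
= one 5000-sample analysis segment) and is required for the default
alpha parameters, whose outer window (1070 samples) exceeds a single
500-sample epoch. Candidate normalization uses the realized per-row
candidate count, so series edges and epoch gaps are handled without
bias.

**Finite-window floor.** For independent *broadband* signals the mean
SL converges to `p_ref` (the hit sets of the two channels are
independent). For independent *narrowband* signals a small positive
bias remains (measured ≈ 0.059 at `p_ref` 0.05 and ≈ 0.011 at 0.01 for
alpha-filtered noise): band-limited autocorrelation concentrates both
channels' recurrences at carrier-period offsets. The frequency-prior
Theiler window suppresses most, not all, of this. Group comparisons are
unaffected (the floor is common to both groups), but absolute SL values
should not be read as calibrated probabilities, and generic (non
band-matched) embedding parameters inflate the floor substantially.

The heavy loops (per-channel hit sets as bit-packed masks, pair-wise
joint-recurrence counts via popcounts) are numba-compiled; an
independent brute-force double-loop oracle in the test suite agrees to
1e-12 on every checked input, and the optimized path is exactly
symmetric in its arguments.

## Graph metrics

Networks stay weighted throughout; proportional thresholding keeps the
`K = round(d · 406)` strongest edges (half-up; ties at the K-th weight
broken by lexicographic channel-pair order for determinism). The
diagonal is never part of any computation.

- **Clustering coefficient** is the geometric-mean triangle form,
  `C_i = Σ_{jh} (w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1))`, computed on the
  **raw** SL weights. SL lives on an absolute (0, 1] scale, and the
  group effect of interest is precisely a cohort-wide weight reduction;
  per-network max normalization (the networkx/BCT default) would cancel
  it. The max-normalized variant is available via
  `global_metrics(..., normalize="max")`.
- **Distances** are 1/weight; shortest paths via Dijkstra.
  **L** averages over node pairs of the largest connected component
  (ties by component label order), so it stays finite on fragmented
  sparse networks; **E_g** averages inverse path lengths over all pairs
  with disconnected pairs contributing zero. Consequently removing
  edges always lowers E_g, and raises L only while the network stays
  connected — below the connectivity threshold the surviving component
  shrinks and L can drop, the expected behaviour for proportional
  thresholding. The Erdős–Rényi bound 2·ln N/N (≈ 23.2 % for 29 nodes)
  marks where random graphs connect.
- **Nodal measures**: strength (weight sum), betweenness (Brandes on
  the distance graph, unnormalized fractional path counts — delegated
  to networkx), local efficiency (mean inverse distance inside each
  node's neighborhood subgraph; ≤ 1 when weights are ≤ 1).
- **Small-world normalization**: surrogates preserve the thresholded
  topology's degree sequence (double-edge-swap rewiring, 10 swaps per
  edge) and reassign the retained weight multiset randomly to the
  rewired edges. γ = C/⟨C_s⟩, λ = L/⟨L_s⟩, σ = γ/λ (exact identity).
  Ensemble size defaults to 50, seeded. Dense graphs admit few legal
  swaps; the implementation then keeps the topology and still shuffles
  weights. Surrogates whose largest component degenerates are skipped;
  an all-degenerate ensemble is an error.

## Group statistics

- **Permutation tests** use the pooled-variance two-sample t on
  covariate-adjusted values. Covariates (age, sex, IQ by default; sex
  factorized) are removed by OLS residualization and group labels are
  permuted over the residuals, preserving group sizes — the
  Freedman–Lane scheme. The p-value uses the add-one estimator
  `(1 + #{|t*| ≥ |t|}) / (B + 1)`, bounded below by `1/(B+1)`. The
  default is two-sided; `alternative="greater"/"less"` reproduces the
  literal one-sided exceedance rule. 10 000 permutations by default.
- **NBS**: edge-wise pooled t tests over the 406 pairs; edges beyond
  the primary threshold (default t = 2.61, the one-tailed p = 0.005
  critical value at df = 142; direction configurable) form a graph
  whose connected components are sized by link count. The null
  distribution of the *maximal* component size over label permutations
  yields each component's corrected p — the canonical max-statistic
  rule. Zero suprathreshold edges is a no-finding, not an error.
- **Partial correlations** residualize metric and score on the
  covariates and take the Pearson correlation of the residuals, with
  `df = n − n_cov − 2` for the t-transform p-value. The pipeline
  computes them in the patient group at 30 % density, where nodal
  comparisons also run (significance p < 0.01 uncorrected for nodal
  maps, p < 0.05 elsewhere). No correction is applied across the
  density sweep — comparisons at neighbouring densities are strongly
  dependent and are reported as a profile, not as independent tests.
- **Demographics**: 2×2 chi-square without continuity correction for
  sex; pooled-variance t tests (patient − control) for age, education
  and IQ.

## Problem sizes in tests and the acceptance script

The package defaults mirror the study design (57 + 87 subjects, 120-s
recordings at 1000 Hz, ten 2-s epochs retained at 250 Hz, 10 000
permutations). The automated suites run the same machinery at reduced
scale, chosen once as part of the experimental design: cohorts of 8–10
subjects per group, 16–32-s recordings generated directly at 250 Hz,
four retained epochs, `p_ref = 0.05` with `n_ref = 5` (a 100-sample
recurrence window) for the Monte-Carlo suites, 500–1000 permutations,
and 20–50 replicates for calibration (permutation-p uniformity,
NBS family-wise error, planted-effect recovery). The acceptance script
uses 12 + 16 subjects with the full 10-epoch, `p_ref = 0.01` analysis
in the alpha and gamma bands. At these sizes the whole-scalp mean-SL
permutation test is underpowered in any single small cohort (as the
README example shows) while the NBS recovers the planted subnetwork
decisively — pooling evidence over connected edges is exactly its
purpose.

## Known limitations

- SL absolute values carry the finite-window narrowband bias described
  above; compare within, not across, parameter settings.
- The EOG model and its regression correction are linear; nonlinear
  blink dynamics would leave residuals.
- Betweenness on weighted graphs assumes unique path lengths almost
  surely; exactly tied paths (measure-zero for continuous weights) fall
  back to networkx's fractional counting.
- The rewired-surrogate null preserves degrees and the weight multiset
  but not the weight-topology correlation; γ and λ inherit that
  convention.
- EDF export quantizes to 16 bits over each channel's physical range
  (error ≤ range/2¹⁶); round-trips are exact only to that resolution.
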