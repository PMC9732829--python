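# Methods

`lfpstates` implements a complete analysis chain for asking how tightly the
oscillatory "state" of one cortical site is coupled to the state of another,
in multichannel local field potential (LFP) recordings made under a fixed
anesthetic concentration — and for asking whether many weak pairwise
couplings suffice to confine the *global* activity pattern to a
low-dimensional set of discrete states. Because the recordings the method
was designed for are not distributable, the package ships a synthetic-data
generator that plants known ground truth (discrete spectral states with a
tunable coupling parameter, and laminar evoked responses with a known
current-sink depth), so every stage is testable end to end.

## Pipeline

### Spectral state extraction

1. **Conditioning** (`preprocess`): anti-aliased staged decimation to
   1 kHz, a zero-phase Hamming windowed-sinc FIR bandpass at 0.1–200 Hz
   (applied forward-backward via FFT convolution; tap count targets a
   0.05 Hz transition at the low edge, capped for short signals), and
   per-probe rereferencing to the mean over clean channels. Artifact
   detection is a deliberately simple RMS-floor mask (burst-suppression
   epochs are near-isoelectric); externally supplied masks are unioned in.

2. **Multitaper spectrogram** (`spectral`): 6 s windows stepped by 100 ms,
   17 Slepian tapers at time–bandwidth product NW = 9, each window
   zero-padded to 2^16 samples. Power is read out on 279 frequencies,
   log-spaced 0.14–10 Hz and linear 10–300 Hz, snapped to padded-FFT bins
   (snapping may collapse a handful of the lowest log points; up to five
   collapses are tolerated). FFTs run in single precision; eigenspectra are
   averaged in double.

3. **Smoothing and rank normalization**: a median filter spanning 10
   frequency steps, then a symmetric exponential ("Poisson") window
   spanning 2 min along time, then per-frequency rank-order normalization
   over unmasked windows — rank r of N maps to (r−1)/(N−1), ties get
   midranks. Rank normalization removes the 1/f power-law baseline and makes
   fluctuations comparable across frequencies; it is invariant to any
   per-frequency strictly monotone transform of power.

   *Why symmetric:* the window family and 2 min span are fixed, but neither
   its decay constant nor its alignment is; we pin decay-to-1%-of-peak at
   each edge and center the window. A causal variant of this span carries a
   ~26 s group delay, which would smear and delay state boundaries — the
   downstream machinery localizes transitions to within a few seconds
   (score flanks of ±3 s), and the measured impulse-pair resolution of the
   full pipeline is ~6 s, so zero-phase smoothing is the only consistent
   choice. On synthetic data the causal variant also degrades state
   recovery substantially (argmax-label agreement with planted states drops
   from ~0.7 to ~0.5 NMI).

4. **NMF states** (`states`): each channel's normalized spectrogram A
   (F × N) is factorized individually as A ≈ U Vᵀ with non-negative
   loadings/scores (multiplicative updates, Frobenius objective, tol 1e−5,
   ≤500 iterations, best of 5 seeded restarts; an optional warm start from
   a smaller-K fit makes error curves over nested K monotone). U and V are
   rescaled so loading columns have unit L2 norm; the relative Frobenius
   error E = ‖A − UVᵀ‖_F/‖A‖_F is reported. The rank K is chosen by
   bi-cross-validation: time-downsample by 20 (strided), hold out a random
   20% of rows and columns, fit on the remainder, refit scores on the
   row-held-out data with loadings fixed and loadings on the column-held-out
   data with scores fixed, and score the held-out block; five replicates per
   K, and K is the smallest value whose increment improves mean error by
   less than one percentage point.

5. **Discrete states**: the component with the highest rescaled score is the
   window's state. Segments shorter than 100 s whose own mean score is less
   than 1.1× a flanking component's mean score (within the segment) are
   absorbed into that flank; if both flanks qualify, the boundary with the
   smaller score-vector jump (mean over 3 s after minus 3 s before,
   Euclidean norm) is the one ignored. The scan repeats to a fixed point
   (each merge strictly reduces the segment count, so it terminates).
   Labels are channel-local: index 2 on one channel has no relation to
   index 2 on another.

### Coupling measures (`coupling`)

All three are symmetric and bounded in [0, 1]:

- **Transition synchrony** — SPIKE-synchronization applied to transition
  times: each transition r gets τ(r) = half the smaller of its flanking
  inter-transition intervals (single flank at the edges; τ = ∞ for a
  singleton train); two transitions coincide iff they are mutually nearest
  and |Δt| < min(τ_i, τ_j) (Δt = 0 always coincides; nearest-neighbor ties
  break toward the earlier transition). The pairwise score is the mean
  indicator over all transitions of both trains; a transition's *global*
  score is its mean indicator over all other channels.
- **NMI (symmetric uncertainty)** — U(X,Y) = 2·I(X;Y)/(H(X)+H(Y)) with
  plug-in entropies in bits; 0 when both sequences are constant. Invariant
  to relabeling, so channel-local state indices are no obstacle.
- **CCA similarity** — the mean of the min(L,M) canonical correlations
  between two channels' score matrices (columns centered; thin-QR + SVD;
  rank-deficient inputs truncate to effective rank with missing directions
  contributing 0). Invariant to invertible linear maps of either state
  space, so it sees shared structure even when NMF split states
  differently in the two channels.

### Null model and statistics (`nullstats`)

A first-order Markov chain is fit to each channel's window-resolution label
sequence *including* self-transitions — this preserves dwell-time
statistics, so surrogates have realistic inter-transition intervals — and
simulated to produce surrogate sequences of the original length (default
1000; the shipped analyses use 200). For CCA, surrogate score rows are
drawn from the channel's own score matrix conditioned on matching state.
Pairwise observed values are tested against the surrogate distribution with
a one-tailed z test (coupling can only meaningfully exceed independence)
and Bonferroni correction over pairs.

Group contrasts on pairwise matrices never treat pairs as independent:
permutation tests shuffle whole channels (rows and columns together;
one-tailed p with +1 smoothing), and between-recording contrasts bootstrap
rows and columns of rectangular cross-probe matrices with replacement.
Note the permutation p has a combinatorial floor set by the number of
distinct channel relabelings — with few channels it cannot reach small
values regardless of effect size.

### Global state (`globalstate`)

The rescaled score vectors of all channels are concatenated per window into
one joint state vector and subjected to PCA (centered, not standardized —
the unit-norm loading convention already equalizes scales). The summary
statistic is the number of components needed for 80% of the variance,
compared against the same statistic on surrogate joint matrices built from
the Markov-shuffled, state-conditioned score surrogates (which preserve
every single-channel property but no cross-channel coordination).

### CSD layer localization (`csd`)

The current source density is the depth-convolution of the trial-averaged
evoked potential with K(z) = (z²−σ²)/(σ⁵√2π)·exp(−z²/2σ²), σ = 280 µm (the
second derivative of a Gaussian; negative for |z| < σ; sinks are negative).
Edge rows use the truncated kernel recentered to zero sum, so
depth-constant offsets never leak into the CSD. L4 is the channel with the
earliest post-stimulus crossing below −3 pre-stimulus SDs *sustained for
3 ms* (the sustain requirement rejects isolated noise excursions; ties go
to the larger sink). Analysis channels are then taken at 140 µm intervals
above and below L4, at most 10 per probe, chosen symmetrically.

## Synthetic data (`synth`)

Hidden states run on a 1 s clock. A master Markov chain with geometric
dwell (default mean 120 s) drives all channels: at each master transition —
and at t = 0 — every channel independently locks onto the master's state
for that master segment with probability c; otherwise it displays its own
independently evolving chain with the same dwell statistics. c = 1 yields
identical paths, c = 0 fully independent ones, and label agreement is
monotone in c.

The 120 s default dwell reflects the transition statistics the method is
designed for (on the order of 100–200 transitions across a multi-hour
recording, i.e. a couple of minutes between switches) and sits above the
100 s merge threshold, so unambiguous segments survive merging.

Signals are rendered as a 1/f background plus stochastic band-limited
resonators (white noise through second-order bandpass filters) whose
amplitudes switch with the hidden state, sample-aligned to the state clock.
Default state profiles give each state a distinctive dominant band from a
physiological pool (slow ~1 Hz, delta ~2.5 Hz, theta ~6 Hz, spindle ~12 Hz,
beta ~25 Hz, gamma ~40/70 Hz) plus a weaker shared band. Evoked responses
inject a spatially Gaussian, temporally biphasic potential at a configurable
sink depth with uniform 3–5 s inter-stimulus intervals; the analytic second
depth-derivative of the injected profile puts the earliest CSD sink at that
depth and latency.

What the generator does *not* emulate: volume conduction between channels,
burst-suppression waveforms, nonstationary drift in state profiles, or
cross-frequency coupling. Passing tests therefore demonstrate correctness
of the machinery and calibration of the statistics under a matched
generative model, not performance on real tissue.

## Numerical and design notes

- **Seeding**: every stochastic stage takes a seed; the pipeline derives
  per-stage seeds from the master seed as SeedSequence([master, counter])
  folded below 2³¹. Reruns are bit-identical.
- **Masked windows** are excluded from rank normalization (N counts only
  unmasked windows), carried as NaN, and dropped before NMF.
- **Problem sizes in the shipped analyses**: 8 channels × 20 min at a 1 s
  spectrogram step, 200 surrogates, 50 surrogate PCAs; the null-calibration
  analyses use 6-channel hidden-state simulations of 3000 s over 50 (type-I)
  and 20 (power) seeded runs. These are deliberate desk-scale analogues of
  the multi-hour, 1000-surrogate design the method targets.
- **Known limitations**: (i) at pipeline scale the synchrony and CCA nulls
  are mildly anti-conservative — merged observed sequences have a dwell
  floor that geometric surrogates lack, and surrogate score rows lack the
  within-state autocorrelation that the 2 min smoother imprints on real
  scores; the calibration suite therefore tests the null at the
  hidden-state level, where it is exactly specified. (ii) NMF tends to
  oversplit (selected K exceeds the planted state count), which depresses
  synchrony between channels by inserting channel-specific sub-state
  flips; NMI and especially CCA are robust to this, which is precisely why
  three complementary measures are carried. (iii) The impulse-pair time
  resolution of the full spectrogram pipeline measures ~6–7 s (window
  length plus smoothing), with the exact value depending on the pinned
  window decay constant.
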