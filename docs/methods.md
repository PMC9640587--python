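# Methods

This note documents the models and procedures implemented in `cppmap`, the
choices made where the methodology left room, and what the synthetic-data
validation does and does not establish.

## Synthetic CPP experiments

Every analysis in the package is validated against experiments generated by
`cppmap.synthetic`, which emulates a two-compartment CPP study (two
25 × 25 cm boxes joined by a 6.5 cm door) with four analyzed sessions
(pre-baseline, baseline, test 1, test 2) and shared neuron identity across
sessions.

**Behavior.** The trajectory is a momentum random walk at 30 Hz: speed
follows an Ornstein–Uhlenbeck process (default mean 12 cm/s, SD ≈ 4 cm/s,
autocorrelation ≈ 1 s, occasional single-frame pauses, hard cap 30 cm/s),
heading accumulates Gaussian turn noise (SD 0.35 rad/frame), walls reflect,
and the midline wall can only be crossed inside the door window. The animal
shuttles between compartments through episodic "leave bouts" (Poisson rate
0.003 per frame; during a bout the heading steers toward the door until the
crossing). Compartment preference is modelled as an *asymmetry of the bout
rate* — the non-preferred compartment is left sooner (extra rate
0.004 × bias) — never as a continuous drift. This matters: a continuous pull
toward the other compartment distorts where the animal goes *within* the
non-preferred compartment (everything bends toward the door), which starves
deep place fields of visits in test sessions and manufactures spurious
compartment-specific place-cell loss that occupancy matching cannot remove.
With rate-asymmetric bouts, within-compartment foraging statistics are
bias-independent, and null experiments show no disPCp/disPCnp asymmetry.
Default biases: 0.35 toward the naturally preferred compartment in
pre-baseline/baseline (≈ 58/42 occupancy), 0.5 toward the drug-paired
compartment in tests (≈ 60/40) — preference shifts of the magnitude seen in
real CPP. Head direction is the movement heading plus wrapped Gaussian noise
(SD 0.25 rad); the behavioral literature gives no generative model here, so
these are free parameters exposed in `SimConfig`.

**Neurons.** Each neuron carries homotopic 2D Gaussian place fields (one per
compartment at the same within-compartment position, present independently
with probability 0.85); the secondary field's peak is scaled by a uniform
factor in [0.35, 1], producing the rate-remapping regime in which roughly
half the cells have inter-compartment map correlations above 0.4. Peak event
probability per 33 ms frame is Normal(0.12, 0.04) (≈ 3.6 Hz peak rate),
field width Normal(4, 0.8) cm, and all neurons share a spontaneous event
floor of 0.002 per frame (0.06 Hz), which keeps binarization and shuffle
tests non-degenerate. Optional head-direction (von-Mises-shaped gain) and
speed (power-law gain) modulation is normalized to unit session mean so
modulation reshapes rather than starves a neuron's event budget. Event
amplitudes are lognormal; non-event frames are exactly zero.

**Session effects and clusters.** Planted labels: `disappear` (planted
tuning in a designated compartment is zero in both test sessions),
`appear` (tuning in a compartment switched on only in tests), `remap`
(fields move to random positions in tests), otherwise stable. Neurons are
assigned to five temporal clusters tied to spatial sectors (SW/NW/SE/NE and
the door junction); cluster members share both a sector-located field
(jitter SD 3 cm) and a slow multiplicative gain (lognormal OU, τ = 2 s,
strength 0.6) — the ensemble co-fluctuation that makes temporal clusters
more than pure place-field overlap. Calcium-like traces for clustering are
the amplitude trains filtered by an exponential indicator kernel
(τ = 0.6 s) plus white noise.

**What the generator does not emulate:** calcium indicator saturation and
rise kinetics, deconvolution artifacts, cross-session registration errors,
non-place covariates (theta phase, acceleration), inter-animal variability
in field statistics, and drug effects on running statistics. Passing the
recovery tests therefore shows the *analysis* is correct and calibrated
under the stated statistical structure, not that real recordings satisfy
that structure.

## Preprocessing

Deconvolved amplitudes are binarized per neuron at 3 × the population SD of
the full trace (zeros included), making the rule invariant to trace
rescaling; constant nonzero traces are flagged and excluded. Frames below
2 cm/s are discarded everywhere. Maps use 1.8 cm half-open bins (origin at
the SW corner); bins with < 0.1 s occupancy are excluded from spatial
information and map correlations (pairwise-complete). Smoothing uses a
Gaussian kernel with SD = 2 **bins** (3.6 cm), truncated at 4 SD and
renormalized over included bins at boundaries; whether the stated SD is in
bins or cm was ambiguous, so it is exposed as `smooth_sd_bins`. Occupancy
matching retains, per spatial bin, the minimum frame count of the two
conditions (uniform random removal from the denser one), repeated over
seeded iterations (default 50) whose results are averaged.

## Place cells

Spatial information uses unsmoothed rates: SI = Σ Pᵢ (λᵢ/λ) log₂(λᵢ/λ) with
λ = Σ Pᵢ λᵢ over included bins (the SI shuffle machinery exploits the
algebraic reduction SI = (1/k)[Σ c log₂ c − Σ c log₂ sec] + log₂(T/k) over
event counts c, which makes 1000 shuffles per neuron cheap). The shuffle
null circularly shifts the event train by a uniform draw in [5%, 95%] of the
trace length (the identity shift is never drawn); the stated shift range is
adopted from the decoder's shuffle control since none is given for the SI
test. Classification repeats the full shuffle test on 20 occupancy-matched
down-samplings across compartments (homotopic within-compartment bins);
PCI = passing fraction, place cell ⇔ PCI ≥ 0.3 and mean rate ≥ 0.1 Hz, with
a reliability flag when a matched compartment has under 60 s of data. Field
size thresholds the smoothed matched map at 50% of peak, takes 8-connected
components, and reports the largest. Note the bound SI ≤ log₂(n bins) holds
only under uniform occupancy; the general bound is log₂(1/min Pᵢ).

## Cell typing and CorrDiff

Functional labels are pure functions of the per-session, per-compartment
place-cell flags (see README for the truth table); disPCp and rtPCp are
mutually exclusive by construction. Rate vs non-rate remapping splits at an
inter-compartment correlation of 0.4 (strictly greater = rate). CorrDiff
aggregates per-neuron baseline-minus-test inter-compartment correlations
over a cell type with the mean (median available via `aggregate=`; the
choice is not dictated by the method), giving two values per animal
(baseline vs test 1, baseline vs test 2). Preferred-compartment ties break
toward left (practically impossible at 30 Hz).

## Bayesian decoding

Events are summed into non-overlapping 0.8 s bins labelled by the spatial
bin of the window's mean position (robust to within-bin motion); the decoder
vocabulary reuses the 1.8 cm rate-map grid. The multinomial parameter is
θ(Xᵢ|y) = (cᵢᵧ + 1)/(Σₖ cₖᵧ + N) with an empirical location prior. The
stated "weights within a location bin sum to the prior" clause is ambiguous;
it is implemented as per-location count normalization rescaled by the prior
(`prior_weighting=True`), off by default because plain Laplace counts
already realize the estimator's stated form and decode identically under
argmax in our tests. The two-step variant multiplies the posterior by
N(y_{t−1}, σ_t²) with σ_t = 2.5·v_t floored at one bin width (a stationary
animal must not freeze the decoder); the first bin falls back to one step,
the previous position is the previous *decoded* position, and the Gaussian's
scale constant cancels in the argmax. Argmax ties break to the smallest
label. The shuffle control circularly shifts the binned test activity
jointly across neurons (per-neuron shifts available via a flag; the method
statement does not fix this), 100 shuffles, shift range [5%, 95%].
Knock-outs zero neuron columns at prediction time only — ablating training
data would let the model compensate — and reconstructed CPP time is the
fraction of decoded bins per compartment.

## Consensus clustering

Traces are noise-filtered at 2 × the RMS residual between raw and denoised
trace. Each of 100 iterations subsamples 90% of frames without replacement
and runs k-means with 10 restarts *under the Pearson correlation distance* —
implemented exactly as Euclidean k-means on row-standardized traces, with
the rows first projected onto their N-dimensional Gram coordinates (an
isometry, so results are unchanged but runtime no longer scales with trace
length). A correlation-vector feature space is available as an alternative
(`feature_space="corr_vector"`) but is markedly more stable per iteration,
which collapses the PAC curve's discriminative power. The consensus matrix
(co-assignment frequencies) is cut by complete linkage on 1 − consensus.
PAC is the off-diagonal fraction strictly inside (0.1, 0.9); the chosen K is
the PAC minimum over the interior search range K = 3..9 (curves reported for
2..10), with the cophenetic correlation's local maximum reported alongside
(PAC governs disagreements). Sector templates place two Gaussian fields at
homotopic within-compartment positions (variance 12.5 cm² for the field
nearer the midline, 25 cm² for the far one); the center cluster — ensemble
peak nearest the midline — is held out first, and the remaining four
clusters are assigned by the 4! permutation with maximum summed correlation,
which subsumes the "maximum summed correlation" tie-break.

## LN-Poisson models

Design matrices are one-hot over visited 1.8 cm position bins, 20°
head-direction bins and 2 cm/s speed bins (capped at 30 cm/s, open-ended
last bin) at dt = 0.5 s. Fitting maximizes Σ(n·u − eᵘ) − (β/2)Σ wᵀLw by
L-BFGS with the analytic gradient; L is the graph Laplacian of the 4-
neighbour grid (position), the circular chain (head direction — circularity
adopted, unstated) or the chain (speed); β defaults to 5. Fold scores are
Pearson correlations between predicted and observed counts on random 10%
held-out folds minus the 95th percentile of 500 circular shuffles of the
observed counts (raw binned counts, no extra smoothing). All seven model
classes are scored on the *same* fold partition so the forward search's
one-sided sign-rank comparisons (α = 0.05, n = 10 folds) are paired; the
selected model must itself beat the null or the neuron is unclassified.

## Problem sizes in the validation suite

The test and acceptance runs use scaled-down study conditions chosen for
single-CPU turnaround: sessions of 5–15 min (clustering uses 15 min, the
length real baseline sessions have), populations of 40–150 neurons,
10–20 seeds or 8 synthetic animals per statistical check, and the method's
stated iteration counts (1000 SI shuffles, 20 PCI iterations, 100 decoder
shuffles, 100 consensus iterations, 500 LN shuffles, 10 folds). Planted
effect strengths for recovery checks are stated in each test (e.g. 15%
disappear-in-preferred neurons; "strong" mixed selectivity uses
head-direction concentration κ = 3 and speed exponent 3.5).

## Known limitations

- PAC-based K selection is only reliable when the subsampling perturbs
  k-means enough to expose ambiguity at wrong K; on very long, very clean
  recordings the consensus matrix can be near-binary at several K and the
  PAC minimum becomes a near-tie (the cophenetic curve is reported for
  exactly this reason).
- The LN speed variable is intrinsically harder to recover than position or
  head direction at matched modulation strength because window-averaged
  speed is a low-pass proxy of the instantaneous covariate.
- The decoder assumes conditional independence of neurons given position;
  the planted cluster co-activity violates this mildly, which is realistic
  and slightly inflates decoding error rather than biasing it.
- `classify_place_cells` is O(neurons × iterations × shuffles × events);
  at full study scale (hundreds of neurons, 20 min sessions) a session takes
  on the order of a minute per compartment pair.
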