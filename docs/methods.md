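# Methods

This note documents the models, conventions and numerical choices
behind `tvcentrality`, and what the synthetic-data validation does and
does not establish about real data.

## Network construction

Each parcel's time series is z-scored to mean 0 and sample standard
deviation 1 (ddof = 1) *within each fMRI run*, runs are concatenated,
and the Pearson product–moment correlation is taken over every parcel
pair of the concatenated series. A parcel whose within-run variance is
zero up to floating-point cancellation (sd ≤ 1e−12 × max|x|) is a hard
error at this stage, with the parcel and run named; inside a sliding
window the same condition only flags that window (NaN column plus a
logged warning), since a brief flat stretch should not abort a run.

The **proportional threshold** keeps the largest *signed* correlations:
edge count = round-half-up of `density × N(N−1)/2` over unordered pairs
(upper triangle), ties at the cutoff broken by ascending (row, column)
index so the edge set is deterministic and nested across densities.
Negative correlations may in principle enter the retained set at high
densities; at the 7.5% default they essentially never do. The graph is
binary, undirected, zero-diagonal, and may be disconnected — no
giant-component enforcement is applied.

Density can be fixed (default 0.075) or selected as the argmax of the
mean **flow coefficient** over the candidate grid
{2.5, 5, 7.5, 10, 12.5, 15}%. For a binary undirected graph the flow
coefficient of a node with degree k ≥ 2 reduces to
`f_i = 1 − C_i` where `C_i` is the local clustering coefficient
(each unconnected ordered neighbour pair is a potential two-step path
through the node); nodes of degree < 2 score 0. Note that on the
synthetic block cohort the mean-flow profile *decreases* with density
(denser thresholds recruit ever more within-community edges, raising
clustering), so selection lands on the sparsest candidate — real
cortical networks, where long-range low-clustering edges enter at
intermediate densities, can instead peak mid-grid. The acceptance
script reports the selected value for the synthetic cohort as computed.

## Centralities

**Eigenvector centrality** is the leading eigenvector of the full
adjacency matrix, computed by symmetric eigendecomposition
(`scipy.linalg.eigh`, top eigenpair) rather than power iteration, for
bit-reproducibility; power iteration is retained purely as a test
oracle. The vector is oriented by its largest-magnitude entry,
residual negative entries (numerically ~0) are clamped, and the result
has unit Euclidean norm, so `A·EC = λ₁·EC` holds to 1e−8. On a
disconnected graph the vector belongs to the component with the
globally largest eigenvalue; other components receive (near-)zero
weight. Users should be aware that this makes windowed EC a
winner-take-all quantity across components. An edgeless graph is an
error (λ₁ = 0 leaves the scaling undefined).

**Louvain communities** use networkx's greedy two-phase
implementation (Newman–Girvan modularity at resolution γ, default 1).
Because Louvain is order-dependent, the partition is the best-of-`n`
restarts (default 100 static, 10 per window), each restart seeded from
a generator derived from the user seed; community labels are renumbered
1..K by smallest member node so identical partitions always serialise
identically. An edgeless graph yields singletons with Q = 0.

**Participation coefficient** follows
`PC_i = 1 − Σ_m (K_i(m)/K_i)²` with `K_i(m)` the node's edges into
community m; isolated nodes get PC = 0 by convention (the ratio is 0/0
there). PC is 0 under a single-community partition.

## Sliding windows

The window spans `round(50 s / TR)` samples (50 samples at TR = 1 s),
as the half-open sample range `[t − L/2, t − L/2 + L)` around centre t,
stepped one sample at a time; the first and last half-window carry no
centre, so a T-sample run yields `T − L + 1` windows. Windows are
rectangular (no taper). Each window is processed exactly like the
static pipeline — correlation, proportional threshold, then EC, or
Louvain + PC with a per-window seed derived deterministically from
(seed, window index) — and the per-window equivalence is asserted
exactly in the tests. For tPC, per-window restarts are reduced to 10:
a 15-min run at TR 1 s solves ~850 community problems per participant,
and restarts beyond 10 change Q only in the fourth decimal on networks
of this size.

## Visual saliency

The saliency model is the classic bottom-up architecture: per frame,

1. channels at 0–1 scale: intensity `I = (r+g+b)/3`; colour opponency
   `RG = R − G`, `BY = B − Y` with the broadly tuned
   `R = r − (g+b)/2`, `G = g − (r+b)/2`, `B = b − (r+g)/2`,
   `Y = (r+g)/2 − |r−g|/2 − b`, negatives clamped and all colour set to
   0 where `I < max(I)/10`; four orientation-energy channels from a
   quadrature Gabor pair (wavelength 7 px, θ ∈ {0°, 45°, 90°, 135°})
   applied to the intensity pyramid;
2. 9-level dyadic Gaussian pyramids (separable 5-tap binomial kernel,
   factor-2 decimation, ceiling dimensions at odd sizes);
3. centre–surround contrasts `|centre − upsampled surround|` for
   centres c ∈ {2, 3, 4} and surrounds s = c + {3, 4} — 6 intensity,
   12 colour and 24 orientation maps, all resampled to level 4;
4. per-map normalisation by the closed-form max-norm operator: rescale
   to [0, 1], then weight by `(M − m̄)²` where M is the global maximum
   and m̄ the mean of all other strict 3×3 local maxima. A map with one
   dominant peak keeps its weight; a map with many comparable peaks is
   suppressed. The closed form was chosen over the iterative
   difference-of-Gaussians variant for determinism and speed; the two
   differ quantitatively, so absolute saliency values are not
   comparable across implementations, though peak locations are robust;
5. normalised maps are summed per channel, each conspicuity map is
   normalised once more, and the three channels are averaged.

The output lives at pyramid level 4 (scale factor 16 with ceiling
division), so a 1024 × 720 frame gives a 64 × 45 map. A 1024 × 768
screen with a 64 × 45 target implies a 1024 × 720 content region, i.e.
letterboxed movie frames; the generator and tests therefore use
16:9-ish content directly. Frames must be at least 256 px in their
smaller dimension (2⁸ for the 9-level pyramid).

Two implementation details matter numerically: the even Gabor kernel
has its DC component removed, and Gabor convolution uses constant
('nearest') edge extension — scipy's reflected extension is inexact
once the kernel outgrows the image, which happens at coarse pyramid
levels, and would manufacture spurious contrast on perfectly flat
frames. With both in place a uniform frame scores exactly zero
everywhere, and the map is invariant to a global brightness shift (as
long as the shift does not move pixels across the low-luminance colour
cutoff).

The **mean saliency signal** is `s̄(t) = (1/F)(1/XY) Σ_f Σ_x Σ_y
s(x, y, f)` over the F = fps × TR frames of each TR bin (F must be
integral; a trailing partial bin is dropped), low-pass filtered by a
5th-order Butterworth applied forward–backward (zero phase) with
reflective padding, cutoff 0.1 Hz. The filter preserves DC, passes
0.01 Hz within 0.0002%, and attenuates 0.4 Hz by ~47 dB.

## Group statistics

Correlations are Fisher-z transformed (`z = atanh r`) before testing.
The group test is a per-parcel one-sample t test against zero (or a
paired t test on participant-wise differences), two-tailed p,
Bonferroni-corrected by the number of parcels and capped at 1. The
signed standard-normal equivalent `Z = sign(t) · Φ⁻¹(1 − p/2)` is
reported alongside, and the significance flag is `Z > z*` with
`z* = Φ⁻¹(1 − (α/n_tests)/2)` computed from the configured FWE level
and test count rather than hard-coded — at α = 0.01 over 360 parcels,
z* ≈ 4.19. The flag is deliberately one-sided-positive, matching how
directional contrast maps are read; the two-tailed corrected p is in
the table for both-tail audits, and the family-wise error of the
procedure is verified empirically on null data (200 simulated studies,
20 participants × 60 parcels: observed FWE within the binomial 95%
band of the nominal 0.01 — Bonferroni runs conservative).

Group-average correlation maps are `tanh(mean(atanh r))` across
participants. Two spatial map correlations r₁, r₂ over n parcels are
compared with the independent-samples Fisher statistic
`Z = (atanh r₁ − atanh r₂)/√(2/(n−3))`; this treats the maps as
independent samples, which overstates Z when both maps share parcels —
the dependent-correlations correction needs the cross-map correlation,
which callers rarely have, so the simple form is provided and this
caveat documented. Head-motion (or any participant-level covariate)
confound checks are plain per-parcel Pearson correlations across
participants.

Time-varying series are aligned to the saliency signal by window-centre
sample index, trimming the signal to the centres; an optional integer-TR
lag (default 0) shifts the signal, and no hemodynamic convolution is
applied.

## Synthetic data

The cohort generator is a Gaussian factor model. With global factor
g(t), community factors c_k(t) and i.i.d. noise e_i(t),

    x_i(t) = s·( √r_b · g(t) + √(r_w − r_b) · c_k(t) + √(1 − r_w) · e_i(t) )

so the population correlation is exactly `r_w` within a community and
`r_b` across communities, for any overall amplitude s (`noise_sd`,
default 1 — it scales the series, not the correlations; the defaults
r_w = 0.6, r_b = 0.1 give block structure comparable to thresholded
cortical matrices). Everything is reproducible from (seed,
participant) via independent seed sequences.

**Saliency coupling** scales the global-factor loading of a chosen
parcel subset by `max(0, 1 + gain · z(driver(t)))` — the factor-model
construction exists precisely so that time-varying coupling is a single
loading, not a new Cholesky per timestep. The clamp at zero prevents
sign flips for large positive gain; a negative gain intentionally
inverts the coupling, and gain 0 reproduces the stationary generator
bit-for-bit (same code path, multiplier ≡ 1).

The calibrated reference cohort (20 participants, 60 parcels in four
communities of 15, 900 TRs at 1 s, gain 1.5, 100-s sinusoidal driver)
couples the *entire first community*. Monte-Carlo calibration showed
why: coupling part of a community drags its uncoupled mates along
(their edges to the driven parcels strengthen, and EC rewards
connection to central nodes), producing positive group-mean driver
correlations ~0.24 in parcels that were never coupled. Coupling the
whole community removes that ambiguity. What cannot be removed is
displacement: EC has unit norm, so when the coupled community's
centrality rises the other 45 parcels' falls, giving them systematic
*negative* driver correlations around −0.2. This is a property of
eigenvector centrality, not a generator artefact, and it is why
detection is defined on the positive tail. Under these conditions the
group test recovers 100% of coupled parcels and flags 0% of uncoupled
ones at FWE 0.01.

The movie generator renders deterministic 8-bit RGB frames: isotropic
Gaussian blobs (σ = radius/3, truncated at 3σ, support reported as the
ground-truth mask) added as `contrast · (colour − background)` on a
uniform background, with frame indices half-open in time
(onset ≤ f/fps < offset).

**What passing does and does not show.** The generator produces
stationary (up to planted coupling) Gaussian series with exact block
correlations and white noise. It has no hemodynamic response, no
autocorrelated fMRI noise spectrum (so effective degrees of freedom in
windowed correlations are overstated relative to real data — an AR(1)
option was considered and deliberately left out of the defaults), no
head-motion artefacts, no vertex-level structure, and its movies have
no motion, flicker or semantic content. Passing the planted-recovery
and calibration checks therefore demonstrates that the *pipeline*
computes what it claims and has its error rates under control at
realistic problem sizes; it does not demonstrate sensitivity on real
cortical data, which requires the real cohort.

## Problem sizes and runtime

The test suite and acceptance script run everything at sizes chosen to
finish in well under a minute per stage on one CPU while keeping the
statistics meaningful: 360 parcels wherever geometry or counting is
what is being checked (thresholding, density selection), 40–60 parcels
and 10–50 replicate graphs for oracle comparisons, the full calibrated
cohort (20 × 60 × 900) for planted recovery, and 200 simulated studies
for the FWE check. A single 1024 × 720 frame takes ~0.7 s through the
saliency model.

## Known limitations

- The flow coefficient's directed general form is not implemented; the
  binary-undirected reduction (1 − clustering) is used throughout.
- Map-correlation comparison assumes independent maps (see above).
- The windowed-EC winner-take-all behaviour on disconnected graphs
  means near-zero tEC for parcels in small components; interpret tEC
  of sparse networks accordingly.
- CIFTI-2 reading averages grayordinates per dlabel parcel and reads
  the series step as TR; surface geometry, medial-wall handling and
  volume structures beyond the label table are out of scope.
- No permutation or FDR alternatives to Bonferroni, no
  autocorrelation-adjusted degrees of freedom, and no inter-subject
  correlation analysis are provided.
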