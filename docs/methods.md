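# Methods

## Model

The decoder treats each event (an SWR or any immobility window) as a hidden
Markov process over the joint state (*x<sub>k</sub>*, *I<sub>k</sub>*): a
latent position on a discretized track and a discrete movement dynamic.
Three dynamics are modeled. *Stationary*: position cannot change between
2 ms steps (identity kernel). *Continuous*: position performs a Gaussian
random walk with variance 6.0 cm² per step, evaluated on shortest-path
distances between grid-bin centers so that probability flows along the
track, never across gaps; 2 SD = 4.90 cm per 2 ms, i.e. latent speeds up to
roughly 25 m/s are plausible under this kernel. *Fragmented*: position may
jump anywhere (uniform kernel), giving a well-defined notion of spatially
incoherent activity. When the dynamic switches, the movement kernel depends
on the ordered pair: transitions into or out of fragmented are uniform,
continuous→stationary is the identity, stationary→continuous is the random
walk. The discrete chain stays in its current dynamic with probability 0.98
per 2 ms step — a geometric dwell with mean 100 ms, about one ripple — and
switches to either other dynamic with probability 0.01 each. Initial
conditions are uniform over dynamics (1/3) and position.

Inference is exact grid-based filtering/smoothing: a forward (causal) pass
with per-slice renormalization, then a backward (acausal) pass in the
two-filter ratio form, dividing the propagated smoothed slice by the
one-step predictive with a zero guard. Integrals over position are Riemann
sums over bin centers × widths. All likelihoods are computed in log space
and shifted by their per-slice maximum before exponentiation; this is exact
up to the per-slice constants that the normalization removes. The backward
pass reproduces brute-force path enumeration on small instances to 1e-10.
Note the joint chain is deliberately *not* reversible (the kernel table is
asymmetric across the stationary/continuous pair), so smoothed posteriors
are not symmetric under time reversal.

## Observation models

Both likelihoods are Poisson in 2 ms bins and shared across dynamics.
Sorted spikes: log *p*(*O<sub>k</sub>*|*x*) = Σ<sub>i</sub>
*N<sub>ki</sub>* log(λ<sub>i</sub>(*x*)Δ) − λ<sub>i</sub>(*x*)Δ, with
place fields λ<sub>i</sub> from a per-cell Poisson GLM: log-link, cubic
B-spline bases over linearized position with knots every 5 cm placed per
track segment (bases never bridge the 15 cm layout gaps), an unpenalized
intercept, and an L2 penalty of 0.5 on the spline weights. The penalty
exists to stabilize low-count fits; on abundant data it changes the fitted
peak by well under 1 Hz. Fitting is Newton–Raphson started at
β₀ = log(mean rate), with step-halving, a gradient ∞-norm tolerance of
1e-6, and a 100-iteration cap (values not externally prescribed; chosen as
conventional defaults). Silent cells are pinned to a 1e-10 Hz floor with a
warning.

Clusterless decoding replaces sorting with a marked point process per
tetrode: λ<sub>i</sub>(*m*|*x*) = µ<sub>i</sub> *p<sub>i</sub>*(*x*, *m*) / π(*x*)
and ground rate Λ<sub>i</sub>(*x*) = µ<sub>i</sub> *p<sub>i</sub>*(*x*) / π(*x*),
with all densities estimated by Gaussian product-kernel KDE (bandwidth
6.0 cm per position dimension, 24.0 µV per amplitude dimension) on
movement-period samples, and µ<sub>i</sub> the movement-period mean rate.
Position kernels are renormalized over the track grid per training point, a
boundary correction that makes π, *p<sub>i</sub>*, and the position margin
of the joint density integrate to exactly one on the bounded track; without
it a plain KDE loses a few percent of mass off the track ends. The
factorization is then exactly self-consistent: ∫Λ<sub>i</sub>π d*x* =
µ<sub>i</sub>. Densities are floored at 1e-15 before division.

Movement (encoding) periods are samples with running speed above 4 cm/s,
where speed is the absolute gradient of linear position smoothed with a
50 ms Gaussian.

## Geometry

Tracks are graphs of straight segments with 2D node coordinates. 2D
positions are assigned to segments by a small HMM decoded with Viterbi: the
observation model is a Gaussian on point-to-segment distance (SD 5 cm); the
per-frame transition model scores each segment pair by a Gaussian penalty
(same SD) on the mismatch between the along-graph distance of the projected
points and the Euclidean displacement, plus a 0.1 diagonal bias, rows
normalized. The exact functional form of this transition model is a design
choice; the qualitative requirement is that single noisy frames near
junctions do not flip the segment assignment, which the tests check against
naive nearest-segment labeling. Assigned frames are orthogonally projected
and mapped to a 1D axis on which segments occupy disjoint intervals
separated by 15 cm gaps. Position grids partition each edge into equal bins
no wider than 3 cm (the trailing bin may be narrower) and carry an
all-pairs shortest-path distance matrix computed with the bin centers
inserted as graph nodes. 2D grids bin occupied positions, fill sub-bin
holes by morphological closing (padded so borders are not eroded), and drop
isolated single-bin specks; a full morphological opening is not used
because it would erase track arms only one or two bins wide.

## Event detection

SWRs: each LFP trace is band-passed 150–250 Hz with a zero-phase 101-tap
FIR (Hamming), squared, summed across tetrodes, smoothed with a 4 ms
Gaussian, square-rooted, and z-scored over the whole session. Candidates
need z ≥ 2 sustained for ≥ 15 ms while the animal moves slower than
4 cm/s; detections are extended to the surrounding mean crossings and
merged if they touch. This threshold is deliberately permissive: band-passed
white noise yields a small nonzero detection rate (the smoothed consensus
power has a 10–20 ms correlation time), which vanishes at z = 3. High-MUA
periods apply the same gating to a z-scored multiunit rate. Events can be
filtered to those with spikes on at least 2 (configurable) tetrodes.

## Summaries

The smoothed dynamics marginal is thresholded per bin at 0.80: an
individual dynamic strictly above threshold wins; otherwise the
stationary+continuous or fragmented+continuous sum strictly above threshold
yields a mixture label (larger sum wins if both qualify); otherwise the bin
is unclassified. Strict inequality follows the "above 0.80" rule; the
threshold is configurable. The 95% HPD region takes bins in descending
posterior order until 95% of mass is covered (ties broken by bin index);
its size is the summed bin width. Replay speed is the absolute value of the
Gaussian-smoothed (2.5 ms SD) gradient of the MAP position track, averaged
within classified segments of at least 20 ms (shorter segments are not
reported because one 3 cm bin per 2 ms step is 1500 cm/s — slow speeds are
unresolvable at that granularity). Distance from the animal is the graph
shortest path between the MAP bin center and the animal's projected
position; stationary periods at ≥ 30 cm are flagged non-local. Events are
spatially coherent if they contain stationary, stationary-continuous
mixture, or continuous periods, and spatially incoherent if they contain
fragmented or fragmented-continuous mixture periods.

## Baselines

The standard-decoder suite computes a 20 ms-bin posterior under a uniform
prior and fits constant-speed lines two ways. The Radon-style fit scans a
dense slope × intercept grid (default 101 slopes spanning ±10⁴ cm/s —
an odd count so the zero-slope line is always a candidate — and every bin
center as intercept), scoring each line by the summed posterior at the
nearest bin per time step (bins farther than half a bin contribute
nothing). Significance comes from circularly shifting each time bin's
posterior by an independent random offset (1000 shuffles; p = (1+#{shuffle
≥ observed})/(1+n)). A common-offset variant is provided but documented as
non-rejecting: a circularly shifted line is still a line with the same
score. The regression fit draws 1000 position samples per bin from the
posterior and fits OLS against time, selecting among arm combinations by
R². The MAP-speed baseline differentiates the per-bin argmax track.
Encoding shuffles: position resampling with replacement (destroys the
spike–position pairing, preserves the occupancy marginal) and run-order
permutation with within-run circular shifts (preserves local spike
correlations); both leave spike trains untouched.

## Synthetic data and what the tests show

The generator reproduces the simulation study conditions: 19 cells with
Gaussian place fields (SD 6 cm — "36 cm variance" is read as 36 cm² for
dimensional consistency — 15 Hz peak, 10 cm spacing) on a 180 cm linear
track; encoding data are inhomogeneous-Poisson spikes along back-and-forth
constant-speed traversals. The run speed is not externally prescribed; the
default is 10 cm/s, a slow-but-typical running speed that gives each cell
roughly 340 encoding spikes over 15 traversals, comparable to a
well-sampled session cell. The three-segment test sequence fires one
interior cell once per 2 ms bin for 60 ms (stationary), then sweeps the
track with the nearest-peak cell firing each bin (continuous, short
sequential bursts), then fires uniformly random cells one per bin for 30 ms
(fragmented). Constant-speed test trajectories fire each cell while the
sweep is within half a field spacing (5 cm) of its peak, so the firing
windows tile the track; at high speed this degenerates to one spike per
cell. Synthetic waveform marks are isotropic 4D Gaussians around per-cell
means laid out ≥ 3 mark bandwidths apart, so the clusterless encoder can
resolve them. Ripple fixtures are white noise plus Hann-windowed 150–250 Hz
bursts.

These conditions are idealized: place fields are identical, evenly spaced
Gaussians with no directionality, theta modulation, or rate remapping;
replay rasters are noise-free constructions; marks are perfectly separable
clusters; LFP noise is white. Passing tests therefore demonstrate that the
inference machinery is correct and that the classification behaves as
designed under its own generative assumptions — not that real recordings
will yield any particular proportion of categories. Two behaviors observed
on synthetic data deserve emphasis. First, burst structure alone (a cell
firing several consecutive 2 ms bins) is classifiable short-timescale
stationarity even under a spatially shuffled encoder; the
position-resampling control therefore demonstrates its full contrast
(classified fraction collapsing, HPD regions tripling) on sparse
single-spike rasters, and the run-order shuffle exists precisely to probe
the burst confound. Second, with single-spike-per-crossing sweeps, slow
trajectories are mostly silence and the time-averaged dynamic probabilities
sit near the 1/3 prior; the speed-band structure of the dynamics requires
the dwell-firing construction above.

## Numerical choices and limitations

3 cm bins balance the random-walk variance (6 cm²), the KDE position
bandwidth (6 cm), and the spline knot spacing (5 cm). Random-walk rows are
renormalized so track ends do not leak mass, which makes the kernel
slightly more concentrating at boundary bins. Uneven trailing bins use
their true widths in all Riemann sums; uniform kernels weight bins by
width. HPD ties and MAP ties break to the lowest bin index. The filter
aborts with a diagnostic if a slice has zero total mass (all-−∞
likelihood). Classification at threshold exactly equal to a probability sum
is unclassified (strict inequality). The decoder's per-event cost is
O(T · n_dyn² · n_bins²) with one dense matrix–vector product per random-walk
kernel per step; a 280 ms event on a 60-bin grid decodes in well under a
second, and the acceptance studies (tens of decodes plus GLM fits) run in a
few minutes on one CPU. Known limitations: no 2D decoding demonstration
beyond the grid machinery and unit tests; no automatic bandwidth or
penalty selection; no online decoding; the linearization transition model
is a documented surrogate for an empirically estimated one.
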