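# Methods

## Generative model

A molecule's conformation follows a continuous-time Markov chain over 2
or 3 states with generator matrix Q (rows sum to zero, off-diagonal
rates ≥ 0). Each state carries a FRET efficiency E_s; states are ordered
by increasing E, and molecules start in the highest-FRET (assembled)
state. The exact event path is sampled (exponential holding times,
embedded-chain jumps), then rendered onto the 10 Hz camera grid: a frame
that spans a transition receives the time-weighted average of the
sub-interval emissions, which is what a time-binning detector records.
Ideal per-frame emissions are `acceptor = I_tot·E`,
`donor = I_tot·(1−E)` with I_tot = 1000 counts by default, mixed through
the leakage matrix `M = [[1−l_DA, l_AD], [l_DA, 1−l_AD]]`
(defaults l_DA = 0.017, l_AD = 0.165, the reference detection path;
settable to zero for cross-talk-free optics), and finally perturbed by
i.i.d. Gaussian noise per channel (σ = 80 counts, i.e. 0.08 of the
total intensity — the reference noise level used throughout testing).

Photobleaching is one irreversible exponential event per dye (default
rate 0.005 s⁻¹ each, mean 200 s, matching illumination "until most dyes
bleach" over a ~200 s acquisition). After acceptor bleach the donor
recovers the full total intensity; after donor bleach both channels drop
to zero-mean background noise. Triplet blinking is not modeled — the
assay suppresses it chemically — and neither are camera images or
diffusion; the simulator emits extracted two-channel traces directly.

Labeling is stochastic over two dye sites: each site is labeled with
probability `label_efficiency` (default 0.9, a realistic maleimide
labeling yield; the value is not dictated by the assay description and
is chosen once here) and a labeled site is a donor with probability
`donor_prob` (default 0.5). Donor+acceptor molecules produce FRET
traces; donor-only molecules produce constant donor traces (with one
step per donor bleach); acceptor-only and unlabeled molecules are
invisible under donor excitation but still appear in the ground-truth
ledger. Fields default to 500 molecules and 3 fields per condition, the
reference field density; tests and the acceptance script use smaller
counts chosen as adequate for their statistical tolerances.

Randomness: one `SeedSequence([seed, field, molecule])` substream per
molecule, so any molecule is reproducible independently of simulation
order, and identical configs give byte-identical traces.

## FRET computation and classification

Leakage is removed by solving the full 2×2 mixing system per frame
(singular only at l_DA + l_AD = 1, which is rejected); sequential
subtraction differs at O(l_DA·l_AD) and is not invertible, so it is not
offered. The efficiency is the uncorrected proximity ratio
`E = I_A/(I_A + I_D)`; frames whose total falls below a floor (20% of
the molecule's pre-bleach median intensity) are marked invalid (NaN) and
excluded from histograms and HMM fitting, never silently dropped from
section bookkeeping.

Donor bleach is located automatically as the first frame after which the
boxcar-smoothed (5 frames) total intensity never again exceeds 30% of
the pre-bleach level; two further frames are trimmed because the frames
spanning the step carry partial intensity. A terminal low-FRET run is
treated as candidate acceptor bleach and trimmed, implementing the
assay's discriminating criterion: an anti-correlated down-step that
never returns to high FRET cannot be distinguished from acceptor
photobleaching, whereas one that returns is a conformational transition.

Classification of each donor-visible molecule:

- `excluded` — no high-FRET dwell at all (no colocalized acceptor,
  e.g. donor-only molecules), median intensity above 1.5× or below 0.5×
  the field's single-molecule level (multi-complex spot / no credible
  signal), or fewer than 50 analyzable frames;
- `without_transitions` — high FRET for the entire pre-bleach trace;
- `with_transitions` — at least one completed low-FRET excursion.

The threshold idealization used for classification applies a 3-frame
median filter and the same high-state boundary (E > 0.5 two-state) as
the dwell analysis, so classification and HMM agree by construction.
The median filter makes single-frame noise spikes inert at the cost of
absorbing true one-frame dwells; at the reference noise level this
trade-off leaves classification agreeing with the ground-truth ledger
for ≥ 95% of molecules (verified in the test suite). The fraction of
molecules without transitions is reported per field as
`n_without / n_total` (the denominator includes excluded molecules;
they never enter the numerator), mean ± SD across fields.

Traces are sectioned as: section I = first dwell (entry unknown),
section III = final dwell (exit unknown / possible bleach), section II =
everything between. Only section II carries usable kinetics.

## HMM idealization

Each transitioning molecule is fitted independently (no pooling) by
Baum–Welch EM with Gaussian emissions, on all pre-bleach valid frames.
Initial guesses: means from the user (defaults E = 0.2/0.8 two-state,
0.2/0.5/0.8 three-state), σ = sample SD of the trace (floored at 1e-3
so noiseless data cannot collapse a state), transition matrix 0.95
self-transition with uniform off-diagonals, uniform initial state
probabilities. The forward–backward pass uses Rabiner scaling plus a
per-frame max-rescaling of the emission matrix, so underflow cannot
occur on 2000-frame traces. Iteration stops at relative log-likelihood
change < 1e-6 or 500 iterations; the likelihood is non-decreasing by
construction and asserted in tests. States are reported sorted by mean,
making results invariant to permuting the initial guesses. A state that
captures no Viterbi frames flags the fit (degenerate), and molecules
with fewer than 20 analyzable frames are refused, logged, and skipped —
a failing molecule never aborts a run.

The per-frame transition matrix is the primary output; conversion to
rates uses `k = −frame_rate·ln(p_stay)` at reporting time only (whether
the reference analysis fitted on the frame grid or in continuous time is
not documented; we fit discrete-time).

## Dwell kinetics

Dwells are contiguous same-state runs of the Viterbi path, labeled by
applying the state boundaries to the fitted state means (not the raw
state index), restricted to section II: the first and last runs of each
trace are dropped because their true start/end are unknown. Durations
are integer multiples of the frame interval; a dwell's duration is
`n_frames / frame_rate`.

Dwell histograms are built on linear (default 1 s bins) and log10
timescales (0.25-decade bins, 3-bin moving-average smoothing for the
minimum search; neither bin width is dictated by the reference analysis
and both are config-exposed). The short/long partition threshold is the
interior local minimum of the smoothed log histogram between its two
largest modes; when the histogram is unimodal the configured default is
returned with a flag. The defaults — 0.56 s for high-FRET dwells and
0.32 s for low-FRET dwells — are retained for all two-state conditions
so that populations are comparable across conditions. Short means
strictly `< threshold`. Population SDs are computed across fields of
view, never by per-dwell bootstrap.

Rates are fitted two ways: (1) unweighted least squares of `A·exp(−kt)`
to linear-histogram counts at bin centers ≥ the cutoff (the default,
mirroring the reference procedure); (2) closed-form MLE for the
left-truncated exponential, `1/k = mean(d | d ≥ c) − c`, which is
statistically efficient and serves as the documented cross-check (the
two agree within 15% on well-sampled data, and the MLE's Monte-Carlo
bias is < 2%, both test-asserted). Fits with fewer than 20 dwells
beyond the cutoff are refused with a diagnostic.

## Binding arithmetic

The isotherm `f = L/(K_d + L)` assumes ligand in large excess over
binding sites (pM surface density vs µM ligand), so depletion is
neglected. With K_d = 1.5 µM this gives 25% occupancy at 0.5 µM and
93% at 20 µM. The competition model is single-site mutually exclusive
binding, `f = (L/K_L)/(1 + L/K_L + C/K_C)`; the simulated competition
assay occupies each tether by an independent Bernoulli draw of that
probability and counts each occupied tether once. Competition assay
counts are normalized per field as ligand spots / tethered complexes,
mean ± SD across fields. Fitting K_d values from competition curves is
out of scope.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies
on — Markov state dynamics, camera integration, Gaussian read noise,
cross-talk, stochastic labeling, and single-step bleaching — so passing
tests demonstrate that every stage recovers known ground truth under
those assumptions. Real traces additionally contain blinking residuals,
baseline drift, non-Gaussian (Poisson-mixed) noise, spot-detection
artifacts, and stage drift; none of these are emulated, so test results
bound algorithmic error only, not instrument effects. One consequence
verified by the ledger tests: observable interior dwells are
length-biased by bleach censoring (mean ≈ 1/(k + k_bleach), not 1/k),
so validation compares recovered dwells against the ledger's own
interior dwells rather than against raw exponential means.

## Numerical and design choices

- Two-site labeling gives (with full efficiency and p = 1/2) donor-
  visible classes DD:DA:AD in equal parts, of which 2/3 are
  FRET-capable; the simulator exposes the labeling parameters rather
  than hard-coding any cap on the fraction of static molecules.
- Colocalization is judged from acceptor signal under donor excitation
  (no direct-excitation channel is modeled).
- Empty inputs produce empty outputs plus warnings, not exceptions;
  non-converged mixture fits are returned flagged with diagnostics.
- CSV is the canonical interchange format (header row, comma delimiter,
  '.' decimal, %.10g floats — at least 6 significant digits survive a
  round trip); HDF5 (`/fields/<field>/<molecule>`, shape (2, T)) is the
  bulk format. Frames are 0-based; a frame's time is its start,
  `frame/frame_rate`.
- Reading vendor microscope formats (.pma/.traces) is out of scope.

## Known limitations

- Bleach detection assumes an irreversible step to background; slow
  decay or re-activation would be mis-segmented.
- The multi-complex and low-signal exclusions need a field-level
  reference intensity; single-trace analysis skips them.
- Dwells censored by the end of section II are excluded rather than
  survival-modeled; multi-exponential dwell distributions are not
  fitted.
- The number of HMM states is user-specified; no variational model
  selection is provided.
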