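# Methods

`ribofret` analyses two-color smFRET trajectories of surface-immobilized
ribosome complexes and ships a synthetic-trace generator so that every stage
of the analysis can be validated by parameter recovery against known ground
truth. This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## The measurement being modeled

A donor dye on the small ribosomal subunit and an acceptor on the large
subunit report on intersubunit rotation: the semi-rotated conformation sits
near FRET efficiency 0.22, the non-rotated conformation near 0.34, and the
eEF2·GDPNP-stabilized fully rotated conformation near 0.17. FRET efficiency
is computed ratiometrically, E = I_A / (I_A + I_D), after background
subtraction. Experiments are either *delivery* mode (acceptor-labeled 60S
subunits flowed in at the start of observation; FRET appears when a subunit
joins) or *preformed* mode (80S complexes assembled beforehand; FRET from
frame 0).

## Synthetic traces

Each molecule is an alternating two-state renewal process: the dwell in
state *i* is drawn from an exponential mixture Σ w_k Exp(τ_k). Double
exponentials are realized as per-dwell mixture draws by default; a
molecule-level mode (each molecule commits to one component per state)
exists because the physical origin of the kinetic heterogeneity is unknown.
A configurable `static_fraction` of molecules never transitions. In
preformed mode the first dwell is drawn from the equilibrium
residual-lifetime distribution (length-biased component choice), since
observation starts mid-dwell; in delivery mode the process starts fresh at
arrival.

Arrival times are exponential with rate k_on·[60S] (k_on in μM⁻¹s⁻¹,
concentrations in nM); an `active_fraction` of molecules is
binding-competent, the rest render as pure background. Donor and acceptor
photobleach with exponential lifetimes clocked from arrival; donor
bleaching drops both channels to background, acceptor bleaching returns the
donor to the full intensity budget. The camera integrates the
occupancy-weighted state intensities over each exposure (partial-frame
weighting at transitions and bleach events) and adds white Gaussian noise
per channel per frame — an EMCCD's excess noise folded into a single sd,
which is all the Gaussian-emission HMM downstream assumes.

Defaults chosen once as realistic EMCCD-scale values: total intensity 1000
counts, background 50 counts, channel noise sd 40 counts at 100 ms and 46
at 25 ms (25 ms imaging uses ~3× laser power and a smaller photon budget),
donor bleach lifetime 200 s at 100 ms and 70 s at 25 ms, acceptor lifetimes
2× the donor's. Seconds are used internally everywhere.

What the generator does *not* emulate: PSF-level image formation, spectral
crosstalk, gamma/detection-efficiency asymmetries, donor blinking,
intensity drift, and diffusing molecules. Passing recovery tests therefore
validate the statistical machinery (idealization, censoring, dead-time and
merging corrections), not robustness to those instrumental effects.

## Calibrated fixtures

`generate_fixtures(name)` returns ready-to-run configurations whose ground
truth encodes the published summary kinetics of the 80S–CrPV-IRES system:
bimolecular 60S arrival at 3.5 μM⁻¹s⁻¹ with 70% binding-competent
complexes; spontaneous exchange with mean dwells 0.97 s (semi-rotated) and
0.38 s (non-rotated); eEF2-driven rotation whose fast/slow phase rates
follow k(c) = k_max·c/(K_half + c) with plateaus 1.0 and 0.2 s⁻¹; a static
fully rotated GDPNP population at FRET 0.17; and a wash experiment whose
control arm freezes after buffer exchange.

Where only summary statistics are published, the remaining freedom was
fixed once by calculation, not by iteration against recovery results:

- Spontaneous-exchange mixtures. The non-rotated dwell distribution is
  pinned by its mean (0.38 s) and median (0.05 s):
  0.75·Exp(0.047 s) + 0.25·Exp(1.379 s) satisfies both exactly. The
  semi-rotated amplitudes are unconstrained beyond the 0.97 s mean;
  0.5·Exp(0.35 s) + 0.5·Exp(1.59 s) was chosen as a moderate split.
- eEF2 saturation. K_half = 100 nM for both phases: with the published
  plateaus, any K_half ≤ 50 nM makes the published 8.4 s semi-rotated mean
  dwell at 100 nM unattainable for every amplitude, so the smaller values
  suggested by "saturation near 200 nM" are internally inconsistent with
  the printed means. Fast-phase amplitudes grow with concentration; the
  100 nM values (0.2 semi-rotated, 0.5125 non-rotated) are solved exactly
  from the printed 8.4/5.9 s means. Sordarin lowers K_half 20-fold.
- Observation windows. 300 s for 100 ms experiments (the stated
  observation window); 150 s at 25 ms, where the 70 s donor bleach
  lifetime ends almost all traces well before the window does.

## Trace processing

Changepoints in the total intensity are found by binary segmentation with
a Gaussian likelihood-ratio acceptance (RSS gain > σ²(θ² + 2 ln n), θ = 4),
which stays sensitive to short segments embedded in long traces — a raw
segment-mean-difference test fails exactly there. Donor bleaching is the
final total-intensity drop to the trace floor; molecules with ≥ 2 downward
steps are aggregates and fail QC. Acceptor bleaching leaves the total
unchanged, so it is detected in the acceptor channel and confirmed by the
anticorrelated donor rise. The usable window runs from arrival to the first
bleach event.

Background is taken per trace from the post-donor-bleach segment; traces
that never bleach in-window borrow the condition's median post-bleach
background (the detector background is shared across a field of view), and
as a last resort the lowest-mean changepoint segment of the acceptor —
exact on background-only traces and conservative (signal-level) on
never-dark traces, which then simply fail arrival detection instead of
false-firing.

Arrival is the first run of ≥ 3 consecutive valid frames with FRET > 0.1
(midway between the off baseline and the lowest conformational state),
confirmed by an acceptor rise of ≥ 3 noise sd; molecules without an
in-window arrival are right-censored in arrival fits. The signal floor for
FRET validity is 3 noise sd of the total; FRET outside [0, 1] is clamped
only for histogramming.

## Idealization

A Gaussian-emission HMM with emission and transition parameters pooled
across all traces of a condition is fitted by maximum-likelihood EM
(hmmlearn engine), initialized by a quantile split with jittered restarts
(10 by default; the pipeline uses 3, which is indistinguishable in
practice on these well-separated two-state data), tolerance 1e-6. States
are always reported sorted by emission mean. The state count is chosen by
BIC over {1, 2} — the FRET-off state is excised upstream by the
arrival/bleach window, which is why a two-FRET-state model suffices; the
criterion does select 3 when an off baseline is left in. Constant data
flag the fit non-identifiable.

Decoding uses the Viterbi path, with one stabilization: the decoding copy
of the model caps emission sds at 1.15× the narrowest state's sd. Camera
time-averaging inflates the apparent width of a state that hosts invisible
fast excursions, and a wider emission makes Viterbi stickier — without the
cap the effective event-detection floor wanders from dataset to dataset
and the dwell corrections below lose their calibration. The reported
emission parameters are the raw fit.

Transitions are *amplitude-qualified* when the flanking dwell-segment mean
FRET values differ by at least half the fitted state separation. "Rotating"
molecules have ≥ 2 qualified transitions with ≥ 2-frame flanks, matching
the operational definition used for the published rotating fractions.

## Dwell-time estimation

Dwells are run lengths of the decoded path; runs shorter than
`min_dwell_frames` are merged symmetrically into their neighbors (odd frame
to the earlier side). The default is 2 frames; the 25 ms spontaneous-
rotation analysis uses 1, because at that framerate a single frame is as
long as the median non-rotated dwell and the 2-frame rule would discard
the mode of the distribution. Last dwells (and, in preformed mode, first
dwells, which begin before observation) are right-censored; in delivery
mode the first dwell starts fresh at subunit joining and is complete.

The estimator then has to contend with the camera: dwells much shorter
than ~2 frames are invisible, and every invisible dwell merges its two
flanking partner-state dwells. Three calibrated ingredients handle this,
all measured against simulator ground truth (decoded paths vs true paths),
none tuned against recovery targets:

1. **Record model.** A true dwell of m frames survives as a record of
   ≥ kmin frames with probability q(m − kmin) = {…, 0.007, 0.15, 0.64,
   0.90, 0.94, ~1}, and retained records carry a ±2-frame duration-error
   kernel (0.05, 0.19, 0.55, 0.18, 0.03), renormalized at the record floor
   (a dwell at the floor can only smear upward — the measured conditional
   kernels match this renormalization). The record floor is
   kmin = min_dwell_frames + 1.7 frames; records below it are discarded
   and the likelihood conditions on retention.
2. **Merging.** Observed records are geometric concatenations of true
   dwells across invisible partner dwells. The geometric compound of an
   exponential mixture is again an exponential mixture of the same order
   (rational Laplace transform; computed by partial fractions and verified
   against Monte Carlo), so the likelihood transforms the fitted
   single-dwell mixture into the record distribution exactly, to first
   order in the partner's missing rate ρ. The two states' fits are coupled
   — ρ for one state is the other state's modeled missing probability —
   and iterated twice.
3. **Degeneracy guards.** Under right censoring, mixtures are degenerate
   along τ → ∞ at vanishing weight (an "immortal" component absorbing the
   longest censored dwells); component weights are bounded below by 2% and
   time constants above by 3× the longest observation, both of which are
   unidentifiable regions at realistic sample sizes.

Fits maximize the resulting likelihood (Nelder–Mead, multiple quantile-
anchored starts); single vs double exponential is selected by BIC unless a
model is forced. Confidence intervals come from the observed information
(finite-difference Hessian) with the delta method for derived quantities.
Because the fitted mixture estimates the *true* dwell distribution, the
reported mean is its mixture mean Σwᵢτᵢ and the reported median is the
model-implied median. The empirical median of detected dwells is reported
alongside but measures the detection floor, not the kinetics — at 25 ms it
sits several-fold above the true median for the fast non-rotated state,
which is why the model-implied median is the headline estimate.

Arrival kinetics fit a single-exponential with a never-arriving fraction
(cure model) by censored MLE per concentration; k_obs is regressed on
concentration by inverse-variance-weighted least squares (free intercept
by default, through-origin available) and the slope is reported in
μM⁻¹s⁻¹. Saturation curves fit k(c) = k_max·c/(K_half + c) by weighted
least squares; a flagged, unidentifiable K_half is reported when the data
show no curvature. Because single-series hyperbolic fits ride a
k_max/K_half ridge, the concentration-series analysis also offers a joint
fit of several rate series with a shared K_half
(`fit_hyperbolic_shared`) — the study observes one saturation
concentration for both phases and both rotation directions, and the
precisely measured slow phases then pin the saturation point for the
noisy fast phases. Per-point uncertainties are floored at 10% of the rate
so no single overconfident fit dominates.

First-event analysis measures the time from window start to the first
qualified transition, right-censoring molecules without one; identical
first-event times short-circuit to a flagged degenerate summary. Wash
analysis counts qualified transitions in equal-length windows on both
sides of the wash.

## FRET distributions

Pooled (frames-pooled, not per-molecule means) raw FRET values are
decomposed into one or two Gaussians by EM (scikit-learn engine), selected
by BIC; a forced two-component fit collapses to one, flagged, when the
single-component BIC wins or the means land closer than a quarter of the
pooled sd. Post-synchronized heatmaps align traces at arrival or at a
chosen qualified transition (first event per molecule by default), bin
FRET at 0.02 and time at the frame interval, and normalize each populated
time column to 1.

## Known limitations

- The merged-record model is first order in the partner's missing rate;
  at the 25 ms spontaneous-exchange conditions (where roughly half of the
  non-rotated dwells fall below the effective dead time) recovered means
  still carry a ~5–10% coefficient of variation at 200 molecules. An exact
  phase-type likelihood of the full merged process would tighten this.
- The retention/smear constants are calibrated for emission separations
  and noise comparable to the fixtures (separation ≈ 3–4 noise sd); very
  different SNR regimes would need recalibration against ground truth.
- No crosstalk or gamma correction is applied by default (correction
  factors are accepted as options); the simulator does not generate such
  distortions.
- Fits with fewer than ~20 uncensored dwells warn and may be unstable;
  per-concentration double-exponential fits at the lowest eEF2
  concentration are dominated by censoring and enter downstream fits only
  through their large uncertainties.

## Problem sizes

The validation fixtures use the published per-condition molecule counts
(102/130/117 arrival; 200 spontaneous; 143/129/268/202/169 across the eEF2
series; 150 GDPNP; 142/126 wash) at 3000 frames × 100 ms or 6000 × 25 ms.
The full recovery run completes in a few minutes on one CPU; unit tests
use smaller synthetic sets generated at test time.
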