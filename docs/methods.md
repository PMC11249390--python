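# Methods

This note documents the models behind `stallflow`, the parameters that
matter, the synthetic data the package validates itself against, and the
numerical and design choices that were genuinely open.

## Stall detection

**Model.** A capillary stall is an interval during which a segment's
angiographic intensity collapses toward background because red blood cells
stop moving through it. Detection operates on a T×H×W stack of projected
angiogram frames (default 60 frames of 512×512 px at 9 s/frame; 4-D volumes
are first flattened by per-frame maximum intensity projection along Z).

**Segmentation.** Capillaries are delineated once, on the *time-mean* image,
so that segments which vanish in individual frames — precisely the stalls of
interest — are still present in the map. The mean image is enhanced with a
Frangi-type multiscale bright-ridge filter (scales 1, 1.5, 2, 3 px, spanning
capillary half-widths at micrometre-scale lateral resolution), binarized
(Otsu threshold by default, overridable), skeletonized, pruned of terminal
spurs shorter than 10 px (spurs otherwise split long branches at spurious
branch points; the longest branch of each skeleton component is never
pruned, so small tubes survive), cut at branch points, filtered to branches
of ≥ 5 skeleton px, and grown back onto the binary mask by watershed on the
inverted vesselness. On default synthetic stacks with 250 rendered tubes
this yields ~230–280 labeled segments.

**Event calling.** Each segment's trace is its per-frame mean intensity. The
per-capillary threshold is α × median(trace) with α = 0.5 by default; frames
strictly below threshold are stall-flagged, and maximal flagged runs of at
least `min_duration` frames (default 3, i.e. ~27 s at 9 s/frame) become true
events. The fraction-of-median rule is our automatization of a per-capillary
threshold; α is exposed in config and nothing in the package depends on the
specific value beyond the recovery tests. The summary proportion counts
*segments with at least one true event* over all segments; an event-count
rate (`event_rate`) is also reported, since a segment may stall repeatedly.
Duration statistics pool all true events.

Indices are 0-based; an event's `start_frame` is the first flagged frame and
`duration_frames` counts flagged frames.

## Bolus kinetics

**Model.** After a rapid intravascular dye injection the concentration at an
ROI rises from a flat baseline to a peak; arteries rise before veins. ROI
traces are per-frame medians over the ROI mask (default sampling 33.3 ms
over 45 s).

**Arrival** is the first time the (lightly smoothed) trace exceeds baseline
mean + 3·SD and stays above for 3 samples; the baseline window is the first
max(10, n/10) samples. A small relative floor (10⁻⁹ of the excursion) keeps
the threshold strictly above baseline on noiseless data. The **peak** is the
smoothed global maximum (last sample for monotone traces).

**Half-max rise time.** t½ is where the rising limb crosses midway between
I_arrival and I_peak. The crossing is estimated by a least-squares line fit
to the *raw* samples inside the 30–70% rising band (the band is located on a
0.2 s moving-average copy), solving the fitted line for the half level. On
traces too short for a band (< 3 samples) the estimator falls back to
two-point linear interpolation, which reproduces hand-computable cases
exactly. This choice is deliberate: the first raw-sample crossing is biased
early and noisy (its error at 20 dB SNR is ~0.25 s), while the band fit is
exact on noiseless traces (error ~10⁻⁵ s) and reaches ~0.07 s mean absolute
MTT error at 20 dB SNR — within one–three samples.

**MTT** = t½(vein) − t½(artery). MTT is invariant to per-trace affine
intensity rescaling by construction. A negative MTT is returned with a
warning rather than suppressed, to keep the estimator honest on noisy data.
**BFI** = (I_peak − I_arrival)/(T_peak − T_arrival). The trace median
(`I_median`) is recorded in kinetics output for completeness but drives no
formula.

## Network flow and tracer transit

**Graph model.** Vessels are cylinders with Poiseuille conductance
g = π d⁴ / (128 μ L). Internal units are µm, s, mPa·s; `edge_conductance`
returns µm³ s⁻¹ mPa⁻¹ and boundary pressures are converted from mmHg once
(1 mmHg = 133 322.4 mPa). Viscosity is a constant effective 2 mPa·s;
a diameter-dependent law can be substituted by passing per-call viscosity
and editing conductances, but none is applied by default.

**Flow solve.** Mass conservation at interior nodes with Dirichlet
boundary pressures gives a sparse SPD system solved directly. Components
with no pressure-fixed node (possible only in hand-built graphs) are
assigned zero flow and reported. Conservation residual on the default
network is ~10⁻¹³ relative to the mean |edge flow|.

**Stalling.** `apply_stalls` blocks round(f × n_capillaries) capillary edges
drawn uniformly without replacement from the id-sorted capillary list,
multiplying their conductance by 10⁻⁶ — near-total blockage that keeps the
system nonsingular. Arterioles and venules are never blocked.

**Tracer advection.** Each edge is a plug-flow delay line with transit
τ = volume/|flow|; at each node the outgoing concentration is the
flow-weighted average of the delayed incoming concentrations (complete
mixing). Edges carrying less than 10⁻⁹ of the maximum |flow| (in particular
blocked edges) transmit nothing. The time step must resolve the fastest
transmitting edge; `transit_summary` auto-picks dt = 0.45 × min τ, so the
discretization rescales exactly with flow magnitude — this is what makes the
boundary-pressure linearity check exact to machine precision. The inlet
bolus is a 0.7 s rectangular pulse starting at 0.5 s by default.

**Transit measurement** reuses the half-max-rise estimator on the simulated
concentration curves (no smoothing, zero baseline), per artery–vein
measurement-point pair (6 × 6 = 36 pairs by default); unreached vein points
flag the pair invalid rather than entering the mean. The default
stall-fraction sweep grid is {0, 0.5, 1, 2, 2.5, 3}% ∪ {4, 6, 7, 8, 9, 10}%
— six control-like and six inflammation-like scenarios; a coarser
{0, 1, 3}/{4, 8, 10}% grid can be passed instead.

**Pressure perturbation** multiplies the inlet–outlet pressure difference by
a factor with the outlet fixed. Because the model is linear, flows scale
with the factor and every plug-flow transit scales inversely.

## Synthetic data

**Angiograms.** 250 curvilinear tubes (random-walk centerlines, widths
2–4 px) are placed one per cell of a regular grid, which keeps them disjoint
and makes the ground-truth label map exact. Vessel baseline intensities are
uniform in 0.8–1.2 (background 0.15), with multiplicative per-pixel noise of
CV 0.10 on vessels and additive σ = 0.03 on background. ⌊f·n⌋ segments are
chosen for stalling; each gets one event of duration 3 + Poisson(mean − 3)
frames (default mean 5) at a uniform start, during which the segment drops
to background level — mimicking the disappearance of flowing cells rather
than a hard zero. Geometry, noise and stall selection use independent seeded
RNG streams. What the generator does *not* emulate: vessel crossings and
loops, depth-dependent shadowing, motion artifacts, and spatially correlated
speckle — so passing recovery tests demonstrate correctness of the
algorithmic chain, not robustness to every in-vivo nuisance.

**Bolus pairs.** The arterial curve is a peak-normalized gamma-variate
A·((t−t₀)/αβ)^α·e^(α−(t−t₀)/β) (α = 3, β = 1.5 s, t₀ = 5 s), the standard
indicator-dilution shape; the venous curve is the same kernel evaluated at
t − delay (exact, analytic delay), optionally dispersed by a Gaussian kernel
whose width is recorded in the truth record. Additive Gaussian noise is
applied independently per trace and the result clipped at zero. Real venous
curves are additionally dispersed and recirculate; the default pair is the
cleanest case that still exercises every estimator.

**Networks.** A (10, 8, 8) cubic capillary lattice (60 µm, 4 µm edges,
±10% jitter) is diluted by a deterministic checkerboard rule on transverse
edges — degree-guarded so no dead ends arise — bringing the mean capillary
degree to ~4, between the full lattice (6) and cortical branching (~3).
Sixteen penetrating arterioles and sixteen ascending venules per side attach
at evenly spaced, staggered face positions (penetrating vessels are
quasi-regularly spaced in cortex); binary trees with Murray-like taper
(child = parent·2^(−1/3), floored at 8 µm) collect them to a single inlet
(60 mmHg) and outlet (10 mmHg). Six tree leaves per side, evenly spread, are
labeled as measurement points. The defaults give 1168 capillary edges,
baseline transit ~0.6 s and arteriole velocities of a few mm/s. The number
of penetrating vessels matters for cohort statistics: with only 8 per side
the per-animal stall response is heavy-tailed (a random block adjacent to an
attachment throttles a whole territory), while 16 self-average it.

**Cohorts.** `simulate_cohort` draws per-animal stall fractions uniformly
from the group range (control 1–3%, inflammation-like 4–10%), builds a
per-animal network (jittered geometry), simulates MTT under that animal's
random blockage, couples mean stall duration positively to severity, and
derives per-animal BFIs from a bolus pair whose delay equals the simulated
MTT. Ten animals per group, as in the modeled experiment.

## Pipeline

`run_all` derives independent per-stage seeds from one top-level seed by
SHA-256 hashing (stable across processes; < 2³¹), validates the config
before running, writes per-stage CSVs (floats at 12 significant digits),
and emits a manifest with the config hash, stage seeds, package version and
output list. Identical configs produce byte-identical numeric outputs.

## Numerical choices and degenerate inputs

- Constant images yield an all-zero vesselness response (no ridges), not an
  error; an empty binary mask raises "no capillaries detected".
- α must lie strictly in (0, 1); traces shorter than the minimum duration
  are rejected.
- Identical samples give t = 0, p = 1 in both t-tests; zero-variance inputs
  with distinct means raise, since t is undefined.
- The tracer time grid must be finer than the fastest edge transit; the
  error names the limiting edge.
- Blocked edges keep 10⁻⁶ of their conductance, so the linear system never
  becomes singular; their residual flow is below the transmission floor and
  they carry no tracer.

## Known limitations

- The capillary bed is a diluted regular lattice, not a reconstructed
  cortical network; absolute transit values depend strongly on
  angioarchitecture and should be read as relative quantities.
- The flow model is linear (constant viscosity, rigid vessels, no red-cell
  phase separation). One consequence, computed by the acceptance script: at
  8% blockage the network loses ~14% of its flow, but the measured transit
  lengthens only ~10–12%, because the blocked capillaries' volume leaves the
  perfused set along with their flow (plug-flow V/Q cancellation). A 20%
  boundary-pressure increase, by exact linearity, shortens transit by 16.7%
  — so in this model a 20% pressure change outweighs 8% stalling, and the
  qualitative ordering "stalling dominates pressure" holds only for pressure
  perturbations up to ~10–12%. Reproducing a stronger stall dominance
  appears to require nonlinear haemodynamics or realistic angioarchitecture,
  both outside this package's scope.
- Bolus estimators assume a single-passage rise; recirculation and strong
  venous dispersion are not modeled.
- Stall detection assumes stalls darken a segment below half its median
  intensity; partial stalls (slow flow rather than stopped flow) are not
  separable from noise at the default α.
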