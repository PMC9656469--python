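# Methods

`rodflux` implements the quantitative analysis chain of a rod-photoreceptor
calcium-handling study: macroscopic voltage-gated calcium channel (VGCC)
conductance estimation from voltage ramps, cell-attached single-channel
analysis, Fluo-4 fluorescence calibration with store-content metrics, and the
summary-statistics layer used to compare wild-type (WT) and *Cacna2d4*-mutant
(MUT) rods. A synthetic-data generator emulates every input so the whole chain
is verifiable offline. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Whole-cell ramp analysis (`rodflux.iv_ramp`)

Ramp currents (240 ms, −80 to +50 mV) are averaged across sweep replicates,
corrected for the ohmic leak, and fitted with the two-component activation
model

    I(V) = g_Ca / (1 + exp(-(V - V_Ca)/S_Ca)) * (V - E_rev)
         + g_Cl / (1 + exp(-(V - V_Cl)/S_Cl)) * (V - E_Cl)

with conductances in nS (g·mV = pA), the calcium reversal fixed at
E_rev = +50 mV and the chloride reversal at E_Cl = 0 mV. The fixed reversals
anchor the component labels: the branch whose driving force vanishes at
+50 mV is the VGCC, the one vanishing at 0 mV the calcium-activated chloride
conductance.

**Leak subtraction.** An ordinary least-squares line is fitted to the samples
whose command voltage lies in the closed window [−80, −70] mV (inclusive,
voltage comparisons at 1e−9 mV) and subtracted everywhere. A caveat the
package makes measurable rather than hides: for half-activation near −28 mV
and slope ~10 mV the Boltzmann tail still contributes ~1–3% of the peak
current inside that window, so the leak line absorbs part of the activation
foot and the subsequent fit inherits a deterministic bias of order 20% on
g_Ca that is present even at zero recording noise. The bias attributable to
noise and sweep averaging alone — measured by fitting the same simulated cell
with and without noise through the identical pipeline — is below 5% (median,
200 simulated cells); the acceptance script reports both numbers.

**Fitting.** The model is partially linear: for fixed (V_Ca, S_Ca, V_Cl,
S_Cl) the conductances solve a non-negative linear least-squares problem.
`RampIVModel.fit` therefore profiles the conductances out (variable
projection, NNLS inner solve) and searches the four-dimensional gating space
from several starts, then polishes all six parameters with `curve_fit` to
obtain the covariance. Unit weights are used (no weighting scheme is implied
by the data). Bounds: conductances ≥ 0, slopes in (0.1, 50) mV,
half-activations in (−80, +40) mV. On noiseless forward-model data the fit
recovers all free parameters to numerical precision over the admissible grid.
Non-convergence is reported on the results object, never silent.

Conductance density is 1000·g_Ca/C_m (pS/pF). Membrane resistance from step
protocols is the inverse slope of the steady-state I/V line (mean of the last
200 ms of 2 s steps) over [−120, −90] mV; a flat I/V yields an infinite
resistance with an explicit flag.

## Single-channel analysis (`rodflux.single_channel`)

Cell-attached records (1 kHz sampling, 0.2 kHz low-pass) are cut into 1.9 s
stretches and binned into all-points amplitude histograms at 0.02–0.05 pA.
Each histogram is fitted with a sum of up to three area-parameterized
Gaussians

    C(x) = sum_i A_i / (w_i sqrt(pi/2)) exp(-2 (x - xc_i)^2 / w_i^2).

The component count is selected by a BIC-style score,
m·ln(RSS/m) + penalty·3N·ln(m) over the m bins, i.e. a larger N is retained
only when three extra parameters buy a sufficient residual drop; the penalty
multiplier is configurable (default 1) and every candidate's score is
reported. Initialization places centers at the largest local maxima of a
lightly smoothed histogram. Two pragmatic safeguards address the fact that
filtered level distributions are not exactly Gaussian: components whose
centers coincide within three bin widths are pooled after fitting, and, at
the record level, a stretch amplitude more than three scaled MADs (floored at
two bin widths) from the median of its sibling stretches is excluded from the
mean — an occasional stretch otherwise resolves a spurious intermediate level
formed by filter-transition samples.

**Peak differencing.** The unitary amplitude is the mean spacing of adjacent
peak positions, signed in the direction from the closed level toward the open
levels. The closed level is identified as the component with the largest area
(the baseline occupies most of a record), which makes the sign insensitive to
constant offsets of the current axis. For three-peak ladders the mean of the
adjacent differences is used.

Transmembrane voltage in the cell-attached configuration is
V_trans = V_rest − Vp, with V_rest assumed −60 mV (WT) or −40 mV (MUT).
Per-voltage amplitudes (mean ± SE over ≥3 stretches) are regressed on
V_trans; the slope gives the unitary conductance (pA/mV → pS × 1000) and the
x-intercept the reversal potential, with the intercept SE propagated by the
delta method.

## Fluo-4 calibration and trace metrics (`rodflux.calcium`)

Fluorescence is normalized to F_MAX, the peak in 10 µM ionomycin + 30 mM
Ca²⁺. The effective dissociation constant is solved per cell from a
calibration point at 494 nM free calcium. Two conversion conventions are
implemented and must be chosen explicitly:

- linear (default):  [Ca²⁺] = Kd (F − F0)/(F_MAX − F0),
  Kd = Ca_cal (F_MAX − F0)/(F_cal − F0)
- hyperbolic:        [Ca²⁺] = Kd (F − F0)/(F_MAX − F),
  Kd = Ca_cal (F_MAX − F_cal)/(F_cal − F0)

The linear form is affine in F and can only report concentrations up to Kd at
F = F_MAX; the hyperbolic form is the textbook single-wavelength saturation
relation. Both round-trip exactly at zero noise, and both reproduce the
494 nM point by construction. Under the hyperbolic form, samples at or above
F_MAX are returned as NaN (flagged, not raised).

Trace metrics: KCl response amplitude = statistic over the segment (default:
maximum; plateau mean available) minus the mean of a 20 s pre-stimulus
baseline; baseline drift = least-squares slope of F/F_MAX over a pre-stimulus
window (≥4 samples); store metrics from the 25 mM K → 0 Ca/EGTA → ionomycin
sequence use the mean of the last 5 s of recovery, the minimum during
0 Ca/EGTA (the drop's extreme), and the ionomycin peak minus that floor.
The three ratios are (rec − baseline)/baseline, (floor − rec)/rec, and
ΔCa_iono/(rec − floor). Under the linear dye form all three are invariant to
the calibration scale. The MRS-1845 block is the mean of the last 10 s of the
drug segment minus a 20 s pre-drug baseline, returned with that baseline for
covariate analysis. Quality control discards cells whose 40 mM KCl response
is below 0.1 ΔF/F_MAX — exactly 0.1 is kept — and logs every exclusion with
its value. The Mn²⁺-quench level (~100 nM equivalent) is carried as a
plotting reference only, never used in computation.

## Statistics (`rodflux.stats`)

Two-sample comparisons default to the pooled-variance Student's t
(two-tailed), computable either from raw samples or from printed
(mean, SEM, n) summaries; the pooled form is the one that reproduces the
published statistics for unequal group sizes, and this consistency ships as
a test. Welch's form is available. Two-way ANOVA (genotype × [K]o) uses
statsmodels OLS with type II sums of squares by default (type logged);
repeated exposures of the same cells are treated as independent
observations, mirroring the published analysis, and this is a documented
simplification. Bonferroni post-hoc comparisons use the ANOVA residual mean
square with p multiplied by the number of comparisons and capped at 1.
One-way ANCOVA is the nested-model F (y ~ group + covariate vs
y ~ covariate) with a slope-homogeneity pretest (group × covariate
interaction, α configurable, default 0.05); forcing the covariate slope to
zero reduces the group F exactly to the one-way ANOVA F. Regression slopes
are tested with the classical OLS t on n − 2 df; an exact line is flagged
rather than producing a division error. No automatic outlier handling:
exclusions are explicit inputs and are logged.

## Synthetic data (`rodflux.synthetic`)

The generators define the package's study conditions.

**Ramps** are the forward model plus g_leak (V − E_leak) plus white Gaussian
noise per sweep (default 9 sweeps). Sampling is 5 kHz by default — amplitude-
domain analysis is insensitive to the sampling rate, and this keeps
Monte-Carlo suites small.

**Channel records** sum independent two-state Markov chains (exact
discrete-time transition probabilities, stationary initial state), scale open
counts by gamma (V_trans − V_rev) with inward current negative, add white
noise, and apply a single-pole recursive low-pass at 200 Hz. The recording
hardware used a multi-pole Bessel filter; a single pole is sufficient for
amplitude-domain tests, which is all the analysis consumes.

**Fluorescence traces** integrate a deliberately phenomenological,
discrete-time first-order relaxation model of cell-body [Ca²⁺] driven by the
perfusion protocol; the published phenomenology is amplitudes, slopes and
ratios, so parameter recovery only needs a controllable forward model, not a
mechanistic flux model. During a K segment [Ca²⁺] relaxes toward
baseline + k_response([K]o) at the extrusion rate (default 0.15 /s); after
washout a fraction recovery_deficit of the achieved rise is retained as the
new baseline. Between stimuli the baseline creeps up at
drift_gain·(1 − store_content) nM/s — the surrogate for store-depletion-
activated cation-channel (CSC) influx; MRS-1845 scales both this term and the
accumulated elevation by (1 − mrs_block_fraction), reversibly. In 0 Ca/EGTA
the trace relaxes toward a floor of Ca_baseline·store_content·egta_floor_share
(+ configurable minimum, default 0): full stores hold [Ca²⁺] up when influx
is blocked, depleted stores let it collapse toward the chelated limit — the
direction the imaging data show. Ionomycin in 0 Ca releases
iono_release_gain·store_content while the store empties within the segment
(total release); ionomycin in 30 mM Ca, the 494 nM calibration saline and the
Mn²⁺ quench clamp the dye readout (F_MAX, the 494 nM level, and the ~100 nM
reference respectively). Caffeine adds caffeine_release_gain·store_content
transiently. [Ca²⁺] is converted to fluorescence by inverting the chosen dye
form; white Gaussian noise is added last. All draws flow from one seeded
generator per call.

**Cohorts** draw per-cell parameters from per-genotype normal distributions
(clipped to admissible ranges), simulate a KCl-series trace per cell, and
measure the per-cell quantities downstream statistics consume. Defaults
follow the published group values where those are printed: baseline [Ca²⁺]
477.65 (WT) / 260.43 (MUT) nM, Kd 990.25 / 932.79 nM, g_Ca 0.29 / 0.10 nS,
and C_m near 20 / 15 pF so the conductance-density means land at 14.50 /
6.62 pS/pF (note these densities imply a C_m an order of magnitude above a
rod's 2–5 pF; the package follows the printed values). Store content (0.85
WT / 0.20 MUT), K-response gains (60–420 nM scaled by genotype), release
gains and the extrusion rate are package choices set once so the forward
model lands near the printed response amplitudes and ratios; they were not
fitted. Simulated WT/MUT cohorts reproduce the study's qualitative
signature — smaller K-evoked responses, steeper baseline drift, a more
complete 0 Ca/EGTA drop, smaller caffeine and ionomycin responses, and a
larger unitary conductance in MUT — which is what the directional tests
assert; the generator makes no claim to reproduce per-cell magnitudes of
real recordings.

**What passing tests do and do not show.** The generators share the
analysis-side model families (Boltzmann activation, Gaussian levels,
first-order calcium kinetics), so recovery tests validate the estimation
machinery, not the biological adequacy of those families. Real records
contain drifting seals, multi-state gating, dye bleaching and compartment
artifacts that are deliberately out of scope.

## Numerical choices and degenerate inputs

- Voltage-window membership uses a 1e−9 mV tolerance; window endpoints are
  inclusive.
- All-zero ramp traces fit with both conductances at the zero bound.
- Flat step I/V → infinite R_m with `finite=False`, not an exception.
- Zero-count histograms and histograms with fewer than five occupied bins are
  rejected before fitting; a mixture size whose parameters outnumber the
  bins is excluded with a logged reason.
- Degenerate (zero-variance) t tests return a flagged result with p = 1 for
  equal means.
- Seeds: every simulation function takes an explicit integer seed; derived
  seeds stay below 2^31.

## Known limitations

- No dwell-time or kinetic single-channel analysis, no sub-conductance
  states, no idealization.
- No series-resistance or capacitance-transient handling (assumed done at
  acquisition).
- The repeated-exposure design is analyzed as independent observations; no
  mixed-effects modeling.
- The fluorescence model has no photobleaching, no spatial diffusion, no
  mechanistic SERCA/CICR kinetics; the drift–store coupling is a surrogate,
  not a fitted mechanism.
- Printed summaries are rounded to 2–3 significant figures, which bounds how
  closely the published t statistics can be recomputed from them (three of
  the fourteen cannot be matched to better than a few percent from the
  printed inputs alone).
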