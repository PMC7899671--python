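# Methods

## Scope and model

`chanlink` analyses whole-oocyte TEVC recordings of GABA_A receptors in
which spontaneous (unliganded) channel activity is measurable as a
PTX-blockable standing current. Two levels of description are used:

**Two-state linkage model.** Pore gating in each liganded condition is
approximated by a single closed and a single open state, so each condition
has one gating free energy dG = -kT ln(Po/(1-Po)). Open probabilities are
obtained from current-amplitude ratios under an assumed open probability in
saturating GABA (Po-GABA-max): Po(0) = Po-GABA-max * I_PTX/I_GABA-max and
Po(DZ) = Po(0) * I_DZ-max/I_PTX. The drug's energetic contribution is
ddG_DZ = dG1 - dG0; a uniform offset across constructs is estimated by the
least-squares unit-slope line dG1 = dG0 + ddG, whose solution is the mean
of the per-construct differences. The amplitude ratios reference maximal
currents to the zero-current level revealed by PTX block (evoked deflection
plus I_PTX); evoked deflections themselves are measured from the
spontaneous-current baseline. This convention is what makes
I_PTX/I_GABA-max an estimator of Po(0)/Po(GABA-max).

**MWC allosteric model.** A two-conformation (closed C / open O) scheme
with two equivalent, independent GABA sites and one DZ site. L is the
unliganded C/O probability ratio; each bound GABA multiplies the gating
equilibrium by c and bound DZ by d (both in (0, 1] for positive
modulators, i.e. the open state binds with higher affinity c*K_G, d*K_D).
The closed form

    Po = [1 + L (1+G/K_G)^2 (1+D/K_D) / ((1+G/(c K_G))^2 (1+D/(d K_D)))]^-1

is checked in the test suite against a 12-state partition-function
enumeration (2 conformations x 3 GABA occupancies with binomial degeneracy
x 2 DZ occupancies) to 1e-12. Ligand efficiency,
eta = [1 - log K / log(factor K)] x 100%, is the fraction of binding energy
converted to gating energy; its logs are of molar-valued quantities, so
the molar unit convention is part of the definition.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| kT | kcal/mol | 0.5925 | room temperature (298.15 K); the recordings are at room temperature and this value reproduces the tabulated energies best. Configurable. |
| Po-GABA-max | – | 1.0 (L9'T background), 0.85 (WT) | gain-of-function L9'T receptors open with near-unit probability in saturating GABA; WT maximal Po is the literature value. A sensitivity table recomputes all energies under alternative assumptions (e.g. 0.5). |
| baseline window | s | 5 | pre-pulse stretch free of responses (washout gaps are much longer than the decay time constant). |
| smoothing | s | 0.1 | moving average for locating response extrema. |
| peak amplitude estimator | s | mean over final 1 s of the application | see "Numerical choices". |
| grace period | s | 1 | extends the peak-location search past pulse end for slow solution exchange. |
| Hill bounds | – | EC50 in [1e-10, 1e-1] M, n in [0.2, 5] | generous physical bounds; initialisation by coarse log-grid scan. |
| MWC bounds (log10) | – | L in [-6, 9], K in [-12, 0], c,d in [-8, 0] | positive-modulator regime; an `allow_inverse` flag admits d > 1. |

## Global fit and parameter sharing

Estimated-Po curves are built by rescaling normalized pooled Hill fits:
GABA curves run from Po_spont = Po_max * r_ptx_gaba to Po_max; DZ curves
from Po_spont to Po_spont * r_dz_ptx (rejected if that exceeds 1). The
standard sharing scheme fits per-construct L, shared K_G, K_D and c, one d
shared between the L9'T background and wild type, and a separate d for
constructs carrying V279A. The single mutant V279A in the wild-type
background is never fitted: its L follows from the independence assumption
L_V279A = L_WT * (L_L9'T/V279A / L_L9'T), and its responses are treated as
model predictions. GABA-only ("front face") scheme variants — all
constructs sharing K_G and c; L pinned from unliganded Po with per-construct
K_G; fully free per-construct affinities — are configurations of the same
fitter (`front_face_scheme`).

L_WT can alternatively be tied to the EC50 relation
L_WT = L_L9'T (EC50_WT / EC50_L9'T)^2 via `wt_L_from_ec50`. Note the two
routes disagree numerically (the relation applied to the pooled EC50
estimates gives ~22600, while the global fit settles near 18000); the
package defaults to fitting L_WT freely and exposes the tie as an option,
asserting neither value as canonical.

Optimization is bounded least squares (scipy `least_squares`, trf) on
log10-transformed parameters, from a moment-style initial guess read off
the curves (L from the spontaneous level, c/d from the asymptote, K from
the half-activation point inverted through the single-site occupancy
ratio) plus seeded Latin-hypercube multi-starts (+/-1.5 decades around the
guess, clipped to bounds; default 8 starts). Residuals are unweighted Po
differences on 40 log-spaced concentrations per curve. A condition-number
diagnostic and a free-parameters-versus-curves check warn on
non-identifiable schemes.

## Synthetic data: what it emulates, and what it does not

The generator emulates the recording conditions: 10 s pulses separated by
washout, PTX bookends, spontaneous PTX-blockable current, ligand-evoked
peaks governed by an MWC (or, alternatively, an exact Hill-curve) ground
truth, linear baseline drift, linear amplitude rundown between the first
and last pulse onsets, additive Gaussian noise, and log-normal per-oocyte
amplitude variability. Defaults: amplitude 500 nA per unit Po, CV 0.3,
noise 2 nA (realistic for hundreds-of-nA TEVC signals), drift ~ N(0,
0.02 nA/s), rundown 15% +/- 50% jitter, rise tau 0.5 s, decay tau 2 s,
washout 60 s, 100 Hz sampling. Washout and sampling are compressed
relative to a real session; the kinetics are phenomenological
(mono-exponential with optional slow desensitization), since pulse
waveforms are a free synthetic choice not constrained by the analysis.

Not emulated: stochastic single-channel gating and channel-number noise,
receptor desensitization kinetics beyond the optional mono-exponential
term, solution-exchange artifacts, series-resistance and capacitance
effects, and the secondary low-affinity inhibitory DZ site (high-DZ
response suppression is handled only by concentration exclusion lists, as
in the analysis itself). Passing tests therefore establish that the
estimators are unbiased and accurate under the stated corruption model,
not that they are robust to every artifact of real recordings.

Determinism: a master seed is fanned out through `numpy` `SeedSequence`
children, one per oocyte (stored in the manifest, < 2^31), so identical
(config, seed) pairs reproduce cohorts bit-for-bit, and a
"corruption-free twin" (same seeds, drift and rundown off, identical noise
realization) serves as the oracle for normalization tests.

## Numerical choices

- **Peak amplitude.** The response location and sign come from the signed
  extremum of the smoothed trace, but the default amplitude is the mean
  current over the final second of the drug application. For responses
  that reach their mono-exponential plateau well within the pulse the two
  agree noiselessly; under noise, an extremum estimator is biased upward
  by selecting the largest noise excursion, which inflates small responses
  and systematically shifts fitted EC50s low (measured: about -0.2 in log
  EC50 at 5% noise versus +0.014 for the plateau mean). The pure extremum
  value remains available via `peak_avg=0` (appropriate for strongly
  desensitizing responses, where the plateau underestimates the peak).
- **Baseline anchors** sit at each pre-pulse window's center of mass, so a
  linear drift is reproduced exactly by the piecewise-linear interpolant
  (linearly extrapolated at the trace ends).
- **Rundown** is corrected by a least-squares line through the PTX peak
  magnitudes versus time, normalized to 1 at the first PTX peak; a line
  crossing zero inside the recorded span is rejected as pathological, and
  the pipeline falls back to uncorrected peaks for oocytes without
  measurable PTX-sensitive current (wild type). With two PTX bookends the
  corrected bookend amplitudes agree exactly; with more, a configurable
  mismatch tolerance warns.
- **Pooling.** Each oocyte is normalized by its measured response at its
  top retained concentration; I_max stays free in the pooled fit because
  the top concentration is not exactly saturating (fixing I_max = 1 biases
  EC50 low even without noise). Points are weighted equally by default,
  with an oocytes-equally option, since the original pooling weights are
  not derivable from the analysis description.
- **Per-oocyte ddG pairing.** GABA- and DZ-series recordings come from
  different oocytes, so per-oocyte ddG values pair each DZ oocyte's ratio
  with its construct's mean GABA ratio by default; a fully per-oocyte
  scheme is available for data sets where both series exist per oocyte.
- **Saturating GABA** is the analytic limit of the closed form, never a
  large finite number. Measured "maximal" ratios, by contrast, are taken at
  the top applied concentration, and simulation tests compare them to
  ground-truth Po evaluated at that same concentration — the quantity the
  statistic estimates (for slowly saturating DZ responses the analytic
  asymptote is about 1% higher than any applied concentration reaches).
- **Degenerate inputs** are rejected with named errors: overlapping pulses,
  baseline windows touching a pulse, <2 PTX peaks, all-equal responses
  (non-identifiable Hill fit), ratios implying Po outside (0, 1), and
  probabilities outside the open interval in the energy map.

## Problem sizes used by the test suite

Deterministic checks run on the tabulated construct-level inputs.
Stochastic studies use: 50 cohorts of 5 oocytes (5% noise) for Hill EC50
recovery; 20 seeds of 5-curve sets (5% multiplicative Po noise, 4
multi-starts) for MWC parameter recovery; 2 constructs x 2 ligand series x
2 oocytes (20% rundown, drift, 2 nA noise) for the normalization-fidelity
check; the demo pipeline runs 5 constructs at 2-3 oocytes per series.
These sizes give stable medians while keeping the whole suite fast.

## Known limitations

- The two-state linkage analysis inherits the Po-GABA-max assumption; the
  sensitivity table quantifies (and the data largely discount) its impact
  on ddG_DZ, but absolute dG0/dG1 values shift with it.
- The MWC scheme has no desensitized or intermediate (flip/preactivation)
  states and no kinetic content; it describes pseudo-steady-state peak
  responses only, and is known to misestimate DZ potentiation of
  subsaturating versus saturating GABA responses in the wild-type
  background.
- Efficiency values depend on the molar unit convention of the logarithms.
- The rundown model (linear in time) matches the correction applied; real
  rundown need not be linear, in which case bookend agreement masks
  mid-recording error.
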