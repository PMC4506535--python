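# Methods

This note documents the models behind `flcs2d`, the synthetic-data
generator, the numerical choices, and what the tests do and do not show
about real measurements.

## The measurement model

A confocal TCSPC measurement records, per photon, a macrotime `T` (absolute
arrival time, seconds) and a microtime `t` (delay after the excitation
pulse, nanoseconds), plus the detector id. Fluorescence is split 50/50
between two detectors, and all correlators pair photons strictly across the
two channels; detector afterpulsing is uncorrelated between detectors, so
cross-pairing removes it by construction (and it is therefore not
simulated).

Conformational states of the molecule are encoded in the donor fluorescence
lifetime through FRET: `E = 1 − τ_DA/τ_D` and `r = R0 [(1−E)/E]^{1/6}`
with `R0 = 41 Å` and `τ_D = 4.0 ns` for the Alexa546/haem pair the fixtures
emulate. A quenched state has both a short lifetime and a proportionally
reduced brightness (equal extinction assumed), hence the generator sets
state brightness `q_P ∝ τ_P`.

## Synthetic photon streams

The generator is a Brownian-dynamics simulation, not a draw from the
closed-form correlation models — the models fitted downstream are never
injected, which makes parameter-recovery tests genuine cross-checks.

* Molecules diffuse in a periodic box around a 3D-Gaussian detection
  profile `W(r) = exp(−2(x²+y²)/w_r² − 2z²/w_z²)` with radial-axial ratio
  `w = w_r/w_z`. Lengths are expressed in units of `w_r`; the diffusion
  coefficient is `D = w_r²/(4 τ_diff)`.
* The conformational state is a continuous-time Markov chain built from the
  scheme's exchange pairs: each pair contributes rates
  `k_ab + k_ba = 1/τ_PQ` with `k_ab/k_ba = K_PQ` (detailed balance against
  the declared populations is validated). State dynamics are propagated by
  exact stochastic jumps inside each diffusion step, so only diffusion
  constrains the integration step (`dt = τ_diff/100` by default; the
  acceptance-scale runs use `τ_diff/50`, which still samples a transit ~50
  times). This replaces a fixed-step discretization of the exchange
  kinetics — the jump propagation is exact at any rate.
* Emission is an inhomogeneous Poisson process with rate `q_P · W(r)`;
  microtimes are drawn as `t0 + Exp(τ_P) + N(0, σ_IRF)` (Gaussian IRF,
  FWHM 50 ps, offset `t0 = 0.25 ns`) and redrawn until they fall inside the
  9.5 ns TCSPC window (truncation, not wrap-around). Dark states have
  `q_P = 0` and emit nothing — at the data level this is indistinguishable
  from a lifetime far below the instrument response.
* Far from the focus the detection weight is zero, so molecules outside a
  4 `w_r` lateral margin are stepped with a 16–64× coarser step (exact for
  free diffusion; state transitions over a coarse interval are sampled from
  the matrix exponential of the rate matrix). This makes wide boxes
  affordable.

**Finite-box physics.** A periodic box replaces the infinite reservoir of a
real sample. Its discrete slow diffusion modes leave a small spurious
correlation plateau at long lags, with amplitude roughly ∝ `w_r²/(L_x L_y)`
and decay set by axial diffusion across the box. With the default lateral
box of 6 `w_r` the plateau is ≈3% of the correlation amplitude — harmless
for microsecond-scale exchange observables, but fatal for the radial-axial
ratio `w`, whose signature is a ~20% bend of the correlation tail at
`ΔT ≈ τ_diff/w²`. Analyses of the deep diffusion tail therefore use a
28 `w_r` lateral box (plateau ≲0.3%). This is the one place where the
simulation geometry must be chosen per observable; both the fixture `w` and
the recovered values are documented in the tests.

**Fixture conditions.** The fixtures encode the cytochrome-c-like system:
lifetimes {70 ps, 280 ps, 300 ps, 1.7 ns, 3.3 ns, two dark}, pair
equilibration times {5, ~0.3 (sub-μs pair), 7, 4} μs, `K = 0.25` for the
native pair, `w = 0.078`. Values never printed by a real experiment were
fixed once as package defaults: diffusion time 0.5 ms (plausible for a
small labelled protein; treated as a free parameter by every fit),
ensemble fractions 0.40/0.35/0.25 for the native/intermediate/unfolded
ensembles, dark-state shares `[D]/[bright] = 0.5` within the intermediate
and unfolded ensembles, and a 0.3 μs time for the sub-microsecond pair
(the data only bound it from above). The dark state of the intermediate
ensemble hangs off the 1.7 ns substate with its edge rate chosen so that
the effective ensemble↔dark relaxation is exactly 7 μs under fast
pre-equilibration of the 300 ps/1.7 ns pair. Brightnesses are scaled so
that traces of ~0.5–4 minutes carry the photon counts the statistics need
(tens of kHz detected rate); real measurements integrate longer at lower
rates, which changes nothing in the analysis chain. Mean focal occupancy
defaults to 1 molecule.

## Correlators and 2D maps

`G_I` counts cross-channel photon pairs whose macrotime difference falls in
a lag window `[ΔT, ΔT+ΔΔT)`, normalized by the Poisson expectation
`2 n₁ n₂ ΔΔT/T₀` (with an end-of-trace availability factor), so an
uncorrelated stream gives 1. Curves are stored as the fluctuation part
`G − 1`. `G_L` weights each pair by the product of its microtimes and is
normalized by the channel-mean microtimes, so a homogeneous sample gives
`G_L = G_I`; the ratio `G_R = G_L/G_I > 1` flags lifetime heterogeneity.
Errors are delete-one jackknife over 32 macrotime segments.

2D emission-delay maps histogram the microtime pair (earlier, later) of
cross-channel pairs in a lag window, both orders (symmetrized). The
uncorrelated part is the same histogram at ΔT = 100–300 ms, where
correlation has decayed; it is scaled by the ratio of Poisson pair
expectations — equivalently of temporal window sizes — and subtracted.
(Scaling by *observed* pair counts would force the subtracted map to sum to
zero and bias amplitudes; it remains available as an option, as does an
outer-product-of-marginals background.) Wide background windows are
subsampled to ≤2×10⁷ pairs via a stride on the earlier photon. Per-bin
variances are estimated from the scatter across 16 macrotime blocks,
floored at the Poisson value: pair counts in single-molecule data are
strongly super-Poissonian (burst noise), and Poisson weights would make the
inversion chase noise in the brightest map regions.

Microtime rebinning conserves counts exactly: 4096 channels (3 ps) → 256
(48 ps) uniformly, then 24 logarithmically widening bins over 0–6.144 ns
for the inversion (bin widths snapped to the 48 ps grid and sorted so they
widen monotonically).

## Maximum-entropy inversion

The decay basis is `exp(−t/τ_k)` convolved with the Gaussian IRF
(exponentially-modified-Gaussian closed form, bin-integrated by Simpson's
rule) on a 40-point log-spaced lifetime grid over 0.05–10 ns. Model decays
are convolved with the IRF rather than deconvolving the data — with 70 ps
lifetimes against a 50 ps IRF the convolution is not optional.

1D: minimize `Q = χ²/2 − ηS` with Skilling entropy
`S = Σ (a − m − a ln(a/m))` relative to a prior `m(τ)`; nonnegativity by
exponential reparameterization, L-BFGS-B with analytic gradients,
warm-started from the sharp nonnegative-least-squares solution. The
regularization constant follows the classical discrepancy rule (χ² ≈ number
of bins) unless fixed explicitly — for noiseless synthetic decays a small
fixed η is appropriate, since the discrepancy rule assumes Poisson noise.

2D: the model map is `Σ_ij C_ij I_i(t′) I_j(t″)` with species decays
`I_i = Σ_k a_i(τ_k) E_k` and a symmetric nonnegative amplitude matrix `C`
(a signed mode is not offered; single-molecule correlation amplitudes are
nonnegative). Optimization is L-BFGS-B over `log a` and `log C` with
analytic gradients, a uniform-weight warm-up stage (the raw Poisson-weight
landscape defeats the initial line search), and multi-start: prior-centred
jitter alternating with starts that localize each species on a block of the
lifetime grid. The discrepancy target counts only upper-triangle bins
(the map is symmetrized) minus fitted parameters, floored at 1.25× the
unregularized misfit in case the variance model is conservative. The prior
is the 1D inversion of the ensemble decay, which contains every correlated
lifetime component.

**Rotational ambiguity.** A species decomposition is only defined up to
nonnegative mixing of the distributions (with `C` transformed
accordingly), and the entropy bias toward the common prior tends to leave a
little of each species in the others. Quantities that feed kinetics are
therefore computed rotation-invariantly where possible (peak volumes of the
*total* lifetime-correlation surface), and the basis used for
species-correlation extraction is purified to its extreme rays: the largest
multiple of every other distribution that keeps a distribution nonnegative
is subtracted. For a two-state system this is the standard uniqueness
condition of nonnegative factorization.

**Species counting** follows the redundancy protocol: decompose for
n = 2…5 and declare n−1 sufficient at the first n where a species repeats
another's lifetime pattern (cosine similarity ≥ 0.98 — the operational
form of "identical peak pattern") or carries <1% of the model amplitude
(an empty species is as redundant as a duplicated one). The outcome is
inherently relative to the data's noise level, in both directions: with
enough photons the inversion starts resolving *incompletely* equilibrated
pairs (a few percent of residual distinctness), while with too few a
genuinely present but dim species (a few percent of the photons, sitting on
the burst noise of the brightest state) is not statistically demanded and
the inversion parks it at zero amplitude. At the packaged trace lengths the
merged count beyond the exchange time is recovered robustly; the full
species count at the shortest lag requires experiment-scale pair statistics
(an order of magnitude beyond what the packaged runs simulate), and the
corresponding test documents this as an open gap rather than masking it.

## Species-resolved correlations and kinetic fits

With the distributions fixed at a reference lag (0.2–4 μs by default), each
lag window refits only `C` by weighted nonnegative least squares. The
uncorrelated background map, decomposed in the same basis, yields the
photon-fraction products `β_iβ_j`; dividing the foreground amplitudes by
them converts to fluctuation correlations `G_ij(ΔT)` on the model scale,
independent of species brightness. Errors come from the Gaussian
covariance of the refit.

The two-state fit holds `K` and `w` fixed (`K` from the diagonal
peak-volume ratio of the shortest-lag decomposition, corrected for the
finite-window exchange factor `⟨e^{−ΔT/τ_R}⟩` in one iteration with the
fitted `τ_R`; `w` from the reference-dye fit) and adjusts `N`, `τ_R`,
`τ_diff` by Levenberg–Marquardt on log-parameters, jointly over `G_AA`,
`G_BB`, `G_AB`. The two-state forms satisfy
`f_A²G_AA + f_B²G_BB + 2f_Af_BG_AB = g_D/N` identically — a property test
holds this to machine precision. Bright/dark blinking is fitted with
`(g_D/N)(1 + A e^{−ΔT/τ_R})`, with diffusion-only as the null model; the
comparison is an F-test at α = 0.01 (the diffusion-only candidate is fitted
over 10 μs–1 ms, where diffusion dominates, and evaluated over the full
lag range). Full-scheme total correlations treat the scheme as disjoint
two-state systems sharing one diffusion time; lifetime weighting replaces
`q_P` by `τ_P q_P`. Effective lifetimes and brightnesses of
window-truncated decays use the closed-form truncated-exponential moments
(with an expm1 series in the uniform limit).

## Problem sizes

The packaged analyses run on one CPU: the two-state recovery uses a 30 s
trace (~1.2×10⁶ photons) in the tests and a 76 s trace (~3×10⁶) in the
acceptance script; the reference-dye geometry fit uses a 240 s wide-box
trace (~8×10⁶ photons) — the radial-axial ratio is the noisiest recovery
(≈12% standard error at this size) because its signature sits on the
weakest part of the correlation decay; the bright/dark recovery uses 22 s
(~2×10⁶ photons); species counting uses a 150 s trace (~2×10⁷ photons),
the smallest size at which the four-species structure at short lags is
statistically demanded. Real experiments integrate one to two orders of
magnitude more photon pairs.

## Known limitations

* No triplet/photophysical blinking beyond explicit dark states, no
  polarization, no pulsed interleaved excitation, no vendor TTTR formats.
* The periodic simulation box leaves a small long-lag correlation plateau
  (see above); wide-box geometry is required for axial-shape observables.
* Map-bin variances are estimated from 16 blocks and rebinned by summation,
  which ignores within-block covariance between bins.
* The species-number criterion is noise-level-relative (discussed above).
* A stretched-exponential relaxation variant for the blinking term is out
  of scope; the exponential form is used throughout.
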