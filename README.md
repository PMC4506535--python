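# flcs2d — two-dimensional fluorescence lifetime correlation spectroscopy

`flcs2d` implements 2D fluorescence lifetime correlation spectroscopy
(2D FLCS) as a tested, reusable Python package. 2D FLCS resolves
microsecond conformational dynamics of single molecules — for example the
folding substates of a FRET-labelled protein diffusing through a confocal
volume — from nothing but the photon record of a time-correlated
single-photon-counting (TCSPC) measurement: for each photon a macrotime
`T` (absolute arrival time) and a microtime `t` (delay after the excitation
pulse) are recorded. The package is aimed at single-molecule
spectroscopists and method developers who want a transparent, end-to-end
reference implementation with simulated ground truth for every stage.

## What it does

1. **Simulate** (`flcs2d.simulate`): Brownian-dynamics photon streams for
   multi-state molecules. Molecules diffuse through a 3D-Gaussian detection
   profile in a periodic box, carry continuous-time Markov conformational
   states (exact jump propagation), and emit photons whose microtimes follow
   the state's fluorescence lifetime convolved with a Gaussian instrument
   response. Built-in fixtures emulate an acid-destabilized cytochrome *c*
   system: substates with lifetimes 70 ps, 280 ps, 300 ps, 1.7 ns and 3.3 ns,
   dark (quenched) states, pairwise equilibration times of 5, 7, 4 and
   ~0.3 μs, equilibrium constant K = 0.25 for the native pair and focal
   radial-axial ratio w = 0.078.
2. **Correlate** (`flcs2d.correlate`): cross-detector intensity and
   lifetime-weighted correlation functions G_I, G_L and their ratio G_R,
   plus lag-windowed 2D emission-delay correlation maps M(ΔT; t′, t″) with
   uncorrelated-background subtraction (scaled by temporal window size) and
   exact-count logarithmic microtime rebinning (256 → 24 channels over
   0–6.14 ns).
3. **Invert** (`flcs2d.ilt`): maximum-entropy inverse Laplace transforms.
   1D: decay I(t) → lifetime distribution α(τ) on a 40-point log grid over
   0.05–10 ns. 2D: a background-subtracted map → n species distributions
   a_i(τ) and a symmetric correlation-amplitude matrix C, minimizing
   Q = χ²/2 − ηS with Skilling entropy S relative to the ensemble-decay
   prior; includes species-number selection by the redundancy of the
   recovered distributions.
4. **Fit** (`flcs2d.kinetics`): species-resolved correlation curves
   G_ij(ΔT) extracted across a lag ladder and fitted with confocal
   diffusion + two-state exchange models

   ```
   g_D(ΔT)  = (1 + ΔT/τ_diff)⁻¹ (1 + w²ΔT/τ_diff)^(−1/2)
   G_AA     = g_D/N (1 + K e^{−ΔT/τ_R}),   G_BB = g_D/N (1 + K⁻¹ e^{−ΔT/τ_R})
   G_AB     = g_D/N (1 − e^{−ΔT/τ_R})
   ```

   plus diffusion-only and diffusion+relaxation autocorrelation models,
   full-scheme total correlations, FRET distance conversion
   (E = 1 − τ_DA/τ_D, r = R0[(1−E)/E]^{1/6}), global decay fitting with
   fixed lifetimes and truncated-decay effective lifetime/brightness.
5. **Orchestrate** (`flcs2d.pipeline`, `flcs2d` CLI): configuration-driven
   runs (simulate → correlate → invert → fit → report) with checkpointing
   keyed by the configuration hash, TSV/HDF5 photon formats (Photon-HDF5
   field naming) and JSON reports.

## Worked example

```python
import flcs2d as F

# two-state system: 70/280 ps lifetimes, 5 us exchange, K = 0.25
scheme = F.fixture_scheme("scheme1")
stream = F.simulate_stream(scheme, duration=30.0, seed=5, dt=1e-5)
print(len(stream), "photons")                     # 1166005 photons

res = F.two_state_analysis(stream, w=0.078, seed=1)
fit = res["fit"]
print(f"tau_R = {fit.tau_R_us:.2f} us")           # tau_R = 5.31 us
print(f"K     = {res['K']:.3f}")                  # K     = 0.213
print(f"N     = {fit.N_pair:.2f}")                # N     = 1.04
```

The pipeline histogrammed photon pairs into 2D emission-delay maps over a
log-spaced ΔT ladder, subtracted the uncorrelated background (ΔT =
100–300 ms), decomposed the shortest-lag map into two lifetime
distributions peaking at ~70 ps and ~280 ps, refit their amplitudes at each
lag, and fit the two-state model: the recovered equilibration time (5.31 μs
vs the 5 μs ground truth) and equilibrium constant (0.213 vs 0.25, from the
diagonal peak-volume ratio of the shortest-lag lifetime-correlation
surface) characterize the hidden exchange between the two conformers —
dynamics far below the diffusion time and invisible in the plain intensity
correlation.

The same workflow is available from the shell:

```
flcs2d simulate --scheme scheme1 --duration 30 --seed 5 -o photons.h5
flcs2d correlate photons.h5 -o corr
flcs2d ilt2d photons.h5 --n auto -o decomposition.json
flcs2d run --scheme scheme1 --duration 30 --seed 5 --output-dir run1
```

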