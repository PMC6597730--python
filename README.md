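# micromotor

MSD analysis and active-Brownian-particle simulation for enzyme-powered
micromotors.

Catalytic microswimmers — micron-sized particles functionalized with an
enzyme such as urease — convert chemical substrate into self-propulsion.
The standard way to quantify that motion from optical-microscopy videos is
single-particle tracking followed by mean-squared-displacement (MSD)
analysis. This package implements that chain end to end for researchers
analyzing (or simulating) such experiments:

- **Physics**: Stokes–Einstein translational and rotational diffusion of a
  sphere, `D_t = k_B T / (6πηr)` and `D_r = k_B T / (8πηr³)`, and the
  rotational diffusion time `τ_r = 1/D_r` that bounds the propulsive
  fitting window.
- **MSD inference**: overlapping time-averaged MSD per trajectory,
  ensemble mean ± s.e.m. across particles, and the propulsive-regime fit
  `MSD(t) = 4 D_t t + v² t²` (valid for `t ≪ τ_r`) yielding the propulsion
  speed `v` and diffusion coefficient `D_t` with standard errors.
- **Synthetic data**: an Euler–Maruyama active-Brownian-particle (ABP)
  simulator whose exact ensemble MSD is
  `4 D_t t + (2v²/D_r²)(D_r t + e^{−D_r t} − 1)`, with optional
  localization noise and rendering into microscopy-like multi-page TIFF
  stacks (Gaussian PSF spots, Poisson/read noise).
- **Tracking**: sub-pixel spot detection (intensity-weighted centroid) and
  globally optimal nearest-neighbour linking with gap bridging.
- **Kinetics-coupled sweeps**: ground-truth speeds driven by a
  Michaelis–Menten rate law with competitive and substrate inhibition,
  `rate = S / (K_m(1 + I/K_i) + S(1 + S/K_s))`, speed linear in rate, so
  dose–response curves, inhibitor titrations, and speed–activity
  correlations can be replicated fully in silico.

## Worked example

Analyze a simulated 20-particle condition at the default thermal
parameters (1.00 µm-radius sphere, 24 °C, water-like viscosity
0.9107×10⁻³ kg m⁻¹ s⁻¹):

```python
import micromotor as mm

tp = mm.ThermalParams()          # 1.00 um sphere, 24 degC, water-like
rot = mm.RotationalScale.from_thermal(tp)
d_t = mm.translational_diffusion(tp)
print(f"D_t = {d_t:.3f} um^2/s, D_r = {rot.d_r:.4f} 1/s, tau_r = {rot.tau_r:.3f} s")

trajs = mm.simulate_ensemble(20, v=2.07, d_t=d_t, d_r=rot.d_r,
                             fps=25, duration=30, seed=42)
curves = [mm.compute_msd(tr, max_lag=1.5) for tr in trajs]
fits = [mm.fit_propulsive(c, rot.tau_r, window_frac=0.2) for c in curves]
mean_v, sem_v = mm.speed_summary(fits)
print(f"fitted speed: {mean_v:.2f} +/- {sem_v:.2f} um/s (true 2.07)")
```

prints

```
D_t = 0.239 um^2/s, D_r = 0.1792 1/s, tau_r = 5.579 s
fitted speed: 2.00 +/- 0.03 um/s (true 2.07)
```

`D_t`, `D_r` and `τ_r` are the Stokes–Einstein values for this sphere; the
fitted ensemble speed sits ~4% below truth, the documented bias of the
truncated-parabola fit at window 0.2·τ_r (see `docs/methods.md`).

The same chain is available from the shell:

```sh
micromotor simulate --n-particles 20 --speed 2.07 --seed 42 --out tracks.csv
micromotor msd --tracks tracks.csv --radius-um 1.0 --temp-c 24 --out results/
micromotor render --tracks tracks.csv --out movie.tif    # synthetic video
micromotor track --stack movie.tif --out retracked.csv   # detect + link
micromotor sweep --config sweep.yaml --out sweep_out/    # full dose-response
```

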