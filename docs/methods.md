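# Methods

## Scope and model

`micromotor` implements the standard motion-analysis chain for enzyme-powered
catalytic microswimmers observed by optical microscopy, together with a
synthetic-data generator so the whole chain can be exercised and validated
without experimental videos.

The physical picture: a micron-sized sphere functionalized with enzyme
converts substrate to product asymmetrically, producing a propulsion speed
`v` along a body-fixed heading. The heading decorrelates by rotational
Brownian motion with coefficient `D_r`, on top of ordinary translational
diffusion `D_t`. This is the active Brownian particle (ABP) model. Its
exact 2-D ensemble mean-squared displacement is

    MSD(t) = 4 D_t t + (2 v^2 / D_r^2) (D_r t + e^{-D_r t} - 1),

which reduces to the propulsive parabola `4 D_t t + v^2 t^2` for lag times
`t << tau_r = 1/D_r`. Inference proceeds the way the field does it:
time-averaged MSD per trajectory, ensemble mean ± s.e.m. across particles,
and an ordinary least-squares fit of the parabola over a short lag window
to extract `v` and `D_t`. `D_r` and `tau_r` are not fitted; they come from
the Stokes-Einstein relations

    D_t = k_B T / (6 pi eta r),    D_r = k_B T / (8 pi eta r^3).

At the package defaults — radius 1.00 um, 24 degC (297.15 K), viscosity
0.9107e-3 kg m^-1 s^-1 — these give `D_t = 0.239 um^2/s`,
`D_r = 0.1792 s^-1`, `tau_r = 5.579 s`.

## MSD estimator

For a uniformly sampled trajectory of N frames at interval dt, the
estimator at lag k·dt averages the squared displacement over all N−k
overlapping start frames, summing the two spatial coordinates. Overlapping
windows are the field standard and maximize data use; the semantics are
pinned down by an O(N²) brute-force pairwise oracle in the test suite that
the production estimator must match bit-for-bit. Non-uniform timestamps are
rejected with the offending gap named; trajectories need at least two
samples.

Localization error of s.d. sigma adds a constant `4 sigma^2` plateau to the
MSD (E|n1−n2|² for i.i.d. 2-D Gaussian noise); the generator exposes this
and the tests verify the plateau by Monte Carlo.

## Propulsive fit

The fit regresses MSD on the no-intercept design {4t, t²}; the coefficients
are `D_t` and `v²`. Standard errors come from the linear fit; `se(v)` by the
delta method `se(v²)/(2v)`. Choices that matter:

- **Window**: default `window_frac = 0.2`, i.e. lags ≤ 0.2·tau_r (≈1.1 s at
  defaults, 27 lags at 25 FPS). Against the exact ABP curve this truncated
  parabola carries a deterministic bias of −4.2% on `v` (the next term of
  the expansion is negative); shortening the window reduces bias but
  inflates variance sharply. The window is configurable and the bias is
  quantified below.
- **Negative v²**: purely Brownian or sub-diffusive data can fit a negative
  quadratic coefficient. This maps to `v = 0` with a non-propulsive flag
  rather than an error — control conditions must yield speeds, not crashes.
- **Per-particle vs ensemble-first**: the default pipeline fits each
  particle's MSD and averages speeds (mean ± s.e.m.), matching how
  per-condition speeds are usually reported. Because `v = sqrt(max(v̂², 0))`
  is concave and clipped, this mode acquires a negative bias at low
  signal-to-noise. The ensemble-first mode (fit the ensemble-mean MSD;
  algebraically equivalent to `sqrt(mean v̂²)`) avoids the clipping bias and
  is what the recovery measurements use. Both are exposed
  (`fit_mode = "per_particle" | "ensemble"`).
- **Weighting**: unweighted OLS by default (transparent); weighting by pair
  count is available behind a flag and makes little difference because pair
  counts are nearly constant over the short window.
- **Ensemble propulsion flag**: a condition is called propulsive by a
  one-sided one-sample t-test (alpha = 0.05) on the per-particle v̂² values,
  which are independent across particles and unbiased under the Brownian
  null; the measured false-positive rate is ≈5%.

### Estimator resolution at study scale

Parameter-recovery simulations at the reference design (20 particles, 30 s
at 25 FPS) show: at `v = 2.07 um/s` the ensemble estimate lands within 10%
of truth in ~100% of replicates (median bias ≈ −4%, the window bias). At
`v = 0.43 um/s` the propulsive term contributes at most ~15% of the MSD
inside the window; the replicate-level scatter of the ensemble estimate is
~10% of `v` on top of the −4% window bias, so only ~60% of replicates land
within 10%. This is a fundamental resolution limit of the parabola fit at
this design size, not an implementation artifact: even an unbiased
estimator with 10% scatter would pass a ±10% band only ~68% of the time.
`D_t` is recovered well at low speeds (the linear term dominates) and is
weakly identified when the v² term dominates.

## Synthetic-data generator

Euler-Maruyama integration of the ABP Langevin equations with
`substeps = 10` internal steps per frame (internal step 4 ms at 25 FPS),
initial headings uniform on [0, 2pi). Defaults mirror the reference
acquisition: 25 FPS, 30 s, 20 particles per condition. The integrator is
validated against the closed-form MSD (500-trajectory ensembles agree
within 3 s.e.m. at every lag to 5 s), against the Brownian and ballistic
limits exactly, and for weak convergence under substep refinement.

What the generator emulates: isotropic ABP motion, localization noise
(default sigma 0.03 um — an assumption; the reference setup's pixel size
and localization precision are not public), and microscopy-like rendering
(Gaussian PSF spots, sigma 0.2 um, on constant background, optional Poisson
and read noise, 16-bit frames at 0.1 um/px — also stated as assumptions).
What it does not emulate: inter-particle interactions, walls, drift
(optional constant drift exists for robustness testing), hydrodynamic or
phoretic fields, 3-D motion, photobleaching. Passing tests therefore show
the inference chain is correct for ideal ABP data; they do not certify
behaviour under crowding, flow, or focus drift in real videos.

## Kinetics coupling

The generator's ground-truth speed is driven by a relative catalytic rate

    rate(S, I) = S / ( K_m (1 + I/K_i) + S (1 + S/K_s) ),

the textbook Michaelis-Menten law with competitive inhibition (inhibitor
raises apparent K_m) and substrate inhibition (S²/K_s term, disabled when
K_s = inf), and `speed = coupling × rate` — linearity between speed and
activity being the empirical observation the generator encodes. The
simulated activity readout is the rate plus multiplicative Gaussian noise
(default CV 5%), standing in for a colorimetric assay.

Preset constants (urease-like: K_m = 30 mM, K_i = 3 mM, K_s = 400 mM,
coupling 2.07 um/s; acetylcholinesterase-like: K_m = 0.05 mM, K_s = 0.2 mM,
coupling 0.86 um/s) are illustrative, not fitted to any experimental curve;
they are chosen to reproduce qualitative shapes only: a rate peak at
`sqrt(K_m K_s)` (≈110 mM and 0.1 mM respectively) and saturating speeds of
2.07 and 0.43 um/s.

One consequence of the competitive form deserves note: at excess substrate
(S >> K_m) competitive inhibition is substrate-rescued — at S = 500 mM and
I = 2·K_i the rate drops only ~5%. A large inhibition drop at excess
substrate would require a non-competitive (e.g. conformational-rigidity)
term that this rate law deliberately does not include. The package
therefore demonstrates the >50% drop at I = 2·K_i in the
inhibitor-sensitive regime (S ≤ K_m; ~60% at S = 10 mM, limiting 66.7% as
S → 0). Whether a high-substrate speed decline reflects viscosity or
substrate inhibition is left open: K_s models the latter, and the sweep
config exposes a viscosity-vs-substrate slope (effective viscosity
`eta (1 + slope · S)`) for the former; both default off/neutral.

## Tracking

Detection: per-frame local maxima above a threshold (default: halfway
between frame median and maximum), minimum separation enforced by keeping
the brighter of close peaks, then sub-pixel refinement by
background-subtracted intensity-weighted centroid over a window of radius
3·psf_sigma. The centroid (rather than a Gaussian fit) is accurate to
~0.001 px on rendered noiseless spots — far inside the 0.05 px RMS budget —
because the clipped spot is symmetric about its centre and the window tails
carry negligible weight.

Linking: per frame pair, a globally optimal minimum-total-displacement
bipartite assignment (Hungarian algorithm) restricted to pairs within
`max_disp` per frame interval; unmatched detections open tracks; tracks
undetected for up to `memory` frames are bridged by persisting the last
position; fragments shorter than `min_track_length` are dropped.
Detections are canonically sorted before linking, so results are invariant
to input row order, and cost ties resolve deterministically toward the
lowest track id.

Default `max_disp = 0.7 um/frame`: the fastest reference speed contributes
0.08 um/frame and the diffusive step at `D_t = 0.239` and 25 FPS has radial
RMS 0.196 um, so 0.7 ≈ v_max/fps + 3×RMS step keeps the miss probability
per frame below 1e-5. (A gate much below ~0.5 um would sever ~10% of
purely diffusive links per frame at these parameters.) Default
`min_track_length = 250` frames (10 s) guarantees every analyzed track
supports MSD lags well past 2 s.

## Pipeline determinism and reporting

Per-condition seeds are `master_seed + crc32(label) mod 2^31`, so adding or
reordering conditions never changes another condition's result. Sweep
outputs (CSV/JSON) are stamped with the config hash (SHA-256 of the
canonical config serialization) and seed. A failed condition is logged and
reported in its row; the sweep continues (CLI exit codes: 0 ok, 1 some
conditions failed, 2 config error).

Speed-activity correlation is computed on condition means (speed from the
MSD fit, activity from the simulated assay) by OLS, reported as adjusted
R² = 1 − (1−R²)(n−1)/(n−2).

## Problem sizes

Validation and the reproduction script use: 500-trajectory ensembles for
simulator-vs-theory checks; 200 replicate 20-particle ensembles per speed
for recovery and null-calibration rates; 100 random trajectories (N ≤ 200)
for the estimator/oracle identity; a 4-particle, 8 s, 512×512 px scene for
the image path; 20-particle conditions for the dose-response and titration
sweeps. These sizes give Monte-Carlo error comfortably below the assertion
tolerances while keeping a full run in tens of seconds.

## Known limitations

- The parabola fit's window bias (−4.2% on v at window_frac 0.2) is
  inherent to fitting the short-time expansion; fitting the exact ABP form
  (linear in D_t and v² when D_r is known) would remove it, but the
  parabola is the method this package exists to implement.
- Low speeds (v ≲ 0.5 um/s at the default thermal parameters) are at the
  resolution limit of a 20-particle, 30 s design; see above.
- The tracker is a functional stand-in validated against synthetic ground
  truth only; no multi-hypothesis or Kalman linking, no 3-D.
- The kinetics module is generative plumbing: it produces qualitative
  dose-response shapes and is not intended for fitting experimental
  kinetic constants.
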