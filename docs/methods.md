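# Methods

## The model

`gatekmc` treats the pericellular hydrogel network as a sequence of
"gates": small ensembles of reversible host–guest crosslinks that block the
addition of one actin monomer at the tip of a filopodial filament. A gate
opens — and the filament can elongate by one monomer — when every blocking
crosslink has both dissociated and been displaced far enough that it cannot
re-form. The package quantifies how the opening statistics depend on the
crosslink chemistry's kinetic constants, and propagates the same kinetics to
two companion observables: bulk stress relaxation (a transient-network
model) and the image-derived statistics used to score cell behaviour
(circularity, nuclear/cytoplasmic intensity ratio, multicellularity).

### Bond kinetics

Each crosslink chemistry is a `HostGuestPair` with association rate k_on
(M⁻¹ s⁻¹), zero-force dissociation rate k_off⁰ (s⁻¹), and a Bell barrier
distance x‡ (nm). Under a tensile force F (pN) the dissociation rate is

    k_off(F) = k_off⁰ · exp(F · x‡ / k_B T),

with k_B T ≈ 4.28 pN·nm at the 310 K culture-condition default. Two
chemistries ship built in, with rate constants entered as round powers of
ten: the fast pair (CD–ADA; k_on = 10⁸, k_off⁰ = 10³, K_eq = 10⁵ M⁻¹) and
the slow pair (CD–CA; k_on = 10¹, k_off⁰ = 10⁻³, K_eq = 10⁴ M⁻¹). Detailed
balance K_eq = k_on/k_off⁰ holds exactly for both; user overrides are
checked against a supplied calorimetric K_eq within one order of magnitude
and warn rather than fail, since kinetic and thermodynamic constants come
from different experiments.

The barrier distance is not an experimentally tabulated number; the package
default x‡ = 0.01 nm is a deliberate modeling choice that keeps the fast
pair's lifetime 1/k_off(F) between 0.79 and 0.98 ms over the whole 10–102 pN
range of filopodium-scale forces — i.e. force-dependence is retained but
weak, and the fast bond remains a millisecond-scale bond under load. It is
configurable per pair for sensitivity analysis.

### Gate geometry and composition

A gate is n_units crosslinking units × valency bonds per unit; the default
4 × 2 = 8 bonds per gate. In a mixed gel a bond is fast with probability
p_fast, sampled i.i.d. per bond. The canonical mixture labels A80C20,
A50C50, A20C80 map to p_fast = 0.8, 0.5, 0.2 under the assumption that the
two guest polymers share the same backbone and degree of guest modification,
which makes molar fraction equal to weight fraction. A correlated mode
(identity drawn once per unit, shared by its valency bonds) is available
behind a flag for sensitivity analysis; it widens the composition
distribution without changing its mean.

### The stochastic gate-opening process

Each bond is a three-state continuous-time Markov chain:

- BOUND → UNBOUND at k_off(F/N_bound), the Bell rate under equal sharing of
  the applied force among the N_bound currently bound bonds (the standard
  motor-clutch load-sharing convention);
- UNBOUND → BOUND at k_on · c_local, a pseudo-first-order rebinding rate
  with c_local = 0.01 M by default (the order of the effective free-host
  concentration in a ~4% w/v gel); setting c_local = 0 disables rebinding;
- UNBOUND → ESCAPED at 2·D(F)/δ², the rate for a freed chain segment to
  diffuse beyond the capture distance δ = 1 nm, with force-assisted
  diffusion D(F) = D₀(1 + αF), defaults D₀ = 10⁶ nm²/s and α = 0.01 pN⁻¹.
  ESCAPED is absorbing; an infinite D₀ is accepted and means displacement is
  instantaneous (bonds skip the UNBOUND state).

The gate is open when all bonds are ESCAPED — dissociation alone is not
enough, because an unbound-but-nearby pair can re-close. Simulation is an
exact Gillespie algorithm: exponential waiting times, no time
discretization, all rates recomputed after every event (load sharing makes
bound-bond rates depend on the global bound count). Because bonds of equal
identity and state are exchangeable, the implementation propagates the six
state counts rather than per-bond labels; this is an exact reformulation
and is verified against a brute-force master-equation integration
(`master_equation_oracle`, dense CTMC over all 3^N per-bond state
combinations, Radau integration, guarded to N ≤ 4).

The headline statistic is the opening probability within a window
t_window = 0.01 s — the timescale of adding one actin monomer — at
F = 10 pN, estimated over 10⁵ replicates with a fresh random gate
composition per replicate and a 95% Wilson score interval. Replicates that
have not opened by t_max are censored; censored replicates never enter the
mean opening time, and the probability estimate is invariant to t_max
beyond the window. The fixed-K_eq sweep varies k_off with k_on = K_eq·k_off
(the bond gets kinetically faster, not weaker) and reports the mean opening
time per grid point; its t_max defaults to 10³/k_off so censoring is
negligible across the grid.

Reproducibility: gate compositions come from a seeded NumPy generator, and
each replicate r draws its event sequence from an independent deterministic
substream keyed by (seed, r), so ensembles are bit-reproducible and
independent of evaluation order.

### Transient-network rheology

Each crosslink species contributes one Maxwell mode with relaxation time
τ = 1/k_off⁰ and weight proportional to its molar fraction, on top of an
optional permanent plateau (off by default — the package takes no position
on whether the measured frequency-independence of G′ reflects a permanent
contribution):

    G(t) = G_p + Σ G_i exp(−t/τ_i),
    G′(ω) = G_p + Σ G_i ω²τ_i²/(1+ω²τ_i²),   G″(ω) = Σ G_i ωτ_i/(1+ω²τ_i²).

This two-mode model is intentionally minimal — no sticky-Rouse spectrum, no
compression/shear distinction (curves are treated as normalized relaxation
functions) — and claims only trend reproduction: the half stress-relaxation
time decreases monotonically with the fast fraction, and a pure slow gel
shows a frequency-independent G′ with G″ ≪ G′ at the 0.1 Hz mechanosensing
frequency. It is not a quantitative fit to any rheometer trace.

`half_relaxation_time` interpolates the time at which a sampled curve falls
to half its initial value; for noisy curves an odd `smooth_window` switches
to a moving-average crossing search with G(0) estimated from the initial
plateau (larger of the window and the first tenth of samples). The curve
must be non-increasing up to a tolerance (default: rises above 10% of G(0)
raise). `fit_spectrum` recovers mode weights and times by least squares in
log-parameter space (positivity for free; times initialized at log-spaced
quantiles of the sampled range); non-convergence is flagged on the result,
never silent. On two equal modes separated by 10⁶ in time with 1% noise,
both times are recovered within a few percent (15% budget).

### Morphometrics

Circularity is C = 4πA/P² per labeled object, with A the pixel-count area
and P measured on the sub-pixel marching-squares contour of the object's
binary mask after a light Gaussian smoothing whose length scales with the
object's equivalent diameter (σ = max(1, d/60) px). The smoothing step
matters: on a hard 0/1 raster the 0.5-level contour keeps a staircase bias
of ~5% on disks (and pixel-edge counting is up to ~27% off), while the
smoothed contour measures a rasterized disk at C = 1.000 and is stable
under 2× resampling to better than 2%. The cost is a known, bounded bias on
sharp corners: an axis-aligned square reads ~3% above the analytic π/4, and
concave star tips are slightly rounded. Objects touching the image edge are
measured but flagged.

The nuclear/cytoplasmic ratio divides the mean intensity over a cell's
nucleus pixels by the mean over its cytoplasm (cell minus nuclei); the
statistic is configurable to integrated intensity. Nuclei attach to the
cell or cluster containing their centroid, falling back to largest overlap
when the centroid lands on background; unassigned nuclei are reported, and
per-cell failures (no nucleus, empty or zero-intensity cytoplasm) produce
error records rather than exceptions. A cluster is multicellular iff it
contains strictly more than two nuclei.

### Synthetic data

Phantoms are pure functions of a spec and a seed and always carry their
answer key: disks/ellipses/stars with exact continuous-geometry area,
perimeter (Ramanujan's approximation for ellipses, shoelace/edge sums for
star polygons) and circularity; two-channel cell images with
piecewise-constant intensities (so the noise-free N/C ratio is exact) plus
additive Gaussian noise truncated at zero (Poisson shot noise behind a
flag); and log-spaced relaxation-curve samples with the generating spectrum
attached. They emulate segmentation outputs and rheometer traces, not raw
micrographs: no point-spread function, no intensity gradients, no
segmentation errors, no 3D stacks. Passing tests therefore validate the
measurement code downstream of segmentation, not segmentation itself.

## Numerical and design choices

- Equal load sharing among bound bonds; the alternative (full force on one
  bond) can be emulated with valency 1 geometries.
- Escape as a first-passage *rate* 2D/δ² competing with rebinding, rather
  than an explicit spatial walk; D(F) linear in force. All four parameters
  (D₀, α, δ, c_local) are explicit configuration.
- Whether rebinding operates at all during a gate-opening attempt is
  physically ambiguous; c_local = 0 brackets the no-rebinding reading.
- "Required force" readouts, where wanted, are defined as the smallest
  force on a grid reaching opening probability ≥ 0.5 — a package
  convention, exposed through probability-vs-force sweeps rather than a
  dedicated routine.
- The master-equation oracle refuses gates above 4 bonds (3⁴ = 81 states is
  exact and fast; 3⁸ would be slow and add nothing as a test oracle).
- Problem sizes used by the shipped analyses: 10⁵ KMC replicates per
  mixture for opening probabilities (matching the headline ensemble), 10⁴
  per grid point for the k_off sweep, 5×10⁴–10⁵ for oracle comparisons;
  these give CIs far narrower than the effects being demonstrated.
- Config keys carry units in their names (force_pN, t_window_s); unknown
  keys are rejected with their path; stage failures are isolated and
  recorded in the manifest.

## Known limitations

- The gate is a zero-dimensional bond ensemble: no network topology, mesh
  statistics or filament mechanics; force enters only as a parameter and
  actin only through the 0.01 s window.
- The rheology bridge is qualitative by construction (see above).
- Morphometrics is 2D-only, matching circularity quantification on
  projected confocal data; 3D shape metrics are out of scope.
- The Bell barrier distance default is an assumption, not a measurement;
  conclusions that depend on the *absolute* force sensitivity (rather than
  the fast/slow contrast) should sweep x‡.
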