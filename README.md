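# gatekmc

From crosslink binding kinetics to 3D cell spreading in supramolecular
hydrogels.

Hydrogels crosslinked by reversible host–guest complexes — a cyclodextrin
(CD) host threading an adamantane (ADA) or cholic acid (CA) guest — confine
encapsulated cells in a polymer network that the cells themselves must
reorganize to spread. The two chemistries have similar equilibrium binding
constants (K_eq = k_on/k_off ≈ 10⁵ vs 10⁴ M⁻¹) but dissociation rate
constants six orders of magnitude apart (k_off ≈ 10³ vs 10⁻³ s⁻¹), so a
CD–ADA network reorganizes under cellular forces on the millisecond scale
while a CD–CA network is effectively static on the timescale of actin
polymerization. `gatekmc` implements the modeling chain that links these
molecular numbers to cell-scale observables:

- **kinetics** — Bell slip-bond law `k_off(F) = k_off⁰·exp(F·x‡/k_BT)` for a
  crosslink under tension, bond lifetimes, and detailed-balance validation of
  user-supplied rate constants against measured K_eq.
- **gate model** — the set of multivalent crosslinks (default 4 units ×
  valency 2 = 8 bonds) that must dissociate *and* be displaced before one
  actin monomer can add at a filopodial tip: a "gate-opening event".
  Mixed gels (A80C20, A50C50, A20C80 = 80/50/20 wt% fast polymer) give each
  bond a fast identity with probability equal to the fast weight fraction.
- **KMC engine** — exact Gillespie simulation of the per-bond Markov chain
  (BOUND → UNBOUND at the force-shared Bell rate, UNBOUND → BOUND by
  rebinding at k_on·c_local, UNBOUND → ESCAPED by force-directed diffusion at
  2·D(F)/δ²), ensemble first-passage statistics with Wilson confidence
  intervals, mixture and fixed-K_eq k_off sweeps, and a brute-force
  master-equation oracle for gates of ≤ 4 bonds.
- **rheology** — transient-network bridge: each crosslink species is one
  Maxwell mode with τ = 1/k_off, giving G(t), G′/G″(ω) and half
  stress-relaxation times for any mixture, plus least-squares spectrum
  recovery from noisy relaxation curves.
- **morphometrics** — cell circularity C = 4πA/P² on labeled masks with
  sub-pixel contour perimeters, nuclear/cytoplasmic intensity ratio (e.g.
  YAP), and the multicellularity rule (a cluster with more than two nuclei).
- **synthetic data** — phantoms with exact answer keys (rasterized shapes
  with analytic circularity, two-channel cell images with known N/C ratio,
  relaxation curves with known spectra) so every stage is testable without
  downloads.

## Worked example

Probability that a gate opens within the ~0.01 s it takes to add one actin
monomer, at a 10 pN filopodial force, for the three canonical mixtures:

```python
from gatekmc import MixtureSpec, opening_probability

for label in ("A80C20", "A50C50", "A20C80"):
    res = opening_probability(MixtureSpec.from_label(label),
                              force=10.0, t_window=0.01,
                              n_replicates=100_000, seed=1)
    print(label, f"{res.opening_probability:.5f}", res.ci95)
```

prints

```
A80C20 0.16745 (0.16514861043203216, 0.1697769381291468)
A50C50 0.00364 (0.0032853311151576975, 0.004032802349965738)
A20C80 0.00001 (1.7652477303783092e-06, 5.664709659040968e-05)
```

The ordering is the point: gates in a gel with 80% fast crosslinks open
within the actin-polymerization window roughly 50× more often than in a
50/50 gel and four orders of magnitude more often than in a 20/80 gel,
because a gate is effectively open only if *every* blocking bond is a fast
one and manages to dissociate and escape in time. This is the kinetic
explanation for why cells spread rapidly in fast-crosslink gels and stay
round in slow-crosslink gels of the same stiffness.

The same machinery is scriptable from a shell:

```bash
gatekmc open-prob --force-pn 10 -n 100000 --seed 1 -o results/
gatekmc sweep-koff --keq 1e5 -n 10000 -o results/
gatekmc rheo -m A80C20 -m A50C50 -m A20C80 -o results/
gatekmc make-fixtures -o fixtures/ && gatekmc quantify \
    --cells fixtures/cell_mask.tif --nuclei fixtures/nucleus_mask.tif \
    --intensity fixtures/cell_intensity.tif -o results/
```

or driven end-to-end from one YAML config (`gatekmc run -c config.yaml -o
out/`), which writes tidy CSVs, a `manifest.json` sufficient to reproduce
every table bit-for-bit, and a run log.

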