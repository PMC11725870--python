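# Methods

## Reversible-aggregation model

Clusters ("higher-order transient structures") of a single membrane-protein
species are treated as nmers in equilibrium with monomers on a 2D surface,
each cluster independent of the others (grand-canonical, dilute limit). Two
parameters:

- `dG_bulk` — standard free energy, in RT units, of transferring one monomer
  into an infinite close-packed bulk-phase sheet. Negative is cohesive.
  Typical fitted values for weakly self-associating receptors are −0.5 to
  −2.5 RT.
- `A0` (μm²) — configurational unit area; `1/A0` is the standard-state
  concentration of the oligomerization reaction, playing the role the 1 M
  convention plays in solution chemistry. Large `A0` makes dilute proteins
  behave as if concentrated.

An nmer's free-energy deficit relative to bulk is a boundary energy taken
proportional to `n**alpha` with `alpha = 0.5` for compact 2D clusters
(perimeter scaling). `alpha` is exposed as a parameter in [0, 1):
`alpha = 0` is the linear-aggregate (polymer-chain) case in which the
unbonded chain ends do not grow with n; it supports no phase transition and
is flagged accordingly (`phase_transition_capable`). The nmer density is

    c_n = A0**-1 (A0 c_mon)**n exp[(n**alpha - n) dG_bulk],

the critical monomer concentration `exp(dG_bulk)/A0`, the critical
distribution `A0**-1 exp(n**alpha dG_bulk)`, and the critical total
concentration the series `A0**-1 Σ n exp(n**alpha dG_bulk)`. For cohesive
parameters the distribution is strictly monotonically decreasing at or below
criticality; this is a property test in the suite.

Numerics: nmer densities are evaluated in log space (stable for large n);
the critical series is summed in blocks and terminated when an integral
tail bound `∫_N^∞ x exp(dG x**alpha) dx` (valid once the integrand
decreases, i.e. beyond `x**alpha > 1/(alpha |dG|)`) falls below the
requested relative tolerance. A geometric-ratio tail bound is *not* usable
here: the term ratio of `n exp(dG n**alpha)` increases monotonically toward
1 for `alpha < 1`, so no fixed ratio bounds the tail; the integral bound is
the simplest rigorous alternative. Inverting the mass constraint
`Σ_{n≤nmax} n c_n = ctot` uses Brent's method on the bracket `(0, ctot]`,
which always contains the unique root because the total is strictly
increasing in `c_mon` and bounded below by its n = 1 term.

## Mass-constrained fitting

The measured quantities are per-size cluster densities and the total
protein density `ctot`. Fits impose `Σ n c_n = ctot` exactly: for any
candidate `(dG_bulk, A0)` the monomer density is resolved by the constraint
solve, never fit. The outer problem is 1D in `dG_bulk` (deterministic
coarse grid over the bounds, then bounded local refinement — reproducible,
and verified in tests against a dense grid scan); at each `dG_bulk`, each
dataset's `A0` is profiled out by a bounded scalar minimization over
`log10 A0`. Global fits share `dG_bulk` and sum per-dataset losses. A fit
whose optimum touches the `dG_bulk` bounds is flagged not converged, never
silently returned.

Loss: with per-bin standard errors, inverse-SE weighted least squares on
densities; without, unweighted least squares on densities. Plain
least squares on log densities was evaluated and rejected as a default: the
floored zero-count tail bins dominate the objective and push fits toward
zero cohesion on simulation-derived histograms, while linear-density least
squares reproduces an independent published fit of the same toy-model
distributions to within the Monte-Carlo scatter. Log loss remains available
(`loss="log"`, floor 10⁻⁶ μm⁻² applied only inside the logarithm).
Zero-count bins inside 1..nmax are retained; `nmax` defaults to the largest
observed size per dataset. `dG_bulk` and `A0` are separately identifiable
because they enter the model through distinct powers of n; identifiability
is weak far below criticality and tightens near it (the recovery tests
sample at ~60% of the critical total density). Uncertainty is by
seed-controlled nonparametric bootstrap over clusters (multinomial resample
of cluster counts, refit).

The shared-`A0` refit (`fit_shared_A0`) fixes `dG_bulk`, shares one `A0`
across datasets, matches only the n = 1..6 densities (the well-populated
head), and still resolves each dataset's `c_mon` from its own `ctot` at its
full observed `nmax`.

## Attractor model

The competing mechanism partitions proteins into discrete attractive
regions of density `mtot` (μm⁻²) with association constant `Ka` (μm²).
In this nonsaturable grand-canonical variant each attractor's occupancy is
Poisson with mean `λ = Ka c_free`, and mass balance
`ctot = c_free (1 + Ka mtot)` is linear, so the solve is closed-form.
Observed clusters are attractors with n ≥ 1 proteins; free proteins are
experimentally indistinguishable from bound singletons and are reported in
the n = 1 bin. The exact published form of the attractor prediction was not
available; this variant is chosen to reproduce its qualitative behavior —
peaked at an interior mode at high `ctot`, monotone when `λ ≪ 1` — and is
used for model discrimination (fit both models with the same loss, compare
residuals).

## Lattice toy model

Excluded-volume random walkers on a `width × height` square grid (default
100×100). Per sweep, particles are updated in random order; each draws
among {stay, up, down, left, right} with weights {w, 1, 1, 1, 1}, where
`w = pwait_bound` (default 50) if the particle has an occupied 4-neighbor
and `pwait_free` (default 1) otherwise. A draw into an occupied or
off-grid site becomes a stay (rejection rule): this keeps the stated
5-outcome weighting while preserving exclusion, and the random-order
*sequential* sweep avoids the two-particles-one-site conflicts of parallel
updates. Boundaries are reflecting by default (the simulated membrane patch
is bounded); periodic is available, in which case cluster binning merges
components across the seam. The grid maps to physical units via `rpg`
(default 0.1 μm per grid unit → 0.01 μm² site area; a 100×100 grid is
100 μm²), and optionally to time via `rpg²/4D`.

Clusters are 4-connected components of occupied sites (the same
connectivity as the binding rule), binned per snapshot and time-averaged.
Defaults: 1,500 burn-in sweeps, 3,500 production sweeps sampled every 10
(350 snapshots). The bound-state escape probability is 4/54 per sweep
(mean dwell ≈ 13 sweeps), so 1,500 sweeps is far beyond the cluster
relaxation time; the occupancy-uniformity and trend tests in the suite
check equilibration behavior directly. These problem sizes keep a full
four-density sweep (200/400/1000/2000 particles at 2/4/10/20 μm⁻²) around
ten seconds while leaving per-bin Monte-Carlo errors well below the fitted
effect sizes. This model is an illustrative kinetic toy — the waiting
weights are not derived from an nmer energy function — so fitted `A0`
values need not equal the site area; empirically they come out an order of
magnitude larger, absorbing finite dilution and the multi-site footprint of
simulated clusters.

## Point-pattern statistics

Coordinates in nm, areas in μm². Cluster linkage is single-linkage
connected components under a distance cutoff (KD-tree pairs + connected
components); a pair at exactly the cutoff links. The cutoff is a
first-class parameter recorded in outputs — with immunogold-style labels it
should scale with label size (roughly 3× the label diameter); synthetic-data
tests use 15 nm against a 5.2 nm packing spacing. Background subtraction is
per-size density subtraction clamped at zero, with clamped bins recorded.
Centroid nearest-neighbor distances (clusters of ≥ 3 points by default) are
tested against complete spatial randomness; the CSR sampler is validated
against the closed-form 2D Poisson law `F(r) = 1 − exp(−π λ r²)`.
Pairwise-distance histograms take all pairs within a maximum distance
(optionally restricted by localization precision) and the main peak is fit
with a single Gaussian expanded from the modal bin to half height; a
comparable secondary maximum outside the window sets a flag. Labeling
efficiency is modeled as independent binomial thinning. Distances are
Euclidean in the sheet plane (no tilt correction); polygon membership
counts boundary points as inside.

## Synthetic data generator

Emulates the study conditions: per-size cluster counts are independent
Poisson draws with mean `density[n] × area` (matching the theory's
independence assumption and making error bars analytic), centroids are
uniform (CSR) in the membrane region, and each size-n cluster is laid out
as a compact hexagonal spiral with nearest-neighbor spacing 5.2 nm
(default; isotropic jitter sd 0.4 nm), randomly rotated. The observation
model composes binomial thinning (labeling efficiency, default 1.0) with a
uniform Poisson background (default 0 μm⁻²); channels annotate
signal/background unless generated blind. Default region: a 50 × 50 μm
rectangle (the scale of a stitched montage of one membrane sheet).
Supercritical requests are rejected with the critical total concentration
named. What the generator does **not** emulate: non-uniform background,
antibody-linker geometry and label size (clusters appear exactly at their
packing spacing), protein-rich membrane islands, montage stitching
artifacts, or detection errors — so passing recovery tests demonstrate the
pipeline and estimator, not robustness to those real-data effects.

## Design choices and limitations

- Energies are stored in RT units throughout; concentration μm⁻², area μm².
  No general unit system.
- The thermodynamic-activity reparameterization of the fit (`A0` as a
  multiple of a reference area) is intentionally not implemented; `A0` is
  reported directly.
- Maximum-likelihood multinomial fitting is out of scope; the least-squares
  losses above are the supported objectives.
- Identifiability degrades far below criticality (the distribution
  approaches a featureless geometric decay); single-dataset fits there can
  err by several tenths of an RT even at 10⁴ labels. Global fits across
  densities and near-critical designs are the recommended regimes.
- The bootstrap resamples clusters, not labels, so it captures counting
  noise but not labeling-efficiency uncertainty.
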