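# Methods

## The system being modeled

The superficial superior colliculus (SC) integrates two topographic
visual inputs. Retinocollicular topography is established first (during
the first postnatal week in mouse) by chemoaffinity gradients, correlated
spontaneous retinal waves and axonal competition. Corticocollicular (V1)
axons arrive during the second week and must terminate in register with
the retinal map. `mapalign` treats only this second, *alignment* stage:
the retinal map is a fixed background that enters through the
activity-energy kernels, and the optimized object is the V1→SC
connection-count field.

All positions are expressed in Ω-space: a common retinotopic unit square
for both layers, with x = azimuth (nasal–temporal retina → anterior–
posterior SC, medial–lateral V1) and y = elevation (dorsal–ventral
retina → lateral–medial SC). Each layer is a regular N×N lattice at cell
centers ((i+0.5)/N, (j+0.5)/N); the cell-center convention avoids
duplicated boundary coordinates and keeps all kernels resolution
independent. The wiring state n(r⃗_s, r⃗_l) is a dense nonnegative
integer matrix over (SC site, V1 site) pairs with cached axonal and
dendritic marginals n_A, n_D (audited against full resummation in
tests).

## Energy functionals

Total energy is E = E_a + E_c + E_u.

**Chemoaffinity.** Per-contact cost from opposing exponential
guidance-molecule gradients,

    g_a(r_s, r_l) = alpha_a (e^{x_s} - 1) e^{-x_l}
                  - beta_a (e^{y_s} - 1)(e^{y_l} - 1),

summed with contact multiplicity. The typeset source expression admits
several groupings; this one was adopted (and frozen) because it produces
per-axon SC fields graded along both axes with opposing signs, matching
the published supplementary field maps. It is linear in counts, so its
contribution to any elementary move is contact-local.

**Competition.**

    E_c = sum_l [beta_c n_A(l)^2 - alpha_c n_A(l)] + sum_s gamma_c n_D(s)^2.

The linear term rewards axonal outgrowth, the quadratics penalize
crowding on both the axonal and dendritic side. Marginal changes under a
single add/remove have the closed form beta_c(±2 n_A + 1) ∓ alpha_c +
gamma_c(±2 n_D + 1).

**Activity, correlational model.** SC firing is assumed purely retinal;
a contact is rewarded by the wave-correlation between source and target
coordinates:

    E_u = -gamma_u sum n(r_s, r_l) C(r_s, r_l),

with C = e^{-|r_s - r_l| / beta_u} for the wild type. Mutant genotypes
replace C with a two-peak kernel: peaks at azimuth x_l/2 (amplitude
alpha_u) and x_l/2 + 1/2 (amplitude 1), exponent given by the elliptical
distance with azimuthal scale kappa_u·beta_u and elevational scale
beta_u. At kappa_u = 1 a single peak reduces exactly to the wild-type
kernel, which is why the elliptical (square-root) form was chosen over a
Gaussian one; the Gaussian variant is kept behind
`ModelParams.kernel_form = "gaussian"` for sensitivity checks.

**Activity, integrational model.** V1 inputs also drive SC firing. Each
contact's bracket gains the synaptic-weight-normalized correlation with
the *other* V1 axons converging on the same SC dendrite:

    A(r_s, r_l) = [sum_{q != l} D(r_s, q) n(r_s, q) e^{-|r_l - q|/beta_u}]
                / [sum_{q != l} D(r_s, q) n(r_s, q)],

    E_u = -gamma_u sum n(r_s, r_l) [ A(r_s, r_l) + xi_u C(r_s, r_l) ],

where D(r, q) = e^{-(|r - q| / 2 nu_u)^2} is the synaptic weight of a
contact and xi_u the strength of retinal drive relative to V1 drive.
Conventions: "other axons" excludes only the same V1 *source site* (a
contact does not correlate with its own source's contacts); when no
other axon is present the 0/0 ratio is defined as 0; mutant genotypes
use the two-peak kernel for the retinal term but keep the isotropic
axon–axon correlation. As xi_u → ∞ the (renormalized) bracket converges
to the correlational kernel, which is verified numerically.

## Genotype presets

| parameter | WT | Isl2-EphA3 | Isl2-EphA3 / β2-KO | notes |
|---|---|---|---|---|
| alpha_a / beta_a | 60 / 90 | 60 / 90 | 60 / 90 | chemoaffinity |
| alpha_c / beta_c / gamma_c | 450 / 1 / 1 | same | same | competition |
| beta_u | 0.11 | 0.11 | 0.231 | correlation length (Ω units) |
| gamma_u | 20 | 20 | 8.7 | activity scale |
| alpha_u | — | 0.625 | 0.625 | anterior/posterior amplitude ratio |
| kappa_u | — | 1 | 4 | azimuthal stretch |
| nu_u / xi_u (integrational) | 0.15 / 3 | 0.15 / 3 | 0.15 / 3 | weight width / retinal drive |

The knock-in duplicates the retinal azimuth map (two-peak kernel); the
wave-disrupted double mutant additionally rescales beta_u and gamma_u.
Those rescalings derive from exponential fits a + b·e^{-x/k} to
correlation-index-vs-distance curves of retinal waves:
`fit_wave_correlation` performs the fit and `scale_params` applies
gamma_u ← gamma_u · b_alt/b_ref and beta_u ← beta_u · k_alt/k_ref. This
direction (division by the reference/altered ratios) is the one that
maps the wild-type preset onto the knockout preset and is asserted in
the tests.

## Optimizer

A simulated-annealing variant with no cooling schedule. Each step:

1. propose adding one contact at a uniformly random (SC site, V1 site)
   pair; accept with P = 1/(1 + e^{gain·ΔE}), gain = 4;
2. propose removing one uniformly random *existing contact*
   (count-weighted, via an explicit contact list); accept likewise.

The two sub-moves are evaluated and accepted independently; this reading
(rather than a coupled swap) is forced by the observation that the
steady-state connection count differs from the initial one, which a
count-conserving swap could not produce. Runs last
`steps_per_neuron × N²` steps (default 15,000 per neuron); snapshots of
the density summary, the exactly recomputed energy, and acceptance
counters are taken every 500,000 steps by default.

ΔE is evaluated incrementally: chemoaffinity and the correlational /
retinal activity terms are contact-local table lookups; competition uses
the closed-form marginal update; the integrational axon–axon term
recomputes only the affected SC site, with per-site caches (weighted
count sums and per-source correlation sums) updated in O(active sources)
per accepted move and rebuilt exactly from the counts at every snapshot
to cap floating-point drift. The inner loops are numba-compiled; the
pure-Python path (`propose_move` / `step` / `delta_energy`) implements
the identical semantics and is the reference for the oracle tests, which
compare every incremental ΔE against a full recomputation to 1e-9 over
all six (model, genotype) conditions, and the compiled path's
accumulated energy against exact recomputation at snapshots.

Reproducibility: a run is fully determined by (initial state, params,
schedule); per-chunk RNG seeds derive from `schedule.seed` through
`numpy.random.SeedSequence`.

Initial conditions: random wiring with 50 contacts per neuron on average
(a fixed total of 50·N² contacts at uniform pairs, i.e. multinomial —
the distribution law is a package choice), or the extreme `empty` /
`full` states used to demonstrate initial-condition independence.

## Analyses

* **Densities** are Gaussian KDEs of connection endpoint coordinates,
  count-weighted, with Silverman bandwidth (scipy). If the weighted
  sample is degenerate (all mass at one point — where scipy would
  silently underflow to a zero density) a Gaussian bump of
  lattice-spacing width is substituted. Unnormalized 1-D densities
  integrate to 1 over an enlarged support (tested to 2%).
* **Termination zones**: for each V1 seed disk (radius 0.04 Ω units;
  default seeds on the 3×3 grid {0.25, 0.5, 0.75}²), the 2-D SC density
  of its connections. Zone size is reported two ways: the SC *area
  fraction* above 20% of the zone maximum (on a 60×60 evaluation mesh)
  and the 1-D azimuth *width* of the super-threshold set.
* **Peak detection**: local maxima above 20% of the profile maximum,
  merged within one KDE bandwidth (the notion of a "duplicated" zone is
  operationalized as ≥2 surviving peaks; separation is the distance
  between the outermost ones).
* **Convergence summary**: five SC-azimuth profiles for V1 azimuth bands
  at {0.1, 0.3, 0.5, 0.7, 0.9} (half-width 0.04, widened to 0.75 lattice
  spacings on coarse grids so every band resolves sites), 100 points
  each, max-normalized and concatenated; the convergence trace is the
  Euclidean distance between consecutive snapshots' summaries.
* **Retinal-drive sweep**: the duplicated-map genotype re-annealed from
  scratch at each drive value (gamma_u for correlational, xi_u for
  integrational), ≥2 seeds per value, reporting per-value median
  profiles and peak separations. Transition sharpness is summarized by
  the log10 span between the largest still-unimodal value (separation ≤
  0.15) and the smallest clearly duplicated one (≥ 0.35), plus the
  largest single-step separation jump.

## Problem sizes

The published scale (100×100, 1.5×10⁸ steps) takes hours per run; the
package's own study conditions are desk-scale: converged-run analyses on
30×30 lattices, sweeps and initial-condition comparisons on 20×20, all
at the canonical 15,000 steps per neuron. All energies are resolution
independent, and the reported phenotypes are stable across N = 20–30 and
across random/empty/full initializations. Memory of the precomputed
kernel tables scales as N⁴ (≈0.8 GB per table at N = 100; the
integrational model holds three).

## What the simulations do and do not show

Reproduced robustly at desk scale (both models): wild-type alignment
(all nine seed zones unimodal, peak-to-seed error < 0.05), the
duplicated azimuth map of the knock-in (central-seed peak separation
0.5 ± 0.1), the single broadened zone of the wave-disrupted double
mutant with the correlational zone broader than the integrational one,
convergence (doubling the run changes the mean dendritic load by < 5%,
late trace distances < 10% of the trace maximum), and the
single→duplicated transition of both models under increasing retinal
drive, monotone in the drive parameter.

Known deviations, stated plainly:

* **Absolute connection counts.** With the preset energy coefficients
  the count equilibrium is set by 2(beta_c + gamma_c)·n ≈ alpha_c + |L|
  (L the per-contact chemo+activity energy at retained pairs), giving a
  mean dendritic load of ~127 (correlational) / ~135 (integrational) per
  SC neuron — several-fold above the 18–25 historically associated with
  these parameter values. No grouping of the ambiguous chemoaffinity
  expression reconciles the two at these coefficient magnitudes, and all
  *spatial* phenotypes are insensitive to the discrepancy. The presets
  are kept verbatim and the count tests report the measured values.
* **Zone area fraction.** The 2-D 20%-threshold area of a wild-type
  termination zone measures ~1.6% of SC area at N = 30 (tight zones with
  correctly placed peaks), below the ~5% figure quoted for the full
  scale; "width" and "area" are conflated in the original description
  and the 2-D area reading was fixed a priori.
* **Transition sharpness.** At desk scale both models' drive transitions
  are gradual with nearly equal logarithmic width (~0.2 decades, no
  per-seed bistability), so the reported *sharper* integrational
  transition is not resolved at N ≤ 30; the cooperativity of the
  axon–axon term plausibly needs the full axon population.

Other limitations: no inhibitory circuitry, no anatomical (mm)
coordinates or asymmetric visual-field magnification, no retinal
ganglion cell subtypes; retinal activity enters only through static
kernels, not a wave simulation.
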