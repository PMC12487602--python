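# Methods

This note records the modelling choices behind `lvhsim`: what is computed,
which simplifications were made where the design was genuinely open, and what
the tests do and do not demonstrate.

## Idealized anatomy

The biventricle is two truncated ellipsoidal shells. The LV is centred at
the origin (default cavity semi-axes 28 × 28 × 50 mm, wall 11 mm, basal
truncation plane 11 mm above centre); the RV is a thinner closed shell
(5 mm wall) placed adjacent on the right-anterior side with a 2 mm gap. The
shells are *not* conformally fused: the septum is represented by the LV
sector facing the RV (|φ| ≤ 60°), and the two chambers are electrically
independent components of the eikonal graph. This is acceptable because each
chamber carries its own fascicle sources — physiologically, the right bundle
branch — so no front needs to cross the LV–RV boundary; the price is that
septal breakthrough interplay between the chambers is not modelled.

Meshing is structured: a parametric grid in (transmural *u*, apicobasal *v*,
azimuth *φ*) with an apex column, split into tetrahedra around cell
centroids so faces always conform. Nodes are linear blends between the
endocardial and epicardial ellipsoid surfaces, which makes the discrete
tissue volume converge to the closed-form shell volume (the residual error
is the polygonal-ring area deficit, < 1% at default resolution) and makes
the ventricular coordinates exact by construction: *t* = *u*, *z* = *v*,
*φ* the grid azimuth with its seam at the posterior junction and φ = 0 at
mid-septum. A P1 finite-element Laplace solve provides the coordinates for
meshes loaded from plain files without parametric metadata.

Fibres are rule-based: helix angle linear in *t* from +60° (endo) to −60°
(epi), transverse angle from −65° to +25°; the triad (f0, s0, n0) is built
from the local wall-tangent frame and is orthonormal to machine precision.

## Growth

The driver is a reduced inflation experiment instead of a finite-element
mechanics solve. The LV cavity volume increases by `compliance × pressure`
(default 6 ml/mmHg, sized so that the 10 mmHg overload stretches the
endocardium roughly 10% above its 5 mmHg baseline); the increment is
distributed through the wall with the incompressible thick-shell map
`r(R) = (r_i³ + R³ − R_i³)^{1/3}` on an equivalent spherical shell whose
radii reproduce the actual cavity and tissue volumes. Every wall-tangent
direction then stretches by r/R and the radial direction by (R/r)², so
det F = 1 identically; under this surrogate the fibre and in-plane
cross-fibre stretches coincide, and the serial/parallel sarcomere
distinction lives entirely in how θ feeds back into the geometry. This is
the main simplification of the package: stress fields, residual stress and
regional stretch heterogeneity beyond the transmural gradient are out of
scope, which is defensible here because only the grown *geometry* enters the
ECG chain.

Growth kinetics: `dθ/dt = k σ(θ) max(λ − λ_crit, 0)` with
`σ(θ) = 1/(1 + exp(γ(θ − θ_max)))`, integrated with explicit Euler
(Δt = 1 normalised time unit) through a pressure protocol of ramp-up (100
units), hold (600), ramp-down (100). λ_crit is the stretch at the 5 mmHg
baseline inflation, recomputed on the regenerated geometry after every
cycle, which gives the homeostatic behaviour that growth stops when loading
returns to baseline. Defaults: γ = 10, θ_max = 4.0, k = 6·10⁻⁴ per time
unit for eccentric growth and 2.5·10⁻³ for concentric growth. The
asymmetry in *k* and the high θ_max are deliberate: dilation raises mass
with θ³ while thickening raises it roughly linearly, and the septum-weighted
asymmetric mode needs local multipliers near 3 to double total LV mass; with
these defaults the +100% ladder completes in 17–49 cycles depending on
growth type.

Geometry update per cycle: eccentric scales every LV dimension by the
wall-averaged θ_f (h/R preserved exactly); concentric adds
`(θ̄_t − 1) × h₀` of wall thickness, split 70% inward / 30% outward
(concentric LVH reduces cavity volume), modulated for the asymmetric form
by `w(φ) = w_min + (1 − w_min) exp(−(φ/φ_w)²)` with w_min = 0.25 and
φ_w = 60°, referenced to the septal mean of θ_t. The mesh is regenerated
parametrically at fixed resolution, so element arrays stay aligned across
cycles and no element can invert (an explicit guard rejects inward growth
that would close the cavity).

Mass bookkeeping: LV tissue volume (free wall + septum) × 1.053 g/ml;
height-indexed mass `mass / height^2.7`; LVH when the index strictly
exceeds 51 g·m⁻²·⁷ (male cutoff; the female value is configurable and not
asserted anywhere).

## Activation

The eikonal equation ∇T·M∇T = 1 with
`M = v_f² f0f0ᵀ + v_t² s0s0ᵀ + v_n² n0n0ᵀ` (0.6/0.4/0.2 m/s) is solved as
a shortest path on the mesh edge graph with edge cost
`|e|/√(êᵀM̄ê)` (M̄ averaged over adjacent tetrahedra) and a virtual
super-source encoding per-fascicle initiation times. The graph solution is
deterministic, exactly checkable against an independent Dijkstra oracle,
and overestimates the continuum arrival time by a metrication error that
shrinks under refinement — the QRS durations reported on the coarse test
fixture (~75 ms healthy) are therefore systematically wider than what a
converged PDE solver would give, and only *relative* changes across models
should be interpreted. The solver sits behind a small interface (metric +
sources → LAT) so a fast-marching implementation can be dropped in.

The fast sub-endocardial layer (2 m/s isotropic) comprises elements whose
nodes all lie shallower than t = 0.15 and whose apicobasal position is
inside [0.1, 0.9]; the basal bound is strict on all nodes (the conduction
network must never touch the base, where the valve annuli are), the apical
bound uses the element centroid (the network thins gradually toward the
apex). At production resolution the layer covers ≈ 76% of the endocardial
surface area, consistent with the target of roughly 80%.

Default fascicle positions are anatomical approximations (three LV, two RV,
all starting at t = 0 ms) and are config-overridable; subject-specific root
locations from ECG personalisation are outside this package's scope. For
grown models the fascicle node sets are transferred from the healthy mesh
through ventricular coordinates, never re-derived on the grown anatomy —
the conduction system is assumed untouched by growth.

## ECG forward model

Each node's transmembrane voltage is a logistic upstroke from −85 to
+25 mV (2 ms upstroke) shifted to its activation time; repolarisation is
not modelled, so only the QRS exists. Extracellular potentials use an
infinite homogeneous volume conductor with the torso conductivity
0.22 S/m: each tetrahedron contributes a dipole `−V_e σ_i ∇V_m` (linear
shape-function gradient, centroid source point, σ_i = 0.34/0.6/0.6 S/m in
fibre coordinates). The bounded heterogeneous torso, blood pools, lungs and
skin are not modelled; the infinite-conductor sum preserves the dipole
far-field (1/r²) physics that drives lead-amplitude behaviour but not
boundary-condition effects, so absolute amplitudes are calibration-bearing.
The conventional 0.28 scaling applied to simulated leads is carried as an
explicit, configurable metadata field, not folded into any threshold.

Electrodes sit on a cylindrical torso surrogate (radius 14 cm) at standard
angular positions; limb electrodes are placed at shoulder/hip distances.
Lead algebra is standard and the identities I + III = II and
aVR + aVL + aVF = 0 hold to numerical precision by construction.

## QRS features and criteria

Simulated (noise-free, single-beat) signals are segmented by the
across-lead RMS crossing 5% of its peak — a package convention chosen for
determinism, since no universal onset/offset operator exists; published
absolute QRS durations are treated as fixtures, not as targets of this
operator. Clinical-style records go through zero-phase 0.5 Hz high-pass /
150 Hz low-pass / 50 Hz notch (Q = 30) filtering and a derivative-threshold
beat detector with ±60 ms windows; records without a detectable QRS are
dropped and counted. R/S amplitudes are baseline-corrected by the pre-onset
median, so extraction is offset-invariant and commutes exactly with
amplitude scaling.

Criteria: Sokolow–Lyon S(V1) + max(R(V5), R(V6)) ≥ 3.5 mV; Cornell
R(aVL) + S(V3) ≥ 2.8 mV (male) / 2.0 mV (female default, configurable);
Peguero–Lo Presti deepest-precordial-S + S(V4) ≥ 2.8 / 2.3 mV, with a
switch for the original all-lead deepest-S variant. Comparisons are
inclusive: the bundled reference family contains a symmetric-concentric
model detected at exactly 3.5 mV, which fixes the convention. Metrics use
the standard definitions; precision and F are reported as undefined when no
positives are predicted. The bundled reference tables contain two internal
inconsistencies (an eccentric precision/F footer that contradicts its own
values, and masses in four asymmetric rows that do not equal
volume × density while their indices follow volume-based indexing); the
tests document these rather than force agreement.

## Cohort statistic and synthetic data

`D_i` is the relative difference of 95% truncated means (floor(n·0.025)
values dropped per tail — the rounding rule is a package choice) of
per-record max |QRS| per lead; for multi-beat records the per-record value
is the median across beats (outlier-robust; the choice is free since any
per-record reduction works). D is invariant to common rescaling of all
records.

The synthetic cohort generator produces 500 Hz 12-lead records as trains of
difference-of-Gaussian QRS complexes (R width ≈ 12 ms, lead-specific
R/S polarity mix), lognormal amplitude variation (σ = 0.30 shared across
leads per record, 0.10 per lead), baseline wander (0.1 mV at 0.33 Hz),
50 Hz interference (0.02 mV) and white noise (0.01 mV) — noise levels
sized to be realistic yet fully removable by the standard filter chain. The
LVH cohort multiplies lead i by s_i, so the population value of D_i is
s_i − 1 by construction; the default scale factors (aVL 1.937, III 1.773,
V1 1.69, I/V5/V6 ≥ 1.5, remaining leads 1.2–1.4) encode the
lead-sensitivity pattern reported for large clinical LVH cohorts. Records
are generated from seed-sequence-spawned independent streams, so a cohort
is a pure function of (spec, master seed) down to the bit level.

What the synthetic cohort does *not* emulate: P/T waves, rhythm and beat
morphology variability, pathology beyond amplitude scaling, inter-lead
correlation structure of real torsos, or Einthoven-consistent limb leads
(leads are generated independently; the consistency identities apply to the
*derived* simulated ECGs, not to the synthetic cohort records). Passing the
parameter-recovery tests therefore shows the statistic and pipeline are
correct and unbiased under the generator's assumptions — not that the
clinical effect sizes themselves are reproduced from raw data.

## Problem sizes and numerical conventions

Tests and the acceptance script run on a coarse fixture mesh
(2 × 6 × 14 structured cells per chamber, ≈ 3.8 k tetrahedra): the full
30-model growth ladder takes seconds and the complete
growth→activation→ECG→criteria study under ten seconds, which the package
treats as its standard desk-scale configuration; the default mesh
(5 mm target edge, ≈ 25 k tetrahedra) is used where geometric accuracy
matters (volume and surface-fraction checks). Ties in the eikonal solve are
resolved deterministically; all serialized indices are 0-based; SI units
internally (m, s, S/m) with mm/ms/mV at reporting surfaces.

## Known limitations

- The inflation surrogate has a single compliance knob and spherical-shell
  transmural structure; it cannot represent regional wall-stress
  distributions, and concentric growth rates inherit its in-plane/radial
  degeneracy (the concentric driver equals the tangential stretch).
- Eccentric remodelling of the RV and atria is absent; the RV never grows.
- Graph-eikonal metrication widens all absolute activation times at coarse
  resolution.
- The infinite-conductor ECG omits torso boundary effects; amplitude levels
  are only meaningful relative to the control model and the 0.28
  calibration.
- Lead amplitudes along the eccentric ladder rise strongly in net terms but
  are not strictly monotone level-by-level at coarse resolution (small dips
  of a few percent occur, e.g. in V5 at low growth levels); tests assert
  the trend and the net increase, not strict monotonicity of every lead.
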