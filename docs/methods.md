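# Methods

This note documents the models, numerical choices and calibrations behind
the package, and what its validation does and does not show.

## Source model

The equivalent dipole layer (EDL) represents ventricular electrical
activity as a double layer on the closed ventricular surface (endocardium +
epicardium + basal band) whose local strength is proportional to the
transmembrane potential (TMP).  Two consequences shape everything else:

* a spatially uniform TMP over the closed surface produces **no** external
  field (closed-layer null).  Our discretization preserves this exactly
  (see below), so the baseline of every simulated ECG is structural, not
  numerical;
* opposing endocardial/epicardial normals cancel, so purely *transmural*
  timing gradients are nearly invisible at the body surface.  This is an
  intrinsic property of the source model, not an artifact, and it dictates
  several gold-standard design choices documented below.

Per node, `TMP_j(t) = H(t − τ_j) · r(c_j (t − τ_j))` with
`c_j = s20/(ρ_j − τ_j)`.  The upstroke `H` is a cubic smoothstep of 2 ms
width (exactly 0 before τ_j, exactly 1 from τ_j + 2 ms), which makes the
waveform differentiable in τ while honoring the step contract at 1 ms
sampling.  The repolarizing limb `r` is the flipped (cumulative) integral of
the dominant T-wave, normalized to fall from 1 to 0 and forced monotone;
`s20` is its 20%-level crossing, so the stretch lands each node's 80%
amplitude loss exactly at ρ_j.  The plateau amplitude (100, nominally mV) is
shared by the simulator and the inverse and cancels out of the estimation.

**Dominant T-wave.** Two extractors are provided: the RMS-curve shape
(default) and the first temporal singular vector of the T-window signal
matrix (`dominant_t_method="svd"`).  The default is the RMS variant: the
limb construction divides by the *net* integral of the waveform, and the
(possibly biphasic) SVD factor can have a near-cancelling net integral,
degenerating the limb into a step; the RMS shape is single-signed, with its
noise floor subtracted inside the window.  The template deliberately lacks
the phase-1 notch of real action potentials; the gold-standard waveform has
one, making waveform mismatch part of the validation conditions.

## Volume conductor

Piecewise-homogeneous nested compartments: thorax, two lungs, intracavitary
blood, and the ventricular wall, with conductivity presets A (matched) and
A1–A4 (literature variants; thorax 0.2, lungs 0.04–0.06–0.01, blood
0.6–0.75, myocardium 0.1–0.4 S/m).  Boundary-element discretization:
vertex collocation, lumped-linear dipole-layer elements (each triangle's
analytically computed solid angle split equally over its vertices), jump
terms written with the *interior vertex angle* (the row sum of the
own-surface kernel block) rather than the smooth-surface 2π, and rank-one
deflation of the additive-constant null space.  Because the solid angles
are exact, uniform strengths on closed surfaces cancel to machine
precision — the closed-layer null and the nesting consistency hold by
construction, not to discretization accuracy.

Validation oracle: a current dipole in a homogeneous conducting sphere,
solved spectrally (spherical-harmonic solution of the interior Neumann
problem; the l=1 term reproduces the classical `3 p·r̂ /(4πσR²)` central
dipole result to machine precision).  The BEM reproduces the oracle to
0.3% relative RMS at 1280 faces and 0.06% after one refinement.

**Amplitude calibration.** The ideal dipole layer on this compact phantom
overestimates body-surface amplitudes (no intra/extracellular partition,
heart close to the chest wall).  A single dimensionless gain
(`EDL_GAIN = 0.1`) is applied to the transfer matrix so that a 100 mV
plateau produces physiological QRS peaks (~1–2 mV); microvolt noise levels
then carry their usual clinical meaning, and the baseline 20 μV condition
corresponds to ≈17–21 dB SNR depending on the beat (high-noise 80 μV ≈ 7
dB), matching the range reported for body-surface mapping.  The gain is a
units convention: it cancels between forward and inverse and only scales
the meaning of "μV of noise".

## Geometry

The ventricular surface is a thick-walled half-ellipsoid cup (outer shell =
epicardium, inner shell = endocardium, annular basal cap), a single closed
surface so the EDL null property is exact; vertices carry
epicardial/endocardial/basal labels for per-class error reporting.  The
study phantom uses ≈390 ventricular nodes (7.6 mm mean edge) to keep
repeated inverse solves fast; `make_ventricle` itself defaults to ≈1500
nodes.  The forward model refines the cup by one midpoint subdivision
(4× faces) — the inverse never sees the fine transfer matrix.

Surface Laplacian: cotangent weights normalized by the one-third vertex
area.  Geodesics: Dijkstra on the edge graph augmented with one-ring
unfolding shortcuts (≤2% error against great circles at icosphere
refinement 3).

**Transmural links.** For propagation purposes the cup's two shells are
additionally connected by endo↔epi nearest-neighbor edges with euclidean
(wall-thickness) length, for the gold-standard spread and the fastest-route
metric alike.  Without them, activation reaches the epicardium only around
the basal rim, tens of milliseconds late — an artifact of representing a
solid wall by its boundary surface; real myocardial activation crosses a
10 mm wall in ~12 ms.

## Gold-standard simulator

Activation: geodesic distance (with transmural links) from the stimulus
site(s) over a uniform 0.8 m/s velocity; the sinus-analog beat uses five
staggered endocardial foci (Purkinje-like), the ectopic analogs one
epicardial RV-base or one endocardial septal site.

Repolarization: `ρ = τ + APD` with three deliberate properties, each chosen
for a physiological reason and calibrated once against the scales the
method is validated on:

1. **APD couples to the transmurally averaged activation time**
   (slope 2.0 for sinus — inverse repolarization, concordant T; 0.5 for
   ectopic — repolarization following activation, discordant T).  Regional
   cm-scale heterogeneity drives APD, while electrotonic coupling equalizes
   it across the thin wall; the ms-scale transmural activation delay leaves
   no APD imprint.
2. **A smooth random heterogeneity field** (Gaussian-kernel-smoothed white
   noise, SD 25 ms, correlation length 3–3.5 cm) is added after being
   decorrelated in-sample from the activation reference, so the configured
   slope is the realized coupling for every seed (a single long-wavelength
   draw can otherwise cancel it by chance).
3. **The final ρ field is smoothed with a 1 cm space constant** —
   repolarization is electrotonically low-pass and carries low spatial
   frequencies, unlike the activation wavefront's ridge structure.  The
   resulting true maps have REG_rep ≈ 8–12 s/m and ranges of ≈90–100 ms,
   i.e. the regularization target for "realistic" repolarization smoothness
   is a property the simulated truth actually has.

The forward TMP waveform has a 1.5 ms upstroke, a 10% phase-1 notch of 5 ms,
and a logistic limb pinned to 20% amplitude at ρ (width ∝ APD).  Forward
ECGs use the fine-mesh transfer matrix with preset A; Gaussian noise (σ in
μV) is added per electrode and sample; maps are transferred to the inverse
mesh by nearest neighbor (exact on the parent-vertex block).

What the simulator does **not** emulate: anisotropic 3-D propagation,
ionic-model dynamics, fiber architecture, septal geometry, cardiac motion
and respiration.  Passing validation here therefore demonstrates the
inverse machinery under controlled mesh/waveform/conductivity/noise
mismatch — not clinical-grade accuracy on real anatomies.

## Inverse pipeline

1. **Fiducials** from the (5 ms smoothed) RMS curve: QRS onset/J-point at
   5%-of-peak crossings (raised to twice the baseline floor), T-end as the
   last 5%-of-T-peak crossing.
2. **Template** from the dominant T-wave on the window (J+10 ms, T-end+40 ms).
3. **Fastest-route activation**: every node × velocities {0.6, 0.8, 1.0}
   m/s × global time shifts {−8…+8 ms} scored by QRS correlation; greedy
   focus addition (min over foci) while the gain exceeds 0.01; per-focus
   onset delays refined by cyclic coordinate search (multifocal rhythms
   fire staggered).  The shift grid matters: the RMS-threshold onset biases
   the anchor enough to derail focus selection otherwise.
4. **Initial repolarization**: sinus `ρ0 = ρ̄ − α(τ − τ̄)` with α = 0.5 and
   ρ̄ anchored at the template's own 20% crossing (the mean repolarization
   time implied by the measured T-wave); ectopic `ρ0 = τ0 + (T_end − J)`.
5. **Activation pre-pass** (LM, activation block only), then a
   **smooth-subspace repolarization initialization**: damped Gauss–Newton
   over the 12 smoothest Laplacian eigenmodes.  The T-wave constrains only
   low spatial frequencies; solving that sub-problem first makes the final
   result independent of the crude physiological prior.
6. **Alternating Levenberg–Marquardt** on the residual
   `[vec(Φ(τ,ρ) − Φ_meas)/‖Φ_meas‖_F ; √λ·diag(√a)·L·t/1000]`, i.e. the
   least-squares objective `RD² + λ_dep REG(τ)² + λ_rep REG(ρ)²`.  Analytic
   Jacobians via the template's time derivative; Gauss–Newton blocks use the
   Hadamard identity `JᵀJ = (AᵀA) ∘ (S Sᵀ)`; multiplicative damping;
   accepted steps never increase the objective; ρ ≥ τ + 20 ms enforced by
   projection.  Outer loop stops when the ECG correlation gains < 1e-3 or
   at 15–30 rounds.  The linear-form objective RD + λ·REG is available for
   reporting.
7. **λ selection**: geometric bracketing and log-bisection on the achieved
   REG (monotone non-increasing in λ), targets 25 s/m (activation) and
   10 s/m (repolarization), acceptance band ±20%; the bisection itself
   stops at 0.7× the band so achieved values sit near the center.  Two
   alternating selection rounds, warm-started, because tuning one block
   drifts the other's achieved REG; if a refinement round cannot bracket,
   the previous solution is kept.

## Numerical details and degenerate inputs

* Units: meters, milliseconds, millivolts, S/m internally; REG in s/m
  (times converted to seconds inside the functional).
* 1 ms sampling, linear interpolation at level crossings.
* Template evaluated by linear interpolation, extended with plateau 1 on
  the left and 0 on the right; derivative from the gridded gradient.
* Constant timing maps: REG = 0; Pearson correlation of a constant map is
  reported as NaN ("missing").
* Disconnected meshes: geodesic distances return inf for unreachable
  vertices; phantom validation rejects open/non-manifold/degenerate
  surfaces and intersecting compartments (winding-number containment).
* LM divergence (no accepted step at any damping) terminates the block;
  the best iterate is returned with its convergence flag.

## Study sizes and determinism

The shipped study conditions: ≈390-node inverse mesh, ≈1540-node forward
mesh, 120 electrodes, 500 samples at 1 ms, three beats, five conductivity
presets, four noise levels.  A full REG-targeted inversion takes a few
seconds on one CPU; the complete acceptance recomputation a few minutes.
All randomness (APD fields, measurement noise) flows through explicit
integer seeds; reruns are bit-identical.

## Known limitations

* The phantom has no septum or right-ventricular cavity; "RV-base" and
  "septal" beats are positional analogs on a single cup.
* Transmural repolarization gradients are intrinsically near-invisible to
  the EDL; accuracy claims concern the tangential pattern on the two
  surfaces.
* The λ search assumes the achieved REG is monotone in λ, which holds
  empirically here but is not guaranteed for arbitrary data.
* Fiducial detection assumes a single beat per record with a dominant QRS
  in the first 250 ms.
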