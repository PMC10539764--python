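# Methods

## Model

A solute tumbling near an alignment-medium particle does not sample all
orientations equally: placements where it overlaps the particle are
forbidden, and placements where its partial charges sit in the particle's
electrostatic field are re-weighted by the Boltzmann factor. `rdcalign`
computes the resulting orientational order directly:

1. The medium particle is represented by (a) a set of hard spheres for
   sterics and (b) a scalar electrostatic potential Φ (kT/e) on a regular 3D
   grid (OpenDX, e.g. an APBS solution), plus a director **n** — the particle
   axis that orients along the magnetic field.
2. The solute's geometric centre visits every node of a translation grid
   restricted to a slab `z ∈ [z1, zN]` around the particle's central section
   (end effects of the finite particle model are excluded). At each node it
   assumes every rotation of a deterministic quasi-uniform cover
   (`n_sphere` Fibonacci-spiral directions × `n_spin` equally spaced spins;
   default 100 × 18 = 1800).
3. Each placement gets weight 0 if any solute atom centre lies within
   (atom vdW radius + sphere radius) of a medium sphere, else
   `w = exp(-clip(E, ±max_pot))` with `E = Σ_a q_a Φ(r_a)` by trilinear
   interpolation (atoms outside the grid contribute nothing; the symmetric
   energy cap keeps single deep placements from dominating).
4. Summing weights over translations gives a weight per orientation, and the
   order matrix in the solute frame is

   S = lcS · wv · [ ⟨(3 c cᵀ − I)/2⟩_w − ⟨(3 c cᵀ − I)/2⟩_uniform ],

   where c is the director expressed in the solute frame, `lcS` scales for
   the incomplete ordering of the liquid-crystal phase (default 0.8) and
   `wv` for the medium concentration (default 0.12); both are pure linear
   scales on S. Subtracting the **unweighted average over the same finite
   orientation set** removes the discretization bias of the cover, so any
   interaction-free system yields S = 0 exactly at any sampling density.
5. Couplings follow as `D = Dmax(a,b,r) · uᵀ S u` with
   `Dmax = μ₀ γ_a γ_b h / (16 π³ r³)` (≈ 23.3 kHz for C–H at 1.09 Å).

Translation nodes so far from the particle that the solute's bounding sphere
cannot touch any medium sphere (plus `reach_padding`, default two grid steps)
are skipped. Far free volume adds the same weight to every orientation and
therefore only dilutes ‖S‖ after baseline subtraction; the *magnitude* of S
is consequently a convention tied to the integration slab — as it is in any
finite-volume treatment — while its anisotropy (eigenvectors, rhombicity,
coupling ratios) is not.

**Orientation canonicalization.** Before sampling, the solute is rotated into
its gyration-tensor principal frame with deterministic sign fixes. All
weights are computed there, and S is rotated back to the input frame at the
end. This makes predictions *exactly* independent of how the input structure
happens to be oriented (verified to ~1e-13), which finite orientation covers
cannot otherwise guarantee. Note that rotating the director while holding the
medium geometry fixed changes the physics and is not a symmetry.

## Tensor fitting and quality statistics

With ≥ 5 measured couplings, `D = Dmax uᵀ S u` is linear in the five
independent elements of the traceless symmetric S, solved by
`numpy.linalg.lstsq` (SVD); a rank check rejects degenerate bond-vector sets
(e.g. all vectors parallel). Eigenvalues are ordered |Sxx| ≤ |Syy| ≤ |Szz|
(exact magnitude ties break by descending signed value), eigenvectors are
canonicalized to the z ≥ 0 hemisphere (axes are headless), `Da = Szz/2`,
rhombicity `= (2/3)(Sxx − Syy)/Szz`.

Fit quality: Pearson R; `Q = rms(D_exp − D_calc)/rms(D_exp)`; QS, which is Q
after rescaling predictions by the best-fit slope of D_exp on D_pred —
**through the origin**, since couplings have no physical offset (the main
open design choice here; flagged in the CLI output); and `RQ = (R+1)²/QS`
with QS floored at 1e-6 so perfect fits give a large finite score and RQ
ratios stay well defined. Monte Carlo errors: each replicate perturbs every
coupling by Gaussian noise of its stated accuracy and repeats the full
analysis; R and QS errors are the replicate SDs (default 100 replicates,
explicit seed), and the RQ error follows by first-order propagation,
`rq·sqrt((2·σ_R/(R+1))² + (σ_QS/QS)²)`.

## Ensembles and candidate ranking

Measured couplings of a flexible molecule are population-weighted averages of
per-conformer couplings. Populations are found by exhaustive search over the
simplex lattice with 1 % steps (5 151 points for three conformers),
maximizing RQ of the weighted average against experiment — no assumption
that conformers share an alignment tensor. Exact RQ ties resolve in favour of
earlier-listed conformers (the flat landscape of identical conformers returns
(1, 0, …)). Ensemble-size comparison evaluates every subset of each size;
the optimal RQ is non-decreasing in size by nesting. Candidate ranking
reports RQ with Monte Carlo errors and RQ ratios to the best candidate;
candidates with R < 0.8 are flagged, as weaker correlations are insufficient
to identify the correct stereoisomer. Population uncertainties re-run the
whole grid search per noise replicate.

## Cross-media comparison

Pairwise Pearson correlations over the common (label-normalized) sites of two
media; entries with fewer than 3 shared sites are undefined (NaN), not
errors. Matrices report |R| because a compressed gel aligns with its main
axis orthogonal to the field and inverts the sign of Da — the same ordering,
opposite sign — while the raw sign is kept as a flag and in the underlying
records. Axis projections use the equirectangular (plate carrée) convention
with the molecular x axis at 0° longitude and the antipodal representative
with latitude ≥ 0. Axis-swap detection assigns the axes of one tensor to the
other by the permutation minimizing the total inter-axis angle (|cos|, axes
headless) and reports a swap when a non-identity assignment aligns well and
the permuted eigenvalue magnitudes agree within tolerance — the situation
where noise relabels two near-degenerate axes with little effect on
back-calculated couplings.

## Synthetic test systems

The fixtures generate every input programmatically:

* **Media**: sphere-packed rods (director = rod axis) or planar walls, with
  an analytic screened-Coulomb (Yukawa) potential of the sphere surface
  charges (Bjerrum length 7 Å, default Debye length 10 Å) evaluated on the
  grid. This exercises the identical steric and grid-interpolation code paths
  as a Poisson–Boltzmann potential of an atomistic helical polymer, but it is
  *not* such a model: no helical groove chirality, no dielectric boundary, no
  salt-concentration dependence beyond the single Debye length. Passing tests
  therefore validate the mechanics and physics invariants of the pipeline,
  not the accuracy of any real medium's predicted alignment.
* **Solutes**: rod/disc/sphere/bent atom arrangements with alternating C/H
  elements, 0.05 Å seeded jitter, and neutral/dipolar/quadrupolar zero-sum
  charge patterns.
* **Benchmark tables**: deterministic stand-ins mimicking published
  multi-medium panel layouts — nine media per rigid solute with sparse
  coverage for two of them (5 and 6 sites), a sign-inverted compressed-gel
  medium, and a three-conformer system with eight CH couplings whose
  "experimental" values are generated at reference populations
  (0.2, 0.3, 0.5) plus 0.5 Hz noise (a realistic accuracy for one-bond CH
  couplings). They are labelled synthetic throughout and are not
  transcriptions of measured data.

## Numerical choices and problem sizes

* Production-scale sweeps (0.4 Å spacing, 129×129×385 grid, 1800
  orientations) are supported; the test suite and the acceptance script use
  reduced systems — ~15×15×21 to 41×41×57 translation grids, 240–450
  orientations, ≤ 25 medium spheres — chosen so each sweep resolves the
  contact geometry it probes.
* The binary steric boundary makes grid convergence first-order: refinement
  consistency holds (< 10 % per element) once the base spacing resolves the
  ~4 Å contact features, i.e. ~1 Å here; a 2 Å base grid is demonstrably too
  coarse.
* Orientation cover: deterministic Fibonacci spiral including the +z pole,
  spins about each direction; the identity is always the first rotation.
  Isotropy of the cover is O(1/n) (verified < 5e-3 at 1000×4).
* Population-recovery robustness under noise depends on the conditioning of
  the conformer prediction matrix, not only on pairwise correlations: at 5 %
  relative noise and eight couplings, mixtures of well-separated patterns
  (pairwise |r| ≲ 0.9) recover within 5 grid steps in ≥ 90 % of replicates,
  while near-collinear pairs (|r| ≳ 0.95) do not — the package reports
  per-population Monte Carlo SDs so such cases are visible.
* Degenerate inputs: single-atom solutes are valid (isotropic by symmetry,
  S = 0 to machine precision); an all-excluded sweep raises "solute cannot
  approach medium"; all-zero predictions make the slope (hence QS) undefined
  and raise.

## Known limitations

* The magnitude of S (and so of predicted couplings) depends on the slab and
  shell conventions above and on the `lcS`/`wv` scales; only tensor
  anisotropy and coupling ratios are convention-free. Fits absorb the scale
  through the QS slope.
* No Poisson–Boltzmann solving, no periodic boundaries, no multi-particle
  media, no RCSA data, and no charge computation (charges are consumed from
  two-column files).
* The stand-in benchmark tables cannot reproduce statistics of the published
  panels they are modelled after; analyses of real data require the measured
  RDC tables and a real medium potential.
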