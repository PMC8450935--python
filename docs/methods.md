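# Methods

## The model

Antifreeze proteins (AFPs) adsorb to growing ice nuclei through a dedicated
face, the ice-binding surface (IBS); the rest of the surface is the
non-ice-binding surface (NIBS). This package quantifies how the water
density in the first nanometre around these proteins deviates from bulk,
both for the shell as a whole and separately over the IBS and NIBS.

All distances are referenced to a smooth **protein ellipsoid** rather than
the corrugated molecular surface. The ellipsoid is fitted to the protein
heavy atoms by mapping the weighted gyration tensor onto a uniform solid
ellipsoid: if λ₁ ≥ λ₂ ≥ λ₃ are the gyration-tensor eigenvalues, the
semi-axes are aᵢ = √(5λᵢ) along the corresponding eigenvectors. This choice
is parameter-free, exact in the sphere limit, and equivariant under rigid
motions. Because every density is finally normalised by the same geometry
through the fictitious-shell reference (below), the downstream increments
are insensitive to the precise ellipsoid convention; the fit is exported as
a small YAML record so any run can be reproduced or the ellipsoid replaced.
By default the ellipsoid is fitted once, to the trajectory-average heavy-atom
structure after rigid-body (Kabsch) superposition of every frame onto the
first, so all frames share one reference surface.

**Density profiles.** Water molecules are represented by their oxygen site.
For each frame, oxygens are re-imaged to the periodic box image nearest the
ellipsoid center and binned by signed distance d from the ellipsoid surface
(half-open bins, default width 0.02 nm out to 2 nm). Bin volumes are
differences of parallel-body volumes, V(d+Δ) − V(d), where the parallel
body {x : dist(x, surface) ≤ t} of a convex body obeys the Steiner formula

    V(t) = V + S·t + M·t² + (4π/3)·t³

exactly, with S the surface area and M the integrated mean curvature, both
evaluated by Gauss–Legendre quadrature over the ellipsoid parametrisation.
A scrambled-Sobol quasi-Monte-Carlo integrator for the same volume is kept
as an independent cross-check (the two agree to much better than 0.5% in
the tests); Steiner is the default because it is exact and O(1) per bin
edge. Signed distances are computed by solving the nearest-point
orthogonality condition tᵢ ↦ aᵢ²uᵢ/(aᵢ²+t) with bracketed bisection
(machine-precision convergence; exact for spheres; for interior points on a
principal plane the in-plane solution is used, and the exact center maps to
−c — solvent never sits there in practice).

**Fictitious bulk-filled shell.** Raw profiles mix density physics with
geometry: protein atoms protrude through the ellipsoid surface, so even
bulk-distributed water would show structure versus d. The reference that
cancels this is a *fictitious* configuration set: each protein frame is
overlaid on a bulk-water frame (frame i ↔ bulk frame i mod N), and every
water molecule with any atom closer than the sum of vdW radii to any
protein atom (minimum image) is removed as a whole molecule. The profile of
these configurations, ρ_b,fict(d), is bulk-distributed wherever water can
sit, and the ratio ρ(d)/ρ_b,fict(d) reads directly as the relative density
versus bulk. A plateau detector reports the smallest distance beyond which
|ratio − 1| stays within a tolerance for a run of bins; it is a diagnostic
confirming the 1 nm shell thickness, never an override of it.

**Whole-shell metrics.** With shell thickness 1 nm, V_shell = V(1 nm) from
the parallel body, V_ex the volume enclosed by the solvent-accessible
surface (union of spheres of radius vdW + 0.14 nm probe, integrated on a
0.02 nm voxel grid), and N_shell the count of water oxygens with d ≤ 1 nm
(no inner cutoff — waters cannot penetrate the protein; synthetic waters
inside the surface would be counted and logged):

    ρ_shell = ⟨N_shell⟩ / (⟨V_shell⟩ − ⟨V_ex⟩)
    η       = ρ_shell/ρ_bulk − 1
    v       = N_A·(V_ex − ΔN/ρ_bulk),   ΔN = N_shell − ρ_bulk(V_shell − V_ex)

with 1 nm³·N_A = 0.6022 l/mol, so v (the partial molar volume) is the
excluded volume minus the bulk-equivalent volume of the excess shell
waters; algebraically v = 0.6022·(V_shell − N_shell/ρ_bulk). Statistical
errors are standard errors of block means over 3 contiguous
subtrajectories (sd of block means / √3; the remainder frames join the last
block). These η/v forms reproduce the published whole-shell table for all
eight AFPs from its printed (V_ex, V_shell, N_shell) inputs to within
±0.002 in η and ±0.03 l/mol in v — the arithmetic validation fixture that
runs in the test suite.

**Per-surface metrics.** SASA is computed Shrake–Rupley style: 960
golden-spiral test points per atom on spheres of radius vdW + 0.14 nm, a
point being exposed when outside every neighbour's accessible sphere;
per-atom areas sum exactly to the total, so residue selections partition it
(S(IBS) + S(NIBS) = S(whole protein) identically). Atoms with partial
charge |q| ≤ 0.2 e are classified nonpolar (boundary inclusive), giving the
hydrophobic area fraction S_pho/S. The local density of a surface is
ρ_surf = ⟨N_w⟩/⟨S⟩ — ratio of means, not mean of ratios — where N_w counts
distinct water molecules whose oxygen lies within 0.55 nm (minimum image)
of any heavy atom of the selection's residues; a water near the IBS/NIBS
boundary may count for both surfaces (the counts are independent). The
fictitious configurations give ρ_surf^fict with the real protein's SASA
series, so

    η_surf = ρ_surf / ρ_surf^fict − 1

reduces to ⟨N_w⟩/⟨N_w^fict⟩ − 1. "Heavy atoms of the selection" means all
non-hydrogen atoms of the listed residues, exposed or not — selections are
residue-level, and buried atoms rarely have waters within 0.55 nm anyway.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| shell thickness | 1.0 nm | hydration-shell outer boundary (distance from ellipsoid surface) |
| ρ_bulk | 33.33 nm⁻³ | bulk water number density at 300 K; measured from the bulk trajectory when one is supplied |
| probe radius | 0.14 nm | SASA probe and excluded-volume probe |
| surface cutoff | 0.55 nm | first-hydration-layer cutoff for N_w |
| charge threshold | 0.2 e | |q| bound for nonpolar atom classification (inclusive) |
| bin width / d_max | 0.02 / 2.0 nm | profile binning |
| n_blocks | 3 | subtrajectories for error estimation |
| SASA points | 960 | test points per atom (doubling changes totals < 0.3%) |

vdW radii and partial charges are explicit input via a parameter table
(exact residue:atom pairs first, element fallback second); analyses refuse
to run on unparameterised atoms rather than defaulting silently. The
shipped defaults follow common OPLS-AA/SPC-like conventions and are meant
for synthetic systems and quick looks — real force-field output should be
analysed with its own table.

## The synthetic generator

The analyses consume only positions, so the generator emulates the
*statistical* structure of solvated trajectories with an inhomogeneous
hard-core point process — no forces, thermostats or dynamics. Water oxygens
are placed by random sequential addition with a 0.26 nm periodic hard core
(mimicking the O–O exclusion hole; ~80% of the RSA saturation density at
bulk conditions, handled by a numba cell-list kernel), with per-frame
counts drawn Poisson so the mean density is unbiased. Enhancement is
applied by independent thinning from a base density ρ(1+η_max) down to

    λ(x) = ρ_bulk · (1 + η₀(d(x)))          [optionally per patch]

and zero inside the protein's solvent-accessible volume. Because RSA points
are marginally uniform and thinning is independent, the realised mean
intensity equals λ(x) *exactly*, which is what makes ground-truth
expectations computable: expected shell counts and increments are obtained
by Monte-Carlo integration of λ over the counting regions — using only the
intensity definition and geometric primitives, never the estimators under
test. The pseudo-protein is a uniform atom cloud inside a target ellipsoid
(radii 0.15–0.19 nm) split into two half-ellipsoid patches ("IBS"/"NIBS")
with configurable polar fractions for the two-component charge
distribution (|q| ≤ 0.2 vs > 0.2).

Two deliberate couplings make the recovery tests exact rather than
approximate: the synthetic water oxygen's vdW radius equals the SASA probe
(0.14 nm), so the generator's exclusion region, the analysis excluded
volume, and the fictitious-overlay removal region all coincide; and step
enhancements extend to d < 0 so the few pocket positions between the
ellipsoid surface and the accessible surface carry the same enhancement as
the shell.

What the generator does *not* emulate — orientational order, hydrogen-bond
networks, density layering (the oscillatory first-peak structure of real
hydration water), protein flexibility, and time correlation between frames
(frames are independent, so block errors are if anything conservative
relative to correlated MD frames). Passing recovery tests therefore
demonstrate that the estimators are unbiased and correctly normalised for a
known density field; they do not validate force fields or sampling of real
trajectories.

## Numerical choices and degenerate inputs

- Distance solver: 70 bisection iterations on a guaranteed bracket
  (no Newton step to fail); exact sphere shortcut; exact-center special
  case returns −c.
- Steiner coefficients: 256-point Gauss–Legendre × 256-point trapezoid grid
  (machine precision for smooth integrands; sphere values exact to 1e-12).
- Excluded volume: voxel-center counting at 0.02 nm; relative error well
  under 0.5% at protein scale (tested against sphere and two-sphere
  closed forms).
- Half-open distance bins [d, d+Δ); shell membership d ≤ thickness.
- Ellipsoid fit requires ≥ 4 atoms and full-rank gyration tensor; coplanar
  or collinear input raises with the rank reported.
- Zero fictitious bins are flagged undefined (NaN), never infinite ratios.
- Only orthorhombic boxes; triclinic input raises an explicit unsupported
  error. Boxes too small for the requested shell (bounding-sphere test
  2(a_max + d_max) vs the shortest box edge) raise rather than silently
  wrap.
- Blocks: series shorter than n_blocks raise; the last block absorbs the
  remainder.

## Design choices

- **Ellipsoid construction.** The gyration-tensor mapping is this package's
  documented choice among several reasonable "protein as ellipsoid"
  constructions; the ratio normalisation makes shell increments robust to
  it, and the exportable ellipsoid record lets users substitute another.
- **Steiner-first volumes.** The Steiner evaluation is exact for convex
  bodies at t ≥ 0 and O(1) per call; QMC is retained as the independent
  cross-check rather than the workhorse.
- **Boundary waters count for both surfaces.** IBS and NIBS water counts
  are computed independently; a water within 0.55 nm of both surfaces
  contributes to both. The alternative (unique assignment to the nearer
  surface) would couple the two estimates; independence keeps each
  selection's ρ_surf self-contained.
- **Water identity by residue name** ({SOL, HOH, WAT, TIP3, SPC},
  configurable), with the oxygen as the molecule position everywhere.
- **No intermediate caching.** Reruns are deterministic by construction
  (the analysis has no random state), so the pipeline recomputes rather
  than maintaining a checksummed cache; only the fitted ellipsoid is
  persisted, for the reproducibility record.
- **Scale of the validation runs.** The recovery tests use 120-atom
  pseudo-proteins in 4.6 nm boxes over 200 frames — enough for ~0.2%
  relative error on shell counts, which resolves the designed 5–10%
  enhancements at 3σ while keeping the suite desk-scale.

## Known limitations

- Interior signed distances inside the evolute of a strongly anisotropic
  ellipsoid use the symmetric (in-plane) nearest point; distances there can
  be slightly overestimated in magnitude. Irrelevant for solvent positions,
  which are exterior.
- The excluded-volume voxel grid and the SASA point sampling are
  deterministic but resolution-limited; both resolutions are exposed.
- Triclinic boxes, structure repair, protonation and force-field parsing
  are out of scope; radii/charges come from the parameter table.
- η_surf compares each surface against its own bulk-filled reference; it is
  not a decomposition of the whole-shell η (the counting regions overlap at
  patch boundaries and extend only to 0.55 nm).
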