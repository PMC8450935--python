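# afpshell

Hydration-shell density analysis for antifreeze proteins (AFPs) — and for
any solvated protein trajectory where you want to know how much denser the
first water layer is than bulk, and where on the surface that excess sits.

AFPs depress the local freezing point by adsorbing to ice nuclei through a
flat, relatively hydrophobic ice-binding surface (IBS). A recurring
observation is that the water density around the IBS is *lower* than
around the rest of the protein (the NIBS), and that this asymmetry tracks
surface hydrophobicity and antifreeze activity. Quantifying it needs care:
protein surfaces are corrugated, so raw density-vs-distance profiles mix
real physics with geometry. This package implements the
ellipsoid-referenced, fictitious-shell methodology that separates the two:

- the protein is modelled as an **ellipsoid** (gyration-tensor fit,
  aᵢ = √(5λᵢ)), and solvent density ρ(d) is binned by distance d from its
  surface using exact parallel-body (Steiner) volumes;
- **fictitious configurations** — the protein overlaid on bulk-water
  frames with vdW-overlapping waters removed — give the bulk-distributed
  reference ρ_b,fict(d), so the ratio ρ/ρ_b,fict is geometry-free;
- the **whole-shell increment** η = ρ_shell/ρ_bulk − 1 with
  ρ_shell = ⟨N_shell⟩/(⟨V_shell⟩ − ⟨V_ex⟩) (shell = 1 nm parallel body,
  V_ex = solvent-accessible volume, probe 0.14 nm), and the **partial
  molar volume** v = N_A(V_ex − ΔN/ρ_bulk) from the excess shell waters;
- **per-surface increments** η_surf = ρ_surf/ρ_surf^fict − 1, with
  ρ_surf = ⟨N_w⟩/⟨S⟩ counting waters within 0.55 nm of a surface's heavy
  atoms per unit Shrake–Rupley SASA, plus hydrophobic surface fractions
  S_pho/S from the |q| ≤ 0.2 e partial-charge rule;
- a **synthetic generator** (inhomogeneous hard-core point process with
  exactly known intensity) so every estimator is validated against ground
  truth without any MD input.

Inputs: PDB/GRO structures, multi-model PDB or XTC/DCD trajectories, a
vdW-radius/partial-charge parameter table, and a per-protein list of IBS
residues. All lengths are nm internally; outputs are TSV.

## Worked example

Generate a synthetic protein whose shell water density is 10% above bulk,
then analyse it end to end (8 frames keeps this quick; validation runs in
the test suite use 200):

```sh
$ afpshell synthesize --out-dir syn --frames 8 --seed 3 --box 4.6 \
      --atoms 120 --enhancement 0.1
wrote 8-frame synthetic system to syn/ (120 protein atoms)

$ afpshell shell syn/run.yaml --out-dir out
eta = 0.101 +- 0.012, v = 1.35 l/mol

$ afpshell surface syn/run.yaml --out-dir out
IBS: eta_surf = 0.112 (S_pho/S = 0.40)
NIBS: eta_surf = 0.138 (S_pho/S = 0.37)
WP: eta_surf = 0.111 (S_pho/S = 0.39)

$ afpshell profile syn/run.yaml --out-dir out --bin-width 0.1 --d-max 1.2
$ head -5 out/synthetic_profile.tsv
distance_mid  density_real  density_fict  ratio    stderr
0.05          8.11835       7.21631       1.125    0.116179
0.15          21.0727       19.2323       1.09569  0.0742959
0.25          31.4543       28.3166       1.11081  0.0485061
0.35          34.525        31.2924       1.10331  0.0510617
```

Reading the numbers: the whole-shell increment recovers the designed 10%
(η = 0.101 ± 0.012), and v is small because the pseudo-protein is tiny
(v ≈ 0.6022·(V_shell − N_shell/ρ_bulk) l/mol). In the profile, both raw
densities dip near the surface — that is protein geometry, not physics —
while their ratio sits flat at ≈ 1.1 inside the shell and relaxes to ≈ 1.0
beyond 1 nm (the last bins read 1.03 and 0.99). The per-surface increments
land near 0.1 on both half-surfaces, with ±0.02–0.03 errors at 8 frames.
With a real system you would point `run.yaml` at your own
structure/trajectory/bulk files, your force field's radius/charge table,
and the crystallographically assigned IBS residues; `afpshell report`
batches several proteins and adds η-vs-v correlations and
moderate-vs-hyperactive class means.

## Layout

```
src/afpshell/
  structure_io.py    file I/O, data model, parameters, selections
  ellipsoid.py       ellipsoid fit, signed distances, parallel-body volumes
  profiles.py        density profiles, fictitious overlay, ratio, plateau
  shell.py           N_shell, V_ex, eta, partial molar volume, block errors
  surface.py         SASA, hydrophobic fractions, eta_surf
  synthetic.py       ground-truth point-process generator
  pipeline.py        per-protein orchestration, correlations, TSV output
  reference_data.py  published per-protein values (cross-check inputs)
  cli.py             profile / shell / surface / synthesize / report
docs/methods.md      model, assumptions, parameters, limitations
```
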