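# trajcontact

Comparative molecular-interaction analysis of protein conformational
ensembles, built for the question "which specific interactions make a
modified protein more stable than its native counterpart?" — the situation
that arises, for example, when a chemically conjugated insulin analog
(a phenylalanine coupled to the B29 lysine ε-amine) resists heat and
fibrillation better than native insulin and the explanation is sought in
its MD ensemble: an extra T-shaped aromatic π-π contact, an extra backbone
hydrogen bond, and damped terminal fluctuations.

It is aimed at structural-bioinformatics users who have two trajectories of
matched systems (as multi-model PDB files) and want the standard battery of
desk-scale comparisons, each with explicit, configurable geometric criteria:

- **Contact-population maps.** Residues *i, j* are in contact in a frame
  when any pair of their non-hydrogen atoms lies within a cutoff
  (default 4.5 Å, minimum-image when a box is present).  The map
  C ∈ [0,1]^{R×R} holds the fraction of frames with the contact, and
  ΔC = C_variant − C_reference localises interactions gained (+) or
  lost (−) upon modification.  Residues are numbered by chain-concatenated
  serial index (insulin: A1..A21 → 1..21, B1..B30 → 22..51).
- **Hydrogen bonds.** Geometric criteria over N/O donors with attached H
  (attachment = H within 1.2 Å) and N/O acceptors:
  H···A ≤ 2.5 Å, ∠(D–H···A) ≥ 120°, D···A ≤ 3.5 Å.
- **Aromatic π-π interactions.** Ring templates for PHE/TYR/TRP/HIS plus
  user templates for nonstandard residues; a ring pair within 7.0 Å
  center-of-mass distance is classified by the unsigned interplanar angle
  θ: parallel (θ ≤ 30°), T-shaped (θ ≥ 60°), oblique otherwise.
- **Distance distributions.** Per-frame distances between named atoms or
  ring centers of mass, histogrammed on a fixed 0.1 Å grid and normalised
  to Σp = 1, with prominence-based peak detection ("one prominent peak
  near 2 Å").
- **RMSF.** Per-residue root-mean-square fluctuation of Cα (or all heavy
  atoms) about its time-mean position after iterated least-squares (Kabsch)
  superposition; for isotropic jitter of σ per coordinate, RMSF = σ√3.
- **Nonbonded energies.** Pairwise totals E_elec = Σ k_e q_i q_j / r_ij
  (k_e = 332.0636 kcal·Å/mol·e²) and E_vdw = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]
  with Lorentz–Berthelot combining, over a fixed exclusion scheme — a
  self-consistent *comparative* metric between matched systems, not a
  reproduction of a simulation engine's bookkeeping.

A seeded synthetic-trajectory generator (`trajcontact.synthetic`) builds
toy two-chain ensembles in which every one of these observables is designed
in with known ground truth (exact contact schedules, Gaussian-jittered
H-bond and ring geometry, per-residue fluctuation amplitudes), so the whole
pipeline is testable end to end.

## Worked example

The bundled insulin-like comparison: a 51-residue reference and a variant
whose B29 carries an aromatic ring, with a designed T-shaped B29–A19 ring
pair (~5 Å, ~90°), a designed B29(C=O)···A3(H–N) hydrogen bond (~2 Å), a
strengthened B28–A4 contact (population 0.9 vs 0.1) and halved terminal
fluctuations:

```
python analysis/01_simulate.py        # generate both ensembles + config
python analysis/02_compare.py         # full comparison → results/compare/
python analysis/03_parameter_recovery.py
```

The recovery step prints designed vs recovered values:

```
delta_contact_B28_A4   designed    0.8  recovered 0.8000
hbond_peak_A           designed      2  recovered 1.95
ring_com_peak_A        designed      5  recovered 4.95
terminal_rmsf_ratio    designed    0.5  recovered 0.5124
mean_hbonds_reference  designed      0  recovered 0.000
mean_pipi_reference    designed      0  recovered 0.000
mean_hbonds_variant    designed      1  recovered 0.998
mean_pipi_variant      designed      1  recovered 1.000
```

i.e. the contact-population difference is recovered exactly by
construction, both distance distributions are unimodal with peaks within
one 0.1 Å bin of the designed 2 Å / 5 Å values, the variant/reference
terminal RMSF ratio matches the designed σ ratio of 0.5 to ~2 %, and the
variant gains exactly one hydrogen bond and one π-π interaction per frame
(the 0.998 reflects the designed distance jitter occasionally crossing the
D···A criterion).  The comparison summary also reports the energy ordering
E_vdw(variant) = −3.96 < E_vdw(reference) = −0.25 kcal/mol, driven by the
designed attractive ring contact.

The same pipeline is available as a CLI (`trajcontact compare --config …`,
plus `fixture`, `contacts`, `hbonds`, `pipi`, `rmsf`, `energy`
subcommands) for running on real multi-model PDB trajectories.

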