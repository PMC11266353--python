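# Methods

This note documents the models, criteria and numerical choices behind each
analysis stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Trajectory model and residue numbering

A trajectory is a multi-model PDB: the first model defines the topology
(atoms grouped into residues, chains in file order), every further model is
one coordinate frame in Å.  Residues receive a 1-based *serial index* by
occurrence order with chains concatenated; gaps in author numbering do not
create serial gaps.  For an insulin monomer (21-residue A chain followed by
the 30-residue B chain) this yields A1→1, A21→21, B1→22, B30→51, so the
full residue×residue maps span serials 1–51.

Hydrogens are identified from the element column when present; otherwise a
leading-character heuristic on the atom name is used (digits skipped, H/D
means hydrogen) and the decision is logged per file.  Only orthorhombic
CRYST1 boxes are honoured — the angles must be 90° or the box is treated as
absent — because every distance here is a point-pair or point-COM distance
for which the componentwise minimum-image fold is exact in an orthorhombic
cell.  Waters and monatomic ions are stripped on reading by default
(`keep_solvent=True` retains them); HETATM records on protein chains, such
as a chemically modified residue, are always kept.

## Contact populations and ΔC

A residue pair is in contact in a frame iff *any* pair of their
non-hydrogen atoms is within the cutoff (default 4.5 Å); this
heavy-atom-any-pair reading — rather than a residue-COM distance — is what
the population map C averages over frames.  Minimum-image distances are
used exactly when the frame carries a box.  Sequence-adjacent pairs are
included in the matrix (the map shows the full grid); consumers can mask
them for display.  ΔC is the elementwise difference variant − reference,
matched by serial index, with the modified residue matched positionally
(its name may differ).  "Stable partner" reporting uses a population
threshold, default 0.5 (present most of the time).  Frame striding is a
config option, default 1 (every frame counted).

## Hydrogen bonds

PDB input carries no bond records, so donor–hydrogen attachment is
geometric: each hydrogen is assigned to its nearest N/O within 1.2 Å.
Candidate acceptors are all N/O heavy atoms outside the donor's residue.
Acceptance criteria (all configurable) are H···A ≤ 2.5 Å,
∠(D–H···A) ≥ 120°, D···A ≤ 3.5 Å — common geometric conventions chosen
because no single universal threshold set exists; the 2.5 Å H···A bound
comfortably contains the ~2 Å peak such bonds produce.  These defaults are
assumptions and are echoed into every pipeline report.

## Aromatic π-π interactions

Ring templates: PHE/TYR 6-ring (CG, CD1, CD2, CE1, CE2, CZ); TRP 5- and
6-ring; HIS (and HID/HIE/HIP) 5-ring.  Nonstandard aromatic residues — for
instance a lysine–phenylalanine conjugate — are matched by user-supplied
name→atom-name templates.  A residue missing template atoms is skipped
with a warning, not an error, because stripped or coarse models are common.

Ring planes are fit by SVD (normal = smallest principal axis of the
centered ring coordinates) rather than a bond cross product: robust to
thermal ring puckering.  Normal signs are arbitrary, so the interplanar
angle is always folded to [0°, 90°].  A pair of rings from distinct
residues within 7.0 Å COM–COM distance is classified parallel (θ ≤ 30°),
T-shaped (θ ≥ 60°, the CH/π hydrogen-bonding geometry; treated as a single
interaction class) or oblique.  The thresholds are conventions, set so
that a ~5 Å near-perpendicular Phe/Tyr pair classifies as T-shaped;
per-frame π-π counting registers any ring pair within the COM cutoff.

## Distance distributions

Distances are taken between resolved selections: a single named atom
(`chain:resnum:name`) or a ring center of mass (`ring:chain:resnum`,
mass-weighted).  Histograms use a 0.1 Å default bin width with edges
anchored at absolute multiples of the bin width, so binning is independent
of the data minimum and distributions from different systems share a grid.
Probabilities are counts normalised to sum to 1.  Peaks are local maxima
with prominence ≥ 0.05 of probability mass (distributions padded with a
zero bin on each side so boundary maxima are found); "unimodal" means
exactly one peak at that prominence.  No kernel smoothing is applied.

## Superposition and RMSF

Alignment iterates fit-to-mean: every frame is superposed (Kabsch,
closed-form SVD solution with determinant-sign reflection correction) onto
the mean structure of the alignment selection (default: all Cα), the mean
is recomputed, and the cycle repeats until the mean stabilises (tolerance
1e-12 Å on the mean coordinates, cap 500 passes; the per-pass fits are
vectorised over frames).  Iterating to convergence, rather than a fixed
two passes, makes alignment idempotent to numerical precision — the slowly
decaying mode is a global rotation of the whole ensemble, which RMSF does
not feel but coordinates do.

RMSF per residue is √⟨|x − ⟨x⟩|²⟩ of its probe atom about its *time-mean*
position (stable to frame choice, unlike a first-frame reference).  The
default probe is Cα; an all-heavy-atom option combines atoms as the square
root of the mass-weighted mean of per-atom squared fluctuations.  For
isotropic Gaussian jitter of σ per coordinate the expectation is σ√3.
Note a small systematic: re-fitting 6 rigid degrees of freedom to R
jittered residues absorbs ≈ √(1 − 2/R) of the fluctuation (≈ 2 % at
R = 51), and chain-end residues with high fit leverage lose slightly more.
Ratios between matched systems are insensitive to this; absolute
closed-form checks are therefore done on pre-aligned ensembles.

## Nonbonded energies

E_elec = Σ_{i<j} k_e q_i q_j / r_ij with k_e = 332.0636 kcal·Å/(mol·e²)
(the CODATA-derived constant used by AMBER-family codes), and
E_vdw = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] with Lorentz–Berthelot combining
(arithmetic σ, geometric ε).  Sums run over all non-excluded pairs with no
distance cutoff and no 1-4 scaling.  When no bond table is available the
exclusion list is all intra-residue pairs plus the peptide-bridging
backbone pairs (C, O, N, H, CA) of chain-adjacent residues — enough to
remove absurd bonded Coulomb terms without full bond topology.  Applied
identically to both systems, this makes energy *differences* meaningful;
the totals are deliberately not comparable to a simulation engine's
(which would add bonded terms, scaling conventions, PME and solvent).
A non-excluded pair below 0.1 Å raises an error (clash or missing
exclusion).  Parameters come from a TSV table (chain, resnum, atom_name,
q, σ, ε; `*` wildcards; exact rows override wildcards).

## Synthetic ensembles and what passing tests show

The generator builds two-chain peptides from minimal residues (N, H, CA,
C, O, plus an ideal 1.39 Å-radius hexagon where a ring is directed) laid
out on a 9 Å grid so that undirected residues never touch.  Directives
then impose ground truth per frame:

- *Contacts*: the mobile residue is held at a 4.0 Å CA–CA separation from
  its anchor in exactly round(p·F) frames (schedule by seeded shuffle, so
  populations are recovered **exactly**) and at 8.0 Å otherwise.
- *Hydrogen bond*: the mobile partner is rigidly rotated and translated so
  that N–H···O=C is collinear up to a Gaussian angle jitter, with
  H···O ~ N(2.0 Å, 0.15²) by default, approaching the acceptor oxygen on
  the side opposite its carbonyl carbon and spun 90° about the bond axis
  so no reciprocal contact is faked.
- *Ring pair*: the mobile ring is rebuilt at a Gaussian-jittered COM
  distance (default N(5.0, 0.3²) Å) along the anchor ring normal with a
  Gaussian-jittered interplanar angle (default N(90°, 5°)), so COM
  distance and angle equal the draw exactly.
- *Fluctuations*: each residue is rigidly displaced by N(0, σ² I₃) per
  frame (default σ = 0.15 Å; directive-mobile residues are positioned
  after jittering, so their designed geometry is unaffected).
- Optional global rigid-body motion (uniform random rotation + N(0, 2² Å)
  translation) exercises the superposition step.

The bundled insulin-like pair uses the native A/B-chain sequences, gives
the variant a ring-bearing B29 conjugate with the T-shaped B29–A19 ring
pair, the B29→A3 backbone hydrogen bond and a strengthened B28–A4 contact
(0.9 vs 0.1), and halves the fluctuation of the four undirected terminal
residues (A1, A2, B26, B30: σ 0.25 vs 0.5 Å; designed RMSF ratio 0.5).

These fixtures emulate the *statistical structure* of real ensembles —
contact schedules, unimodal interaction-distance distributions, fluctuation
amplitudes — not their physics: there is no solvent, no realistic
side-chain packing, no correlated dynamics, and energies on toy parameters
are only ordering checks.  Passing tests therefore demonstrate that each
analysis recovers known ground truth under controlled conditions, not that
any particular real system shows these features.

## Problem sizes and determinism

Default analysis sizes were chosen so the whole suite and the acceptance
script each run in well under their comfortable desk budget: the paired
comparison uses 51-residue systems (~265 atoms) at 60–2000 frames;
distribution and RMSF closed-form checks use 5000 frames where sampling
error must sit below the stated tolerances (peak within one 0.1 Å bin;
RMSF within 2 %, ratios within 5 %).  All stochastic steps draw from a
single seeded generator, so identical configs and seeds give byte-identical
trajectories, tables and reports.

## Known limitations

- PDB only (no DCD/XTC/TRR, no mmCIF); coordinates quantised to 10⁻³ Å on
  round trip.
- No cation-π, salt-bridge or halogen-bond detection; no energy-based
  H-bond scoring; no B-factor conversion or PCA of fluctuations.
- Energy totals are comparative metrics under a shared exclusion scheme,
  not force-field energies.
- H-bond/π-π thresholds are documented conventions; results near the
  thresholds are sensitive to them by construction.
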