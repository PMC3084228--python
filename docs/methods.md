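# Methods

This note documents the models implemented in `offpipe`, the defaults and
their rationale, what the synthetic fixtures do and do not emulate, and the
numerical choices a user should know before trusting or extending the
results.

## Binding-site representation

Receptors are reduced to C-alpha traces. The **geometric potential** of
residue *i* is the distance-weighted neighbour count
`g_i = Σ_{j≠i, d_ij<d_c} (1 − d_ij/d_c)` with neighbour cutoff `d_c = 10 Å`,
min–max scaled to GP ∈ [0, 100] per structure (an all-equal trace maps to
50). GP is rotation/translation invariant and monotone in burial: core
residues score high, surface residues low. Each residue also carries the
unit vector toward its neighbour centroid (undefined, and flagged NaN, for
isolated residues). This burial score stands in for richer pocket
descriptors used by mature site-comparison servers; it deliberately ignores
sequence conservation and solvent topology.

A **ligand-defined site** is the set of receptor residues with any heavy
atom strictly within 5.0 Å (default, configurable) of any ligand heavy atom.
Hydrogens are ignored throughout site definition because typical inputs are
crystallographic. Site overlap between a reference and predicted site is
normalized by the reference size (`16 shared of 22 → 0.727`).

## Order-independent site alignment

Candidate residue pairs (i ∈ A, j ∈ B) become vertices of a correspondence
graph when their weight

    w(i,j) = S(aa_i, aa_j) / S_max + λ (1 − |GP_i − GP_j| / 100)

exceeds `w_min`; `S` is BLOSUM62, `S_max = 11` its largest diagonal entry,
λ = 1. Edges connect vertices with `|d_A(i,i′) − d_B(j,j′)| ≤ ε = 1.5 Å`
and distinct residues on both sides, so every clique is an injective,
geometrically consistent partial matching. The aligner returns the
maximum-weight clique: exact branch-and-bound when the graph has at most
`exact_limit = 30` vertices (ties broken toward the lexicographically
smallest pair list, for determinism), otherwise greedy seed-and-extend with
32 restarts from the highest-weight seeds (fixed seed). The rigid transform
and RMSD over matched C-alphas come from Kabsch superposition (proper
rotation enforced via the SVD sign correction).

**Choice of `w_min` = 0.8.** For a random residue pair the expected weight
is ≈ 0.62 (chemistry term ≈ −0.05, environment term ≈ 0.67 for uniform GP),
with spread ≈ 0.2. A vertex threshold of 0.4 admits essentially every
GP-compatible random pair, which makes decoy alignments score almost as well
as genuine ones: measured on the screening fixtures, even an exact site copy
then sits only ~8–10 null standard deviations above the decoy background,
and the stringent significance tier (p < 10⁻⁴) becomes unreachable for about
half of random fixtures. Requiring roughly one standard deviation of
positive evidence per pair (0.8) keeps genuine correspondences (an identical
residue pair with a 50-point GP mismatch still qualifies at ≈ 1.03) while
collapsing the random-pair background; the same copy then sits 14–20 null
deviations out. The threshold is a parameter of `AlignParams` and can be
lowered for remote-similarity searches at the cost of a heavier null.

## Extreme-value significance

Screening scores are calibrated against a background of decoy alignments:
GP-preserving residue-label shuffles of the library sites (geometry and GP
profile intact, chemistry destroyed), 200 by default. A Gumbel model
`p(score ≥ s) = 1 − exp(−exp(−(s−μ)/β))` is fitted by maximum likelihood
from a method-of-moments start (`β₀ = s√6/π`, `μ₀ = mean − 0.5772 β₀`);
p-values are clamped to (1e-300, 1]. Hits are tiered at p < 10⁻³
(significant) and p < 10⁻⁴ (stringent), both configurable. The decoy-shuffle
null keeps realistic site geometry, so it is conservative for queries whose
geometry is genuinely rare.

## Pose transfer, interaction score, NDS

Ligand poses move between frames by the site-alignment rigid transform
(alignments map B onto A; the ligand takes the inverse). Local refinement is
rigid-body only (3 translations + 3 rotations, Powell coordinate descent,
displacement capped at 5 Å): a transferred pose is *refined in place*, never
re-docked, and the refined score never exceeds the starting score by
construction. Torsional flexibility is out of scope.

The interaction score is deliberately simple: LJ 12-6 plus Coulomb with a
distance-dependent dielectric ε(r) = 4r and a −1.0 kcal/mol bonus per
N/O–N/O pair within 3.5 Å (distance-only hydrogen-bond criterion, since
poses may lack hydrogens). Its absolute values are not meaningful; the
pipeline only uses it through the **normalized docking score**, the z-score
of a pose against ≥ 20 random rigid placements of the same ligand on the
same receptor. NDS is invariant under any affine recalibration applied
jointly to score and background, which is exactly why it travels across
scoring functions; externally computed score tables can be normalized and
filtered through the same code path. Hits with NDS ≥ 0 (no better than
random) or any receptor–ligand heavy-atom pair closer than 1.5 Å are
removed.

## MM/GBSA

Free energies are assembled end-point style per snapshot and averaged:

    G = E_MM + G_GB + G_SA − T·S,    ΔX = X_complex − X_receptor − X_ligand,
    ΔG_bind = ΔH_bind − TΔS_bind

- **E_MM**: harmonic bonds `k(r−r₀)²` and angles `k(θ−θ₀)²`, Fourier
  torsions `Σ Vn/2 (1 + cos(nφ − φ₀))`, LJ 12-6 (rmin/ε form,
  Lorentz–Berthelot combination) and Coulomb at ε_in = 1 over all
  non-excluded pairs, no distance cutoff (cutoffs belong to MD production,
  not rescoring); 1-2/1-3 pairs excluded, 1-4 pairs scaled by 0.5 (vdW) and
  1/1.2 (electrostatics). The analytic gradient of every term is verified
  against central differences in the test suite.
- **G_GB**: OBC generalized Born. Effective radii use
  Hawkins–Cramer–Truhlar pairwise descreening integrals and the tanh
  rescaling `1/α_i = 1/ρ̃_i − tanh(aΨ − bΨ² + cΨ³)/R_i` with
  (a, b, c) = (1.0, 0.8, 4.85), intrinsic radii from a modified-Bondi-style
  per-element table (H 1.2, C 1.7, N 1.55, O 1.5, S 1.8, P 1.85 Å;
  editable per atom type), radius offset 0.09 Å, zero ionic strength. The
  pair energy is the Still function including self terms; an isolated ion
  with a forced radius reproduces the Born formula exactly.
- **G_SA** = 0.0072 kcal·mol⁻¹·Å⁻² × SASA, with SASA from the LCPO
  (linear combination of pairwise overlaps) approximation, probe 1.4 Å,
  hydrogens at zero area, per-atom areas clamped at zero. LCPO coefficients
  are per-atom-type inputs; the coefficients shipped for the synthetic
  carbon bead, P = (1.00063, −0.99590, −0.03341, 0.00725), were fitted once
  by least squares against Monte-Carlo sphere-sampling areas on a training
  set of random clusters and validated on held-out clusters (≤ 1% total-area
  error; the exact two-body coefficients (1, −1, 0, 0) err by up to 14%
  when triple overlaps occur). The Monte-Carlo sampler ships in the package
  as the independent numerical reference.
- **Entropy**: mass-weighted Hessian by central finite differences of the
  analytic gradient (step 10⁻⁴ Å), up to six near-zero external modes
  removed (a restrained/trapped system keeps all modes), remaining negative
  eigenvalues dropped with a warning. Vibrations use the quantum
  harmonic-oscillator entropy per mode; translation is Sackur–Tetrode at
  1 atm; rotation is the classical rigid rotor (σ = 1; zero for a single
  atom; the linear-molecule formula applies when the smallest principal
  moment vanishes). Temperature defaults to 298 K. Before normal-mode
  analysis each subsystem is minimized without restraints by L-BFGS-B to a
  gradient inf-norm of 10⁻³ kcal·mol⁻¹·Å⁻¹ — the five-stage protocol's
  conjugate-gradient steps converge too slowly to produce Hessian-quality
  minima, so the tighter quasi-Newton pass is used only here. Gas phase
  (ε = 1) is used during this minimization. Entropy can be skipped or
  strided (`entropy_stride`) for cost control; strided runs average the
  entropy over the sampled snapshots only.
- **Single-trajectory convention**: receptor and ligand coordinates are
  sliced from each complex snapshot, so intramolecular terms cancel exactly
  in ΔE_MM; the tests assert term-by-term identity.

The **five-stage restrained minimization** releases positions progressively
— hydrogens; + waters (skipped when absent); + side chains; all atoms with
harmonic restraints k = 4.0 kcal·mol⁻¹·Å⁻² (E = k·d², AMBER convention) on
protein backbone and ligand; unrestrained — using conjugate-gradient steps
(gradient inf-norm tolerance 0.1 kcal·mol⁻¹·Å⁻¹ per stage). The final
unrestrained energy must not exceed the starting energy; intermediate
restrained stages may trade restraint energy for strain.

**Stability diagnostics** operate on ensembles fitted to their first frame
over the backbone selection (default N, CA, C, O; the coarse fixtures use
CA/CB). The receptor passes if max backbone RMSD < 3.0 Å over the window;
the ligand is flagged POCKET_EXIT if its mean heavy-atom RMSD exceeds 4.0 Å
or its centroid strays > 5.0 Å from its first-frame position in more than
half the snapshots. The fit precondition is enforced by checking that
refitting cannot improve any snapshot's backbone RMSD.

A published ensemble-average MM/GBSA table for Nelfinavir and
co-crystallized kinase inhibitors ships as packaged data for bookkeeping
checks: the consistency checker verifies ΔG = ΔH − TΔS per row within
0.01 kcal/mol (printed rounding) and flags the two AKT2 rows, whose printed
values violate the identity by 8–10 kcal/mol — treated as a printing
inconsistency and never used as a numerical target.

## Signed network propagation

Nodes are typed (off_target, intermediate, pathway, effect) and edges signed
(activation, inhibition, dual); duplicate edges with conflicting signs
collapse to dual with a warning. Inhibited off-targets seed "down";
activation preserves a direction, inhibition flips it, dual yields both. The
production algorithm is a monotone fixpoint over the lattice
∅ < {up}, {down} < {up, down}, which terminates on cyclic graphs and equals
brute-force simple-path enumeration on DAGs (the enumeration ships as the
test oracle). Supporting path counts per direction are tallied for the
report. The analysis is purely qualitative — no weights, no kinetics — and
the bundled kinase/pathway edge list is an illustrative transcription of a
published figure's described topology, not ground truth.

## Synthetic fixtures: what they are and are not

`make_synthetic_complex` builds a coarse receptor — CA beads on a spherical
cap around a concave pocket, one inward CB dummy per residue, random residue
identities — and a self-avoiding 1.5 Å-step ligand walk seated in the pocket
mouth with every receptor–ligand heavy-atom distance ≥ 2.5 Å; generation is
bit-reproducible per seed. The emitted parameter block types the beads
(CAB/CBB/LIG), carries small alternating charges and soft LJ parameters, and
records bonds and angles with equilibrium values measured from the generated
geometry, making each fold its own bonded reference state (bead spacing is
far beyond covalent-detection range, hence the explicit topology).
`perturb_ensemble` emulates MD snapshots as i.i.d. Gaussian coordinate noise
plus an optional rigid ligand drift of `k·drift` Å at snapshot *k* — the
pocket-exit scenario.

These fixtures preserve the *geometry and statistics* the pipeline's logic
depends on (pocket concavity, site sizes of ~10–25 residues, realistic CA
spacing, clash distances) but not protein physics: no secondary structure,
no hydrogens, no torsional ligand flexibility, no correlated thermal motion.
Green tests therefore validate the algorithms and their statistical
calibration, not the accuracy of any particular free-energy prediction on
real kinases — reproducing published absolute ΔG values would require
nanosecond explicit-solvent MD on crystal structures, which is outside this
toolkit's scope (it consumes snapshot ensembles; it does not generate
production MD).

Default demo conditions: an 18-residue receptor with an 8-atom ligand
(query site ≈ 10–16 residues), one planted target (rigid site copy with a
single residue mutation, hosted on the query receptor), 30 decoy complexes,
100-alignment EVD background, 10-snapshot ensembles with 0.15 Å noise at
10 ps spacing, entropy every 5th snapshot. Snapshot windows are half-open on
the left, (start, end], so the last 2 ns of an 8 ns run at 10 ps spacing is
exactly 200 frames.

## Numerical choices and degenerate inputs

- PDB dialect: fixed-width v3.3; altLoc other than blank/'A' skipped;
  insertion codes rejected with a line-numbered error; elements from columns
  77–78 with an atom-name fallback. Coordinates are always Å, times ps.
- Kabsch superposition requires ≥ 3 non-collinear pairs (rank check at
  tolerance 1e-8) and enforces det(R) = +1.
- EVD fitting requires ≥ 50 non-constant scores; NDS requires ≥ 20
  non-constant decoy scores.
- All-equal GP traces map to 50; empty ligand-defined sites warn and return
  zero residues; single-residue profiles carry no direction vector.
- The pipeline manifest hash-chains config and every stage output (SHA-256);
  seeds are mandatory config, never wall-clock derived; reruns are
  bit-identical.

## Known limitations

- The geometric potential and the alignment score are this package's own
  definitions, chosen for rotation invariance, burial sensitivity and
  oracle-checkable small cases; scores are not comparable to any external
  site-comparison server.
- The hydrogen-bond criterion is distance-only (no angles); donor/acceptor
  typing is by element.
- GB uses zero ionic strength; salt effects belong to explicit-solvent MD
  setups, which this toolkit does not run.
- The greedy clique search is a heuristic above 30 correspondence vertices;
  exactness is only guaranteed (and tested) below that size.
- Normal-mode entropy assumes a true local minimum of the gas-phase
  potential; snapshots are re-minimized before each analysis, so strided
  entropy averages mix minimized and unminimized information (standard
  practice for end-point methods, but worth remembering).
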