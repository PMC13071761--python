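# Methods

`ptmgate` compares two molecular-dynamics ensembles of an enzyme–regulator
complex — a fully **reduced** state and a **PTM-modified** state (thiol
modifications of cysteines: sulfenylation, S-nitrosylation,
S-glutathionylation, disulfides) — and quantifies how the modification
redistributes collective dynamics, gate conformations, hydrogen-bond
networks, interaction energies, and binding free energies.  This note
records the models, the numerical choices, and what the synthetic validation
data does and does not establish.

## Data model and units

Coordinates are stored in nm internally; Ångström appears only at the
PDB/XYZ file boundary (Å ÷ 10 on read, × 10 on write).  Energies are
kcal/mol; alchemical work samples are in kT with an explicit `kT` parameter
for conversion.  Residue numbering is 1-based and mirrors the topology file
with no renumbering, so literature site labels (e.g. C398) can be used
directly.  Selections accept plain residue indices (resolved in every chain
that contains them, which also covers concatenated straight-through
numbering of a complex) or chain-qualified `"A:33"` entries; results always
carry chain-qualified labels.

## Experiment-plan enumeration

The per-site plan enumerates (cysteine × PTM type) systems plus one reduced
baseline; replicas expand last, so the baseline counts once.  With 11
cysteines and the three thiol PTM types this gives 34 systems, or 102 cases
at three replicas.  The alchemical schedule is the 13-value λ ladder
0.00, 0.05, 0.10, then 0.10 steps to 0.90, 0.95, 1.00, applied to two
decoupling stages (electrostatics first, then van der Waals/masses/bonded),
26 windows in total.  Disulfides are representable as explicit residue pairs
but are not enumerated per single site.

## Superposition and PCA

Rigid-body fits use the quaternion/SVD least-squares solution
(`scipy.spatial.transform.Rotation.align_vectors`), which always returns a
proper rotation.  Ensemble alignment iterates align → recompute mean →
align until the mean moves < 1e-12 nm (typically 2–3 passes); the converged
frame set is unique up to one global rotation, which leaves every covariance
spectrum unchanged.  The alignment reference (mean structure, iterated) is a
package choice: common practice varies between first-frame and mean-structure
references and the difference is absorbed by the iteration.

The comparative PCA concatenates the Cα coordinates of all replicas of both
states after joint alignment, builds one 3m × 3m covariance matrix
(mass-unweighted) and diagonalises it once.  Eigenvalues are clipped at zero
(they can be −1e-16 from rounding); each eigenvector's largest-magnitude
component is made positive so projections are reproducible.  Per-source
projections against these shared eigenvectors make reduced and PTM-modified
occupancies of the collective-motion space directly comparable; centroid
shifts are PTM-minus-reduced means of the projections per group.  Mode
contributions are normalised per-residue displacement magnitudes; the
top-fraction set is the minimal descending-sorted prefix reaching the
requested cumulative fraction, with ties resolved toward the lower residue
index.  Selections with fewer than three atoms cannot be superposed and are
analysed as-is (this is what makes single-residue known-covariance
validation fixtures meaningful).

## Cross-correlation and the redistribution score

DCCM entries are C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over Cα
deviations from the time mean, replicas pooled by concatenation after
per-replica alignment.  Residues with zero fluctuation get 0 off-diagonal
entries (not NaN) and are flagged, keeping fractions defined on degenerate
inputs.

Strong coupling uses strict inequalities at ±0.2.  For each residue,
f⁺ (fraction of partners with C_ij > 0.2) and f⁻ (C_ij < −0.2) are computed
over the n−1 partners; the redistribution score is
(f⁺−f⁻)_PTM − (f⁺−f⁻)_reduced ∈ [−2, 2], paired by residue label across
states.  Positive scores mean net enrichment of correlated over
anti-correlated coupling upon modification.

**A caveat worth stating plainly:** removing overall translation and
rotation before the DCCM is itself a linear filter on the fluctuations.
Subtracting the frame centroid shrinks a pair correlation by roughly
(Σ_j C_ij + Σ_j C_ji)/n, which is material for small systems (≈ 0.08 for a
coupled pair at ρ=0.6 among 40 residues).  Generator-recovery tests
therefore run the DCCM with `fit=False` — the synthetic frames carry no
global motion by construction, so the fit would only inject this artefact —
while real pipelines keep the fit on, where it is needed and where n is
large enough to make the shrinkage negligible.

## Gate states and hydrogen bonds

The gate is defined by a lower residue pair (default 33/37) and an upper
pair (default 241/243).  The distance mode is explicit configuration because
the defining atoms are a modelling choice: `min_sidechain_heavy` (default;
minimum over all lower–upper side-chain heavy-atom pairs) or
`centroid_sidechain`.  Distance distributions are classified by the peaks of
a Gaussian KDE (Silverman bandwidth; peaks are local maxima above 10% of the
global maximum, a noise floor the package chooses since density-estimation
detail is otherwise unspecified): a single peak below 0.4 nm is *closed*,
within [0.4, 0.7] nm *open*, above 0.7 nm *wide_open*; peaks in both the
closed and open regions give *open_closed*.  When peaks fall only in the
open and wide-open bands, the tallest peak decides — a package tie-break.
Band occupancies use half-open intervals [0, 0.4), [0.4, 0.7], (0.7, ∞);
both boundaries belong to the open band, matching "less than 0.4" and
"exceeds 0.7" conventions.

Hydrogen bonds use a donor–acceptor distance ≤ 0.35 nm and a
deviation-from-linearity angle ≤ 30°, measured at the donor between the D→H
and D→A directions (the GROMACS-style vertex convention; the vertex choice
is configurable in the criteria but the angle's donor-vertex form is the
documented default).  Donor/hydrogen covalency can be supplied explicitly;
the pipeline infers it geometrically from the first frame (H within
0.115 nm of an N/O).  Pair occupancy is the fraction of pooled replica
frames with at least one qualifying bond between the two residues in either
direction.

## Free energies

The Bennett acceptance ratio solves
Σ_F f(β(W_F − C)) = Σ_R f(β(W_R + C)) (f the Fermi function) by bisection —
the residual is strictly monotone in C — followed by a Newton polish to
1e-10 kT, then ΔG = C + kT ln(n_F/n_R).  The sample-size correction's sign
was verified by Monte-Carlo on Crooks-consistent Gaussian fixtures with
n_F ≠ n_R; this form is identical to the maximum-likelihood formulation
with ln(n_F/n_R) carried inside the Fermi arguments.  Uncertainty is the
standard asymptotic variance
kT²·[(⟨f²⟩/⟨f⟩²−1)/n_F + (⟨f̂²⟩/⟨f̂⟩²−1)/n_R].  When the mean acceptance
probability on either side underflows (< 1e-15) the two work distributions
share essentially no support: the estimate is still returned but flagged
unconverged with an infinite standard error and a warning.

Window totals add along the schedule with quadrature errors, after checking
that each stage's windows tile [0, 1] without gaps.  RBFE is the
protein-leg total minus the water-leg total (negative = the modification is
more favorable in the protein environment).  The per-PTM-type L1 summary is
the Manhattan distance of the per-site RBFE vector from zero, i.e.
Σ|RBFE| — the reference vector is taken as zero since the magnitude of all
site effects is what the summary is meant to aggregate.

## Interaction energies and flow graphs

Residue-pair nonbonded energies are direct frame-averaged sums over all
atom pairs between the two residues: Coulomb k_e·q_a·q_b/(ε·r) with
k_e = 332.0636 kcal·Å/(mol·e²), plus 12-6 Lennard-Jones with
Lorentz–Berthelot combination.  This deliberately replaces
continuum-solvation (PB/GB) post-processing with transparent uniform-
dielectric pair sums: the quantity feeding the network is a ranking
threshold, not an absolute binding energy, and the direct sum is exactly
reproducible.  No distance cutoff is applied by default (residue pairs are
few); 1–2/1–3/1–4 exclusions do not arise because only inter-residue pairs
are summed.  Pairs with |mean total| strictly above 10 kcal/mol are
"strong"; both attractive and repulsive strong pairs are retained and
labelled, since sign conveys mechanism.

Flow graphs are layered DAGs per gate-state group (alternating open/closed,
closed, open-or-wide-open): regulator-region residues → intermediate enzyme
residues → gate residues.  Intermediates are enzyme residues with a strong
edge to a gate residue, whether or not a regulator region also reaches them
(paths with limited regulator involvement keep their gate edge only).
Edges carry the mean energy and a charge category — like-charged,
oppositely-charged, or polar/uncharged-with-charged — with ASP/GLU negative
and ARG/LYS positive; histidine counts as uncharged by default
(configurable), since its protonation is structure-dependent.

## Synthetic data: what it emulates, and what it does not

The generators supply every analysis stage with inputs whose ground truth
is analytic:

* **Fluctuation ensembles** draw i.i.d. Gaussian residue displacements
  around a helical reference structure.  Couplings are specified at residue
  level and applied identically to x, y, z, so the expected DCCM entry
  equals the recipe correlation exactly; displacements move all atoms of a
  residue rigidly, so Cα statistics see the recipe unchanged.  Sampling uses
  the eigen-decomposition square root, so exactly singular targets (ρ = ±1,
  zero variance) are handled without jitter.  An optional AR(1) coefficient
  adds frame memory but defaults off: all analyses under test except
  occupancy time series are frame-order-invariant.
* **Gate dynamics** are first-order Markov chains with Gaussian emissions
  per state; the chain starts from its stationary distribution (the
  left unit eigenvector), so finite-sample occupancies are unbiased.
  `embed_gate_in_structure` then imposes the series exactly on a designated
  atom pair.
* **Work samples** use the Gaussian pair W_F ~ N(ΔG+σ²/2, σ²),
  W_R ~ N(−ΔG+σ²/2, σ²), which satisfies the Crooks fluctuation relation
  with known ΔG in kT units.
* **State pairs** sample a base and a perturbed correlation recipe; the
  expected redistribution score is computed directly on the two generative
  correlation matrices.

What passing these tests shows: the estimators are correct on data obeying
their own model assumptions, at the sample sizes stated below.  What it
does not show: behaviour on real trajectories with temporal correlation,
anharmonic or multi-basin dynamics, solvent-mediated effects, or
force-field error.  The generators contain no physics — they are oracles
for the analysis code, not for the biology.

## Problem sizes and tolerances used in validation

Monte-Carlo checks use the sizes at which their analytic tolerances are
meaningful: DCCM recovery at 20 000 frames (±0.03, the ~4σ Fisher-z band),
PCA eigenvalue recovery at 50 000 pooled frames (5%), Markov occupancies at
50 000 steps (±0.02), BAR coverage at 10⁵ work samples per direction with
|error| < 3·SE required in ≥ 99% of seeded runs across
ΔG ∈ {−2, 0, 5} kT × σ ∈ {0.5, 1, 2} kT.  Exact identities (plan counts,
trace/eigenvalue identity, occupancy normalisation, Coulomb constant
arithmetic, gate-closure/H-bond correspondence on the coupled fixture) are
asserted to 1e-9 or tighter.  The full suite runs in about half a minute on
one CPU.

## Known limitations

* The headline magnitudes reported for the real complex (PC variance
  percentages, interfacial-energy shifts, per-site RBFE values) require the
  original microsecond-scale ensembles; this package reproduces the
  *methods* and validates them on synthetic ground truth, not those numbers.
* Pair energies are vacuum/uniform-dielectric sums; they rank interactions
  but are not solvated binding energies.
* H-bond donor inference is geometric and assumes resolvable N/O–H
  covalent distances in the first frame.
* The KDE peak classifier is sensitive to bandwidth for series shorter than
  ~100 frames; the pipeline warns below that length.
* No periodic-boundary imaging: input coordinates are assumed whole.
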