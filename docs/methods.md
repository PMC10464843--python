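# Methods

This note records the models, conventions and design choices behind
`tcrforge`, in the order the pipeline runs.

## Clustering and mutation pathways

A cluster is anchored on the CDR3 sequence of a solved TCR-peptide-MHC
complex (the *core*).  A specificity record is a candidate when it shares
chain, V gene, J gene, epitope and CDR3 length with the core and its
Hamming distance from the core is at most 3; no insertions or deletions are
considered.  V/J genes compare on the full allele-resolved string by
default (`allele_level=False` strips the `*NN` suffix); epitope identity is
required at the sequence level, with the MHC allele recorded but not
matched unless requested.  TCRα and TCRβ clusters are built independently —
chain pairing is deliberately ignored.

Membership additionally requires *connectivity*: the candidate must be
reachable from the core through single-substitution steps inside the
candidate set (accretion to a fixed point).  The default `observed` mode
demands that every stepping stone be an observed sequence; `free` mode
admits any candidate within distance 3 regardless of intermediates.

A *mutation pathway* is a distance-monotone chain core → member: each step
is one substitution and the Hamming distance from the core grows by exactly
one per step, so a member at distance *d* is reached in *d* steps through
hybrids of the differing positions.  In `observed` mode intermediates must
be cluster members.  One subtlety follows from the asymmetry between the
two definitions: a sequence can be *connected* to the core only through a
non-monotone walk (up to distance 2, sideways, then on), in which case it
is a member with zero pathways.  This cannot occur in the synthetic
clusters used for validation, which plant every intermediate of at least
one monotone order, and it is surfaced rather than hidden on real data (a
member without pathways simply yields no build orders).

Two pathway counters are exposed because they answer different questions:
`full_pathways` counts distinct core→member step sequences, and
`build_orders` counts unique (template, prefix) model builds after shared
prefixes are deduplicated.  Members, pathways and orders are emitted in
lexicographic order so every downstream artifact is deterministic.

## Surrogate structure modeling

The modeling contract is: substitute exactly one residue, keep every
main-chain heavy atom fixed, then optimize.  The built-in surrogate backend
implements it with an internal ideal-geometry table (bond lengths, angles
and default dihedrals for every side-chain heavy atom, NeRF placement).
The parent's CB is kept when present; side-chain dihedrals are copied from
the parent whenever the four defining atoms exist there under the same
names, so conservative substitutions (Asp→Glu, Gln→Glu, ...) inherit the
parent's chi angles.  Aromatic rings built from internal coordinates close
only approximately; this is irrelevant to the distance- and energy-based
analyses, which never measure ring closure.

Optimization arms mirror the minimized/repacked dichotomy the analyses
compare.  For the surrogate backend, `minimized` is the identity — a
coordinate-restrained minimization holds backbone atoms essentially at
their template positions, and the surrogate has no internal strain to
relax — while `repacked` runs a greedy chi1 grid sweep (30° steps) over
CDR3 residues within 10 Å of the peptide, minimizing a soft clash score
against the peptide.  Failed builds mark their descendants `skipped` and
the run continues (`fail_fast` raises instead).  Models sharing the
template's TCR chain sequences, final CDR3 and chain form one
*non-redundant* group whose numeric properties are averaged when the
non-redundant view is requested.

## Contacts

Contacts are residue pairs between the CDR3 range and the peptide chain
whose minimum heavy-atom distance is below 5 Å; hydrogens are ignored even
if present, matching what crystal structures usually provide.  Main-chain /
side-chain attribution uses the atom pair achieving the minimum distance
(backbone = N, CA, C, O, OXT).  Interaction typing uses residue-interaction-
network style distance rules, with precedence IONIC > HBOND > VDW:

* IONIC — oppositely charged side-chain group atoms (Asp/Glu carboxylate
  vs Lys NZ / Arg guanidinium / His ring nitrogens) within 4.0 Å;
* HBOND — donor and acceptor heavy atoms within 3.5 Å (no angle term,
  since hydrogens are absent);
* VDW — everything else under the 5 Å cutoff.

Per contacting CDR3 residue exactly one pair carries `closest_flag`
(smallest distance, ties broken by lower peptide position).  Four analysis
groups are formed: all pairs, closest pairs, pairs with at least one
side-chain part, and the intersection of the last two — the default slice
for descriptor analyses, because side chains carry the physicochemical
identity of a residue.

## Interface energetics

Energies are computed only over CDR3↔peptide atom pairs (face 1 = CDR3,
face 2 = peptide) and every pairwise contribution is attributed to the
CDR3-side residue, so the per-residue profile over CDR3 positions sums to
the total exactly (checked to 1e-9).  Three presets reproduce the term
taxonomy the analyses need:

| preset | terms |
|---|---|
| `large_patch` | fa_atr, fa_sol, hbond_sr_bb, hbond_lr_bb, hbond_bb_sc, hbond_sc |
| `small_patch` | large_patch minus hbond_sr_bb and hbond_bb_sc |
| `full` | all of the above plus fa_rep (clash penalty) |

The surrogate term forms are simple finite-ranged pair potentials in
arbitrary units: fa_atr is the attractive Lennard-Jones branch
−ε(r_m/r)⁶ capped at 6 Å (ε = 0.1, r_m from per-element radii, flat at −ε
inside contact); fa_rep the corresponding repulsive branch inside r_m;
fa_sol a +0.2 burial penalty per polar-atom pair within 4.5 Å; the hbond
terms a −1.5 well with a cosine switch from 2.6 to 3.5 Å between
donor/acceptor heavy atoms, classed by the backbone flags of donor and
acceptor.  Because CDR3 and peptide are different chains, interface
backbone-backbone bonds are long-range by definition and `hbond_sr_bb` is
identically zero at the interface; the preset identity
small = large − (sr_bb + bb_sc) is exercised through the bb_sc term.
These surrogate values are *not* comparable to Rosetta ref2015 totals —
real score tables can be supplied through the precomputed dialect when
exact energies matter.  All terms vanish beyond 6 Å, so a substitution
farther than 10 Å from every peptide atom provably leaves the interface
energy unchanged.

`dEnergy` is E(child) − E(parent) for models one substitution apart, with
the substituted residue's minimum distance to the peptide recorded from
the child geometry.  Correlation analyses use |dEnergy|, since substitution
scores measure exchangeability, not direction; signed values remain
available.  *Energetically valuable positions* of a template are the
positions attaining the minimal per-residue energy under each preset,
unioned across presets when they disagree (ties within 1e-9 all qualify);
they are computed on the unmodified template.

## Descriptor scales and substitution indices

Each residue carries 47 named scales; a contacting pair carries 94 values
under `cdr3.` / `p.` prefixes.  Kidera factors (KF1-KF10), VHSE1-VHSE8,
Cruciani PP1-PP3, z-scales Z1-Z5 and the five Atchley factors are embedded
from their original publications.  Two families could not be sourced
offline and are deterministic derived stand-ins with the field's names and
property roles, flagged as such in their docstrings: Blos1-Blos10 are
eigenvector scores of the BLOSUM62 matrix (ten orthogonal axes of the
substitution profile, the first tracking hydropathy), and F1-F6 are
principal-component factors of the embedded scale compendium, sign-aligned
so F1 tracks hydrophobicity, F2 secondary structure, F3 bulk and F6
electronic properties.  Both can be overridden with replacement tables.

Scales group by the property they represent (hydrophobicity, steric,
electronic, secondary structure).  The literature assigns some scales to
several groups (Blos1 to three); the package keeps that multi-membership
view (`group_memberships`) and offers a single-group `primary_group` view
(first listing group, else `unassigned`) for partitioned analyses.

Substitution statistics use BLOSUM62 and BLOSUM100 in three index kinds.
The half-bit integer scores (BLA) are the NCBI matrices bundled with
biotite.  Bit-unit scores are derived as SIJ = BLA/2 (exact up to the
published rounding), and target frequencies as QIJ = p_i p_j 2^{SIJ} with
Robinson-Robinson background frequencies, renormalised to sum to one —
reconstructions of, not copies of, the NCBI qij/sij files.  The adjusted
index of a substitution, M[a][b] − (M[a][a] + M[b][b])/2, is zero for
every identity substitution and non-positive for every BLOSUM62 BLA/SIJ
off-diagonal pair (diagonal dominance, verified exhaustively).

## Statistical analyses

Pearson correlations relate adjusted indices and substitution-to-peptide
distances to |dEnergy| per (preset × optimization arm), pooled and per
chain, for all substitutions and the contacting subset; Spearman
correlations relate CDR3-side to peptide-side scales within property
groups, with a Shapiro-Wilk normality test on each group's correlation
distribution.  Cells with n < 3 or zero variance are reported as
not-computable rather than dropped silently.  Multiplicity adjustment
defaults to Bonferroni with m = the number of tests in the run
(Benjamini-Hochberg selectable); the method and m are part of the output —
no attempt is made to reconstruct any external multiplicity universe.

## Machine learning

Per-residue contact energies are discretized into five equal-frequency
classes at the 20/40/60/80 percentiles.  Binning is fitted on the pooled
data before the 70/30 stratified split by default (that order of
operations), with a train-only option; bin edges are returned so the same
bins apply to held-out rows.  Feature selection ranks the 94 descriptors
by repeatedly fitting a 500-tree random forest on the training split and
dropping the least important 10% (mean decrease in impurity), then scores
candidate subset sizes {1..20, 25, 30, 40, 60, 94} by stratified 10-fold
CV accuracy on the training rows; the smallest size within one standard
error of the best wins.  Tree count, elimination step, folds and sizes are
all arguments.  Evaluation on the test split reports accuracy with an
exact binomial 95% CI, Cohen's kappa, the confusion matrix and a McNemar
test against the majority-training-class baseline.  Every fit takes an
explicit seed and is reproducible.

## Synthetic data: what it emulates, what it does not

The generators define the validation conditions and produce their ground
truth by brute force, never by calling the modules under test.

*Repertoires* plant clusters by sampling mutation chains from the core and
adding every intermediate, so each member has at least one monotone
pathway by construction; the manifest's pathway list is an exhaustive
permutation scan.  Decoys violate exactly one named rule (wrong V, wrong
J, wrong length, wrong epitope, distance > 3, disconnected) and the
generator verifies by BFS that they stay outside the cluster.  Sequences
are uniform over the alphabet — real repertoires' positional biases and
VDJ-recombination statistics are not emulated, so passing tests show rule
correctness, not realism.

*Toy complexes* place CDR3 residues on a widely spaced strand (10 Å pitch,
side chains toward the peptide) and tune free-standing peptide residues
opposite their planned partners by bisection until each planned contact is
realized within ±0.2 Å; unplanned pairs stay beyond 6 Å or generation
fails.  Residue pairs are chosen to realize the intended interaction type
(charged pairs for IONIC, hydroxyl-tipped residues for HBOND so the tuned
minimum-distance pair is the donor-acceptor pair, apolar residues for
VDW).  These are controllable geometric probes, not physical loop
conformations.

*Planted energy tables* draw random residue pairs and set the target to a
linear combination of named informative scales plus optional distance term
and Gaussian noise.  Effects apply to standardized scale values (z-scored
over the 20 residues) so one unit of effect means one SD of every scale.
Small per-row feature noise breaks exact collinearity between descriptor
columns.  The default informative set is five hydrophobicity-group scales
chosen to be mutually non-collinear over the 20 residues (pairwise
|r| < 0.7): amino-acid scales within one property family are heavily
aliased (|r| up to 0.96), and demanding that feature selection recover a
planted scale whose near-duplicate is also in the table is statistically
ill-posed.  Recovery of the planted set into RFE's top ten, and test
accuracy well above the 0.2 chance level, are demonstrated at the fixture's
reference seed; impurity-based rankings still shuffle aliased neighbors,
so the recovered *signal* is checked as hydrophobic (top features belong
to, or strongly correlate with, the hydrophobicity group) rather than as
an exact name match beyond the planted five.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
200 planted repertoires (≤ 20 candidates each) for the clustering oracle,
100 randomized toy complexes for the contact oracle, 10 complexes for the
energy identities, 200-row planted tables for correlation recovery, and
the 500-row descriptor-energy fixture (300-tree forests, 5-fold CV) for
the machine-learning checks.  The end-to-end acceptance run builds all
models for two toy templates with eight-member clusters under both
optimization arms.

## Known limitations

Surrogate energies are relative, not thermodynamic; only chi1 is swept in
repacking; ring geometry is approximate; backbone flexibility, CDR1/CDR2
contacts, and CDR3-MHC interactions are out of scope.  The Blos and F
scale families are derived stand-ins (above).  mmCIF input is not
supported, and CDR3 boundaries come from annotation, never from structure
parsing.
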