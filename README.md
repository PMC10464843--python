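# tcrforge

Template-anchored modeling of T-cell receptor CDR3 loops in TCR-peptide-MHC
complexes, and analysis of the CDR3-peptide complementarity features that
emerge from it.

## The problem

T cells recognize infected cells when the T-cell receptor (TCR) binds a
peptide presented by an MHC molecule.  Databases such as VDJdb hold many
thousands of TCR sequences with experimentally known peptide specificity,
but only a few hundred solved TCR-peptide-MHC structures exist.  Because
one to three amino-acid substitutions in the hypervariable CDR3 loop rarely
change specificity, a solved structure can serve as a template for modeling
the structures of closely related database sequences.

`tcrforge` implements that pipeline for structural immunologists:

1. **Clustering** — each solved structure's CDR3 is the *core* of a cluster;
   database records join if they share chain, V gene, J gene, epitope and
   CDR3 length, lie within Hamming distance 3 of the core, and are reachable
   from it through single-substitution steps (no indels).
2. **Mutation pathways** — for every member, all distance-monotone chains
   core → member are enumerated; each chain step is one substitution, so a
   member at distance *d* is built through *d* intermediate models.  Shared
   pathway prefixes are built once.
3. **Modeling** — a pluggable backend applies one substitution per step
   while keeping all main-chain heavy atoms fixed.  The built-in surrogate
   backend rebuilds side chains from an ideal-geometry table (dihedrals
   copied from the parent where atom names coincide) and offers two
   optimization arms: `minimized` (backbone-restrained; a no-op for the
   surrogate) and `repacked` (greedy chi1 sweep of CDR3/peptide residues
   within 10 Å).  An external Rosetta-style tool can be plugged in through
   the same contract; precomputed energy tables are also accepted.
4. **Contacts** — CDR3-peptide residue pairs closer than 5 Å (heavy-atom
   minimum distance), attributed to main/side chains and typed
   IONIC > HBOND > VDW by distance rules, then organized into four analysis
   groups (all, closest, side-chain, closest+side-chain).
5. **Energetics** — CDR3↔peptide interface energies under three term
   presets (`full`, `large_patch`, `small_patch`, mirroring the Rosetta
   term taxonomy), per-residue decomposition, energetically valuable
   position calling, and `dEnergy` — the energy change caused by each
   single substitution.
6. **Descriptors & statistics** — 47 amino-acid scales per residue
   (Kidera, VHSE, z-scales, Cruciani, Atchley, plus substitution-profile
   and factor scales), the adjusted substitution index
   `M[a][b] − (M[a][a] + M[b][b])/2` for BLOSUM62/BLOSUM100 in three index
   kinds, and Pearson/Spearman correlation analyses of indices, distances
   and descriptor pairs with Shapiro-Wilk group tests and multiplicity
   adjustment.
7. **Machine learning** — per-residue contact energies discretized into 5
   quantile classes, recursive feature elimination over the 94 pair
   descriptors, and a random-forest classifier evaluated with a confusion
   matrix, exact-binomial accuracy CI, Cohen's kappa and a McNemar test.

A first-class synthetic-data module generates planted repertoires, toy 3D
complexes with controllable contact geometry, and descriptor-energy tables
with known ground truth, so the whole pipeline is testable offline.

## Worked example

```python
import tcrforge as tf
from tcrforge import synthetic_data as sd

data = sd.generate_toy_complex(sd.ToyComplexSpec(
    contacts=((3, 2, 2.9, "IONIC"), (5, 5, 3.2, "HBOND"), (7, 8, 4.2, "VDW")),
    seed=1))
print("CDR3:", data.cdr3_sequence, " peptide:", data.peptide_sequence)
for p in tf.find_contacts(data.structure, "C", (1, 11), "P"):
    print(f"  CDR3 {p.cdr3_residue}{p.cdr3_position} - peptide "
          f"{p.peptide_residue}{p.peptide_position}: {p.interaction_type.value}, "
          f"{p.cdr3_part.value}/{p.peptide_part.value}, {p.min_distance:.2f} A")

e = tf.interface_energy(data.structure, "C", (1, 11), "P", "small_patch")
child = tf.surrogate_mutate(data.structure, "C", 3, "A")
e2 = tf.interface_energy(child, "C", (1, 11), "P", "small_patch", "child")
de = tf.denergy(e, e2, (3, "E", "A"), 4.0)
print(f"small-patch interface energy: {e.total:.3f}")
print(f"dEnergy of E3A: {de.value:+.3f}")
```

prints

```
CDR3: GLESSPIAGLV  peptide: SKPFYGLVS
  CDR3 E3 - peptide K2: IONIC, side_chain/side_chain, 2.90 A
  CDR3 S5 - peptide Y5: HBOND, side_chain/side_chain, 3.20 A
  CDR3 I7 - peptide V8: VDW, side_chain/side_chain, 4.20 A
small-patch interface energy: -1.026
dEnergy of E3A: +0.510
```

The toy complex realizes its planned salt bridge (Glu3-Lys2), hydrogen bond
(Ser5-Tyr5) and van der Waals contact (Ile7-Val8) at the requested
distances.  Replacing the glutamate with alanine removes the salt bridge,
and the interface energy rises by 0.51 surrogate units — a positive
`dEnergy` means the substitution weakened the CDR3-peptide interface.

The same stages are available as a shell pipeline:

```
tcrforge simulate --what repertoire --seed 3 --out rep/
tcrforge cluster  --records rep/records.tsv --templates templates.yaml --out clusters.tsv
tcrforge pathways --records rep/records.tsv --templates templates.yaml --out pathways.tsv
tcrforge model    --pathways pathways.tsv --templates templates.yaml --store models/
tcrforge contacts --templates templates.yaml --out contacts.tsv
tcrforge denergy  --manifest models/manifest.tsv --templates templates.yaml --out denergy.tsv
tcrforge stats    --denergy denergy.tsv --analysis distance --out stats.tsv
tcrforge ml       --features features.tsv --seed 1 --out ml_report.json
```

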