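# idpensemble

Ensemble-based assessment of intrinsic protein disorder.

## The problem

An intrinsically disordered protein (IDP) has no single well-folded
structure, so asking "what is its structure?" is the wrong question — the
right one is "how heterogeneous is its ensemble of plausible structures?".
Given many independent structure models of one protein — AlphaFold2
predictions run with different seeds, or snapshots from a molecular dynamics
trajectory exported as PDB frames — two signatures separate disordered from
well-folded proteins:

1. **Pairwise heterogeneity.** After optimal rigid superposition (Kabsch),
   models of a folded protein agree to "atomic resolution"
   (RMSD well below 1 Å between any pair), while models of an IDP deviate by
   several Å from each other. The all-pairs RMSD matrix can be rendered as a
   neighbor-joining tree whose branch lengths make the heterogeneity visible
   at a glance.
2. **Contact persistency.** Define the residue-residue distance
   `D_ij` as the shortest distance between any non-hydrogen atoms of
   residues *i* and *j*, and a binary contact `A_ij = 1` iff `D_ij < 3.5 Å`.
   Summing the contact maps over all *N* ensemble members gives a weighted
   residue interaction network (RIN); the *persistency* of an edge is
   `w_ij / N`. In a folded protein most non-backbone contacts are
   *persistent* (present in > 75 % of members); in an IDP they are
   *transient* (present in < 25 %).

Complementary tracks — the radius of gyration `R_gyr` (median ± IQR across
members), AlphaFold's per-residue pLDDT confidence (read from the B-factor
column; `1 − pLDDT/100` is a per-residue disorder proxy) and the PAE matrix
(checked for concordance with the ensemble-mean distance map) — round out
the picture. `assess_disorder` combines these into an explicit, numeric
verdict: **disordered-like** (mean RMSD ≥ 5 Å and transient-majority
contacts), **ordered-like** (mean RMSD ≤ 1 Å and persistent-majority
contacts), or **indeterminate**. All thresholds are configurable and echoed
in every report.

Because real inputs at full strength (thousands of AF2 models,
hundreds-of-ns MD) are far beyond desk scale, the package ships a
seed-deterministic synthetic-ensemble generator that emulates the relevant
statistics: tight "ordered" ensembles, heterogeneous "disordered" ensembles
of independent self-avoiding walks, ensembles with contact frequencies
planted exactly, C2-symmetric homodimers, and pLDDT-like confidence tracks.

## Worked example

```python
from idpensemble import (assess_disorder, neighbor_joining,
                         pairwise_rmsd_matrix, write_newick)
from idpensemble.synthetic_ensembles import (disordered_ensemble,
                                             make_reference_chain,
                                             ordered_ensemble)

# a well-folded archetype: compact reference + 0.2 Å coordinate noise
ref = make_reference_chain(100, compactness=0.5, seed=1)
folded = ordered_ensemble(ref, sigma=0.2, n_members=20, seed=2)
print(assess_disorder(folded).report())

# an IDP archetype: 20 independent self-avoiding walks
idp = disordered_ensemble(n_residues=100, n_members=20, seed=3)
print(assess_disorder(idp).report())
```

prints (numbers are what the code produced for these seeds):

```
Ensemble disorder assessment (20 members)
  verdict: ordered-like
  mean pairwise RMSD: 0.480 ± 0.021 Å
  R_gyr (median ± IQR): 18.625 ± 0.021 Å
  non-backbone edges: transient 10.0%, persistent 68.0%
  mean pLDDT: 90.00
  ...
Ensemble disorder assessment (20 members)
  verdict: disordered-like
  mean pairwise RMSD: 18.583 ± 3.211 Å
  R_gyr (median ± IQR): 21.334 ± 5.632 Å
  non-backbone edges: transient 81.8%, persistent 0.0%
  ...
```

The folded ensemble sits at atomic-resolution agreement with
persistent-majority contacts; the disordered one deviates by ~18 Å between
members with transient-majority contacts. The same analyses are available
from the shell:

```sh
idpensemble simulate --mode disordered --n-residues 100 --n-members 20 \
    --seed 3 --out fixtures/idp
idpensemble rmsd fixtures/idp --out results/rmsd     # matrix, NJ tree, R_gyr
idpensemble rin fixtures/idp --out results/rin       # weighted RIN + classes
idpensemble assess fixtures/idp --out results/assess # combined verdict
```

Real AF2 models work the same way: point the commands at a directory of PDB
files (pLDDT in the B-factor column); pass `--no-plddt-in-bfactor` for MD
frames whose B-factors are not confidences.

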