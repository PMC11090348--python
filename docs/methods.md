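# Methods

## The protocol

`idpensemble` operationalizes a simple observation: the structural ensemble
of an intrinsically disordered protein (IDP) is heterogeneous, that of a
well-folded protein is consistent. The unit of analysis is a
`StructureEnsemble` — N structure models sharing one residue layout — and
the protocol measures four things on it:

1. **Pairwise superposition RMSD.** All models share one sequence, so the
   1:1 residue correspondence is fixed and the minimal RMSD over rigid
   motions has the closed-form Kabsch solution (optimal translation =
   centroid match; optimal proper rotation from the SVD of the covariance,
   computed via `scipy`'s `Rotation.align_vectors`). No structural-alignment
   search is performed — fragment-based aligners solve a correspondence
   problem this pipeline does not have. The residual is evaluated
   explicitly after applying the optimal rotation rather than taken from
   the library's root-sum-square output, which loses ~1e-7 Å to
   cancellation and would blur the "identical up to rigid motion" case.
   Default atom set is Cα (the convention in which sub-Å "atomic
   resolution" agreement is usually quoted); all-heavy-atom RMSD is an
   option. For multi-chain models (homodimers) all chain bijections between
   equal-length chains are enumerated — identity and swap for a dimer — and
   the minimum is reported with the achieving mapping.

2. **Neighbor-joining tree of the RMSD matrix.** The Saitou–Nei algorithm
   with the Studier–Keppler Q-criterion, which reconstructs additive
   matrices exactly. RMSD matrices are not additive, so two conventions are
   fixed for reproducibility: ties in the Q-minimization break toward the
   lexicographically smallest label pair (internal nodes inherit the
   smallest leaf label beneath them), and a negative limb length is clamped
   to zero with the deficit moved to its sibling limb, preserving the
   pair's summed length. Trees are left unrooted (final trifurcation as the
   root node) and serialized as Newick with 6 significant digits. The
   `cophenetic_check` utility reports the maximum |tree path − matrix
   entry| so a user can judge how faithful the rendering is.

3. **Weighted residue interaction network (RIN).** Residue-residue distance
   `D_ij` = shortest distance over all non-hydrogen atom pairs; contact iff
   `D_ij < 3.5 Å`, strictly — "less than" is read literally, and the
   measure-zero boundary is pinned by tests. Summing binary contact maps
   over members gives edge weights `w_ij ∈ [1, N]`; persistency `w/N`
   classifies edges as persistent (> 0.75), transient (< 0.25) or medium.
   Both thresholds are strict inequalities (the boundary value 0.75 is
   medium) and configurable. Backbone edges — |Δ residue index| = 1 within
   a chain, i.e. peptide-bond neighbors whose contacts persist trivially —
   are reported separately; summary statistics are given with and without
   them, since conventions differ on whether "total edges" includes them.
   Residue-class interaction frequencies (aromatic = {His, Tyr, Phe}, with
   Trp addable by flag; Gly; charged = {Asp, Glu, Arg, Lys}; Gly+His — His
   deliberately counts in two groups) are computed per member as the number
   of contacts incident to a class residue, counting an edge once per
   class-member endpoint, and summarized as median ± IQR across members.

4. **Confidence profiles.** Per-residue pLDDT is read from the B-factor
   column (AF2 writes one value per residue, copied to every atom; this is
   verified to 1e-3 and the Cα value used if atoms disagree). The sd track
   uses the population convention (divide by N). The profile-consistency
   score is the median over residues of the sd track. `1 − pLDDT/100` maps
   the mean track to a [0, 1] disorder proxy. Pairwise Pearson correlations
   between disorder tracks are summarized as median ± IQR; a constant track
   yields a missing (NaN) entry rather than a fabricated zero. MD frames,
   whose B-factors mean something else, must be loaded with
   `plddt_in_bfactor=False`, which flags confidence statistics unavailable
   instead of producing nonsense. PAE matrices (asymmetric by definition)
   are symmetrized as `(P_ij + P_ji)/2` and correlated against the
   ensemble-mean distance map over the upper triangle with |i − j| ≥ 2.

## The verdict

The source analyses this package systematizes reach their
ordered/disordered conclusion narratively; `assess_disorder` makes the
decision rule explicit and configurable:

* **disordered-like**: mean pairwise RMSD ≥ `rmsd_hi` (default 5 Å) and
  non-backbone transient fraction ≥ `frac_hi` (default 0.5);
* **ordered-like**: mean pairwise RMSD ≤ `rmsd_lo` (default 1 Å) and
  non-backbone persistent fraction ≥ `frac_hi`;
* **indeterminate** otherwise.

The defaults separate the two regimes with wide margin — folded ensembles
sit near 0.5 Å with persistent-dominated networks, disordered ones at
several Å with ≥ 70 % transient edges — and every report echoes the
thresholds used, labeled as a numeric operationalization. Verdicts on fewer
than 10 members trigger a warning.

## Synthetic ensembles

The generator produces the statistical signatures of real ensembles with a
deliberately minimal geometry: a Cα trace with a fixed 3.8 Å virtual bond
(the observed Cα–Cα spacing in proteins), hard excluded volume of radius
2.0 Å enforced by rejection sampling, and one sidechain-proxy heavy atom
per residue at a fixed 1.5 Å offset — the smallest addition that makes
"shortest heavy-atom distance" differ from the Cα distance. Residue names
are drawn uniformly from the 20 standard amino acids under a sub-seed, so
residue-class statistics are exercised without modeling any particular
composition.

* **Reference chain**: self-avoiding walk; an optional one-sided harmonic
  penalty (`exp(-c · max(0, R_gyr − target)²)`, target `2.5 · n^{1/3}` Å)
  biases growth toward compact conformations; the target relaxes 5 % per
  restart so long chains cannot dead-end forever. Proxies of spatially
  neighboring residues (Cα 4.8–6.3 Å apart, non-adjacent in sequence) are
  greedily paired to point at each other, landing 1.8–3.3 Å apart: solid
  contacts well inside the cutoff, emulating a packed core whose contacts
  survive small coordinate noise.
* **Ordered mode**: reference + i.i.d. Gaussian coordinate noise (default
  σ = 0.2 Å, which yields ~0.5 Å mean pairwise Cα RMSD) + a random rigid
  motion per member, so superposition is always exercised.
* **Disordered mode**: every member an independent self-avoiding walk.
  For 100-residue chains this gives mean pairwise RMSDs well above 5 Å and
  transient-dominated RINs — stronger heterogeneity than a real IDP
  ensemble, which retains local correlations; passing tests therefore
  demonstrate separation of the archetypes, not calibration against any
  particular protein.
* **Planted persistency**: an extended zigzag backbone with no contacts at
  all; a chosen pair's proxies are parked exactly 3.0 Å apart on a rail
  5 Å off the backbone (one rail per pair, 8 Å apart) in exactly
  `round(f·N)` members (banker's rounding, so recovery is exact rather
  than stochastic) and > 6 Å apart otherwise. A post-construction audit
  recomputes every member's contact map and fails loudly if an unplanned
  contact appeared.
* **Dimer mode**: each chain a closed ring (circumference n·3.8 Å) with
  outward proxies; chain B is chain A rotated 180° about the x axis
  (exact C2 symmetry) with the rings stacked 6 Å apart, plus per-member
  noise. Inter-chain contacts can be planted the same way.
* **Confidence tracks**: `clip(base + N(0, noise), 0, 100)` per member and
  residue, constant across a residue's atoms, as AF2 writes them.

All generators are driven by `numpy.random.default_rng(seed)` and are
bitwise deterministic for a fixed configuration.

What the generator does *not* emulate: Ramachandran statistics, sidechain
rotamers, secondary structure, realistic contact-distance distributions, or
the correlated fluctuations of a real trajectory. Results on synthetic
ensembles validate the machinery and the protocol's discriminative logic,
not any claim about a specific protein.

## Numerical choices and conventions

* Distance-map computation exploits residue-contiguous atom storage: two
  `minimum.reduceat` passes over the atom distance matrix, checked exactly
  against an exhaustive double loop in the tests.
* Quantiles use linear interpolation (`numpy.percentile`); IQR = Q3 − Q1.
  Mean ± sd and median ± IQR are both always reported, since the field
  mixes the two conventions.
* Persistency histograms use numpy's half-open bins with the last bin
  closed, so persistency 1.0 lands in the final bin.
* PDB I/O: parsing via Biopython (first-seen highest-occupancy altloc;
  hydrogen detection by element column with an atom-name fallback, since
  MD tools often omit elements; waters and non-amino-acid HETATM dropped;
  histidine protonation-state names HSE/HSD/HSP/HIE/HID/HIP normalized to
  HIS); writing via a fixed-width emitter with confidences in the B-factor
  column. Round trips preserve coordinates to the format's 1e-3 Å.
* Layout identity is the exact (chain, index, insertion code, name) tuple
  sequence; mismatched ensembles are an error naming the offending file,
  never silently realigned.
* The random reference model for RMSD profiles defaults to a fixed,
  documented seed so unseeded reports are still reproducible.

## Problem sizes

Tests and the acceptance script run the protocol at 100 residues ×
20 members × 20 seeds for the separability check, N = 200 members for
planted-persistency recovery, and 100 random additive matrices (4–8 leaves)
for neighbor joining — sizes chosen so the full suite completes in well
under a minute per pillar while leaving each statistical claim comfortably
outside its noise floor.

## Known limitations

* The verdict thresholds are an explicit extrapolation of a narrative
  judgement; borderline ensembles (e.g. partially disordered proteins,
  molten globules) will land in *indeterminate* by design.
* No flexible or partial alignment: constructs with different sequences or
  truncations cannot be compared.
* TM-score, per-residue RMSF, secondary-structure content and
  network-centrality analyses are out of scope.
* mmCIF input, ligands and metal sites are not parsed.
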