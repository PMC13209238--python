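# Methods

This note documents the models, conventions and numerical choices behind
`kinsel`, and what the synthetic-data generators do and do not emulate.

## Binding sites, superposition and site RMSD

A binding site is defined per chain as every residue with at least one
heavy atom within a cutoff (default 5.0 Å) of any heavy atom of that
chain's co-crystallized ligand. Hydrogens are ignored throughout the
structural comparisons. On PDB input, waters, buffer components,
cryoprotectants and monoatomic ions are stripped; all carbon-containing
HETATM groups are ligand candidates and the largest one is taken as the
reference ligand unless a HET code is configured per chain. Alternate
locations are collapsed to the highest-occupancy conformer (ties resolved
toward altloc "A"). Residues are identified by (chain, author residue
number, insertion code), preserved verbatim.

Because site membership varies slightly between conformers, ensemble
comparisons use the **consensus site**: the union of the per-structure
5 Å residue sets. Each pairwise RMSD is then restricted to the site heavy
atoms resolved in both members of the pair, matched by (residue id, atom
name). All chains are first Kabsch least-squares superposed (SVD with a
determinant correction, proper rotations only) onto a single reference —
the chain with the most resolved site heavy atoms, ties to the smallest
id — and all pairwise RMSDs are computed in that one frame *without*
per-pair re-fitting. A shared frame keeps the matrix a coherent geometric
object (per-pair re-fitting can violate the triangle inequality more
severely and makes entries incomparable); the choice is a convention,
documented here because either variant is defensible.

Superposition requires at least three non-collinear atom pairs; collinear
selections are rejected (the rotation about the line is undetermined).

## Clustering and representative selection

The site-RMSD matrix is clustered by hierarchical agglomeration under
**complete linkage**, so each merge height equals the maximum pairwise
distance between the merged groups and heights are monotone
non-decreasing. The flat partition is a dendrogram cut at a configured
cluster count k; when k is not given it is chosen by maximum mean
silhouette width over k ∈ [2, 8] (ties to the smaller k), which is
reproducible and unattended. Cluster indices are renumbered by first
appearance in label order so output never depends on library-internal
ordering.

Each cluster contributes one to three representatives:

1. the **medoid** (minimum sum of within-cluster distances);
2. +1 if the cluster holds ≥ 25% of all structures (population);
3. +1 if its mean within-cluster RMSD exceeds the across-cluster median
   of that quantity (dispersion);

capped at 3 and at the cluster size. Extras are picked greedily to
maximize their minimum distance to the already-selected representatives
(max-min coverage). All ties break toward the lexicographically smallest
structure id, making selection deterministic.

The docking-fidelity filter consumes a table of re-docking pose
deviations (Å) for candidate conformations — the deviation of the
re-docked crystallographic ligand from its crystal pose, supplied as
input, never computed here. A conformation passes at deviation ≤ 2.0 Å
(configurable), the standard docking-fidelity threshold. A failing
representative is replaced by the nearest same-cluster passing structure;
if the entire cluster fails, the original is kept and flagged, with a
warning. This pass/fail rule is a declared stand-in for published
ligand-binding-index scores whose exact formula is not reproduced here.

Classical (Torgerson) MDS is used for visualization only:
eigendecomposition of the double-centred squared-distance matrix, top
coordinates by eigenvalue, zero-padding with a warning when fewer
positive eigenvalues exist than requested dimensions.

## Activity labels and screening metrics

Activity labels follow fixed assay thresholds: active at pChEMBL > 7 or
standard value ≤ 100 nM; inactive at pChEMBL ≤ 5.5 or ≥ 10 µM; unknown in
between. When the two sources give opposite decisive labels the curated
pChEMBL wins and the conflict is logged. Unknown-labelled ligands are
excluded from all metrics.

Scores are lower-is-better everywhere (docking convention). When a score
table carries multiple poses, the best pose per (ligand, conformer,
kinase) is the minimum *total* score, and component metrics use that same
pose's components — pose selection is never per-component.

* **ROC AUC** uses the midrank (Mann–Whitney) convention: the probability
  that a random active outranks a random inactive, ties counting ½.
* **eROCE** is the mean over actives of exp(−α·FPRᵢ), where FPRᵢ is the
  fraction of inactives ranked strictly ahead of active i (ties ½). The
  default α = 20 concentrates the weight on roughly the first 5% of the
  list, comparable in emphasis to BEDROC at the same α; α is recorded in
  every report.
* **EF(f)** uses a top set of ceil(f·N) ligands (ceil, documented, so the
  top set is never empty); boundary ties are resolved by stable input
  order.
* **Cutoff metrics** report confusion counts and precision/recall/F1 at
  fractions {0.2, 0.5, 1, 2, 5, 10}%, with F1 defined as 0 when
  degenerate. Ensemble aggregation sums counts across conformers and
  recomputes the ratios from the pooled counts.

Conformer prioritization keeps conformers with AUC ≥ 0.70 **and** strong
early enrichment, operationalized scale-freely as eROCE and EF1% both at
or above their ensemble medians.

## Relative-rank selectivity

Per kinase, scores are ranked within each selected conformer (midranks),
normalized by ligand count, combined across conformers by the mean of
per-conformer normalized ranks (default; a best-rank alternative is
available by configuration and recorded in the hit-list provenance), and
re-ranked so the final consensus is itself a normalized rank in (0, 1].
The relative rank RR = R_A − R_B is antisymmetric in the kinase roles and
linear over ligand sets; negative values mean preferential kinase-A
ranking. RR is a relative prioritization metric within one screened
chemical space — it is deliberately never converted to a binding
free-energy or ΔIC₅₀-style selectivity claim.

Hit prioritization retains the kinase-A top fraction (default 5%,
ceil(f·N) ligands), drops RR > 0 (default cutoff), then drops
|RR| < 0.05 (default separation margin) as sub-5-percentile noise
unlikely to reflect meaningful separation; hits are ordered by RR, then
kinase-A rank, then ligand id, making the output invariant to input
order. All filter parameters are recorded in the output.

Concordance between isoform rankings uses Spearman ρ and tie-corrected
Kendall τ-b (midranks introduce ties, so the b variant is the right one)
with large-sample p-values, plus mean/SD/skew of the percentile
differences R_B − R_A. The paired component comparison (e.g. vdW and
electrostatic terms of shared actives across isoforms) is a two-sided
Wilcoxon signed-rank test: zero differences are dropped (Wilcoxon's
original convention), the exact null distribution is used for n ≤ 25 and
the normal approximation with continuity correction above that, and
significance is judged at the Bonferroni-adjusted level α/m (0.025 for
the default two comparisons).

Drug-likeness flags (Lipinski ≤ 1 violation of MW ≤ 500 / logP ≤ 5 /
HBD ≤ 5 / HBA ≤ 10; Veber RotB ≤ 10 and TPSA ≤ 140; Ghose windows on MW,
logP, molar refractivity and atom count) are evaluated on *supplied*
descriptor columns. Descriptors are inputs, not computed from structures,
which keeps heavy cheminformatics dependencies out of the core; a missing
descriptor makes the affected flag indeterminate, never a failure.

## Interaction fingerprints

Fingerprint bits are (canonical position, interaction type) pairs on the
standard 85-position kinase binding-site nomenclature, supplied as a
(structure, residue) → label table. Geometric criteria (all configurable):

| interaction  | criterion (defaults) |
|--------------|----------------------|
| hydrogen bond | donor–acceptor heavy atoms ≤ 3.5 Å; D–H···A ≥ 120° only when an explicit H is present on the donor |
| hydrophobic  | apolar C···C ≤ 4.5 Å |
| aromatic     | ring centroids ≤ 5.5 Å |
| ionic        | opposite formal charges ≤ 4.0 Å |

These defaults stand in for the unpublished defaults of commercial
fingerprinting GUIs; they are declared, not reconstructed. Protein
donor/acceptor/charge/apolar typing comes from a small built-in
per-residue table (backbone N donor, backbone O acceptor, standard
side-chain patterns); ligand typing uses elements plus supplied formal
charges and ring definitions. There is deliberately no general chemical
perception engine. Two conventions matter downstream: atoms with a
non-zero formal charge participate only in the ionic bit (a salt bridge
is not double-counted as a hydrogen bond), and a contact at a residue
missing from the position map is recorded under a sentinel `unmapped`
label with a warning, never silently dropped. Water-mediated hydrogen
bonds are out of scope (waters are stripped on read), and π-stacking is
not split into face/edge subtypes.

The hinge motif is positive iff hydrogen-bond bits are present at both
hinge.46 and hinge.48 — the canonical double backbone hydrogen bond that
anchors ATP-competitive inhibitors. Bit enrichment between actives and
inactives reports exact frequencies, their difference, two-sided Fisher
exact p and Benjamini–Hochberg q (q = 0.05 as the default report column;
the descriptive ranking by |difference| is preserved alongside, since the
underlying comparative analyses are typically reported without multiple-
testing correction). Pose consistency is the mean pairwise heavy-atom
RMSD of a ligand's per-conformer poses in the common docking frame,
without re-fitting (re-fitting would mask genuine binding-mode changes);
a ligand is pose-stable below 2.0 Å.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their spec, seed included; no global
random state is used, and identical specs reproduce outputs exactly.

* **Conformer ensembles**: a random base site of five-atom residues; each
  cluster displaces every atom by an independent Gaussian of scale
  σ_between, each member adds per-atom noise σ_within, and every
  structure carries a small ligand so site extraction works. Defaults
  (k = 5 clusters, 8 members, σ_w = 0.3 Å, σ_b = 6 Å) mirror the regime
  of a few well-separated conformational families per kinase with
  sub-ångström within-family variation. One property deserves emphasis:
  because the between-cluster displacement is drawn *per atom*, pairwise
  RMSDs concentrate over the ~100 site atoms, and clusters remain
  separable even at σ_b = σ_w. The genuinely signal-free regime is
  σ_b ≪ σ_w, which is what the null-calibration tests use. The fixtures
  are geometric, not biophysical — they make no attempt to mimic real
  kinase geometry beyond labelled positions.
* **Screen tables**: ligand-level base scores Normal(0, σ) for inactives
  and Normal(−δ, σ) for actives per kinase (drawn independently per
  kinase), an extra −β kinase-A shift for a tagged subset of the actives,
  Normal(0, σ/2) per-conformer jitter, and vdW/electrostatic components
  as fixed fractions (0.6/0.2) of the total plus noise — an arbitrary but
  fixed decomposition for testing component-level statistics, since a
  real engine's decomposition is engine-internal. Defaults (δ = σ = 1)
  put the ligand-level AUC at Φ(1/√2) ≈ 0.76, the realistic middle of
  the structure-based screening range. The closed-form AUC check applies
  to the base scores, which the truth sidecar exposes; conformer jitter
  would otherwise shrink the observed separation. Because the two
  kinases' base scores are independent given the activity label, the
  cross-kinase rank concordance of synthetic screens is much lower than
  for real isoform pairs, where ligand affinities are strongly
  correlated; passing the RR calibration tests therefore demonstrates
  correct null behaviour and bias recovery, not realistic concordance
  levels.
* **Toy complexes**: each requested bit is realized by one residue on a
  wide layout circle with the matching ligand atom offset inward so the
  geometry satisfies its criterion with ≥ 0.3 Å margin while violating
  every other criterion; decoy atoms stay ≥ 0.3 Å outside the largest
  cutoff from every ligand atom. Aromatic bits use parallel stacked rings
  at a centroid separation chosen inside the aromatic cutoff but with all
  atom pairs outside the hydrophobic cutoff. One residue per canonical
  position is enforced; requesting multiple types at one position is
  rejected before any coordinates are emitted.

## Pipeline and determinism

Stages exchange plain files (TSV/CSV/JSON) inside one output directory,
so any stage is independently re-runnable; configuration is a validated
mapping that rejects unknown keys before any computation. A provenance
manifest (config snapshot, input digests, version, per-stage row counts,
timestamps) is written on success and failure alike. Re-running one
config reproduces every data output byte for byte; the manifest is the
single exception, as its timestamps record wall-clock provenance by
design.

Problem sizes in the tests and the acceptance script (e.g. 2000-ligand
screens, 200 null simulations, 100 toy complexes, 1000 random matrices
against the clustering oracle) were chosen so that sampling error is
small relative to the 3-standard-error acceptance bands while the whole
suite runs in seconds on one CPU.

## Known limitations

* No structure preparation (protonation, side-chain optimization) and no
  mmCIF dialects beyond basic coordinates; inputs are assumed prepared.
* The per-pair common-atom convention means entries of one RMSD matrix
  can rest on different atom subsets when structures have unresolved
  site atoms; with complete structures (and all synthetic fixtures) the
  subsets coincide.
* The fingerprint atom-typing table covers standard residues only;
  non-standard residues contribute no donor/acceptor/charge typing and
  only generic side-chain carbons to hydrophobic contacts.
* The docking-fidelity rule is a threshold on supplied pose deviations,
  not a re-implementation of published ligand-binding-index scoring.
* AUC comparisons between conformers are descriptive; no statistical
  test on AUC differences is performed.
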