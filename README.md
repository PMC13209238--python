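# kinsel

Ensemble-docking post-processing for kinase isoform selectivity.

Closely related kinase isoforms — the canonical example being the JAK
family, where JAK1-selective inhibition is therapeutically desirable but
JAK2 cross-reactivity drives dose-limiting toxicity — share nearly
identical ATP-binding sites, so single-structure docking rarely separates
them. A practical alternative is to dock against an *ensemble* of
binding-site conformations per isoform and analyse the resulting score
tables comparatively. `kinsel` implements the non-docking half of such a
campaign; the docking engine itself is consumed as plain score and pose
tables.

The toolkit covers:

* **Binding-site conformational analysis** — binding sites are the
  residues within 5 Å of each chain's co-crystallized ligand; chains are
  Kabsch-superposed onto a common reference and compared by heavy-atom
  site RMSD. The RMSD matrix is clustered by complete-linkage
  agglomeration, each cluster contributes a medoid plus up to two max-min
  diverse representatives, and representatives with poor re-docking
  fidelity are replaced by their nearest passing neighbour. Classical
  (Torgerson) MDS projects the matrix for visualization.
* **Screening-performance evaluation** — ligands are labelled from assay
  data (active: pChEMBL > 7 or ≤ 100 nM; inactive: pChEMBL ≤ 5.5 or
  ≥ 10 µM) and each receptor conformation is scored by ROC AUC, the
  exponential ROC enrichment eROCE = ⟨exp(−α·FPRᵢ)⟩ over actives,
  enrichment factors, and precision/recall/F1 at top-ranked cutoffs from
  0.2% to 10%. Conformers are retained when AUC ≥ 0.70 and both early
  recognition metrics reach the ensemble median.
* **Relative-rank selectivity** — per-ligand docking scores are converted
  to normalized ranks R ∈ (0, 1] per kinase (midranks for ties, rank 1 =
  best), and the relative rank of a ligand between isoform A and B is

  ```
  RR = R_A − R_B
  ```

  Negative RR means preferential ranking for kinase A. The module also
  measures cross-kinase rank concordance (Spearman ρ, Kendall τ-b, the
  ΔR distribution), runs paired Wilcoxon tests on score components with
  Bonferroni correction, filters a screened library to kinase-A-enriched
  hits (top 5%, RR ≤ 0, |RR| above a separation margin), and evaluates
  Lipinski/Veber/Ghose drug-likeness rules on supplied descriptors.
* **Interaction fingerprints** — geometric protein–ligand interaction
  bits (hydrogen bond, hydrophobic, aromatic, ionic) on canonical
  85-position kinase binding-site labels, detection of the two-hydrogen-
  bond hinge motif (hinge.46 + hinge.48), Fisher-exact active/inactive
  bit enrichment, and cross-conformer pose-consistency RMSD.
* **Synthetic data** — seeded generators for conformer ensembles with a
  planted cluster partition, dual-kinase score tables with planted
  activity and isoform-bias effects, and toy complexes whose coordinates
  realize a requested fingerprint exactly. Every stage of the pipeline is
  therefore testable against known ground truth without any downloads.

## Worked example

Generate a synthetic two-kinase screen in which actives score 1σ better
than inactives and a tagged 20% of the actives carry an extra −1σ bias on
kinase A, then evaluate conformers and prioritize kinase-A-selective hits:

```python
from kinsel.screening import best_poses, evaluate_screen
from kinsel.selectivity import normalize_ranks, prioritize_hits
from kinsel.synthetic import ScreenSpec, gen_screen_table

spec = ScreenSpec(n_actives=500, n_inactives=500, delta=1.0, sigma=1.0,
                  beta=1.0, biased_fraction=0.2, n_conformers=2, seed=42)
scores, truth = gen_screen_table(spec)
table = best_poses(scores).merge(truth[["ligand_id", "label"]], on="ligand_id")

for r in evaluate_screen(table[table["kinase_id"] == "kinaseA"]):
    print(f"{r.conformer_id}: AUC={r.auc:.3f} eROCE={r.eroce:.3f} EF1%={r.ef[0.01]:.2f}")

ranks = {k: normalize_ranks(best_poses(scores).query("kinase_id == @k"))
         for k in ("kinaseA", "kinaseB")}
hits = prioritize_hits(ranks["kinaseA"], ranks["kinaseB"])
print(f"hits: {len(hits)} of {hits.attrs['provenance']['n_top']} top-5% ligands")
print(hits.head(3)[["ligand_id", "R_A", "R_B", "rr"]].to_string(index=False))
```

prints

```
kinaseA_conf1: AUC=0.765 eROCE=0.234 EF1%=2.00
kinaseA_conf2: AUC=0.764 eROCE=0.233 EF1%=2.00
hits: 43 of 50 top-5% ligands
ligand_id   R_A   R_B     rr
  lig0572 0.030 0.988 -0.958
  lig0852 0.035 0.978 -0.943
  lig0139 0.022 0.816 -0.794
```

The AUC of ~0.76 matches the normal-overlap closed form Φ(δ/σ√2) for a
1σ activity shift; EF1% = 2 means the top 1% of the ranked list holds
twice the background concentration of actives. Of the 50 ligands in the
kinase-A top 5%, 43 survive the RR filters, and the planted biased subset
is strongly over-represented among them (21 of 43 hits versus 10% of the
library).

The same workflow runs end to end from the command line:

```
kinsel run --seed 1 --out results_dir        # full synthetic pipeline
kinsel sites *.pdb                           # site RMSD matrix from PDBs
kinsel cluster site_rmsd_matrix.tsv --k 5    # clustering + representatives
```

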