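# indepth

Identification of influential genes from drug-induced differentially
expressed genes (DEGs), by reconstructing a directed upstream→downstream
gene network from a genetic-perturbation signature database and ranking the
network's nodes with weighted Kleinberg hub scores.

## Who this is for

Given a transcriptome comparison (drug-treated vs control cells) you usually
get hundreds of DEGs with no indication of which of them *drive* the rest.
`indepth` answers that question using a LINCS L1000-style reference: a large
collection of expression signatures measured after knocking down,
overexpressing, or ligand-stimulating individual genes. If perturbing gene
*g* in the reference reproduces your drug's signature, and *g* itself moved
in the consistent direction in your experiment, then *g* is a candidate
upstream driver — and the genes it significantly moved are its downstream
targets.

## The method

1. **Connectivity scoring.** Every reference record is summarised as a rank
   vector (landmark genes ordered by differential-expression z-score,
   descending; ties broken by higher expression). The query's UP and DOWN
   DEG sets are scored against each ranking with the CMap
   Kolmogorov–Smirnov statistic: for sorted tag positions
   V(1) < … < V(t) in a ranking of n genes,

   ```
   a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t )
   ES = a  if a ≥ b  else  −b
   ```

   and the combined score is (ES_up − ES_down)/2 when the two statistics
   disagree in sign, else 0, so scores lie in [−1, 1].

2. **Cutoff selection.** Compound records in the reference sharing the query
   drug's name are labelled positive, everything else negative; the
   concordance index (ROC AUC, floored at 0.5) measures comparability and
   Youden's J = sensitivity + specificity − 1 picks the score cutoff. With
   no same-name compounds the cutoff falls back to 0.2.

3. **Network construction.** Genetic-perturbation records scoring ≥ cutoff
   become upstream candidates if direction-consistent (knocked-down gene ⇒
   DOWN DEG; overexpressed/ligand-stimulated gene ⇒ UP DEG). Per
   (gene, perturbagen id) only the best-scoring record is kept, and
   knockdown genes supported by fewer than two independent shRNA clones are
   discarded (off-target guard). Edges run from each upstream gene to the
   query DEGs its record moved significantly (|z| ≥ 2) in the query's
   direction; self-loops are removed and parallel edges merged.

4. **Hub scoring.** Each edge u→v is weighted α·δ, where α is u's
   treatment/control ratio in the query and δ is a per-record penalty,
   (number of UP or DOWN query DEGs)/(number of landmark genes the record
   up- or down-regulated), capped at 1. Kleinberg's HITS on this weighted
   adjacency (hub = principal eigenvector of W·Wᵀ, authority of Wᵀ·W, by
   alternating power iteration) ranks the nodes; scores are normalised so
   the most influential gene has hub score exactly 1.

## Worked example

The package ships a synthetic-fixture generator that plants a regulatory
hierarchy (a down-regulated master regulator G001 driving two second-level
regulators and their targets) in a LINCS-like reference, with matched query
intensities:

```bash
indepth synth --seed 0 --out demo/fixture
indepth run --reference demo/fixture --query demo/fixture/query_expression.tsv \
            --drug-name drugX --out demo/run
```

prints

```
upstream selection: 8 genetic records -> 2 >= cutoff 0.5764 -> 2 direction-consistent
                    -> 2 after pert_id dedup -> 2 after >=2-shRNA rule
network: 55 nodes, 54 edges after simplification
top hub: G001 (hub score 1); 55 nodes, 54 edges
```

`demo/run/roc_report.tsv` shows the auto-selected cutoff — three same-name
compound records against 14 negatives give c-index 0.857 and Youden cutoff
0.576 — and `demo/run/hubs.tsv` begins

```
gene   direction  ratio   hub_score  authority_score  n_out_edges  n_in_edges
G001   down       0.291   1          0                54           0
G002   down       0.274   0          1                0            1
G003   up         4.932   0          1                0            1
```

i.e. the planted master regulator G001 (a DOWN DEG with treatment/control
ratio 0.29) is recovered as the single most influential gene: both of its
independent shRNA knockdown records cleared the cutoff, and its 54 outgoing
edges to same-direction downstream DEGs dominate the hub eigenvector. Other
outputs: `scores.tsv` (per-record connectivity scores), `network.sif` /
`network.graphml` (for Cytoscape), `upstream_candidates.tsv`, and
`run_metadata.json` (every parameter of the run, for replay).

The stages are also available separately (`indepth score`, `indepth
network`, `indepth hub`) and as library functions (`indepth.run_pipeline`
and the per-module operations).

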