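# Methods

## Model and assumptions

`indepth` treats a drug-induced transcriptome change as the superposition of
direct drug effects and the downstream programmes of a few *influential*
genes. The reference database supplies the causal information the query
experiment lacks: each knockdown / overexpression / ligand record is an
interventional measurement of what happens when one gene's activity changes.
The method assumes

- the reference and query share a landmark-gene universe on which
  signatures are comparable (only landmark genes are used for scoring;
  larger inferred-gene universes are accepted but not preferred);
- similarity of signatures implies shared mechanism — the justification for
  connecting an upstream gene to the query at all;
- direction consistency is meaningful: a gene whose knockdown mimics the
  drug should itself be down in the drug's signature;
- shRNA off-target effects are record-specific, so requiring two
  independent perturbagen ids per knocked-down gene removes most of them.

## Pipeline stages and their parameters

**Rank vectors.** Per record, landmark genes are ordered by z-score
descending (rank 1 = most up-regulated). Exact z ties are broken by higher
expression value when an expression matrix is supplied, then by
landmark-list order — a deterministic completion of the tie rule, chosen so
rank matrices are reproducible across runs and platforms.

**Regulated sets.** `z_threshold` (default 2, inclusive on both sides)
defines the genes a record significantly moved. The boundary is inclusive
(z = ±2 counts).

**DEG calling.** Treatment/control ratios with an intensity floor
(`floor=50`, applied to both channels before division, so weak signals
cannot produce extreme ratios); UP at ratio ≥ 2, DOWN at ratio ≤ 0.5, both
inclusive. Probe-level data are averaged to genes on the ratio scale
(arithmetic mean; a geometric option exists) before calling, because the
network's nodes are genes. When a precomputed DEG list arrives without
ratios, α defaults to 1 for every gene, with a warning.

**Connectivity score scaling.** The raw combined statistic
ES_up − ES_down is divided by 2 (`scaling="half"`), giving a fixed [−1, 1]
scale on which a cutoff like 0.2 means the same thing for every query. The
batch-relative alternative (`"batch_max"`, rescaling positives by the batch
maximum and negatives by the minimum) is provided for compatibility with
older connectivity-map conventions but makes cutoffs query-set dependent.
A query with only UP (or only DOWN) tags is scored with the missing side's
enrichment treated as 0. The KS statistic itself degenerates to −1/n when
every ranked gene is a tag; callers never hit this in practice because tag
sets are DEG subsets.

**Cutoff selection.** `c_index` floors the ROC AUC at 0.5 (an AUC below
chance means the two databases are not comparable, not that inverting the
classifier is licensed). `youden_cutoff` evaluates J at every observed score
with the predicate score ≥ cutoff ⇒ positive, breaking ties toward the
*largest* maximiser — the more stringent network. The fallback cutoff is
0.2. Whether ROC labelling is restricted to one cell line is configurable
(`roc_cell_filter`); scoring and ROC filters are independent because
genetic-perturbation selection deliberately uses all cell lines (per-line
genetic coverage is usually too sparse) while compound comparability is
cell-context sensitive.

**Edge weights.** α is the upstream gene's query ratio; `alpha_mode="raw"`
uses it as-is (the default), `"symmetric"` uses max(r, 1/r). Raw α
systematically down-weights DOWN-DEG hubs (their ratios are ≤ 0.5 by
construction), which is faithful to the ratio-as-weight convention but can
let up-regulated sources dominate mixed networks; the symmetric mode is the
documented remedy and the choice is recorded in run metadata. δ is capped
at 1 so that records regulating very few landmark genes are never
*rewarded* — δ is a penalty against promiscuous, off-target-prone records,
not a bonus. For a merged parallel edge the largest supporting δ is used,
and the δ numerator counts all query DEGs by default
(`delta_numerator="landmark_only"` restricts it).

**HITS.** Alternating power iteration h ← W·a, a ← Wᵀ·h with sup-norm
renormalisation each step; all-ones initialisation, `tol=1e-10` on the hub
vector's sup-norm change, `max_iter=1000`. Nothing is random, so runs are
exactly reproducible. The final vectors are scaled so the maximum entry is
exactly 1 (division by their own maximum). An edge-free graph returns all
zeros and is reported as `empty_network` by the pipeline — a valid outcome
when the cutoff exceeds every score. Hitting the iteration cap returns the
best iterate flagged `converged=False`; the cap is a runtime guard, and the
oracle-equivalence tests instead run the iteration to convergence
(`tol=1e-13`, large cap) before comparing against a dense
eigendecomposition, where agreement is ~1e-11 sup-norm.

**Signed FDR scores.** Per direction, absent gene sets get FDR 1; FDR 0 is
replaced by the direction table's minimum nonzero FDR ("within each test"
is read direction-locally — the pooled-table reading is equally defensible
but direction-local keeps the substitution on the same null distribution);
scores are ∓log10(FDR) and both directions are summed. Log base 10 is a
module constant. A direction whose FDRs are all zero has no substitute;
those gene sets are flagged rather than scored infinite.

## What the synthetic generator emulates — and what it does not

`PlantedNetworkSpec` plants a three-regulator hierarchy in a 200-gene
landmark universe: a down-regulated master (G001) whose programme includes
a down-regulated secondary regulator (G002) and an up-regulated one (G003),
each with its own targets. The reference contains two independent shRNA
knockdown records per regulator (true targets at mean |z| = 4 over a
N(0, 1) background, so ≈97.7% of true targets clear |z| ≥ 2),
overexpression and ligand records for up-regulated regulators, three
same-name compound records mimicking the drug effect, and six noise-only
decoy compounds. Compound records carry a larger noise scale
(`compound_noise_sd=2`) than genetic perturbations, emulating the
dose/time/batch spread of real drug-treatment replicates; this also keeps
the Youden cutoff below the knockdown score range, as in a usable real
analysis. Query intensities are lognormal (median 400, so the ×0.25 treated
values of DOWN DEGs stay above the floor of 50) with planted fold changes
of 4 and mild multiplicative noise (log-sd 0.1).

Deliberately **not** emulated: probe/array effects and L1000 deconvolution
noise, batch structure, correlated biological variation between genes,
partially overlapping regulons, dose–response, and the sheer scale of a
real reference (~10⁶ records). Passing tests therefore demonstrate that the
algorithmic chain — scoring, cutoff, filters, weighting, eigenvector
ranking — is correct and stable under honest noise, not that the method's
biological error rates on real data are reproduced.

## Numerical choices and degenerate inputs

- Rank tie-breaks and the Youden largest-maximiser rule make every stage
  deterministic; two runs on identical inputs are byte-identical.
- KS positions are computed on integer ranks; the enumeration oracle agrees
  to 1e-12.
- Records with no tag overlap are kept in the score table as unscored rows
  rather than dropped, so record counts audit cleanly.
- Empty upstream selections, edge-free networks, and queries with one empty
  tag side are all valid, handled paths, not errors.
- Problem sizes in the test suite (200 landmark genes, ~17 records, 40
  seeds for the recovery study; random digraphs ≤ 30 nodes for the eigen
  comparisons) were chosen as the smallest sizes at which every pipeline
  behaviour — auto-ROC, both direction rules, the two-clone filter,
  multi-level propagation — is still exercised.

## Known limitations

- The α×δ weighting is asymmetric under raw α (see above); neither variant
  is canonical, which is why both ship.
- The auto cutoff requires same-name compound records; cross-name
  positives (same mechanism, different name) are not matched.
- Downstream genes are landmark-only by construction; an upstream gene's
  targets outside the landmark set are invisible.
- GCT is supported as text (v1.2/v1.3); binary GCTX/HDF5 matrices are out
  of scope.
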