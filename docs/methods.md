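# Methods

This note documents the models, conventions, and numerical choices behind
`hdbn`, in the spirit of a methods appendix: what is computed, under what
assumptions, and where the design was genuinely open.

## Data model

The unit of analysis is one animal's **connectome**: a symmetric,
nonnegative, zero-diagonal matrix of tractography streamline counts over a
bilateral parcellation (default 72 regions, 36 per hemisphere). Region
identity is carried by a **region table** (id, abbreviation, name,
hemisphere) in which every region has a homolog in the opposite hemisphere;
the homolog map is required to be an involution that crosses hemispheres.
Hemisphere is encoded by the leading `L`/`R` character of the abbreviation
unless an explicit column overrides it.

The packaged default table contains every abbreviation used in the analyses
(`CC`, `CB`, `SUC`, `HY`, `IC`, `COA`, `MO`, `SS`, `PIR`, `TT`, `RHP`, `MB`,
`CA1–CA3`, `DG`, `EC`, `TH`, `ICtx`, `MED`, `PONS`, mirrored left/right),
padded to 36 per hemisphere with clearly named placeholder regions
(`PL01–PL15`). The downstream mathematics depends only on cardinality and
labels, so any 72-region table supplied as TSV replaces the default without
code changes. Ten predetermined composite ROIs are built in; the hippocampus
is the union {CA1, CA2, CA3, DG} and the isocortex stands in for the visual
cortex.

Asymmetric input matrices are symmetrized entrywise by the maximum of the two
orientations (with a warning): counts from A-seeded versus B-seeded tracking
differ only by seeding, and all graphs here are undirected. Self-counts on
the diagonal are dropped.

## Graph views and normalization

Graph analysis operates on **views**: the whole matrix, a within-hemisphere
block (ipsilateral-L/R), or a cross-hemisphere block (contralateral). Every
view is normalized by its maximum entry (so the largest weight is exactly 1)
and pruned at the extraction threshold **t = 0.001** applied to normalized
weights. Threshold semantics: entries *strictly below* t are zeroed, so
t = 0 is the identity; normalization and thresholding are idempotent, and all
downstream metrics are invariant to uniform positive rescaling of raw
counts.

The raw contralateral cross-block is asymmetric (entry (a, b) is L-a to R-b)
and carries homolog-to-homolog crossings on its diagonal; the LR and RL
blocks are transposes of one another. Because the metric layer requires a
valid undirected graph, the contralateral *view* symmetrizes the block by the
mean of the two orientations and zeroes the diagonal. Both representations
are exposed: `hemisphere_block` returns the raw block, `hemisphere_view` the
graph-ready one.

Composite-ROI merging sums counts over member pairs; member-to-member counts
internal to a composite collapse onto the diagonal and are dropped, so
off-ROI edge mass is conserved exactly.

## Network metrics

All measures follow the brain-connectivity-toolbox conventions for
undirected weighted graphs with weights in [0, 1]:

| measure | convention |
|---|---|
| density | nonzero upper-triangle count / (N(N−1)/2) |
| clustering | Onnela: C_i = Σ_{j,h}(w_ij w_ih w_jh)^{1/3} / (k_i(k_i−1)); C_i = 0 for k_i < 2; mean over all nodes |
| transitivity | same triangle sum globally / Σ k_i(k_i−1); NaN when no node has degree ≥ 2 |
| path length | Dijkstra on lengths 1/w; mean over reachable ordered pairs, unreachable excluded with a warning |
| global efficiency | mean over ordered pairs of 1/d (1/∞ = 0) |
| local efficiency | global efficiency of each node's neighbor-induced subgraph; 0 for k_i < 2 |
| assortativity | Pearson correlation of endpoint strengths over the edge list, both orientations; NaN at zero variance |
| rich club | φ(k) = 2E_{>k}/(N_{>k}(N_{>k}−1)) on the binarized graph; NaN when N_{>k} < 2 |

Statistically undefined values are returned as NaN (so cohort tables stay
rectangular and group tests can drop-and-count them); structural
impossibilities — an empty graph, N < 2, no connected pair — raise errors.
A point worth noting: a star graph has transitivity 0, not NaN, because its
hub contributes connected triples; only graphs with no node of degree ≥ 2
produce the genuine 0/0.

**Small-worldness.** σ = (C/C_rand)/(L/L_rand), with C_rand and L_rand
averaged over an ensemble of null graphs (default 100) generated by
Maslov–Sneppen double edge swaps on the binarized topology (default 10 swap
attempts per edge) with the original weight multiset shuffled onto the
rewired edges. The ensemble (rather than a single random graph) was chosen
for a stabler normalization; the null ensemble's mean and SD are reported
alongside σ. Proposals creating self-loops or duplicate edges are rejected,
so rigid graphs (e.g. complete graphs) pass through unchanged — which gives
the expected σ = 1 exactly. σ is bit-reproducible given (graph, n_null,
swaps_per_edge, seed). Rewiring is the one expensive step (it is inherently
sequential); on dense 72-node simulated graphs a single σ with 100 nulls
takes on the order of seconds, which is why the demonstration configs use
smaller ensembles.

## Group statistics

**Edgewise comparison.** For a 36-stem parcellation the family is the 630
unordered pairs. Per animal, the ipsilateral observation for a pair is the
mean of its L-L and R-R count entries, and the contralateral observation the
mean of the L-R and R-L entries — the two hemispheres are combined into one
observation per animal, matching the design in which separate per-hemisphere
analyses showed no differences. The pipeline is then: (1) exclude pairs
where more than 50% of all observations (both groups pooled) are zero — a
fraction of exactly one half is kept; (2) transform counts by ln(x+1) (the
pseudo-count avoids log 0; the base only rescales t inputs and leaves t and
p unchanged); (3) pooled-variance two-sample t-test per pair, df computed
from the actual sample sizes (n₁+n₂−2 — always computed, never hard-coded);
(4) BH step-up adjustment jointly across the included pairs of the mode
being analyzed, ipsilateral and contralateral treated as separate families
(each is reported as its own panel); discovery at adjusted p ≤ q, q = 0.05.
Adjusted p-values are assembled into a symmetric signed matrix — positive
where the KO mean exceeds WT, negative otherwise, NaN where filtered — with
display bins "light" (0.01 ≤ |p| < 0.05) and "dark" (|p| < 0.01; a variant
convention labels the dark band 0.005–0.01, with smaller values saturating).

Degenerate edges: zero pooled variance with equal means gives t = 0, p = 1,
sign 0; zero pooled variance with different means is reported as an infinite
t with the smallest positive float as p and a degeneracy flag, rather than
silently passing through the t distribution.

**Region streamline totals** are row sums of the count matrix, compared per
region with the same pooled t and BH across the 72 regions (no log
transform; totals are sums of many edges and far less skewed).

**Network parameters** are compared per metric and view with pooled t-tests
and no multiplicity correction (recorded in the output metadata); NaN metric
values are dropped with their count reported.

**Diffusivity.** AD = λ₁, RD = (λ₂+λ₃)/2, MD = (λ₁+λ₂+λ₃)/3, and FA is the
standard (Basser–Pierpaoli) fractional anisotropy
√(3/2)·‖λ−MD‖/‖λ‖ — chosen because it is the universal definition in the
tensor-imaging literature; it is scale-invariant and hits 0 for isotropic
and 1 for single-eigenvalue tensors to 1e−12. Region-wise group maps use
pooled t per region on per-animal means with configurable correction
(BH default, Bonferroni, or none); the flag column uses the adjusted value,
and both raw and adjusted p are emitted since thresholding conventions for
display maps vary.

**Circuits.** A circuit is a set of composite-ROI nodes and a list of pairs.
Per animal, a pair's connection strength is the summed count between the two
resolved region sets: ipsilaterally the mean of the L-L and R-R block sums,
contralaterally the cross-hemisphere block sum in both crossing directions.
Strength is additive over ROI members (splitting a composite and summing
reproduces the whole). Pairs use raw strengths (sums over many edges;
approximately normal) with pooled t and BH within the circuit only — each
circuit is presented as its own family. Built-ins: the fear-conditioning
circuit (6 pairs over TH, SS, ICtx, HY, COA) and the TLE circuit (7 pairs
over Hipp, TH, ICtx, COA, EC); pair identity is unordered.

## Synthetic cohorts

The generator defines the study conditions under which all statistical
guarantees are verified: **n_WT = 8 vs n_KO = 12** animals, 72 regions.
Counts per edge are `round(lognormal(μ, σ))` with defaults μ = 5.0 (median
≈ 150 streamlines, the scale of mid-strength region pairs in
million-streamline tractography) and σ = 0.5 on the log scale; a
**structural-zero mask** is drawn once per edge per cohort (default
probability 0.3) and shared across animals and groups, so unconnected pairs
are zero for every animal and are exactly the pairs the >50%-zeros filter
removes. This "structural" reading keeps the planted-signal model exactly
recoverable by the log-scale t-test — per-observation dropout would instead
inject extreme log-scale outliers that no t-test models. Planted effects
multiply the KO lognormal mean of chosen edges (equivalently shift μ by
log effect); `bilateral_planted_edges` plants a stem pair on both
hemispheres, mirroring a bilateral group difference.

Diffusivity records draw eigenvalues multiplicatively around the baseline
(1.2, 0.7, 0.5)×10⁻³ mm²/s with log-scale SD 0.05 (a typical between-animal
coefficient of variation for regional tensor scalars), sorted to enforce
λ₁ ≥ λ₂ ≥ λ₃ > 0; planted region effects scale λ₁ (AD), λ₂ and λ₃ (RD), or
all three (MD).

All randomness flows from one integer seed through a spawned seed-sequence
tree (mask, per-animal counts, diffusivity), so identical configs are
bit-identical regardless of iteration order.

**What the generator does and does not emulate.** It reproduces the marginal
count structure (right skew, zero inflation, group effects) and the two-group
design; it does not model spatial autocorrelation between edges, distance
dependence of connection strength, hemispheric asymmetries, or
registration/tracking artifacts. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under its stated
assumptions, not robustness to the full correlation structure of real
tractography data.

## Statistical performance under the study conditions

Computed by the test suite and `scripts/acceptance.py`, all at 8 vs 12
animals, log-SD 0.5, zero probability 0.3:

- On null cohorts the edgewise pipeline's mean empirical false-discovery
  proportion over 200 replicates stays at the nominal 5% level (bounded at
  7.5% with Monte-Carlo slack in the tests).
- With 20 bilateral pairs planted at effect 2.0, the mean empirical FDR over
  200 cohorts remains ≈ 5%, and planted signal is detected (at least one
  planted pair discovered, correct sign) in essentially every seed. Per-edge
  sensitivity at this effect size is moderate (≈ 40%): a 2-fold effect with
  log-scale SD 0.5 and hemisphere averaging has pooled-t noncentrality ≈ 4.3,
  and BH across ~600 pairs demands raw p ≈ 10⁻³. Stronger effects (≥ 2.5-
  fold) are discovered per-edge in the large majority of seeds.
- A ring lattice (36 nodes, degree 4) with 10% shortcuts scores σ ≈ 4
  against 100 degree-preserving nulls, and σ > 1 in ≥ 95 of 100 seeds;
  matched-density random graphs score σ ≈ 1 within the null spread.

## Numerical and design choices

- **Pooled (Student) t** rather than Welch, matching the df convention
  n₁+n₂−2 of the analysis design; Welch is available on request via the
  shared t-test utility if variances are suspect.
- **BH discovery rule** uses adjusted ≤ q (the standard step-up convention);
  the two-stage (Benjamini–Krieger–Yekutieli) variant was considered and not
  made the default because the single-stage procedure is the named method;
  the signed matrices attach signs after adjustment.
- **Tie handling**: equal group means give sign 0 and p forced to 1.
- **Threshold boundary** kept (≥ t survives) so t = 0 is the identity.
- **Missing values** are `NA` in all TSVs; floats use repr-round-trip
  precision so write→read→write is byte-stable, which is what makes the
  pipeline's byte-identical rerun guarantee testable.
- Degenerate inputs are split between NaN (statistically undefined, kept in
  tables) and exceptions (structurally impossible), as listed above.

## Known limitations

- Per-edge power at 2-fold effects is moderate by design honesty: the
  documented conditions are what they are; the suite asserts
  detection-of-signal and FDR calibration, not per-edge recovery rates the
  conditions cannot support.
- The contralateral view's mean-symmetrization discards the (generally
  small) asymmetry between the two crossing directions and the
  homolog-to-homolog diagonal; the raw block is available where that matters.
- Rewiring-based σ on dense graphs is O(swaps × edges) sequential Python;
  budget accordingly or reduce the ensemble.
- The region table's placeholder rows stand in for atlas regions whose
  published names are not bundled; supply a custom TSV for real data.
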