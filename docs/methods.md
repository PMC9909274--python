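# Methods

## Scope and model

`tetraface` implements a two-stage predictor for tetramer protein
complexes.  Stage 1 decides, for each of the six unordered chain pairs,
whether the two chains interact; stage 2 assumes a chain pair interacts and
ranks its L₁×L₂ candidate residue pairs by the probability of being an
interface pair.  Both stages consume the same raw inputs: the one-letter
sequence, the Cα trace, and five per-residue geometric properties (ASA in
Å², RASA as a fraction, and the Voronoi-derived contact/void areas ECA,
ICA, EVA in Å²) that are supplied as TSV tables.  The package does not
compute Voronoi contact areas itself; ground-truth interface labels use a
distance surrogate instead (below).

## Contact definition

A residue pair on two chains is labelled an interface pair when the
residues lie within a cutoff: 8.0 Å between Cα atoms when only the trace is
available, 5.0 Å minimum heavy-atom distance when the structure carries
full atoms.  A chain pair interacts iff it has at least one interface pair;
the interaction boolean is stored as non-emptiness of the interface-pair
set, so the two can never disagree.  Both cutoffs are configurable.  These
are the standard surrogates for area-based contact definitions; without an
area reference they cannot be calibrated against one, which is a known
source of label disagreement near the cutoff.

## Stage-1 featurization conventions

For each amino-acid type the change sequences are built from 1-based
occurrence positions, as in the defining formulas, while all public APIs
index residues 0-based.  Degenerate cases are fixed as follows:

* a letter occurring once yields the single value α₁ − (L+1)/2 for the
  position sequence and β₁ − mean(β over the whole chain) for each geometry
  sequence; all four statistics then collapse to that value, and the
  frequency is 1/L;
* an absent letter yields the sequence [0] and an all-zero 24-feature row;
* the frequency is implemented directly as n/L (the length-based form
  (|f|+1)/L equals n/L only in the non-degenerate case, and the degenerate
  sequences above must not corrupt it);
* the means divide by the occurrence count n, not by the change-sequence
  length n−1 — this is the convention the hand-worked example fixes;
* the ratio R_x^i is defined as 0 when the position-sequence mean is 0.

The pair sample S = |Q_a − Q_b| is standardized per sample over all 480
entries with the population σ; a constant matrix standardizes to zeros
(σ is compared against 1e-12 relative to the matrix scale).  Per-sample
standardization deliberately discards the overall magnitude of S and keeps
only its pattern; a dataset-level alternative is available via
`standardized=False` plus external scaling.  Rows follow the fixed
alphabetical order ACDEFGHIKLMNPQRSTVWY; columns are
[F, A, B, M] then [A^i, B^i, M^i, R^i] for i = ASA, RASA, ECA, ICA, EVA.
Residues with nonstandard names map to 'X' and contribute to no
alphabet-indexed row.

## Stage-1 network

Input 1×20×24 → 3×3 convolution (stride 1, valid) → ReLU → 2×2 convolution
(stride 1, valid) → ReLU → 2×2 max-pool (stride 2, floor) → flatten → dense
→ 2 logits; softmax cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8).
Channel counts default to 2 per convolution layer and are configurable per
layer.  Defaults: learning rate 8.01e-4, batch 128, 20 epochs, decision
threshold 0.5, no class weighting.  The network is implemented in numpy:
the inputs are tiny, no GPU or deep-learning framework is needed, and a
seeded pure-numpy training loop is bit-reproducible, which the determinism
tests assert literally.  Hyperparameter selection is a seeded random search
(log-uniform learning rate in [1e-5, 1e-3], kernel counts in {1..4})
maximizing validation AUC, with ties broken toward the lower learning rate
and fewer kernels; a Bayesian optimizer is intentionally not reproduced.

## Stage-2 featurization conventions

Sequence features treat the chain as circular (head-to-tail wrap) and emit,
per physicochemical property and offset k = 1…10, the forward and backward
interval products as two separate features — the 155 = 5×(20+10)+5
arithmetic forces this reading — plus ten circular window means and the raw
values.  Structure features use no wrap: neighbours are ranked by ascending
Cα distance with ties broken by ascending sequence position.  The weight
factor uses the scale-invariant grouping ω_ξ = exp(−d_ξ²·(k+1)/Σ_{ξ=1}^{k+1}
d_ξ²) at k = 20; the literal grouping exp(−d_ξ²)·(k+1)/Σd² underflows at
protein distance scales (d ≈ 10–30 Å) and is kept only behind the
``literal`` flag.  With all distances equal the default reduces to
ω ≡ e⁻¹, which the tests pin.  The normalizing sum runs over the 21 nearest
*other* residues, per-central-residue; the 21st weight is not emitted.
Duplicate coordinates (zero neighbour distance) are an error.  Because the
descriptors need the 20 nearest residues plus the 21-term normalizer,
chains must have at least 22 residues.

The five bundled physicochemical scales (Kyte–Doolittle hydrophobicity,
Charton polarizability, Grantham polarity, Chou–Fasman helix propensity,
codon multiplicity) are a convenience default; every entry point accepts a
user TSV, and all correctness tests use explicit fixture tables so no
result depends on the bundled values.

## Stage-2 ensemble

Ten balanced sets (all positives + an equal number of negatives sampled
without replacement, independently across sets; a disjoint mode exists
behind a flag) each train an RBF C-SVM (C = 1.0; γ from the median
heuristic, 1/median squared pairwise distance on ≤500 standardized training
rows) with sigmoid-calibrated probabilities (cross-validated calibration,
folds = min(5, smallest class count)).  Features are standardized with
statistics fit on the union of the positives and every sampled negative;
the scaler is persisted with the ensemble.  The fused score is the sum of
member probabilities, reported divided by the ensemble size so it lies in
[0, 1]; the division is order-preserving, so every top-t metric is
unaffected.  Ranking ties break by (chain-1 index, chain-2 index)
ascending.

## Metrics

Confusion metrics with a zero denominator are reported as NaN with a
warning, never silently as 0.  AUC is the rank-based Mann–Whitney statistic
with midrank ties.  NPIRP components follow the fixed chain-pair order
(AB, AC, AD, BC, BD, CD).  Accuracy4t counts a complex as correct at level
z when its NPIRP L0 at the given t is ≥ z, over the complexes with ≥ z
native interfaces.

## Synthetic data generator

The generator emulates the data regime the method targets: four chains of
24–60 residues (compact, loosely self-avoiding Cα walks with 3.8 Å steps),
a configurable fraction of non-interacting chain pairs (default 0.2),
interfaces of at least 3 residue pairs, and correlated property tables —
ASA = max(0, 100 − 9·intra-chain neighbours within 10 Å) + noise (σ = 2),
RASA = ASA over a per-type maximum, ECA ∝ inter-chain neighbour count,
ICA ∝ intra-chain neighbour count, EVA a positive mixture of ASA and ECA.
ECA/ICA thereby carry the structural meaning of exterior/interior contact,
so interface residues have a legitimate geometric signature without any
label leaking into a feature.

Two constraints shape the design.  First, stage 1 only ever sees
|Q_a − Q_b|, so an interaction pattern must be expressible as chain
*similarity*, which is transitive; the interaction graph is therefore a
union of cliques — all four chains, a 2+2 split, or four singletons —
sampled so the expected non-interacting fraction matches the
configuration (the 2+2 split has non-interacting fraction 2/3, so e.g. a
0.2 target draws it with probability 0.3).  Chains within a clique are
homologs: shared clique-specific residue composition (Dirichlet-sampled),
10 % point mutations, jittered copies of one backbone, placed in contact by
a bisection on the separation (pairs) or a shrinking tetrahedral layout
(4-cliques); cliques are separated by 200 Å.  Labels are always recomputed
from the written geometry by the contact labeler, and the generator raises
after bounded retries if a layout fails to realize the planted graph.
Second, the minimum chain length is 24, not the 20 the stage-1 data regime
would allow, because stage-2 descriptors require 22 residues.

What passing tests on this generator do and do not show: they demonstrate
that both stages recover planted, geometry-mediated signal (held-out
chain-pair AUC > 0.65 with the network trained at learning rate 1e-3 for
100 epochs on 60 complexes; interface-pair AUC > 0.8 for the ensemble
trained on 9 complexes with 1:3 positive:negative test sampling — problem
sizes chosen to exercise the full pipeline at desk scale), that the
pipeline is deterministic, and that the bookkeeping is correct.  They do
not show real-structure performance: synthetic chains are not folded
proteins, homology is a much cleaner interaction cue than real interfaces
provide, and the distance labeler is not an area-based contact definition.

## Known limitations

* Real-data benchmarks (curated PDB sets, area-based contact labels,
  tens of millions of training pairs) are out of scope by design.
* The stage-1 standardization destroys the magnitude of |Q_a − Q_b|; on
  data where magnitude is the dominant cue this is a handicap inherited
  from the method definition.
* The worked example's printed ratio value is internally inconsistent with
  its defining formula as typeset in the source material (a fraction bar
  lost in rendering); this package follows the formula, whose value on the
  example is 8/13, and the tests assert that.
* SVM probability calibration is backend-dependent; determinism is
  guaranteed only for a fixed library version and seed.
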