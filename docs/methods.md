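# Methods

This note documents the models and procedures implemented in `acpdesign`,
the parameters that matter, the numerical conventions, and the design
choices made where more than one reasonable convention exists.

## Sequence model and descriptors

Peptides are strings over the 20 canonical one-letter codes, upper-cased on
construction; anything else is rejected with the offending position. The
intended chemistry is short synthetic peptides with amidated C-termini, so
termini are excluded from the charge model by default.

**Pharmacophore features.** Each residue maps to a binary 6-vector:
hydrophobic (L), aromatic (R), H-bond acceptor (A), H-bond donor (D),
positively ionizable (P), negatively ionizable (N). The default table is

| feature | residues |
|---|---|
| L | A C F I L M P V W Y |
| R | F H W Y |
| A | D E N Q S T C Y |
| D | K T C Q H R W N S Y |
| P | H K R |
| N | D E |

Two residues are genuinely ambiguous across pharmacophore-typing dialects:
glycine (no side chain) carries no hydrophobic flag here, proline does.
The table is an ordinary mapping argument, so alternative dialects can be
substituted per call.

**Cross-correlation vector (147 components).** For each of the 21 unordered
feature pairs and separations d = 0…6 (a seven-residue window), the
component is the number of index pairs (i, i+d) with the two features at
the two ends, divided by max(L − d, 1). Counting conventions: each index
pair counts once even if both residues carry both features; at d = 0 the
same-feature components reduce to the frequency of residues carrying the
feature. The divisor makes components length-comparable and bounded;
normalizing by L or by the window count would rescale but not reorder the
components, and the dimensionality and semantics are unchanged under any
of these choices. Components with d ≥ L are zero.

**Global properties.** Eisenberg consensus hydrophobicity (mean over
residues); hydrophobic moment µ_H with 100°/residue, 0-based indexing and
1/L normalization (the characterized lead peptide KIFKKFKTIIKKVWRIFGRF
gives 0.866, matching its published characterization to the printed
precision); net side-chain charge (+1 per K/R, −1 per D/E, histidine by
Henderson–Hasselbalch at pH 7.0 with pKa 6.0, ≈ +0.09); charge density =
charge / average molecular weight of the amidated peptide (amide–hydroxyl
mass difference −0.985 Da); and length. Total dimension 151, fixed order:
cross-correlations (pairs in canonical feature order, d ascending), then
H, uH, charge_density, Len.

**Helical wheel.** Residue i sits at (100·i) mod 360°. The hydrophobic arc
marks every 20° sector (anchored at 0°) containing a hydrophobic residue
and returns 20° times the longest circularly contiguous marked run — 360
when all sectors are marked, 0 when none. All angles are multiples of 20°,
so sector anchoring is exact and origin-invariant.

## Classifier

`AcpClassifier(dataset).fit()` runs the training protocol and returns an
`AcpClassifierResults`:

1. **Stratified split** (when used): each class contributes
   round(N_c·fraction) test members, preserving proportions to within one
   sample; deterministic under the seed.
2. **Correlation pruning**: a greedy scan in canonical feature order drops
   zero-variance features and any feature whose |Pearson r| with a retained
   feature exceeds 0.9 (configurable).
3. **Backward sequential feature elimination**: repeatedly remove the
   feature whose removal maximizes the cross-validated MCC of the linear
   margin classifier (fixed mid-grid C); the returned subset is the path's
   MCC maximum, ties going to the smaller subset, and ties among candidate
   removals to the feature latest in canonical order. Elimination uses
   3-fold CV by default (the fold split and per-fold standardization are
   computed once and reused across the O(F²) subset evaluations; this is
   what makes full backward paths over ~140 candidates affordable).
4. **Margin model**: linear SVM with C selected from a grid by 10-fold CV
   MCC; features are z-scored on the training set; weights are exposed for
   ranking by |w|. A Platt-style logistic calibration of the decision
   values yields the pseudo-probability P_ACP ∈ [0, 1]. The class call
   threshold is P_ACP ≥ 0.5 (the boundary value counts as active).
5. **Applicability domain**: k-means with k = 3 on the standardized
   training descriptors; for a query, S = 1/(1 + mean Euclidean distance
   to the three centroids) ∈ (0, 1]. The raw inverse distance is unbounded
   as the distance approaches zero; the 1/(1+·) form keeps the design
   scores in [0, 1] while preserving monotonicity, and the tested contract
   ϕ_ACP + ϕ_Neg = 0.5 + S holds under any such choice. Aggregation over
   centroids uses the mean (minimum and sum are monotone alternatives that
   would preserve every ranking property tested here).
6. **Design scores**: ϕ_ACP = (P_ACP + S)/2, ϕ_Neg = ((1 − P_ACP) + S)/2.
   Screening tables sort by the requested score, ties broken
   lexicographically by sequence.

A random-forest baseline (500 trees, √F features per split, same metrics
interface) is provided for comparison. The fitted margin model serializes
to a single JSON document (features, weights, calibration, centroids,
standardization, training-data hash, seed); documents missing required
blocks raise a schema error. Forest persistence is intentionally not
implemented.

Metrics follow the standard confusion-matrix definitions (MCC, accuracy,
precision, recall); an all-one-class prediction has an undefined MCC and
is reported as 0 with a warning. CV reports carry the per-fold mean and
standard deviation.

## Virtual libraries

All generators draw lengths uniformly from 11–30 (configurable) and are
deterministic under their seed.

- **Helical**: residue at position i drawn from column (i mod 18) of a
  position–residue probability matrix (18 positions = five helical turns;
  the pattern repeats for longer peptides). The packaged default matrix is
  a synthetic surrogate — hydrophobic pool on the hydrophobic half of the
  wheel, cationic polar pool elsewhere — standing in for position
  statistics of natural helical ACP corpora, which are not redistributable
  here; any user matrix of the same shape is accepted, and columns must
  sum to 1 within 1e−6.
- **Amphipathic arc**: per peptide, an arc width is drawn from the
  multiples of 20° in [100°, 260°]; wheel sectors inside the arc take
  residues from {A,F,I,L,V,W}, sectors outside from
  {G,S,T,N,Q,H,E,D,K,R} with K at double weight (cationic polar face).
  For lengths ≥ 18 every wheel sector is occupied, so the analyzer
  measures exactly the requested arc; for shorter peptides unoccupied
  sectors can split the measured run, so closure is only guaranteed at
  full wheel occupancy (the generator/analyzer round-trip is tested at
  length 18).
- **Gradient**: the arc scaffold with its C-terminal ⌈L/3⌉ residues
  replaced from the hydrophobic pool.
- **Random control**: i.i.d. uniform residues.

Cysteine and methionine are absent from the design pools (synthesis
friendliness, no accidental disulfides), matching their exclusion from the
mutation alphabet.

**Redundancy filter**: exact duplicates removed, then greedy longest-first
clustering; identity is the fraction of matching residues at equal
positions normalized by the shorter length (alignment-free — adequate for
libraries of equal-register designs; it underestimates identity between
frame-shifted homologs). A sequence joins the first representative at
≥ 0.8 identity (configurable in (0.5, 1]), otherwise founds a cluster;
representatives return in first-appearance order. Word-index heuristics of
the original clustering tool are omitted: exact greedy comparison is
affordable at the 10⁵ scale used here. Library sizes default to 10³ in
tests and examples; production-scale runs (10⁵) use the same code path.

## Simulated molecular evolution

The mutation kernel starts from the published Grantham distance table
(atom composition, polarity, molecular volume), drops the C and M rows and
columns, divides each row by its own maximum (mapping to [0, 1] with zero
diagonal — "row-normalized" admits several readings; this one is recorded
in the kernel metadata and makes σ directly comparable across residues),
and applies the Gaussian transition rule. Consequences, all tested: rows
are probability distributions; the self-transition dominates each row;
P(i→j) decreases with d_ij at fixed σ; as σ → 0 the kernel approaches the
identity.

Offspring are drawn positionwise and independently; a position may draw
its own residue (no separate per-position mutation rate — the
self-transition probability at small σ produces the few-substitutions
regime by itself). σ defaults: 0.1 for exploration, 0.06 for close-analog
refinement; λ = 10 per generation by default. Forbidden residues (e.g.
proline, which kinks helices and abolished activity in practice) are
removed from every row with renormalization. Duplicate offspring are
re-drawn up to 100 times, then accepted with a warning so λ stays fixed.
Parents containing C or M are refused with the position reported.

Cohort diversity is summarized by per-position Shannon entropy over
observed residue frequencies, normalized by log₂ 20 to [0, 1] (0·log 0
taken as 0).

**Selection** is external by design: the engine never invents a fitness.
The default comparator ranks offspring by the pair (activity retained,
selectivity ratio), where activity retained means the best (lowest) EC50
over the target-cell columns is at or below a ceiling (default 50 µM, the
usual "inactive above" reporting bound), and the selectivity ratio is
nontarget EC50 divided by that best target EC50. Ties break
lexicographically on sequence. The narrative selection rule this encodes
("keep anticancer activity, maximize the margin to nontarget cells") is
one documented interpretation; any callable `(fitness_row, sequence) →
key` can replace it. A model-based surrogate (P_ACP as fitness) can be
plugged in the same way for purely in-silico loops.

## Synthetic labeled data

`make_fixture` emulates the corpus statistics the classifier assumes:
positives are amphipathic-arc constructions (arc ≥ 140°, cationic polar
face — hence high µ_H and positive charge), negatives are uniform random
sequences (near-zero expected amphipathic moment). The `separation`
parameter is the probability that a peptide follows its class rule rather
than the shared random background: 1 gives the full contrast (a linear
model reaches held-out MCC > 0.9 at n = 400), 0 makes labels pure noise
(|MCC| < 0.3). Defaults — 200 peptides per class, lengths 11–30, seed
42 — mirror a class-balanced, helix-scale design corpus at a size where
training completes in about a minute.

What the fixture does **not** emulate: natural sequence composition biases,
the activity continuum (labels are constructed, not assayed), homology
structure between related peptides, and negatives drawn from real folded
helices. Passing tests therefore demonstrate that the pipeline recovers a
planted cationic-amphipathic signal, not that the shipped defaults would
reproduce any particular performance on curated corpora; training on real
data uses exactly the same code path via `LabeledDataset.from_dataframe`.

## Numerical and interface conventions

- Seeds default to 42; every CLI artifact message echoes the seed, and the
  model JSON stores the seed plus a content hash of the training data.
  CLI subcommands are pure functions of (inputs, options, seed): repeated
  runs are byte-identical. Exit code 2 signals validation errors.
- Standardization uses population (ddof = 0) statistics; zero-variance
  features standardize with divisor 1.
- The linear solver uses liblinear (dual coordinate descent inside
  elimination, primal elsewhere) with tolerance 1e−3 during elimination;
  at the data scales involved the selected subsets are insensitive to the
  tolerance.
- CSV/TSV tables are UTF-8 with a mandatory header and "." decimals; FASTA
  I/O goes through Biopython.

## Known limitations

- The applicability-domain score compresses quickly with descriptor-space
  distance in 151 dimensions; absolute S values are small for generated
  libraries and should be read comparatively, not as probabilities.
- The redundancy filter's positional identity is not an alignment; it is
  intended for same-register designed libraries.
- Exact reproduction of published feature weights or corpus-level scores
  would require the original training corpus, which is not bundled; the
  package ships the machinery plus a synthetic corpus generator instead.
- The forest baseline does not serialize to JSON.
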