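# Methods

## Pocket extraction

Structures are parsed with gemmi from PDB or mmCIF.  HETATM groups are
candidate ligands unless they are waters (HOH/WAT/DOD) or single-atom
metal/ion groups; for alternate locations only the highest-occupancy
conformer is kept.  Two extraction rules are implemented:

* **Distance rule** (default cutoff 5.0 Å): a residue belongs to the pocket
  iff any of its non-hydrogen atoms lies within the cutoff of any
  non-hydrogen ligand atom.  Non-hydrogen atoms are used on *both* sides:
  most deposited structures lack hydrogens, and this makes the rule
  independent of protonation state.  The boundary is closed (d ≤ cutoff),
  which makes monotonicity in the cutoff exact.
* **vdW-contact rule** (pad 0.5 Å, minimum 2 contacts): a residue is a
  binding residue iff at least two distinct atom *pairs* (residue atom,
  ligand atom) satisfy d ≤ r_vdw(a) + r_vdw(b) + pad.  Radii come from a
  bundled Bondi-style table (C 1.70, N 1.55, O 1.52, S/P 1.80, halogens per
  Bondi); an element missing from the table raises rather than guessing.
  Whether the two contacts may reuse one residue atom is ambiguous in the
  rule's usual statement; we count distinct pairs.

Residue identity is (author chain, author residue number, insertion code).
Mapping to sequence positions for embedding lookup is explicit
(`map_pocket_to_sequence`) and validates residue names; unmapped residues
are dropped with a warning and pooling proceeds over the mapped subset.

## Clash quality filter

For transplanted/predicted complexes, a steric clash is any non-hydrogen
atom pair closer than 1.2 Å.  The pocket and ligand clash scores are the
fractions of intra-group pairs below the threshold (a single-atom group has
no pairs and scores 0 by convention); protein–ligand clashes are counted as
pairs.  A complex is kept iff pocket score < 0.005 AND ligand score < 0.01
AND cross count < 5 — values at a threshold are discarded.  Fractions use
non-hydrogen pairs in both numerator and denominator.

## Pocket featurization and the projection network

Per-residue embeddings come from a pluggable provider.  The reference
provider is the final hidden layer of the 650M-parameter ESM-2 checkpoint
(the variant whose width is 1280), with BOS/EOS stripped before alignment;
it requires torch + fair-esm at run time.  The bundled synthetic provider
satisfies the identical contract deterministically and is what the test
suite exercises.  Pocket features are the arithmetic mean of the pocket
residues' rows, pooled across chains when a pocket spans several.

The projection is two layers, 1280 → 512 → 256, each layer
affine → batch normalization → dropout (rate 0.1) → GELU (exact,
erf-based), including a GELU after the final layer.  Batch normalization
uses batch statistics during training (population variance) and running
statistics (momentum 0.1) in eval mode, so inference is deterministic and
batch-order invariant.  The network, its analytic backward pass and the
Adam optimizer are implemented on numpy arrays; the gradients are verified
against central finite differences to 1e-4 relative in the test suite
(entries whose true gradient is zero — the affine biases, which batch
normalization cancels — are checked for near-zero instead).

## The distillation loss

Raw similarities are not probabilities, so each batch anchor's similarity
row over the other B−1 members (latent cosine for P, fingerprint similarity
for Q) is divided by a temperature (default 1.0) and passed through a
softmax; both distributions are floored at epsilon = 1e-8 and renormalized
before the log.  The loss is KL(P‖Q) — the learned pocket distribution in
the leading position — averaged over anchors.  The gradient treats the
epsilon floor as inactive; its effect is O(epsilon) and is covered by the
finite-difference check.  Ligand similarity for Q defaults to cosine on the
2048-bit radius-2 Morgan fingerprints; Tanimoto is selectable and is the
metric used in the ligand-vs-pocket correlation analysis.  Temperature and
epsilon are configuration defaults, not externally fixed values.

## Training loop

Reference schedule: Adam at learning rate 0.001, batches of 128, 4096
training batches per epoch and 256 fixed validation batches, early stopping
with patience 100 (any decrease in mean validation loss resets it),
maximum 2000 epochs, returning the checkpoint with the lowest validation
loss.  Epoch batches are drawn with replacement from the training pool
(each batch is sampled without replacement within itself); the validation
batches are drawn once at startup from a seeded 90/10 split by pocket.  All
randomness — split, batch order, dropout masks, initialization — derives
from the config seed, so runs are bit-reproducible.

Tests and the acceptance script use a proportionally reduced schedule
(64 training / 16 validation batches per epoch, patience 10, max 100
epochs) on the default n = 1400 dataset; on this data early stopping
typically triggers after 30–50 epochs and the reduced schedule recovers
the planted structure fully, so nothing is gained by the reference-scale
schedule at fixture scale.

## Synthetic study conditions

`FixtureSpec` defaults emulate the seven-ligand-type benchmark at desk
scale: 7 classes × 200 pockets, 1280-d embeddings.  Class centers are
random unit vectors; samples add i.i.d. Gaussian noise with per-coordinate
sigma 1/√dim, so the expected within-class cosine of raw embeddings is
≈ 0.5 and between-class ≈ 0 — separable but noisy.  Fingerprints are class
templates of 64 class-specific bits plus 32 bits shared by all classes,
with independent 1% per-bit flips; with disjoint templates and no flips the
between-class Tanimoto is exactly shared/(2·class + shared), which anchors
the generator's unit tests.  The realized within-minus-between fingerprint
cosine gap (~0.54) is reported in dataset metadata.

What this does and does not show: the generator reproduces the *cluster
statistics* of a ligand-type-labelled pocket set — it makes recovery of
similarity structure and downstream classification well-posed and
falsifiable — but not the geometry of real language-model embeddings, real
chemical fingerprint correlations, or any biology.  Passing the recovery
tests demonstrates that the training machinery optimizes the right
objective and that the pipeline is wired correctly, not that the learned
representation transfers to real proteins.

The docking-score generator draws the neutral group from
Normal(−6.15, 1.5²) kcal/mol and the enriched group shifted 1.3 kcal/mol
more negative, matching the magnitude of group separation a real
enriched-vs-neutral docking comparison exhibits; the Gaussian form gives
the enrichment factor a closed-form oracle, EF(c) = Φ((c−μ+s)/σ)/Φ((c−μ)/σ).

## Statistics

* **Hypergeometric enrichment**: ES = (N_i_M/N_i_total)/(N_M/N_total); the
  p-value is the upper tail P(X ≥ observed) — a one-sided test for
  over-representation (the point-mass form is exposed only as a debug
  mode, since a point probability is not a test).  Multifunctional
  proteins count in every annotated class while background totals count
  each protein once.  No multiple-testing correction by default;
  Benjamini–Hochberg is an option.
* **Z-scores** use the global mean and population standard deviation
  (ddof = 0; configurable) over all rows.
* **EF(c)** counts scores ≤ c in each pool; an empty negative count makes
  EF undefined at that cutoff and it is reported as missing, never
  infinity.  Default cutoff grid −10 to −8 kcal/mol in 0.25 steps.
* **Monte Carlo EF** draws the configured sample size from *each* pool
  without replacement per iteration (drawing from real compound pools is
  without replacement; a combined-pool switch is available since the
  sampling population is ambiguous in common usage) and reports mean ± SD
  over iterations.  Note the sample EF is a ratio estimator with a
  first-order upward bias of ≈ EF·(1−p)/(np); tests compare against the
  delta-method-corrected mean.
* **Top fraction** per target is the ⌈f·n⌉ most negative scores, ties at
  the boundary broken by compound id.
* **Mann–Whitney U** (one-sided, x stochastically smaller): U from rank
  sums with midranks; exact p for untied samples with combined n ≤ 20,
  otherwise a normal approximation with tie-corrected variance and
  continuity correction; effect size r = z/√N, signed.

## Screening filters

Proteome screening keeps pockets with volume ≥ 800 Å³ (the threshold value
itself is kept), mean pocket pLDDT ≥ 0.7, and best cosine to the reference
panel strictly > 0.8.  pLDDT is accepted on either the 0–1 or 0–100 scale
and normalized internally (predicted-structure files commonly ship 0–100
while thresholds are quoted on 0–1).  Deduplication by accession keeps the
pocket with the highest cosine.  k-NN search is exhaustive (exact at any
realistic panel size), ties broken lexicographically by reference id, and
exact pocket-id self-matches are excluded when the query set overlaps the
reference set.

## Classifier benchmark

The 9:1 split is stratified by label (plain random splitting can empty the
rarest class).  The feedforward family is one hidden layer of 128 units
(Adam, lr 0.001, up to 200 epochs); the SVM family is RBF with the scale
bandwidth heuristic, one-vs-rest — both are this package's contracts, with
inputs standardized per split.  Metrics are computed from the confusion
matrix with the zero-denominator convention precision/recall = 0, keeping
macro averages defined.

## Known limitations

* The ESM-2 provider is untestable offline; its contract is exercised
  through the synthetic provider only.
* Training at the reference scale (hundreds of thousands of pockets) is
  supported by the same code path but is not covered by the test suite.
* The clash filter and extraction rules assume reasonable input geometry;
  pathological files (all-zero coordinates, duplicated atoms) pass parsing
  and are only caught statistically.
* Long-chain windowed embedding (sequences beyond a provider's context
  window) is delegated to the provider; the synthetic provider has no
  length limit, so stitching is not exercised by tests.
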