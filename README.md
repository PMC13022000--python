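# erepoc

Contrastive representations of protein binding pockets, distilled from the
chemical similarity of their bound ligands.

## The problem

Binding pockets are the functional units that matter in small-molecule drug
discovery — in particular for DNA-encoded library (DEL) screening, where
knowing whether a target's pocket "looks like" pockets that DEL chemistry
has engaged before is directly actionable.  Pockets are flexible, and two
pockets that bind the same ligand can have poor 3D structural similarity, so
geometric alignment alone underdetermines functional similarity.  This
package learns a function-aware pocket representation instead: a pocket is
featurized as the mean of its residues' protein-language-model embeddings,
and a small network is trained so that cosine similarity between pocket
latents mirrors the similarity of the ligands those pockets bind.

## The model

Each residue of the protein sequence is embedded by a protein language
model (reference provider: the 650M-parameter ESM-2 checkpoint, d = 1280
per residue).  A pocket — the residues within 5 Å of the bound ligand, or
the van-der-Waals-contact binding residues — is pooled by the arithmetic
mean of its residue vectors, **P** ∈ ℝ¹²⁸⁰.  A two-layer projection
(1280 → 512 → 256, each layer affine → batch norm → dropout 0.1 → GELU)
maps **P** to a latent **T** ∈ ℝ²⁵⁶:

    T = GELU(W P + b)

Within a training batch of 128 pockets, two per-anchor distributions are
formed over the other 127 members: P(i) from latent cosine similarities and
Q(i) from ligand fingerprint similarities (2048-bit radius-2 Morgan
fingerprints, cosine by default), each via a temperature softmax.  The loss
is the KL divergence

    loss = mean_i Σ_j P_ij log(P_ij / Q_ij)

minimized with Adam (lr 0.001), early stopping on validation loss.  The
network and its gradients are implemented directly in numpy and verified
against finite differences.

Around the model, the package provides the full supporting pipeline:

- `erepoc.structure` — PDB/mmCIF parsing (gemmi), both pocket-extraction
  rules, the steric-clash quality filter (discard at pocket clash fraction
  ≥ 0.005, ligand ≥ 0.01, or ≥ 5 cross clashes), amino-acid enrichment
  ratios;
- `erepoc.chem` — Morgan fingerprints (RDKit), Tanimoto and cosine
  similarity;
- `erepoc.similarity` — exact cosine k-NN, strict-threshold neighbor sets,
  proteome screening filters (volume ≥ 800 Å³, pocket pLDDT ≥ 0.7, cosine
  > 0.8, dedupe by accession), ligand-vs-pocket correlation;
- `erepoc.benchmark` — the 7-ligand-type classification benchmark
  (feedforward and RBF-SVM families, stratified 9:1 split, confusion-matrix
  precision/recall/F1);
- `erepoc.enrichment` — hypergeometric over-representation of protein
  classes (ES = proportion ratio, upper-tail p);
- `erepoc.delstats` — docking-score statistics: global Z-scores,
  enrichment factors EF(c), Monte Carlo EF curves, top-1% extraction,
  one-sided Mann–Whitney U with effect size r = z/√N;
- `erepoc.fixtures` — synthetic generators (toy structures with known
  pocket geometry, planted-cluster embedding datasets, two-group docking
  scores) so the whole pipeline runs offline.

## Worked example

```python
import numpy as np
from erepoc import fixtures, model, similarity

# 7 ligand classes, 200 pockets each, 1280-d embeddings + 2048-bit fingerprints
ds = fixtures.make_embedding_dataset(fixtures.FixtureSpec(seed=7))

cfg = model.TrainingConfig(train_batches_per_epoch=64, val_batches_per_epoch=16,
                           patience=10, max_epochs=100, seed=7)
m, history = model.train(ds.embeddings, ds.fingerprints, cfg)
latents = model.encode(m, ds.embeddings)

r_latent = similarity.ligand_pocket_correlation(latents, list(ds.fingerprints),
                                                n_sample=500, seed=1)
r_raw = similarity.ligand_pocket_correlation(ds.embeddings, list(ds.fingerprints),
                                             n_sample=500, seed=1)
print(f"epochs {history.stopped_epoch + 1}, "
      f"r(latent) = {r_latent:.3f}, r(raw) = {r_raw:.3f}")
```

prints (to run-to-run stochastic variation in the third decimal):

```
epochs 29, r(latent) = 0.998, r(raw) = 0.986
```

i.e. after training, the Pearson correlation between pairwise ligand
similarity and latent pocket cosine over all pairs of 500 sampled pockets
rises to ~1, above the correlation the unprojected pooled embeddings
already carry on this planted-cluster data.  The same latents classify the
seven pocket types at macro-F1 = 1.0 with both classifier families.

The same pipeline is scriptable from the shell:

```sh
erepoc fixtures embeddings --n 1400 --classes 7 --out data/
erepoc train --emb data/embeddings.tsv --fp data/fingerprints.tsv --out model.npz
erepoc encode --model model.npz --emb data/embeddings.tsv --out latents.tsv
erepoc search knn --query latents.tsv --ref latents.tsv -k 5 --out hits.tsv
```

Every command writes a `.manifest.json` beside its output recording the
resolved parameters, seeds and input hashes.

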