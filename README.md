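# ms2struct

De-novo molecular structure recommendation from tandem mass spectra.

## The problem

Identifying the compound behind an MS/MS spectrum is normally done by
matching the spectrum against a reference library — which fails outright
for novel molecules that no library contains. `ms2struct` attacks the
inverse problem directly: given up to four MS/MS spectra of one compound
({[M+H]+, [M−H]−} precursors × {35%, 130%} normalized collision energy),
it generates ranked candidate structures as SMILES strings, including
structures never seen in any database. It is aimed at metabolomics and
small-molecule identification workflows where library search has come up
empty.

## The method

Two neural models share one latent space:

* a **SMILES autoencoder** — a GRU encoder/decoder trained on a
  translation task, randomized SMILES → canonical SMILES, so the
  fixed-length embedding captures the molecule rather than one of its many
  string spellings;
* a **spectra encoder** — two strided 1-D convolutions plus two dense
  layers over the 4-channel binned-intensity tensor (1 Da bins, 0–500 Da,
  max-normalized per channel, missing spectra as all-zero channels),
  trained to minimize the RMSE against the frozen autoencoder embedding of
  the true molecule.

At inference the spectra embedding is decoded two ways: **direct** pure
sampling from the decoder (novel structures), and **indirect** retrieval of
the nearest molecule embeddings from a reference pool. The union is ranked
by discrepancy from the expected molecular weight MW (read off the
precursor peak, hence treated as known) and the top 20 are returned.

Candidates are scored against references with: exact structure/formula
rates; relative discrepancies DMW = mean|ΔMW| / mean MW_ref and
DMF = mean formula distance / mean heavy-atom count; per-element presence
sensitivity/specificity; Morgan (r=2, 1024-bit) fingerprint cosine; and
maximum-common-substructure ratios a_MCS/a_r, a_MCS/(a_r+a_p−a_MCS),
a_MCS/min(a_r,a_p) under strict matching (element, bond order, ring bonds
only onto ring bonds).

Real spectral libraries of this shape are commercial, so the package ships
a deterministic toy fragmentation simulator (single acyclic-bond cleavages,
a second round at high collision energy, exponential intensity decay) that
reproduces the dataset's structure — four conditions, missing spectra,
energy-perturbation augmentation, Tanimoto-disjoint test split — at desk
scale. See `docs/methods.md` for the model, simulator, and design details.

## Worked example

The five CLI stages run the whole study from one YAML config (here just a
seed and an output directory; everything else falls back to the built-in
toy profile — 300 molecules, ≤ 16 heavy atoms):

```text
$ ms2struct simulate -c config.yaml
molecules: 300
  4 spectra: 67
  3 spectra: 121
  2 spectra: 80
  1 spectra: 32
splits: {'train': 274, 'val': 13, 'test': 13}

$ ms2struct train-ae -c config.yaml
final loss: 0.0157
train char accuracy: 0.9998
train exact reconstruction: 0.9964
val exact reconstruction: 0.0000
checkpoint: run/ae.npz (hash 9b3de712e5407d4e)

$ ms2struct train-spec -c config.yaml
rmse epoch 1: 0.7612  final: 0.0156
checkpoint: run/spec.npz (AE hash 9b3de712e5407d4e)

$ ms2struct predict -c config.yaml
wrote 13 candidate tables to run/candidates

$ ms2struct evaluate -c config.yaml
cases evaluated: 13
correct molecules: 0.0%
correct formulas: 7.7%
DMW min/avg: 1.0% / 13.8%   DMF min/avg: 17.7% / 46.1%
Fngp cosine max/avg: 0.47 / 0.22   MCS_tan max/avg: 0.60 / 0.32
```

Reading the numbers: the autoencoder memorizes its 274 training molecules
almost perfectly (99.98% per-token, 99.6% exact round-trip) while unseen
validation molecules do not round-trip at this tiny scale. The spectra
encoder's embedding error collapses (RMSE 0.76 → 0.016), so training
spectra land next to their own molecule in latent space. The 13 test
molecules are deliberately structurally novel (max Tanimoto < 0.9 to
everything in train/val), and the candidates recover them only partially:
the best candidate's molecular weight is within ~1% of the truth, the best
common substructure covers over half the reference (MCS_tan max 0.60), but
exact structure recovery of novel molecules is rare — which is the honest
difficulty of the task at any scale.

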