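# Methods

`ms2struct` recommends de-novo molecular structures for tandem mass spectra
(MS/MS). This note records the models, the synthetic data they are trained
on at desk scale, and the numerical and design choices a maintainer would
want to know about.

## Problem setting

An MS/MS spectrum records fragment-ion m/z against intensity. A molecule's
measurement here is up to four spectra — two precursor ions ([M+H]+ and
[M−H]−) at two normalized collision energies (35% and 130% NCE) — with
missing spectra allowed. The task is the inverse problem: given the spectra,
propose plausible molecular structures, including structures absent from any
reference library. Stereochemistry is out of scope throughout: it is not
recoverable from fragment masses, so all SMILES are stereo-stripped.

## Architecture

Two models share one latent space of dimension `d_embed`:

1. **SMILES autoencoder** (`autoencoder`). A GRU encoder reads a tokenized
   SMILES and projects its final hidden state through a tanh-bounded dense
   layer into the embedding; a GRU decoder, initialized from the embedding,
   emits the canonical SMILES token by token. Training is a translation
   task: each epoch every molecule is presented as a *freshly randomized*
   SMILES (a random atom-ordering rewrite) with the canonical form as the
   target, so the embedding must encode the molecule rather than one surface
   string. The loss is mean per-token cross-entropy under teacher forcing.
   Tokens, not raw characters, are the unit: two-letter elements (Cl, Br)
   and bracket atoms are atomic tokens, since a character-level split would
   corrupt chemistry. Accuracy is reported two ways: teacher-forced
   per-token accuracy, and the exact-reconstruction rate (greedy decode,
   then canonical-SMILES equality; invalid decodes are misses).

2. **Spectra encoder** (`spectra_encoder`). Each spectrum is binned
   (`floor(m/z / bin_width)`, left-closed bins, default 1.0 Da over 0–500 Da)
   and max-normalized; the four (precursor, energy) channels stack into a
   4 × 500 tensor, absent channels all-zero. Two strided 1-D convolutions
   and two dense layers (ReLU between all stages) map the tensor to
   `d_embed`. Training minimizes the RMSE between the spectra embedding and
   the *frozen* autoencoder's embedding of the true molecule.

Both are implemented on a compact NumPy layer library (`nn`) with manual
backpropagation (GRU, strided conv, dense, embedding, masked softmax
cross-entropy, Adam with gradient-norm clipping). All forward/backward
passes are batch-vectorized float32; analytic gradients are pinned by
central-difference tests.

### Generation and ranking (`generation`)

For a query embedding, candidates come from two routes:

* **direct** — decode the embedding repeatedly with *pure sampling* (each
  token drawn from the full untruncated softmax; no temperature, no top-k),
  keep syntactically valid SMILES, canonicalize, deduplicate;
* **indirect** — retrieve the k nearest molecule embeddings (Euclidean)
  from a reference pool and greedy-decode them, falling back to the stored
  pool SMILES when a decode is invalid.

The union is ranked ascending by |MW − reference MW| — the molecular weight
is treated as known, since it is read off the precursor peak — and truncated
to the top 20. Ties break indirect-first, then lexicographically (an
arbitrary but documented and configurable total order). Defaults
`n_samples=100`, `k=20` are package choices.

### Evaluation suite (`evaluation`)

Per candidate set against its reference: molecular-weight and formula
discrepancies, per-element presence sensitivity/specificity (O, N, S, Cl,
F, Br, P, I; carbon excluded as always present; empty denominators reported
as not-available rather than 0), Morgan (radius 2, 1024-bit) fingerprint
cosine, and three maximum-common-substructure ratios
(`a_mcs/a_r`, `a_mcs/(a_r+a_p−a_mcs)`, `a_mcs/min(a_r,a_p)`). Dataset
aggregates divide the mean per-case minimum (or mean) discrepancy by the
mean reference MW / heavy-atom count, × 100.

MCS matching respects element identity, exact bond order, and ring
membership (ring bonds and ring atoms only match their kind), and the
common substructure must be **connected and contain at least one bond** —
so benzene vs cyclohexane scores 0, not 1 atom. RDKit's `FindMCS` performs
the search (10 s cap per pair; on timeout the best-so-far substructure is
used and a warning logged); an independent brute-force enumerator
(connected edge subsets + networkx monomorphism) validates it exhaustively
on a 30-molecule panel in the test suite. Exact-formula comparison includes
hydrogens (the stricter reading); the formula *distance* excludes them by
definition.

## Synthetic data (`simulate`)

Real MS/MS training libraries are commercial, so the package generates its
own study conditions:

* **Library**: seeded random assembly of scaffolds (chains, 5/6-rings,
  aromatics with N/O/S) plus substituents (alkyl, O/N/S, halogens, nitrile,
  carboxyl, ...), deduplicated by canonical SMILES, bounded at
  `max_heavy_atoms` (default 20; default size 2,000).
* **Toy fragmentation**: every acyclic bond is cleaved once; at NCE ≥ 100 a
  second cleavage round applies to each first-level fragment. Fragments
  keep their parent hydrogens, so the two sides of a cleavage sum exactly
  to the parent neutral mass (asserted to 1e-3 Da). Ion m/z = monoisotopic
  fragment mass ± 1.00728 Da by precursor mode. Intensity falls off as
  `exp(−decay·|k − n/2|)` for a k-heavy-atom fragment of an n-atom parent
  (strongest fragment scaled to 999); the precursor peak decays with NCE as
  `999·exp(−NCE/100)`; the seed adds a deterministic ±5% jitter. Peaks
  within 0.01 Da merge.
* **Missing data**: each of the four spectra is deleted independently with
  probability 0.29 — the overall fraction of absent channels implied by the
  availability strata of the reference library this generator emulates —
  re-adding one if all four are deleted. Independent deletion does not
  reproduce that library's bimodal strata shape (missing precursor modes
  come in pairs there); the stratified reporting machinery is exercised all
  the same.
* **Augmentation**: each training instance gains a twin re-simulated at
  NCE ± 5%, standing in for selecting the closest-energy real replicate,
  which requires a deep library that does not exist at desk scale. Channel
  availability and target molecule are preserved; the training split doubles.
* **Partitioning**: a seeded shuffle proposes test molecules; one enters
  the test set only if its maximum Morgan/Tanimoto similarity to all
  remaining train+val molecules is < 0.9 (brute-force verified in tests).
  Val/test fractions default to 1/23 each, echoing ~1K-of-23K proportions.

What the simulator deliberately does **not** model: rearrangement chemistry,
ring-cleavage energetics, isotope envelopes, adducts beyond [M+H]+/[M−H]−,
instrument noise, profile-mode peaks. Passing tests therefore demonstrate
that the architecture learns structure→spectrum→structure associations when
the signal exists; they say nothing about accuracy on real instrument data.

## Study conditions and observed behaviour

The standard desk-scale conditions, fixed in the acceptance tests and
`scripts/acceptance.py`: a 2,000-molecule corpus (≤ 20 heavy atoms) for the
autoencoder (120 epochs, ~5 min CPU) and a 1,000-molecule simulated-spectra
pool for the spectra encoder (100 epochs, ~1 min CPU). The tests assert
teacher-forced token accuracy ≥ 0.95 and exact reconstruction ≥ 0.70 on the
training split, spectra→molecule top-1 self-retrieval ≥ 50% over the pool,
and falling RMSE; the script reports whatever the run actually produces.

## Numerical choices

* Canonicalization delegates to RDKit's canonical SMILES algorithm
  (stereo stripped first); randomization uses a seeded atom renumbering, so
  every stochastic draw in the package flows from explicit integer seeds.
* Multi-fragment (dot-disconnected) SMILES are rejected everywhere: salts
  and mixtures are out of scope.
* Molecular weight for ranking/evaluation is the *average* MW (RDKit
  `MolWt`), switchable to monoisotopic; the simulator's m/z arithmetic is
  monoisotopic, as fragment masses physically are.
* Embeddings are tanh-bounded; Adam runs with norm-5 gradient clipping and
  geometric lr decay (2.5e-3 → 3e-4 over the run) — without the decay the
  decoder plateaus well short of exact-reconstruction memorization.
* The all-zero channel tensor (no spectra at all) is accepted by the
  encoder (finite output) but rejected as a CLI query, since a prediction
  from no evidence is meaningless.
* Checkpoints store weights plus config and a 16-hex weight hash; the
  spectra encoder records its companion autoencoder's hash and `predict`
  refuses mismatched pairs.

## Known limitations

* The decoder has no syntax constraints, so sampled SMILES can be invalid;
  they are filtered, and the validity rate is logged per query.
* GRU capacity, not data, bounds exact reconstruction beyond ~35 tokens;
  `max_seq_len` defaults to 64 tokens and longer molecules are skipped with
  a warning during training.
* The embedding index is a flat exact-distance scan — appropriate for
  1e3–1e5 molecules, not for 1e8.
* One CPU-friendly scale is wired in as defaults; the architecture accepts
  larger vocabularies, deeper GRUs (`n_gru_layers`) and longer inputs
  without code changes.
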