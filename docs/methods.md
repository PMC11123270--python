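# Methods

## The problem

A ¹H NMR spectrum of a small organic molecule shows one resonance per set of
topologically equivalent hydrogens, at a chemical shift δ (ppm) fixed by the
electronic environment of those protons.  Experimental shift libraries cover
only a few percent of known metabolites, drugs, and natural products, so
matching measured spectra against reference libraries fails for most
compounds.  `protonshift` predicts δ for every hydrogen equivalence group of
a molecule directly from its structure, so that large predicted libraries can
stand in for missing experimental ones.

## Model

### Input representation

A SMILES string (or SDF block) is made hydrogen-complete and renumbered
canonically: heavy atoms first in canonical-rank order, hydrogens after,
ordered by their heavy neighbor's slot.  The ranking uses RDKit's canonical
atom ranking with chirality excluded, so the numbering is a pure function of
the molecular graph — the same molecule always receives the same indices,
whatever the input atom order, and stereo annotations picked up from 3D
coordinates on an SDF round trip cannot change it.  A single conformer is
chosen as the lowest-MMFF-energy member of a five-conformer ETKDG ensemble
embedded with a fixed seed; multi-conformer averaging is out of scope.

The molecule becomes a graph: one node per atom carrying an element-type
embedding (vocabulary H/C/N/O/S, width D), and directed edges for every atom
pair within a 4.0 Å cutoff plus every bonded pair regardless of distance.
Each edge carries a Gaussian radial-basis expansion of its interatomic
distance (centers evenly spaced on [0, cutoff], width = spacing) concatenated
with a bonded-pair indicator — the input is "atom types, interatomic
distances, and connectivity", and the indicator is how connectivity enters
the edge feature.

### Network

* **Edge network** — two dense ReLU layers map `[h_src, h_dst, e_rbf]` to a
  per-edge gating feature.
* **Message passing** — T = 3 iterations with shared weights.  The message
  along edge (src→dst) is the edge feature gating a linear transform of the
  source node state; messages arriving at the same node are **summed**, and
  the node state is updated by a gated recurrent (GRU) cell.
* **Readout** — three dense ReLU layers (widths 256/256/128 at full scale)
  and a linear scalar head give one shift per node.  All nodes pass through
  the readout; only hydrogen nodes contribute to loss and output.

Regression targets are standardized with the training-set mean and standard
deviation; the scaling constants live in the checkpoint and are never
fine-tuned.  Because every feature depends only on element types, distances,
and bonds, the output is invariant to rigid motions and equivariant to node
permutations (asserted to 1e-5 ppm in the acceptance suite).

The per-group prediction is the mean of the group's member-node outputs.
Labile hydrogens (bonded to O, N, or S) exchange with protic solvent and are
excluded from output in water mode; in methanol, chloroform, and DMSO modes
they are reported.

### Fine-tuning with frozen layers

Transfer learning bridges a cheap, abundant source domain (e.g. computed
shifts) and a small, accurate target domain (curated experimental shifts).
Exactly **six** layers are trainable during fine-tuning: the two edge-network
dense layers, the three readout layers, and the head.  Embeddings and all
message-passing/GRU weights stay frozen — bitwise unchanged, which the test
suite checks array by array.  The six-layer inventory resolves an ambiguity
in the protocol description (the edge-network dense layers are named
trainable while the message-passing update is named frozen); 2 + 3 + 1 is
the only layer assignment consistent with both statements and the count.

### Training schedule

Defaults are the published protocol: Adam, mean-absolute-error loss over
assigned hydrogen nodes (group shifts broadcast to members), batch size 32,
initial learning rate 5e-4 with a 4% decay every 70 epochs
(`lr = lr0·0.96^⌊epoch/70⌋`), at most 1200 epochs, validation loss checked
every 10 epochs, early stop when a checkpoint's validation loss exceeds
1.10× the previous checkpoint's, and the minimum-validation checkpoint
returned.  The validation split is molecule-level (10% by default,
seed-controlled) so no molecule contributes shifts to both sides.

## Reduced CPU profiles

Full-scale dimensions (D = 256, 64 RBF centers) are impractical for
CPU-bound tests, so a reduced profile is provided: D = 64, 16 RBF centers,
readout widths 64/64/32.  Two optimization profiles accompany it, chosen for
the regimes the tests exercise:

* `TrainConfig.reduced_scratch` — lr0 3e-3, batch 2, 12% decay every 10
  epochs, early stopping effectively disabled.  Scratch runs on noiseless
  oracle labels are *meant* to overfit; MAE + Adam leaves a loss floor
  proportional to the final step size, so a small model on a few hundred
  group labels needs a larger initial rate, many small steps, and a fast
  decay to converge inside a 300-epoch budget.  (Pretraining runs on a few
  hundred molecules use the same profile with batch 8.)
* `TrainConfig.reduced_finetune` — the published schedule itself (lr0 5e-4,
  4%/70 decay, 10% early-stop rule) with batch 8 and a 300-epoch cap, which
  is stable and fast for fine-tuning six layers on tens of molecules.

`TrainConfig()` with no arguments is always the published full-scale
protocol.

## Solvent and reference corrections

The model's native scale is water/DSS (the training condition).  Moving to
methanol, chloroform, or DMSO applies a fitted linear map
δ_solvent = a·δ_water + b; changing the 0-ppm standard (DSS/TMS/TSP) adds a
constant offset on the DSS-anchored scale.  Corrections apply after
per-group averaging, before CSV output.  The shipped calibration is the
identity with zero offsets: the published fitted coefficients live in an
appendix not reproduced in the source text, and inventing numbers and
presenting them as calibrated would be worse than shipping a calibration
tool.  `fit_solvent_map` (ordinary least squares via scipy) calibrates each
map from any paired-shift table; offsets are plain configuration sourced
from the referencing literature.

## Curation

Assignment tables are remapped onto the canonical numbering through an
explicit old→new bijection (records citing unmapped indices go to a rejects
list, never silently dropped).  `validate_dataset` machine-checks the error
classes that plague public assignment tables: shifts bound to non-hydrogen
atoms, shifts outside [−2, 20] ppm, duplicate (molecule, atom) entries, and
equivalent protons reported with a spread above 0.02 ppm (typical
peak-picking precision).  `flag_outliers` compares a predictor against
observations and flags |Δ| **strictly greater than** 1.0 ppm for human
review — the tools build review queues and never auto-correct, because
reassignment is an expert decision.

## Synthetic data

No experimental dataset ships with the package.  A deterministic grammar
(scaffolds: alkane chains, cyclopentane/cyclohexane/THF/pyrrolidine rings,
benzene, pyridine, naphthalene; substituents: hydroxyl, amine, methyl,
ethyl, methoxy, carboxyl, acetyl, formyl, oxo) emits valence-correct C/H/N/O
molecules inside the 31–566 Da window typical of metabolite libraries.  An
additive topological oracle labels each hydrogen group:

    δ(group) = base(class) + Σ increment(element, d)  + noise,  d ∈ {1,2,3}

where `class` is the heavy-neighbor element × hybridization (e.g. sp³ C–H
base 1.0 ppm, aromatic C–H 7.2 ppm, O–H 3.6 ppm) and the increments sum over
heavy atoms within topological distance 3 of the anchor.  Noise is drawn
once per equivalence group, matching how experimental tables report shifts.
Default parameters keep labels in [0, 12] ppm and span ≥ 6 ppm over a
population draw.

A systematically perturbed oracle (global slope 0.95, offset 0.2 ppm,
per-class deltas ≤ 0.3 ppm) emulates the computed-vs-experimental domain gap
that fine-tuning corrects; by construction δ_B = 0.95·δ_A + 0.2 + Δ(class)
exactly.

**What passing tests do and do not show.**  The oracle is additive and
topological, with exact labels; real shifts include conformational,
electronic, and intermolecular effects no additive rule captures, and real
assignments carry correlated errors.  Tests on oracle data demonstrate that
the pipeline is wired correctly — the network can represent and learn
shift-like functions from 3D structure, fine-tuning moves exactly the
designated layers and closes a systematic domain gap, curation flags what it
should — not that any particular accuracy carries over to experimental
spectra.

## Numerical choices

* The network, backprop, and Adam run on a small reverse-mode autodiff core
  over NumPy float64; gradients are verified against central finite
  differences in the test suite.
* Adam uses β₁ = 0.9, β₂ = 0.999, ε = 1e-8; no gradient clipping.
* Sigmoid inputs are clipped to ±60 before exponentiation (saturation is
  exact at double precision long before that).
* Degenerate inputs error early: molecules with < 2 atoms, empty loss masks,
  solvent-map fits with < 3 pairs or constant abscissa, zero-slope map
  inversion, constant observations in R².
* Tie-breaks: equivalence groups are ordered by their lowest member index;
  the best checkpoint is the first one attaining the minimum validation
  loss.
* Problem sizes in the acceptance script: 20 molecules for symmetry and
  capacity checks, 150 pretraining / 40 fine-tuning / 30 held-out molecules
  for the transfer study, 200 pairs for solvent-map recovery, 50 random
  fixtures for metric cross-checks.

## Known limitations

* Shipping solvent maps are identity placeholders until calibrated.
* Single-conformer featurization; conformer-sensitive shifts (rotamer
  averaging, ring flips) are not modeled.
* No ¹³C prediction, no coupling constants, no uncertainty estimates.
* Salts/mixtures, tautomer enumeration, and pH-dependent protonation are out
  of scope; aromatic solvents (pyridine, benzene) need nonlinear corrections
  and are not supported.
* The full-scale (D = 256) profile is CPU-expensive to train in this
  implementation; the reduced profile is the supported test configuration.
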