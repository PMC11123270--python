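# protonshift

Solvent-aware ¹H NMR chemical shift prediction for small organic molecules,
built around a distance-edge message-passing graph neural network with a
layer-frozen transfer-learning protocol.

## Who this is for

NMR-based metabolomics, natural-product, and drug-metabolism work leans on
matching measured spectra to reference libraries, but only a few percent of
known compounds have experimentally assigned ¹H spectra.  `protonshift`
predicts, from a SMILES string or SDF file, one chemical shift δ (ppm) per
hydrogen equivalence group — the quantity an assignment table reports — in
water, methanol, chloroform, or DMSO, referenced to DSS, TMS, or TSP.

## The model in brief

A hydrogen-complete, canonically numbered 3D structure becomes a graph whose
nodes are atoms (element embeddings, width D) and whose edges connect every
atom pair within 4 Å plus all bonded pairs, carrying a Gaussian expansion of
the interatomic distance and a bond indicator.  An edge network (2 dense
layers) gates T = 3 shared message-passing steps with summed messages and a
GRU node update; a readout (dense 256/256/128 + scalar head) maps each
hydrogen node to δ.  Training minimizes the mean absolute error

    MAE = (1/N) Σ |δ_pred − δ_obs|

with Adam, lr = 5·10⁻⁴ · 0.96^⌊epoch/70⌋, batch 32, validation checked every
10 epochs, early stop on a >10% validation rise, best checkpoint returned.
Fine-tuning a pretrained model updates exactly 6 layers (edge network ×2,
readout ×3, head); everything else stays bitwise frozen.  Predictions on the
water/DSS scale are converted to other conditions by linear solvent maps
δ_solvent = a·δ_water + b and constant reference offsets.  Labile hydrogens
(O–H, N–H, S–H) are suppressed in water output and reported in organic
solvents.

The network, backpropagation, and Adam are implemented on a compact
reverse-mode autodiff core over NumPy (`protonshift.autodiff`), with
gradients verified against finite differences in the test suite.

Since no experimental dataset ships with the package, a synthetic module
generates C/H/N/O molecules (31–566 Da) with exact oracle shift labels from
an additive topological rule, plus a systematically perturbed second oracle
for transfer-learning studies.  See `docs/methods.md` for the full account.

## Worked example

Train a reduced-profile model on synthetic data and predict ethyl acetate:

```bash
protonshift synth --n 60 --seed 11 --out-sdf train.sdf --out-assignments train.csv
protonshift train --structures train.sdf --assignments train.csv \
    --reduced --epochs 300 --seed 0 --out model.npz
protonshift predict --smiles "CCOC(C)=O" --solvent water --reference DSS \
    --checkpoint model.npz --out ethyl_acetate.csv
cat ethyl_acetate.csv
```

The run prints (numbers from this exact command sequence):

```
60 molecules, 262 group labels -> train.sdf, train.csv
trained 60 molecules, 300 epochs, best val MAE 0.0349 ppm -> model.npz
input: 3 hydrogen group(s) -> ethyl_acetate.csv
atom_indices,shift_ppm,solvent,reference
7;8;9,1.65,water,DSS
10;11;12,1.44,water,DSS
13;14,2.42,water,DSS
```

Ethyl acetate's eight protons collapse to three equivalence groups — two
methyls (canonical atoms 7–9 and 10–12) and the O–CH₂ (13–14) — one row
each.  The shifts are on the *synthetic-oracle* scale this toy model was
trained on (oracle truth 1.84, 1.49, and 2.16 ppm for these groups), not
experimental values; train on a curated experimental table to get chemical
reality.  Predicting with `--solvent chloroform` would additionally pass the
values through the chloroform solvent map (identity until you calibrate one
with `protonshift calibrate-solvent`).

Methanol (`CO`) illustrates the labile-hydrogen rule with the same
checkpoint: water mode prints one row (CH₃ 1.85 ppm); chloroform mode prints
two (OH 3.73 ppm becomes visible — oracle truth 3.72).

## Repository layout

```
src/protonshift/
  chem_io.py     structures, canonical numbering, 3D embedding, equivalence
  autodiff.py    minimal reverse-mode tensors (the training engine)
  gnn.py         featurization, network, checkpoints, prediction
  training.py    schedule, loss, early stopping, scratch + fine-tune loops
  solvent.py     linear solvent maps, reference offsets, calibration files
  curation.py    assignment remapping, validation, outlier flagging
  synthetic.py   molecule grammar + additive shift oracle
  metrics.py     MAE, R², through-origin slope, cosine similarity
  cli.py         predict / train / finetune / evaluate / curate / synth /
                 calibrate-solvent
```
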