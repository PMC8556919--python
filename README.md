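# specsim

Predict fingerprint-based structural similarity (Tanimoto / Dice) between
pairs of tandem mass spectra, directly from binned peak vectors.

A Siamese dense network (two hidden layers, batch normalization, dropout,
L1/L2 on the first layer) maps each binned MS/MS spectrum to a
low-dimensional embedding; the cosine of two embeddings is the predicted
structural similarity of the underlying compounds. Training pairs are drawn
with balanced sampling over similarity-score bins and augmented on the fly
(low-intensity peak removal, intensity jitter, low-intensity peak addition).
Monte-Carlo dropout provides a per-pair uncertainty estimate (median +
interquartile range over n x n sampled scores). The network is implemented
directly on numpy — no GPU framework needed — with fully seeded,
single-threaded, reproducible training.

## Layout

| module | role |
| --- | --- |
| `specsim.spectra_io` | read/write/select annotated spectra (MGF, MSP, internal JSON) |
| `specsim.binning` | peak filtering, sqrt transform, fixed-grid binning, known-bin reduction |
| `specsim.labels` | InChIKey grouping, RDKit fingerprints, Tanimoto/Dice label matrices |
| `specsim.pairs` | balanced pair generator with score-bin widening and augmentation |
| `specsim.model` | Siamese network, Adam/MSE training, early stopping, text-archive persistence |
| `specsim.ensemble` | Monte-Carlo-dropout draws, median/IQR ensemble scores, IQR filtering |
| `specsim.evaluation` | all-vs-all scoring, per-label-bin RMSE/MAE, precision/recall, same-compound aggregation |
| `specsim.synthetic` | synthetic compound libraries with a planted spectrum–fingerprint correlation |
| `specsim.cli` | `specsim` command-line workflow |

## CLI

End-to-end on synthetic fixtures:

```bash
specsim synth --out lib.mgf --fingerprints-out fps.json --seed 1
specsim preprocess --spectra lib.mgf --format mgf --out binned.json \
    --binning scheme.json --n-bins 1000
specsim labels --fingerprints fps.json --metric tanimoto --out labels
specsim train --binned binned.json --labels labels --model model_dir --seed 1
specsim embed --binned binned.json --model model_dir --out embeddings.tsv
specsim score --binned binned.json --model model_dir --labels labels --out scores.tsv
specsim mc-score --binned binned.json --model model_dir --out mc.tsv --n-draws 10
specsim evaluate --binned binned.json --model model_dir --labels labels --out report.json
```

For real libraries, `specsim labels --spectra library.mgf --fingerprint
daylight --metric tanimoto` computes RDKit fingerprints (daylight / morgan2 /
morgan3, 2048 bits) from the modal structure per 14-character InChIKey
prefix.

Model archives are plain-text directories (`config.json`, `binning.json`,
`weights.json`, `history.csv`, `metadata.json`).

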