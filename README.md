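# semgkit

Classification of forearm movements from multichannel surface
electromyography (SEMG), built around **relative frequency band energy
(RFBE)** features computed with the wavelet packet transform.

Surface EMG measures the summed electrical activity of motor units under
skin electrodes. A myoelectric prosthesis must decide, within a couple of
hundred milliseconds of movement onset, which gesture the user intends —
here one of four: forearm pronation (FP), forearm supination (FS), hand
open (HO) and hand close (HC), recorded on four forearm channels at
1500 Hz. `semgkit` implements that decision pipeline end to end, together
with a synthetic session generator so every stage can be exercised and
tested without access to human recordings.

## Method

1. **Preprocessing.** Each channel is band-pass filtered to 5–200 Hz with a
   4th-order Butterworth filter applied forward–backward (zero phase).
2. **Onset detection.** A 21-sample window slides over the pooled
   channel energy. The threshold is the mean energy of 25 abutting windows
   of rest signal (times a documented safety margin); when 20 consecutive
   windows exceed it, the centre of the last window marks the movement
   onset. Fixed segments of 100–600 ms are cut from each onset.
3. **Features.** Each segment is decomposed per channel with a Symlet-5
   wavelet packet tree to level 3, giving 8 subbands. With subband
   energies `E[i, m] = Σ_k d[i, m](k)²` (channel `i`, band `m`), the RFBE is

   `P[i, m] = E[i, m] / Σ_i E[i, m]`,

   channel `i`'s share of the total energy all channels carry in band `m` —
   a 4 × 8 = 32-dimensional vector. The classical per-channel
   normalisation `RWPE[i, m] = E[i, m] / Σ_m E[i, m]` is provided as the
   comparison baseline.
4. **Feature selection.** Mean-centred PCA; the retained dimensionality
   `k` minimises the Davies-Bouldin index of the projected class structure
   among all `k` whose cumulative explained variance reaches 90%.
5. **Classification.** One-against-all RBF-kernel SVMs (hyperparameters by
   inner 3-fold grid search), evaluated with stratified five-fold
   cross-validation in which selection and training see only the training
   folds.

## Worked example

```python
from semgkit.pipeline import PipelineConfig, run_length_study

table, details = run_length_study(PipelineConfig(seed=1))
print(table[table.method == "rfbe"].to_string(index=False))
```

```
method  segment_ms  n_segments  mean_accuracy  std_accuracy  db_index  k_selected
  rfbe         100         240       0.929167      0.034861  1.367997           9
  rfbe         200         240       0.970833      0.011411  1.314389           7
  rfbe         300         240       0.958333      0.014731  1.091195           7
  rfbe         400         240       0.966667      0.023754  0.918571           5
  rfbe         500         240       0.970833      0.011411  0.960564           6
  rfbe         600         240       0.991667      0.018634  1.051272           6
```

Each row is one synthetic session of 240 detected movement bursts (60 per
class): five-fold cross-validated accuracy (mean ± sd over folds), the
Davies-Bouldin index of the selected feature space (lower = better
separated classes) and the selected PCA dimensionality. Accuracy rises and
the DB index falls as segments lengthen, because longer segments estimate
the cross-channel energy shares more precisely; the same run puts the RWPE
baseline at chance level (~25%), since per-channel spectral shape carries
no class information in this benchmark by construction.

The same stages are available as a CLI (`semgkit simulate | preprocess |
detect | extract | select | evaluate | compare | length-study`).

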