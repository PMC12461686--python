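# embedmap

Neural-network surrogates for t-SNE/UMAP embeddings of large omics data —
forward, inverse, and cross-omics maps.

## The problem

Nonlinear dimensionality reduction (t-SNE, UMAP) has become the default lens
for high-dimensional omics data — mass spectrometry imaging (MSI), REIMS
tissue profiles, Hi-C contact matrices, transcriptomics — but the algorithms
do not scale: exact t-SNE needs the full pairwise affinity matrix, so a
dataset of a few hundred thousand pixels is simply out of reach, new samples
cannot be placed into an existing embedding without recomputing it, and the
reduced coordinates carry no spectral interpretation.

`embedmap` implements the subsample-and-surrogate strategy. A tractable
subset (e.g. every *n*-th pixel) is embedded with the reference method; two
feed-forward networks are then trained on the subset:

* **forward** `f: x ∈ ℝᵖ → y ∈ [0,1]ᵈ` — features to (unit-cube normalized)
  embedding coordinates, so the remaining samples — and any newly acquired
  ones — are embedded by a single network evaluation;
* **inverse** `g: y → x̂` — embedding coordinates back to a pseudo-spectrum,
  so any point of the reduced space (an RGB corner such as [1 0 0], a
  cluster centroid) is interpretable as signed per-feature contributions.

With matched samples across two omics modalities, the same trainer learns a
**cross** map `h: x_A → y_B` from one modality's features into the other's
embedding, projecting (say) metabolomics into a transcriptomics reduction
where class structure is cleaner.

Fidelity is measured as squared Pearson correlation r² between the reference
and surrogate embedding per output dimension (forward), and between held-out
spectra and their reconstructions (inverse); both exceed 0.95 on the
package's synthetic benchmark. Downstream analyses included here: RGB
rendering of embeddings as segmentation images, bounding-box masks,
pseudo-spectrum driver ranking with ppm-tolerance annotation against a
user-supplied table, k-NN novelty flagging of out-of-distribution samples,
leave-one-out LDA on reduced coordinates, the Rand index, and an
asymmetric binner for 1 kb/50 kb Hi-C contact lists.

## Worked example

```python
import numpy as np
from embedmap import (EmbedParams, TrainConfig, every_nth, normalize_embedding,
                      train_forward, train_inverse, tsne_embed)
from embedmap.spectral import centroid_spectrum, rank_drivers
from embedmap.synth import SynthSpec, make_msi_like

# clustered MSI-like image: 6 tissue regions, planted marker ions
ds = make_msi_like(SynthSpec(n_pixels=6000, n_features=300, n_regions=6, seed=7))
sub = every_nth(ds.matrix.n, 5)                      # every 5th pixel
x_sub = ds.matrix.subset(sub.indices)

e = normalize_embedding(tsne_embed(x_sub, EmbedParams(seed=7)))
fwd = train_forward(x_sub, e, TrainConfig(seed=7))
inv = train_inverse(e, x_sub, TrainConfig(seed=7))
print(fwd.summary())

coords_all = fwd.predict(ds.matrix.values)           # embed all 6000 pixels
ps = centroid_spectrum(inv, e, ds.labels[sub.indices] == 0)
print(rank_drivers(ps, 3).to_dataframe())
```

Output (abridged):

```
Neural embedding map
========================================================
direction:      forward
input dim:      300
output dim:     3
hidden layout:  (128, 64)  (tanh)
L2 alpha:       auto (selected 0.01)
epochs run:     406 (max 1000)
split sizes:    (840, 180, 180) (train/test/val)
--------------------------------------------------------
split         r2 min     r2 mean
train         0.9960      0.9964
test          0.9820      0.9846
val           0.9820      0.9843

   rank  feature_index          mz  contribution
0     1             25  266.889632    217.468389
1     2            204  745.819398     12.407457
2     3            103  475.585284     11.551144
```

The summary says the forward net reproduces the reference t-SNE with r² ≥
0.98 per dimension on held-out pixels; the driver table ranks region 0's
planted marker ion (feature 25) as the strongest contributor to its
centroid pseudo-spectrum — the route by which real analyses go from a
segmented image back to candidate biomarkers.

A command-line surface wraps the same calls (`embedmap run`, `embed`,
`train`, `apply`, `drivers`, `cross-train`, `cross-project`, `outliers`,
`render`, `classify`, `evaluate`, `hic-bin`, `synth`); `embedmap run`
writes subset indices, the reference embedding, both serialized maps,
full-data coordinates, an RGB segmentation image and a machine-readable
provenance record.

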