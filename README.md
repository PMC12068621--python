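# corridorvae

Rate-distortion geometry of generative-model latent spaces, studied end to
end on a synthetic benchmark.  The package is for computational
neuroscientists and ML researchers who want a small, fully controlled
testbed for questions like: *when a capacity-limited encoder must compress
its inputs, which distortions appear in its internal representation — and
how do data imbalance and task demands reshape them?*

Everything is self-contained: the data are generated, the models are small,
and every figure-level quantity is a deterministic function of a seed.

## The setup

**Data.** The *Corridors* images are 13×13 binary grids: an all-white
divider row splits the image into an upper and a lower section, each
containing a noisy vertical corridor whose integer position
(`x_UC`, `x_LC` ∈ {0..12}) is the generative factor.  Non-core pixels are
independent Bernoulli draws with probability `exp(-(col-x)²/(2·1.2²))`.
Datasets are balanced (uniform over the 169 position pairs) or biased 10:1
toward the pairs with the lower corridor on the left, or toward aligned
pairs.  Four classification labelings are attached: T1 `x_UC ≤ x_LC`,
T2 `x_UC < 6 ∨ (x_UC ≥ 6 ∧ x_LC ≥ 6)`, T3 `x_UC = x_LC`, and a 25-class
position-binning task T4.

**Model.** A β-VAE with 5-D diagonal-Gaussian latent trained under the
capacity-controlled objective

    L = NLL(x|z) + γ·|KL(q(z|x)‖p(z)) − C(t)| + Σᵢ CEᵢ(z, yᵢ),

where the capacity target C(t) is annealed from 0 to Cmax ∈ {0.3, 1, 3, 6,
10} nats and the optional classifier heads (linear, or nonlinear for T4)
are trained jointly with the VAE.  The experiment registry covers one
unsupervised baseline, two biased-data variants (E1M1, E1M2), four
single-task hybrids (E2M1–E2M4) and a four-task hybrid (E2M5).

**Analyses.** Latent geometry is quantified by distortion ratios
`ρ(u,v) = d₂(u,v)/d₁(u,v)` between two models' embeddings of the same
images (aggregated into 169×169 item-level and class-level matrices), MDS
projections, per-channel KL ("active channels"), channel-activation maps
with an axis-selectivity score, and silhouette-selected cluster counts.
See `docs/methods.md` for the full model description and the numerical
choices.

## Worked example

`examples/02_train_hybrid.py` trains the E2M1 hybrid (linear head on T1) at
a 0.3-nat capacity on a demo-scale dataset:

```
$ python examples/02_train_hybrid.py
  ...
  epoch  49  C=0.30  loss=82.96  mse=0.1653  kl=0.28  f1_T1=0.838
  epoch  59  C=0.30  loss=81.72  mse=0.1573  kl=0.29  f1_T1=0.843

held-out: reconstruction mse/pixel = 0.1573 (0.155 = zero-information bound, 0.055 = pixel-noise floor)
posterior KL = 0.293 nats (capacity target 0.3)
T1 F1 = 0.843 (0.70 = trivial all-positive baseline)
```

The KL column shows the capacity constraint doing its job (KL pinned at
0.3 nats); the classifier has risen well above the trivial baseline while
the reconstruction error sits near the zero-information bound — with only
0.3 nats the encoder keeps little beyond what the task needs.  At the
study scale (`ExperimentRecipe` defaults: 20,000 images, 300 epochs) the
same recipe reaches F1 ≈ 0.87–0.89 at mse ≈ 0.134, and the four-cluster
prototypization, specialization and orthogonalization analyses of
`examples/04_latent_geometry.py` apply; each example script prints what its
numbers mean.

There is also a thin CLI:

```bash
corridors generate-data --n 20000 --weighting balanced --seed 0 --out data/
corridors train --experiment E2M1 --cmax 0.3 --data data/ --out runs/
corridors analyze --model runs/E2M1_cmax0.3/checkpoint.npz --data data/ --out analysis/
```

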