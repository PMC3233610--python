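# scfia — statistical corresponding-feature identification for LC-MS

`scfia` matches the elution peaks of identical peptides across LC-MS runs
("corresponding features"). Transferring a peptide's identity from a run where
Tandem MS fragmented it to runs where it was not selected is what makes
*complete* quantification of the union peptide set possible — the per-run
identified sets overlap little, so alignment-by-identity is the bottleneck of
label-free and SILAC-style quantification pipelines.

Retention-time warping alone cannot resolve crowded chromatograms: after
correcting the mean inter-run time shift, several candidate peaks often remain
inside the residual-shift window. `scfia` therefore scores every candidate
pair with a two-factor likelihood

&nbsp;&nbsp;&nbsp;&nbsp;P(y) = P(AT) · P(AR)

* **AT**, the residual elution-time shift after applying a polynomial warp
  fitted to identified time pairs, modelled as AT ~ N(μ, σ²);
* **AR**, the alignment R²: each peak trace is resampled onto a common grid
  spanning its own detected interval and one is regressed on the other —
  identical shapes give R² = 1. X = 1 − AR is modelled as X ~ Gamma(k, θ),
  f(x | k, θ) = x^(k−1) e^(−x/θ) / (θ^k Γ(k)).

Both models are trained on the top-intensity fraction of peptides identified
in both runs; the candidate with the highest likelihood is reported. Peak
shape is informative because it is a property of the peptide's
physicochemistry and survives even ~50-fold intensity changes (the regression
is affine-invariant), while the time shift reflects run-to-run chromatographic
variation — the two factors are treated as independent.

The package covers the full workflow: mzML reading (MS1 centroids), XIC
extraction at the mono and first-isotope m/z in a ppm window, noise-adaptive
elution-peak detection, ground-truth construction from identification tables,
warp fitting, Gaussian/Gamma model training, maximum-likelihood matching, ROC
diagnostics, multi-run complete-identification propagation with
union/intersection coverage accounting, and a synthetic-data generator that
emulates the crowded, warped, fold-changed regime the method targets.

## Worked example

```python
from scfia import SimConfig, ScfiaConfig
from scfia.pipeline import run_pairwise_experiment

sim = SimConfig(rng_seed=1)                      # two crowded synthetic runs
cfg = ScfiaConfig(rng_seed=1, min_training_size=10)
res = run_pairwise_experiment(sim, cfg, modes=("combined", "at", "gwarp"))

m = res.trained.models
print(f"ground truth: {len(res.prepared.features)} peptides "
      f"({len(res.trained.split.training)} train / {res.n_testing} test)")
print(f"warp degree {m.warp.degree}, AT ~ N({m.at_model.mu:.2f}, {m.at_model.sigma:.2f}^2) s")
print(f"1-AR ~ Gamma(k={m.ar_model.k:.2f}, theta={m.ar_model.theta:.4f})")
print(f"mean candidates per peptide: {res.mean_candidates:.2f}")
for mode in ("combined", "at", "gwarp"):
    print(f"accuracy[{mode}] = {100*res.accuracies[mode]:.2f}%")
```

prints

```
ground truth: 136 peptides (28 train / 108 test)
warp degree 3, AT ~ N(-0.00, 10.11^2) s
1-AR ~ Gamma(k=1.15, theta=0.0819)
mean candidates per peptide: 2.52
accuracy[combined] = 80.56%
accuracy[at] = 75.93%
accuracy[gwarp] = 75.93%
```

The simulated pair shares 136 confidently identified peptides; the 28
brightest train the warp (cubic), the Gaussian residual-shift model (σ ≈ 10 s
— each run contributes ~7 s of jitter) and the Gamma shape model (1 − AR
concentrated near 0). On the 108 held-out peptides, each facing ~2.5
candidate peaks, the combined likelihood resolves more of the crowded cases
than the time-shift ranking or the warp-plus-nearest-feature baseline: an
identified corresponding interval counts as correct only if it contains the
target run's recorded retention time.

## Command line

```sh
scfia simulate --config sim.yaml --seed 7 --out-dir data      # mzML + ID TSVs + truth
scfia train    --run-q1 data/Q1.mzML --run-q2 data/Q2.mzML \
               --ids-q1 data/Q1_ids.tsv --ids-q2 data/Q2_ids.tsv --out models.yaml
scfia match    --models models.yaml --run-q1 ... --out pairs.tsv
scfia evaluate --predictions pairs.tsv --ids-q2 data/Q2_ids.tsv
scfia roc      --run-q1 ... --out roc.csv
scfia complete --runs Q1.mzML --runs Q2.mzML --runs Q3.mzML \
               --ids Q1_ids.tsv --ids Q2_ids.tsv --ids Q3_ids.tsv --out-dir out
```

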