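# fluorotax

Taxonomic discrimination of phytoplankton from narrow-band chlorophyll-a
fluorescence emission spectra.

Low-cost spectrofluorometers deliver noisy, low-resolution spectra, and
only the strongest emission — the Chl-a peak near 680 nm (excited around
470 nm) — rises reliably above their noise floor. The 630–730 nm band
around that peak still carries taxonomic information: accessory pigments
and the Chl-b/c/d ratios of different algal groups subtly reshape it.
`fluorotax` implements a four-block signal-processing chain that turns
such band-limited measurements into a species call, together with the
evaluation harness to compare every block choice:

1. **Denoise** — weighted moving average (square or Gaussian window w(ρ),
   y(λ) = Σ w(ρ)x(λ−ρ)/Σ w(ρ)), Savitzky–Golay local polynomial
   regression, or wavelet shrinkage (Daubechies-9, level 6) with the
   universal threshold `thr = ξ√(2 ln n)`, ξ = median(|D₁|)/0.6745.
2. **Normalize** — Min-Max into [a, b]; growing-spectra modeling (GSM):
   per-wavelength regressions Fl_λ(m) = a_λ·m + b_λ of fluorescence on
   the spectrum maximum across growth states; standard normal variate
   (SNV, per-spectrum moments to (0, 1)); or modified scale-based
   normalization (SBN): SNV level-by-level in the wavelet domain with
   regression-predicted variance targets per level.
3. **Transform / reduce** — derivative spectra, PCA on the covariance
   matrix, genetic-algorithm wavelength selection (fitness =
   cross-validated 1-NN kappa on the candidate bands), and the
   Levina–Bickel maximum-likelihood intrinsic-dimension estimate.
4. **Classify** — 1-NN, a 32-node self-organizing map
   (W ← W + α·h_c·(x − W)), or growing cell structures (a
   self-organizing net grown from a 3-cell triangle).

Chains are scored with fold-averaged confusion matrices and Cohen's
kappa κ = (p_o − p_e)/(1 − p_e) under stratified 5-fold cross-validation,
with every stateful stage fitted on the training folds only.

Because the original five-culture measurement campaign is not publicly
deposited, the package ships a synthetic culture generator that emulates
it: five classes with Gaussian-peak spectral shapes on the 630–730 nm
band, a dual-sampling growth campaign with logistic amplitude growth,
one deliberately confusable class pair, and a sensor-degradation
simulator (resolution ÷2 + additive Gaussian noise).

## Worked example

```python
from fluorotax.pipeline import ChainConfig, run_chain
from fluorotax.synth import SynthConfig, degrade, generate_cultures

data = generate_cultures(SynthConfig(seed=7))          # 172 labelled spectra
noisy = degrade(data, factor=2, variance=0.03, seed=1)  # low-cost sensor

config = ChainConfig.from_dict({
    "denoise":    {"method": "wma", "sigma": 1.56},     # Gaussian window
    "normalize":  {"method": "snv"},
    "transform":  {"method": "pca", "n_components": 3},
    "classifier": {"method": "knn", "k": 1},
    "folds": 5, "seed": 11,
})
report = run_chain(config, noisy)
print(round(report["kappa_averaged"], 3))
```

This prints `0.942`: even after halving the spectral resolution to 2 nm
and adding noise of variance 0.03, the chain still assigns essentially
every held-out spectrum to the right culture (κ = 1 means perfect
agreement, κ = 0 chance level). On the clean data the same chain reaches
κ = 1.0. The report also carries the fold-averaged confusion matrix —
what little confusion remains sits between the two look-alike cultures —
and the per-fold kappas.

The same chain is available from the shell:

```sh
fluorotax synth --per-class 20 --seed 1 -o cultures.csv
fluorotax degrade --factor 2 --variance 0.03 -i cultures.csv -o degraded.csv
fluorotax run-chain --config chain.yml --data degraded.csv --out report.json
```

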