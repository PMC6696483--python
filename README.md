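# thzopenset

Open-set recognition of pharmacological compounds from terahertz
absorbance spectra.

## The problem

Terahertz time-domain spectroscopy (THz-TDS) resolves intermolecular
vibrations, so structurally similar drug candidates — e.g. bi-heterocyclic
compounds sharing the same core — still show distinct spectral
fingerprints in the 10–70 cm⁻¹ band. In a screening laboratory, a newly
measured sample is either one of the compounds already synthesised and
catalogued, or a genuinely new structure that must be flagged for deeper
analysis. That makes the task *open-set*: the classifier must identify
known compounds **and** reject samples from compounds it was never
trained on. This package implements a complete pipeline for that task,
aimed at chemometrics and analytical-chemistry practitioners; because
measured spectra of such candidate compounds are rarely public, it ships
a statistically faithful synthetic spectrum generator so the whole
evaluation protocol runs end to end.

## The method

1. **PCA feature extraction.** Spectra digitised at *I* ≈ 1200 subbands
   are highly redundant; the top *J* eigenvectors of the empirical
   covariance give scores `z = Vᵀ(x − x̄)` that preserve essentially all
   variance at *J* ≈ 35.
2. **One-vs-rest kernel SVMs.** For each of the *C* known classes a
   binary soft-margin SVM is trained in score space by solving the dual
   quadratic program

       min_λ ½ λᵀHλ − eᵀλ    s.t.  yᵀλ = 0,  0 ≤ λ_r ≤ C_ξ,

   with `H_rs = y_r y_s k(z_r, z_s)`, via sequential minimal
   optimization (SMO). The Gaussian RBF kernel
   `k(z, z') = exp(−‖z − z'‖² / 2σ²)` is the default; polynomial
   `(zᵀz' + β₀)^d` and perceptron `tanh(β₀ zᵀz' + β₁)` kernels are also
   provided.
3. **Data-driven kernel training.** σ² is learnt per classifier by
   minimising the *n*-fold cross-validated misclassification count Ψ
   with Nelder–Mead under the exponential reparameterization
   `σ² = exp(σ̃²)` (positivity for free), restarted from many random
   points because Ψ is non-convex and piecewise constant.
4. **Open-set decision rule.** A test spectrum is scored by all *C*
   classifiers: exactly one positive decision value names the compound;
   none rejects the sample into the extra class *C*+1 (candidate new
   structure); several positive claims are adjudicated by *k*-nearest
   neighbours (Euclidean metric in score space) among the claiming
   classes' training samples.

The evaluation protocol mirrors an open-set measurement campaign:
each class in turn is held out as the "unknown", the ensemble is trained
once on the rest, and 30-sample test sets drawn from a later-measured
(drift-affected) batch are scored at unknown-compound fractions 0, 0.1,
…, 1.0 — 13 hold-outs × 11 scenarios = 143 cells.

## Worked example

```bash
python examples/open_set_classification.py
```

trains on 12 of the 13 synthetic compound classes and evaluates the
later-measured batch:

```
trained 12 one-vs-rest classifiers; unknown-class id = 13
known compounds (later batch): 100.0% correctly identified (360 spectra)
held-out compound: 100.0% rejected into the unknown class (30 spectra) - candidates for a new structure
```

Every known-compound spectrum is claimed by exactly one classifier (its
own), and every spectrum of the never-seen compound is claimed by none,
landing in the unknown class — the behaviour that makes the ensemble
usable for novelty screening. The other examples show the generator
(`generate_spectra.py`), the redundancy of spectral data
(`pca_features.py`), the plateau structure of the CV-MCR objective
(`train_binary_kernel.py`), and a scaled-down full protocol
(`full_protocol.py`).

A thin CLI wraps the same functions:

```bash
thzopenset generate --classes 13 --per-class 30 --seed 42 --out s.csv --labels l.csv
thzopenset train --spectra s.csv --labels l.csv --pcs 35 --model-out model.json
thzopenset classify --model model.json --spectra s.csv --out predictions.csv
```

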