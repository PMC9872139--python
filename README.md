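# snvsig

Survival-prognostic signatures from **highly sparse binary genotype
matrices** — rare somatic mutations coded 0/1 per gene per patient, often
with ≥ 99% zeros. At that sparsity, applying an ℓ1-penalized Cox model
directly is unstable: it selects either nothing or a large set of noise
markers whose apparent performance is inflated. `snvsig` implements a
multi-stage alternative for biostatisticians working with cohort mutation
data (e.g. masked-somatic-mutation MAF files plus overall-survival
phenotypes):

1. **Screen** — univariable Cox per marker (Efron ties, Newton iteration),
   keep markers with Wald p < α;
2. **Compress** — a shallow auto-encoder
   `y = ReLU(Wx + b)`, `z = σ(W'y + b')`, trained with Adam to minimise the
   mean cross-entropy `−Σ_k [x_k log z_k + (1−x_k) log(1−z_k)]` averaged
   over entries, turns the screened 0/1 matrix into `d` continuous
   features (the hidden activities);
3. **Select** — LASSO-Cox, `−(1/n)·log PL(β) + λ‖β‖₁`, by IRLS +
   coordinate descent with sequential strong rules and KKT verification,
   λ tuned by 10-fold cross-validated partial-likelihood deviance;
4. **Evaluate** — Cox signature with mean-zero risk score; cross-validated
   Harrell C and Nagelkerke R² (stepwise-AIC inside each training fold),
   maximally-selected log-rank cutoff, Kaplan–Meier + log-rank,
   IPCW time-dependent AUC(t), Breslow baseline hazard and
   predicted-vs-observed calibration.

A `direct` comparison arm runs stage 3 straight on the binary markers. A
synthetic-data module generates sparse genotype/survival matrices with
known effects, sparse image-like matrices, and the thresholding corruption
operator, so the entire pipeline is testable without any downloads.

## Worked example

```python
import json
from snvsig.synthetic import GenotypeSimSpec, gen_binary_genotypes, gen_survival
from snvsig.pipeline import PipelineConfig, run

spec = GenotypeSimSpec(n=150, p=100, zero_prob=0.95, k_true=4,
                       beta_true=(1.5, 1.5, -1.5, 1.0), censor_rate=0.25, seed=42)
X = gen_binary_genotypes(spec)
surv = gen_survival(X, spec)
cfg = PipelineConfig(arm="ae", hidden_dim=25, epochs=100, lasso_nfolds=5,
                     eval_folds=3, full_eval=True, seed=42)
res = run(cfg, X, surv)
print(json.dumps(res.summary(), indent=2, default=float))
```

prints

```json
{
  "status": "ok",
  "arm": "ae",
  "n_samples": 150,
  "n_markers": 100,
  "n_screened": 9,
  "n_extracted": 9,
  "n_selected": 2,
  "n_features": 2,
  "apparent_c": 0.6429393486016803,
  "apparent_c_se": 0.027258122268354546,
  "r2_nagelkerke": 0.1533351942480081,
  "r2_cox_snell": 0.15302286589454217,
  "score_range": [-1.0787188385071467, 1.8400067260275346],
  "cv_c_mean": 0.6282466096788517,
  "cv_c_sd": 0.09098960446528138,
  "cv_c_se": 0.05253287263148779,
  "cv_r2_mean": 0.1591425285430599,
  "cutoff": 0.011007281678746646,
  "logrank_chi2": 37.25460029237986,
  "logrank_p": 1.036701510041805e-09
}
```

Reading this: 9 of the 100 markers pass univariable screening; the
auto-encoder compresses them into continuous hidden features (the hidden
dimension is capped at the screened-marker count, so 9 here) of which the
CV-tuned LASSO-Cox keeps 2. The signature discriminates with a
cross-validated Harrell C of 0.63 (SD 0.09 across the 3 folds) and
explains R² ≈ 0.16 of the survival variation; splitting patients at the
optimal score cutoff 0.011 separates the risk groups decisively
(log-rank χ² = 37.3, p ≈ 1e-9).

The same flow is available from the shell:

```sh
snvsig simulate --n 150 --p 100 --zero-prob 0.95 --k-true 4 \
    --beta 1.5,1.5,-1.5,1.0 --censor-rate 0.25 --seed 42 --out-prefix demo
snvsig screen demo.matrix.tsv --alpha 0.05 --out screen.tsv
snvsig pipeline config.yaml demo.matrix.tsv --outdir out/
```

For cohort mutation data, `snvsig build-matrix cohort.maf phenotype.tsv
--out matrix.tsv` parses the MAF dialect (nonsense mutations removed by
default, multiple mutations per gene collapsed to 1) and merges overall
survival; `scripts/tcga_replication.py` wires the full real-data analysis
for user-supplied downloads.

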