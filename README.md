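# thorbfnn

Imputation of missing continuous morphological trait values in
specimen-level tables — built for trait-based ecology, where databases of
avian (or other) morphometrics routinely lack a third to a half of the
entries for hard-to-measure traits, and where discarding incomplete rows
biases downstream functional-diversity and comparative analyses.

The imputer is a three-stage hybrid, phylogeny-free by design:

1. **K-means center placement** — the training predictors are clustered
   with Lloyd's algorithm; the k centroids become the centers of a
   radial-basis-function (RBF) regression network
   `ŷ = Σⱼ wⱼ exp(−γ‖x − cⱼ‖²)` fitted to the natural-log trait value.
   Only the output weights w are gradient-trained (full-batch, RMSprop
   scaling, RMSE loss).
2. **Gaussian-process Bayesian optimization** — the unit count
   k ∈ [10, 25] and shared kernel width γ ∈ [0.05, 0.5] are tuned by
   minimizing the negative validation R² with a Matérn-5/2 GP surrogate
   and expected-improvement proposals, 10 evaluations per feature set.
3. **Correlation-guided combination search** — every size-2 and size-3
   subset of Pearson-screened candidate predictors is tuned and ranked
   by validation R² (log scale); the top five are retained, and missing
   cells are filled by the best subset whose predictors that row has,
   with back-transform `Γ̂ = exp(ŷ)` onto the measurement scale.

The package also ships the seven standard evaluation metrics (MSE, RMSE,
MAE, MedAE, MAPE, MSLE, R²), KNN and random-forest baseline harnesses on
the identical split and features, a complete-case vs mean-imputed
training ablation, and a synthetic generator of allometric avian-style
trait tables with controlled MCAR/MAR missingness and a closed-form
performance ceiling (see `docs/methods.md`).

## Worked example

```python
import thorbfnn as tb

cfg = tb.SyntheticConfig(
    n_species=30, individuals_per_species=40,
    missing_rates={"Wing.Length": 0.3}, mechanism="MCAR", seed=5,
)
table, truth = tb.simulate(cfg)          # 1,200 specimens, 11 traits

ranked, imputed = tb.run_search(
    table, "Wing.Length",
    candidates=["Mass", "Tarsus.Length", "Tail.Length", "Beak.Width"],
    seed=7,
)
for rank, r in enumerate(ranked, 1):
    print(f"#{rank} {r.combo_id}: R2(log)={r.report_log.r2:.4f} "
          f"k={r.incumbent[0]} gamma={r.incumbent[1]:.3f}")
print("audit:", imputed.audit)
```

prints

```
#1 Beak.Width+Tail.Length+Tarsus.Length: R2(log)=0.9142 k=22 gamma=0.061
#2 Beak.Width+Mass+Tail.Length: R2(log)=0.9140 k=16 gamma=0.068
#3 Beak.Width+Tail.Length: R2(log)=0.9135 k=23 gamma=0.162
#4 Mass+Tail.Length+Tarsus.Length: R2(log)=0.9111 k=24 gamma=0.168
#5 Beak.Width+Mass+Tarsus.Length: R2(log)=0.9108 k=19 gamma=0.124
audit: {'observed': 869, 'imputed:1': 331}
```

Reading this: of the ten possible 2–3-trait predictor subsets, the best
explains 91.4% of the held-out variance of log wing length — close to
the generative ceiling of 0.934 for three predictors under this
configuration — using 22 RBF units of width γ=0.061. All 331 masked wing
lengths had their best-combination predictors observed, so every one was
imputed by the rank-1 model (`imputed:1`); none fell through the cascade
to a lower rank or ended `unimputable`.

The same run is available from the shell:

```
thorbfnn simulate --seed 5 --n-species 30 --individuals-per-species 40 --out-dir sim
thorbfnn search sim/table.csv --target Wing.Length \
    --candidates Mass,Tarsus.Length,Tail.Length,Beak.Width --seed 7 --out-dir run
```

writing per-combination metrics, Bayesian-search traces, top-5 prediction
exports, the imputed table with a provenance column, and a run manifest.
`thorbfnn ablate` and `thorbfnn compare` run the ablation and the KNN /
random-forest comparison. Real tables (CSV/TSV/XLSX, e.g. the
individual-level AVONET supplement) are read with
`tb.read_trait_table`; `scripts/avonet_experiment.py` reruns the
four-focal-trait experiment given such a file.

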