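# flornet

Dynamical models of the gene network controlling floral transition in
pea (*Pisum sativum*). The shoot apex integrates mobile florigen-like
signals (FTa1, FTb2) produced in the leaves with a local circuit of
meristem-identity genes and floral repressors (*DET*, *PIM*, *VEG1*,
*LF*, *FTc*, *VEG2*); this package provides the computational machinery
to model that circuit from expression time series, for researchers in
plant systems biology and gene-network inference.

Three arms, sharing one tidy data format:

1. **Mechanistic ODE models.** Each apical gene follows
   `du_i/dt = v_i·F_i(regulators) − λ·u_i`, with `F_i` built from
   Michaelis–Menten activation `x/(K+x)` and repression `K/(K+x)` terms
   in the VEG2–FT complexes and apical proteins, a transport delay τ for
   the leaf-borne signals, and a shared degradation constant
   λ = ln 2 / 3.49 d = 0.199 d⁻¹. Variants differ in the VEG2–FT binding
   mode (competitive shared-pool occupancy vs plain products), an extra
   LF⊣PIM repression, a free Hill exponent on the PIM activation, or
   FTa1 self-activation. Regulators are interpolated from data, so the
   equations decouple into scalar linear ODEs with an exact
   integrating-factor solution available as a verification oracle.
2. **Fitting and model comparison.** The weighted cost
   `wRSS = Σ_g Σ_k (u_g(t_k) − u_g^dat(t_k))² / (u_g,max − u_g,min)²` is
   minimized by seeded differential-evolution ensembles (log-space
   search); models are scored by `NRMSE = sqrt(wRSS/(N·T))` and compared
   with one-sided Mann–Whitney–Wilcoxon rank-sum tests.
3. **Neural regression and knockouts.** A multilayer perceptron learns
   the one-step map from seven genes at one measured time to six targets
   at the next (records expanded to 1,000 normal draws per point).
   Zeroing one regulator while holding the others at data values and
   comparing areas under the predicted curves (`S_knock_out/S_wt`) reads
   the learned topology: ratio < 1 activator, > 1 repressor.

Synthetic-data generators (phenomenological curves, exactly
model-consistent mechanistic tables, and a planted signed network) make
every stage testable end to end with known ground truth. See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

Generate a noise-free dataset from the noncompetitive (MC) model with
known parameters, refit it with a small differential-evolution ensemble,
and compare MC against the competitive baseline MM on the same data:

```python
from flornet import (ConditionKey, DESettings, compare_models, model_spec,
                     generate_mechanistic, run_ensemble)

scope = [ConditionKey("WT", "LD"), ConditionKey("WT", "SD")]
data = generate_mechanistic(model_spec("MC"))          # truth: TRUE_PARAMS_MC

settings = DESettings(popsize=4, maxiter=40)
mc = run_ensemble(model_spec("MC"), data, scope, n_runs=5, base_seed=0,
                  de_settings=settings)
mm = run_ensemble(model_spec("MM"), data, scope, n_runs=5, base_seed=0,
                  de_settings=settings)
print("MC best wRSS :", f"{mc.best_fit.wrss:.3g}")
print("MC NRMSE     :", [f"{x:.3g}" for x in mc.nrmse_values()])
print("MM NRMSE     :", [f"{x:.3g}" for x in mm.nrmse_values()])
print("p (MC < MM)  :", f"{compare_models(mc.nrmse_values(), mm.nrmse_values()):.4f}")
```

Output:

```
MC best wRSS : 0.000189
MC NRMSE     : ['0.164', '0.00164', '0.00178', '0.285', '0.00328']
MM NRMSE     : ['0.304', '0.0155', '0.221', '0.255', '0.32']
p (MC < MM)  : 0.0476
```

The best MC run re-finds the generating dynamics almost exactly (wRSS ≈
2×10⁻⁴; NRMSE is the root-mean-square residual in units of each gene's
dynamic range, so 0.002–0.003 means sub-percent misfit). The run-to-run
spread is why the protocol uses ensembles: at this deliberately small
optimizer budget two of five MC runs stall in local minima, yet the MC
distribution still sits below the structurally mismatched MM variant,
and the one-sided rank-sum test picks up the direction (p ≈ 0.048; the
bundled experiments use 10 runs per model and separate far more
decisively).

A command-line interface wraps the same stages:

```sh
flornet generate --kind mechanistic --seed 1 --out run/
flornet fit --data run/dataset.csv --variant MC --n-runs 10 --seed 1 --out run/
flornet nn-train --protocol NN_LDdata --data run/dataset.csv --seed 1 --out run/
flornet knockout --model run/nn_NN_LDdata.json --data run/dataset.csv --out run/
```

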