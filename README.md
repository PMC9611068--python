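# intrinsol

Transparent multilinear QSPR models for the **intrinsic aqueous solubility**
of drug substances.

Intrinsic aqueous solubility, S0, is the solubility of the neutral form of a
compound; its decadic logarithm in molar units, logS0 [M], is pH-independent
and, together with pKa, determines solubility at any pH — making it a key
quantity in drug discovery and biopharmaceutical classification. `intrinsol`
predicts logS0 from the molecular graph with three small published
multilinear regression (MLR) models and their consensus:

```
M1:  logS0 =  8.3304 − 1.64547·SM04_EA(bo) − 0.0935641·ALOGP2
M2:  logS0 = −0.3583 − 0.01662·TPSA        − 0.84928·MolLogP
M3:  logS0 =  9.14318 + 0.82617·XlogS − 2.71151·SpMax1_Bhp − 0.50016·SHBd
M_cons: the unweighted mean of the available member predictions
```

The descriptors are classical 2D quantities: the log fourth spectral moment
of the bond-order-weighted edge adjacency matrix (SM04_EA(bo)), a squared
atom-contribution logP (ALOGP2), Ertl's topological polar surface area
(TPSA), the Wildman–Crippen logP (MolLogP), the largest absolute eigenvalue
of a polarizability-weighted Burden matrix (SpMax1_Bhp), the sum of
Kier–Hall E-states over hydrogen-bond donor atoms (SHBd), and a pluggable
group-contribution solubility estimate (XlogS) supplied as an input column.

Beyond prediction the package implements the full surrounding methodology:

* **chemio** — SMILES standardization (one aromaticity/nitro convention),
  unit conversion to log molar, median aggregation of replicate
  measurements, training/held-out overlap removal, CSV/TSV/SMILES I/O.
* **descriptors** — the descriptors above plus matrix assembly and
  prefiltering (missing values, zero variance, |R| > 0.9 collinearity,
  name blacklists).
* **models** — the M1–M3 registry, consensus averaging,
  statsmodels-style OLS fitting (`SolubilityMLR(...).fit()` →
  `MLRResults` with standard errors, R², RMSE, leverage, LOO CV and a
  `summary()` table) and JSON model archives.
* **selection** — the three descriptor-selection workflows behind the
  models: stepwise forward selection with collinearity control (BMLR
  style), orthogonal matching pursuit with a minor-improvement rule for
  the model size, and random-forest preselection (many seeded forests,
  permutation importance, frequency filter) followed by exhaustive search
  over all subsets of up to three descriptors.
* **evaluation** — R² (Pearson), R²det about the identity line, RMSE, MPP
  (fraction of predictions within 0.5 log units), leave-one-out R²cv and
  the strong-outlier rule (|residual| > 2 log units).
* **applicability** — leverage h = x′(X′X)⁻¹x, warning leverage
  h* = 3(p+1)/n, Williams-plot tables and descriptor range checks.
* **fixtures** — synthetic planted-model regression data (noise presets
  0.17/0.62 log units emulating high/low-consensus interlaboratory SD) and
  bundled toy/drug molecule sets.

## Worked example

Average the published per-model predictions for the six drug substances most
often mispredicted in the 2019 solubility challenge test sets, and apply the
strong-outlier rule to the consensus:

```bash
intrinsol fixtures --what challenge-outliers --out demo
intrinsol consensus --predictions demo/challenge_outliers.csv
```

prints

```
                  set   y_obs     M1     M2      M3 consensus residual  strong_outlier
id
Cisapride       tight   -6.78  -3.92  -4.64   -4.07     -4.21    -2.57            True
Folic acid      tight   -5.96  -3.45  -3.87   -4.31     -3.88    -2.08            True
Cyclosporine A  tight   -5.03  -6.96  -7.77  -10.09     -8.27     3.24            True
Amiodarone      loose  -10.40  -8.58  -6.96   -8.03     -7.86    -2.54            True
Itraconazole    loose   -8.98  -8.03  -6.84   -6.94     -7.27    -1.71           False
Rifabutin       loose   -4.09  -5.68  -7.70   -7.06     -6.81     2.72            True
```

The consensus column reproduces the published consensus values (−4.21,
−3.88, −8.27, −7.86, −7.27, −6.81) at 2 dp, and the outlier flags show the
behavior that motivates consensus modelling: Itraconazole, a strong outlier
for two individual models, falls inside the ±2 log-unit band once the three
models are averaged.

Predicting from structures instead of precomputed predictions:

```bash
printf 'CCO\tethanol\nc1ccccc1\tbenzene\n' > mols.smi
intrinsol featurize --molecules mols.smi --out desc.csv
intrinsol predict --model M2 --descriptors desc.csv
```

which evaluates M2 on the computed TPSA/MolLogP values (for a hypothetical
compound with TPSA = 0 and MolLogP = 0 the prediction is the model
intercept, −0.36 at reporting precision).

Library use mirrors statsmodels:

```python
import pandas as pd
from intrinsol import SolubilityMLR, M2

res = SolubilityMLR.from_dataframe(training_frame, response="logS0").fit()
print(res.summary())          # coefficients, std errors, t, R², RMSE
model = res.as_model("mine")  # archivable LinearSolubilityModel
print(M2.predict({"TPSA": 100.0, "MolLogP": 2.0}))  # -3.71886
```

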