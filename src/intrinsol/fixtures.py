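"""Synthetic data and bundled molecule sets for tests and demonstrations.

The regression-data generator emulates the structure of a descriptor-based
solubility study: a planted sparse linear model over standardized
descriptor columns, with residual noise at one of two preset levels that
mirror the interlaboratory reproducibility of intrinsic-solubility
measurements — ~0.17 log units for high-consensus ("tight") data and
~0.62 log units for low-consensus ("loose") data.

Bundled molecule sets:

* ``TOY_MOLECULES`` — small organics with hand-checkable descriptor values.
* ``DRUG_MOLECULES`` — drug substances named in solubility-challenge
  analyses, bundled purely for descriptor smoke tests; the SMILES are
  standard structures but descriptor values computed from them are NOT
  treated as ground truth anywhere.
* :func:`challenge_outlier_predictions` — published experimental logS0 and
  per-model (M1/M2/M3) predictions for the six drug substances most often
  mispredicted in the 2019 solubility challenge test sets; used as a worked
  example for consensus averaging and outlier flagging.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemio import Dataset, MoleculeRecord, RawSolubilityEntry, SolubilityUnit, from_log_molar
from .errors import SyntheticSpecError

#: Interlaboratory SD presets (log units): high- and low-consensus regimes.
TIGHT_SD = 0.17
LOOSE_SD = 0.62

TOY_MOLECULES: dict[str, str] = {
    "ethane": "CC",
    "propane": "CCC",
    "butane": "CCCC",
    "isobutane": "CC(C)C",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "ethanol": "CCO",
    "acetic acid": "CC(=O)O",
    "nitromethane": "C[N+](=O)[O-]",
    "aniline": "Nc1ccccc1",
    "phenol": "Oc1ccccc1",
    "pyridine": "c1ccncc1",
    "chlorobenzene": "Clc1ccccc1",
    "acetamide": "CC(N)=O",
    "dimethyl ether": "COC",
}

DRUG_MOLECULES: dict[str, str] = {
    "guanine": "Nc1nc2[nH]cnc2c(=O)[nH]1",
    "folic acid": "Nc1nc2ncc(CNc3ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1",
    "amiodarone": "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1",
    "verapamil": "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC",
    "mefenamic acid": "Cc1cccc(Nc2ccccc2C(=O)O)c1C",
    "ofloxacin": "CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23",
    "dipyridamole": "OCCN(CCO)c1nc(N2CCCCC2)c2nc(N(CCO)CCO)nc(N3CCCCC3)c2n1",
    "cisapride": "COc1cc(N)c(Cl)cc1C(=O)NC1CCN(CCCOc2ccc(F)cc2)CC1OC",
    "itraconazole": "CCC(C)N1N=CN(c2ccc(N3CCN(c4ccc(OCC5COC(Cn6cncn6)(c7ccc(Cl)cc7Cl)O5)cc4)CC3)cc2)C1=O",
    "pioglitazone": "CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1",
    "clofazimine": "CC(C)N=C1C=C2N(c3ccc(Cl)cc3)c3ccccc3N=C2C=C1Nc1ccc(Cl)cc1",
    "diazepam": "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
}

# Published per-model predictions and experimental logS0 for the six
# frequent strong outliers of the 2019 solubility challenge test sets.
_CHALLENGE_OUTLIERS = [
    # (name, test set, experimental, M1, M2, M3)
    ("Cisapride", "tight", -6.78, -3.92, -4.64, -4.07),
    ("Folic acid", "tight", -5.96, -3.45, -3.87, -4.31),
    ("Cyclosporine A", "tight", -5.03, -6.96, -7.77, -10.09),
    ("Amiodarone", "loose", -10.4, -8.58, -6.96, -8.03),
    ("Itraconazole", "loose", -8.98, -8.03, -6.84, -6.94),
    ("Rifabutin", "loose", -4.09, -5.68, -7.70, -7.06),
]


def challenge_outlier_predictions() -> pd.DataFrame:
    """Experimental logS0 and M1/M2/M3 predictions for six challenge outliers."""
    frame = pd.DataFrame(
        _CHALLENGE_OUTLIERS, columns=["name", "set", "y_obs", "M1", "M2", "M3"]
    ).set_index("name")
    return frame


def toy_dataset() -> Dataset:
    """The toy molecules as an (unmeasured) molecule dataset."""
    return Dataset(
        [MoleculeRecord(id=name, smiles=smi, name=name) for name, smi in TOY_MOLECULES.items()]
    )


def drug_dataset() -> Dataset:
    return Dataset(
        [MoleculeRecord(id=name, smiles=smi, name=name) for name, smi in DRUG_MOLECULES.items()]
    )


# ---------------------------------------------------------------------------
# Synthetic regression data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a planted-model regression data set.

    Defaults reproduce the selection-study conditions: two signal columns
    with coefficients (2, −1) among 20 standard-normal noise columns,
    n = 200, residual SD 0.1 log units.
    """

    n: int = 200
    p_signal: int = 2
    p_noise: int = 20
    coefficients: tuple[float, ...] = (2.0, -1.0)
    intercept: float = 3.0
    noise_sd: float = 0.1
    noise_correlation: float = 0.0  # equicorrelation among noise columns
    seed: int = 0

    def validate(self) -> None:
        if self.p_signal < 1:
            raise SyntheticSpecError("need at least one signal column")
        if len(self.coefficients) != self.p_signal:
            raise SyntheticSpecError(
                f"{len(self.coefficients)} coefficients for {self.p_signal} signal columns"
            )
        if self.p_signal > self.p_signal + self.p_noise:
            raise SyntheticSpecError("p_signal exceeds total column count")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise SD must be non-negative")
        if not 0.0 <= self.noise_correlation < 1.0:
            raise SyntheticSpecError("noise correlation must be in [0, 1)")


def generate_regression_data(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Generate (X, y, truth) for a planted sparse linear model.

    X columns are named ``sig1..`` (signal) and ``noise01..`` (noise); the
    truth record stores the planted support, coefficients, intercept, noise
    SD and seed, enabling exact parameter-recovery checks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sig_names = [f"sig{i + 1}" for i in range(spec.p_signal)]
    noise_names = [f"noise{i + 1:02d}" for i in range(spec.p_noise)]
    S = rng.standard_normal((spec.n, spec.p_signal))
    N = rng.standard_normal((spec.n, spec.p_noise))
    if spec.noise_correlation > 0.0 and spec.p_noise > 1:
        shared = rng.standard_normal((spec.n, 1))
        rho = spec.noise_correlation
        N = np.sqrt(rho) * shared + np.sqrt(1 - rho) * N
    X = pd.DataFrame(
        np.column_stack([S, N]), columns=sig_names + noise_names
    )
    y_clean = spec.intercept + S @ np.asarray(spec.coefficients)
    y = y_clean + rng.normal(0.0, spec.noise_sd, size=spec.n)
    truth = {
        "support": tuple(sig_names),
        "coefficients": dict(zip(sig_names, spec.coefficients)),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return X, pd.Series(y, name="logS0"), truth


def generate_duplicate_measurements(
    base: Mapping[str, float],
    k: int = 3,
    sd: float = TIGHT_SD,
    seed: int = 0,
    molecular_weights: Mapping[str, float] | None = None,
) -> list[RawSolubilityEntry]:
    """Noisy replicate measurements in mixed units for median-aggregation tests.

    For each compound, ``k`` replicates of the base logS0 value (noise SD
    ``sd`` in log units) are emitted cycling through log-molar, mg/mL and
    molar units; mass-based entries carry the compound's molecular weight
    (default 250 g/mol, a typical drug-substance weight).
    """
    if k < 1:
        raise SyntheticSpecError("need at least one replicate")
    rng = np.random.default_rng(seed)
    units = [SolubilityUnit.LOG_MOLAR, SolubilityUnit.MG_PER_ML, SolubilityUnit.MOLAR,
             SolubilityUnit.UG_PER_ML]
    entries: list[RawSolubilityEntry] = []
    for cid, logs0 in base.items():
        mw = (molecular_weights or {}).get(cid, 250.0)
        for rep in range(k):
            noisy = float(logs0 + rng.normal(0.0, sd))
            unit = units[rep % len(units)]
            value = from_log_molar(noisy, unit, molecular_weight=mw)
            entries.append(
                RawSolubilityEntry(
                    compound_id=cid, value=value, unit=unit,
                    molecular_weight=mw if unit in (SolubilityUnit.MG_PER_ML,
                                                    SolubilityUnit.UG_PER_ML) else None,
                )
            )
    return entries
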