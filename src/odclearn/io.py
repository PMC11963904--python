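"""Readers, writers and model serialization.

CSV is the interchange format for blood-gas records, synthetic datasets and
network input/output pairs; YAML for configuration and model metadata;
plain-text infix strings for learned expressions.  Saturation columns in
clinical CSVs are auto-detected as percent or fraction (values above 1.5
imply percent).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import yaml

from .greybox import NetworkSpec, TrainedNetwork
from .sa_model import BloodGasRecord
from .synthetic import SyntheticDataset

__all__ = [
    "read_blood_gas_csv",
    "write_blood_gas_csv",
    "read_dataset_csv",
    "write_dataset_csv",
    "save_network",
    "load_network",
    "save_gp_model",
    "load_gp_model",
]

logger = logging.getLogger("odclearn")

_MANDATORY = ("pH", "PCO2", "T", "pO2", "SO2", "FCOHb", "FMetHb")


def _fractionize(values: pd.Series) -> pd.Series:
    """Accept saturations as percent or fraction; >1.5 means percent."""
    v = values.astype(float)
    if np.nanmax(v.to_numpy()) > 1.5:
        return v / 100.0
    return v


def read_blood_gas_csv(path) -> List[BloodGasRecord]:
    """Parse a clinical blood-gas CSV into records.

    Rows with missing temperature are dropped (with a logged count), since
    the model cannot place the curve without it.  Unparseable rows are
    skipped and counted.  FHbF is optional and defaults to 0.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    n_missing_T = int(df["T"].isna().sum())
    if n_missing_T:
        logger.info("dropping %d row(s) with missing temperature", n_missing_T)
        df = df[df["T"].notna()]
    df = df.copy()
    df["SO2"] = _fractionize(df["SO2"])
    for col in ("FCOHb", "FMetHb", "FHbF"):
        if col in df.columns:
            df[col] = _fractionize(df[col])
    records = []
    n_bad = 0
    for _, row in df.iterrows():
        try:
            records.append(
                BloodGasRecord(
                    pH=float(row["pH"]),
                    PCO2=float(row["PCO2"]),
                    T=float(row["T"]),
                    pO2=float(row["pO2"]),
                    SO2=float(row["SO2"]),
                    FCOHb=float(row["FCOHb"]),
                    FMetHb=float(row["FMetHb"]),
                    FHbF=float(row.get("FHbF", 0.0) or 0.0),
                )
            )
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.info("skipped %d unparseable row(s)", n_bad)
    return records


def write_blood_gas_csv(records: List[BloodGasRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "pH": r.pH, "PCO2": r.PCO2, "T": r.T, "pO2": r.pO2, "SO2": r.SO2,
                "FCOHb": r.FCOHb, "FMetHb": r.FMetHb, "FHbF": r.FHbF,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_dataset_csv(dataset: SyntheticDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_dataset_csv(path) -> SyntheticDataset:
    return SyntheticDataset.from_frame(pd.read_csv(path))


def save_network(net: TrainedNetwork, path) -> None:
    """YAML metadata next to an .npz weight bundle sharing the stem."""
    path = Path(path)
    arrays = {}
    for i, (W, b) in enumerate(net.params):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    arrays["x_mean"] = net.x_mean
    arrays["x_scale"] = net.x_scale
    npz_path = path.with_suffix(".npz")
    np.savez(npz_path, **arrays)
    meta = {
        "spec": {
            "n_inputs": net.spec.n_inputs,
            "hidden": list(net.spec.hidden),
            "activation": net.spec.activation,
        },
        "weights": npz_path.name,
        "loss_after_adam": float(net.loss_after_adam),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def save_gp_model(model, path) -> None:
    """Persist a fitted GP discrepancy model: YAML metadata + .npz arrays."""
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    np.savez(
        npz_path,
        gamma=model.hyperparams.gamma,
        X_train=model.X_train,
        residuals=model.residuals,
        value_points=model.constraints.value_points,
        deriv_points=model.constraints.deriv_points,
        std_mean=model.standardizer.mean,
        std_scale=model.standardizer.scale,
    )
    meta = {
        "sigma2": float(model.hyperparams.sigma2),
        "sigma_e2": float(model.hyperparams.sigma_e2),
        "deriv_coord": int(model.constraints.deriv_coord),
        "weights": npz_path.name,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def load_gp_model(path):
    from .gp_discrepancy import (
        ConstraintSet,
        GPDiscrepancyModel,
        GPHyperparams,
        _Standardizer,
    )

    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    with np.load(path.parent / meta["weights"]) as npz:
        model = GPDiscrepancyModel(
            hyperparams=GPHyperparams(
                sigma2=meta["sigma2"], gamma=npz["gamma"], sigma_e2=meta["sigma_e2"]
            ),
            constraints=ConstraintSet(
                value_points=npz["value_points"],
                deriv_points=npz["deriv_points"],
                deriv_coord=meta["deriv_coord"],
            ),
            X_train=npz["X_train"],
            residuals=npz["residuals"],
            standardizer=_Standardizer(mean=npz["std_mean"], scale=npz["std_scale"]),
        )
    model.factorize()
    return model


def load_network(path) -> TrainedNetwork:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    spec = NetworkSpec(
        n_inputs=meta["spec"]["n_inputs"],
        hidden=tuple(meta["spec"]["hidden"]),
        activation=meta["spec"]["activation"],
    )
    with np.load(path.parent / meta["weights"]) as npz:
        params = []
        for i in range(len(spec.hidden) + 1):
            params.append((npz[f"W{i}"], npz[f"b{i}"]))
        x_mean = npz["x_mean"]
        x_scale = npz["x_scale"]
    return TrainedNetwork(
        spec=spec,
        params=params,
        x_mean=x_mean,
        x_scale=x_scale,
        loss_after_adam=float(meta.get("loss_after_adam", float("nan"))),
    )
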