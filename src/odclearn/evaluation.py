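"""Study orchestration and diagnostics.

Runs the synthetic noise-ladder study end to end (baseline, constrained-GP
black box, neural grey box, symbolic learned model), computes validation
RMSE on the combined-saturation scale and absolute-error summaries on the
clinical SO2 percentage scale, and provides k-fold splits and per-patient
dissociation-curve bundles for the clinical-CSV path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import gp_discrepancy as gp
from . import greybox, symreg
from .sa_model import odc_curve, sa_predict_matrix, saturation_to_so2
from .synthetic import INPUT_COLUMNS, SyntheticDataset, SyntheticStudyConfig, generate_dataset

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "NoiseLevelResult",
    "kfold_split",
    "absolute_error_report",
    "rmse",
    "run_synthetic_study",
    "run_pipeline",
    "patient_odc_comparison",
]


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


@dataclass(frozen=True)
class FoldSplit:
    """Shuffled, near-equal partition of n records into k folds."""

    k: int
    labels: np.ndarray
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.labels == fold)


def kfold_split(n: int, k: int = 10, seed: int = 0) -> FoldSplit:
    """Deterministic shuffled k-fold split; fold sizes differ by at most 1."""
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        labels[order[start : start + size]] = fold
        start += size
    return FoldSplit(k=k, labels=labels, seed=seed)


@dataclass(frozen=True)
class MetricsReport:
    """Absolute SO2 errors in percentage points with a Tukey box summary."""

    errors: np.ndarray          # percentage points, >= 0
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    rmse_s: float               # RMSE on the combined-saturation scale


def absolute_error_report(
    predictions: np.ndarray,
    observations: np.ndarray,
    FCOHb=0.0,
    FMetHb=0.0,
) -> MetricsReport:
    """Summarize |SO2_pred - SO2_obs| in percentage points.

    Both inputs are combined saturations; the conversion to SO2 uses the
    per-record dyshaemoglobin fractions.
    """
    predictions = np.asarray(predictions, float)
    observations = np.asarray(observations, float)
    if predictions.shape != observations.shape:
        raise ValueError("prediction and observation lengths differ")
    so2_pred = saturation_to_so2(predictions, FCOHb, FMetHb)
    so2_obs = saturation_to_so2(observations, FCOHb, FMetHb)
    errors = np.abs(np.atleast_1d(so2_pred) - np.atleast_1d(so2_obs)) * 100.0
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = errors[(errors >= lo_fence) & (errors <= hi_fence)]
    return MetricsReport(
        errors=errors,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()) if len(inside) else float(med),
        whisker_high=float(inside.max()) if len(inside) else float(med),
        outliers=errors[(errors < lo_fence) | (errors > hi_fence)],
        rmse_s=rmse(predictions, observations),
    )


@dataclass
class NoiseLevelResult:
    """Everything the study reports for one noise level."""

    noise_level: float
    dataset: SyntheticDataset
    rmse_baseline: float
    rmse_gp: Optional[float] = None
    rmse_greybox: Optional[float] = None
    rmse_learned: Optional[float] = None
    expression: Optional[str] = None
    canonical: Optional[symreg.CanonicalCosLogFit] = None
    gp_model: Optional[gp.GPDiscrepancyModel] = None
    network: Optional[greybox.TrainedNetwork] = None
    sr_result: Optional[symreg.SRResult] = None
    constraint_delta_mean: Optional[float] = None
    constraint_delta_sd: Optional[float] = None

    def summary(self) -> Dict:
        return {
            "noise_level": self.noise_level,
            "rmse_baseline": self.rmse_baseline,
            "rmse_gp": self.rmse_gp,
            "rmse_greybox": self.rmse_greybox,
            "rmse_learned": self.rmse_learned,
            "expression": self.expression,
            "canonical": None
            if self.canonical is None
            else {
                "alpha": self.canonical.alpha,
                "beta": self.canonical.beta,
                "gamma": self.canonical.gamma,
                "phase": self.canonical.phase,
            },
        }


def run_pipeline(
    dataset: SyntheticDataset,
    seed: int = 0,
    fit_gp: bool = True,
    fit_nn: bool = True,
    nn_spec: Optional[greybox.NetworkSpec] = None,
    nn_config: Optional[greybox.TrainingConfig] = None,
    sr_config: Optional[symreg.SRConfig] = None,
    gp_starts: int = 8,
    noise_level: float = float("nan"),
) -> NoiseLevelResult:
    """Fit the three corrected models on one dataset and evaluate on its
    validation split."""
    Xv = dataset.X[dataset.val_mask]
    sv = dataset.s_true[dataset.val_mask]
    result = NoiseLevelResult(
        noise_level=noise_level,
        dataset=dataset,
        rmse_baseline=rmse(sa_predict_matrix(Xv, a4_override=0.0), sv),
    )

    if fit_gp:
        model = gp.map_fit(
            dataset.X[dataset.train_mask],
            dataset.s_obs[dataset.train_mask],
            seed=seed,
            n_starts=gp_starts,
        )
        pred = gp.predict(model, Xv)
        result.gp_model = model
        result.rmse_gp = rmse(pred.mean, sv)
        at_constraints = gp.predict(model, model.constraints.value_points)
        result.constraint_delta_mean = float(np.max(np.abs(at_constraints.delta_mean)))
        result.constraint_delta_sd = float(np.max(at_constraints.sd))

    if fit_nn:
        if nn_config is None:
            nn_config = greybox.TrainingConfig(seed=seed)
        net = greybox.train(dataset, spec=nn_spec, config=nn_config)
        result.network = net
        result.rmse_greybox = rmse(greybox.greybox_predict(net, Xv), sv)

        pairs = greybox.export_io_pairs(net, dataset.X[dataset.train_mask])
        sr_config = sr_config or symreg.SRConfig(seed=seed)
        sr = symreg.fit_symbolic(
            pairs[list(INPUT_COLUMNS)].to_numpy(),
            pairs["a4_hat"].to_numpy(),
            config=sr_config,
        )
        result.sr_result = sr
        result.expression = sr.best.to_string()
        result.canonical = symreg.match_canonical_form(sr.best)
        result.rmse_learned = rmse(symreg.learned_model_predict(sr.best, Xv), sv)

    return result


def run_synthetic_study(
    config: Optional[SyntheticStudyConfig] = None,
    noise_levels: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    **pipeline_kwargs,
) -> List[NoiseLevelResult]:
    """The full noise-ladder study: one dataset and three fits per level."""
    config = config or SyntheticStudyConfig()
    noise_levels = tuple(noise_levels) if noise_levels is not None else config.noise_levels
    seed = config.seed if seed is None else seed
    results = []
    for i, nl in enumerate(noise_levels):
        dataset = generate_dataset(config, nl, seed=seed + i)
        results.append(
            run_pipeline(dataset, seed=seed + i, noise_level=nl, **pipeline_kwargs)
        )
    return results


def patient_odc_comparison(
    record_inputs: np.ndarray,
    gp_model: Optional[gp.GPDiscrepancyModel] = None,
    network: Optional[greybox.TrainedNetwork] = None,
    expression=None,
    p_grid: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Per-model dissociation curves for one record, over a pressure grid.

    ``record_inputs`` is a 5-vector (pH, PCO2, FMetHb, T, p).  Curves hold
    the record's other inputs fixed and sweep p; the GP bundle includes a
    +/- 2 SD band of the updated model.
    """
    r = np.asarray(record_inputs, float).ravel()
    if r.shape != (5,):
        raise ValueError("record_inputs must be a 5-vector (pH, PCO2, FMetHb, T, p)")
    if p_grid is None:
        p_grid = np.geomspace(0.5, 45.0, 200)
    pH, PCO2, FMetHb, T, _ = r
    out: Dict[str, np.ndarray] = {"p_grid": p_grid}
    out["baseline"] = odc_curve(pH, PCO2, FMetHb, T, p_grid)
    X = np.column_stack(
        [np.full_like(p_grid, v) for v in (pH, PCO2, FMetHb, T)] + [p_grid]
    )
    if gp_model is not None:
        pred = gp.predict(gp_model, X)
        out["gp_mean"] = pred.mean
        out["gp_band_low"] = pred.mean - 2 * pred.sd
        out["gp_band_high"] = pred.mean + 2 * pred.sd
    if network is not None:
        out["greybox"] = greybox.greybox_predict(network, X)
    if expression is not None:
        out["learned"] = symreg.learned_model_predict(expression, X)
    return out
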