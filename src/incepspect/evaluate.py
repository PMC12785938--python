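"""Metrics (R2, RMSE, RPD), leak-free cross-validated RMSE, residual
diagnostics and the experiment harness that runs the model x strategy x
adulterant-scope matrix."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import spearmanr
from sklearn.model_selection import KFold

from . import baselines
from .nets import NetConfig, fit_net, predict_net
from .preprocess import (
    SplitResult,
    apply_transform_chain,
    fit_transform_chain,
    split_multi,
)
from .select import VariableSubset, cars_select, spa_select
from .spectra_core import SpectraSet

__all__ = [
    "EvalReport",
    "ExperimentConfig",
    "r2",
    "rmse",
    "rpd",
    "rpd_label",
    "rmsecv",
    "run_experiment",
    "residual_table",
    "STRATEGIES",
    "MODELS",
]

STRATEGIES = ("raw", "msc+cars", "snv+cars", "msc+spa", "snv+spa")
MODELS = ("plsr", "svr", "cnn1d", "deepspectra", "incepspect_cbam")
SCOPES = ("corn_flour", "wheat_bran", "rice_bran", "stem_powder", "combined")


# ---------------------------------------------------------------------------
# metrics


def r2(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.size < 2 or y.size != p.size:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant reference values: R2 undefined")
    return float(1.0 - np.sum((y - p) ** 2) / ss_tot)


def rmse(y_true, y_pred) -> float:
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.size != p.size:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - p) ** 2)))


def rpd(y_true, y_pred, ddof: int = 1) -> float:
    """Residual predictive deviation: sd(y_true) / rmse. Returns inf when
    the rmse is exactly zero."""
    y = np.asarray(y_true, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 reference values")
    e = rmse(y_true, y_pred)
    sd = float(y.std(ddof=ddof))
    if e == 0:
        return float("inf")
    return sd / e


def rpd_label(value: float) -> str:
    """Reliability band: < 2.4 poor, [2.4, 3.0) acceptable, >= 3.0 excellent."""
    if value < 2.4:
        return "poor"
    if value < 3.0:
        return "acceptable"
    return "excellent"


@dataclass(frozen=True)
class EvalReport:
    model: str
    strategy: str
    scope: str
    rc2: float
    rmsecv: float
    rp2: float
    rmsep: float
    rpd: float
    rpd_band: str = ""
    n_calibration: int = 0
    n_prediction: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmsep < 0 or (np.isfinite(self.rmsecv) and self.rmsecv < 0):
            raise ValueError("rmse values must be >= 0")
        if self.rmsep > 0 and self.rpd <= 0:
            raise ValueError("rpd must be positive when rmsep > 0")


# ---------------------------------------------------------------------------
# model x strategy plumbing


def _strategy_parts(strategy: str) -> tuple[list[str], str | None]:
    if strategy == "raw":
        return [], None
    try:
        prep, selector = strategy.split("+")
    except ValueError as e:
        raise ValueError(f"unknown strategy '{strategy}'") from e
    if prep not in {"msc", "snv"} or selector not in {"cars", "spa"}:
        raise ValueError(f"unknown strategy '{strategy}'")
    return [prep], selector


def _select_variables(selector: str | None, calibration: SpectraSet,
                      seed: int, selector_kwargs: dict) -> VariableSubset | None:
    if selector is None:
        return None
    if selector == "cars":
        return cars_select(calibration, seed=seed, **selector_kwargs.get("cars", {}))
    if selector == "spa":
        return spa_select(calibration, seed=seed, **selector_kwargs.get("spa", {}))
    raise ValueError(f"unknown selector '{selector}'")


def _fit_predictor(model: str, calibration: SpectraSet, seed: int,
                   net_config: NetConfig | None):
    """Returns (fitted, predict_fn). Nets get min-max normalization fit on
    the calibration rows; baselines handle their own scaling."""
    if model == "plsr":
        # variable selection can leave fewer columns than the default
        # latent-variable search floor; clamp the range to stay feasible
        lo, hi = baselines.DEFAULT_LV_RANGE
        lo = max(1, min(lo, calibration.n_wavelengths))
        fitted = baselines.fit_plsr_cv(calibration, lv_range=(lo, hi), seed=seed)
        return fitted, lambda d: baselines.predict(fitted, d)
    if model == "svr":
        fitted = baselines.fit_svr_gridsearch(calibration, seed=seed)
        return fitted, lambda d: baselines.predict(fitted, d)
    if model in {"cnn1d", "deepspectra", "incepspect_cbam"}:
        from .preprocess import minmax_apply, minmax_fit

        cfg = net_config or NetConfig()
        cfg = replace(cfg, architecture=model, seed=seed)
        norm = minmax_fit(calibration)
        fitted = fit_net(minmax_apply(norm, calibration), cfg)
        return fitted, lambda d: predict_net(fitted, minmax_apply(norm, d))
    raise ValueError(f"unknown model '{model}'")


def rmsecv(model: str, calibration: SpectraSet, strategy: str = "raw",
           folds: int = 5, seed: int = 0,
           net_config: NetConfig | None = None,
           selector_kwargs: dict | None = None) -> float:
    """Pooled k-fold RMSE with all preprocessing (scatter correction,
    variable selection, normalization) refit inside every fold."""
    n = calibration.n_samples
    if n <= folds:
        raise ValueError("need more samples than folds")
    prep_kinds, selector = _strategy_parts(strategy)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    resid = np.empty(n)
    for tr, te in kf.split(np.arange(n)):
        cal, hold = calibration.subset(tr), calibration.subset(te)
        if np.ptp(cal.target) == 0:
            import warnings

            warnings.warn("fold with constant targets encountered", stacklevel=2)
        chain = fit_transform_chain(cal, prep_kinds)
        cal_p = apply_transform_chain(chain, cal)
        hold_p = apply_transform_chain(chain, hold)
        subset = _select_variables(selector, cal_p, seed, selector_kwargs or {})
        if subset is not None:
            cal_p = cal_p.select_columns(subset.indices)
            hold_p = hold_p.select_columns(subset.indices)
        _, predict_fn = _fit_predictor(model, cal_p, seed, net_config)
        resid[te] = hold.target - predict_fn(hold_p)
    return float(np.sqrt(np.mean(resid**2)))


def residual_table(predictions: np.ndarray, targets: np.ndarray) -> dict:
    """Per-sample residuals (prediction - target) with bias diagnostics."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(targets, dtype=float)
    res = p - y
    if y.size >= 3 and np.ptp(y) > 0 and np.ptp(res) > 0:
        rank_corr = float(spearmanr(res, y).statistic)
    else:
        rank_corr = float("nan")
    return {
        "target": y,
        "prediction": p,
        "residual": res,
        "mean_residual": float(res.mean()),
        "rank_corr_residual_target": rank_corr,
    }


# ---------------------------------------------------------------------------
# experiment harness


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment matrix: data source x models x strategies x scopes."""

    data_path: str | None = None  # CSV path; None -> simulator
    simulator_seed: int = 0
    models: tuple = ("plsr", "svr", "incepspect_cbam")
    variants: tuple = ("full",)  # applies to incepspect_cbam only
    strategies: tuple = ("raw",)
    scopes: tuple = ("combined",)
    split_fraction: float = 0.8
    seed: int = 0
    folds: int = 5
    compute_rmsecv: bool = True
    net_config: NetConfig | None = None
    selector_kwargs: dict = field(default_factory=dict)


def _load_data(config: ExperimentConfig) -> SpectraSet:
    if config.data_path is not None:
        from .spectra_core import read_spectra_csv

        return read_spectra_csv(config.data_path)
    from .simulate import NoiseModel, simulate_dataset

    return simulate_dataset(noise=NoiseModel(seed=config.simulator_seed))


def _scope_subset(data: SpectraSet, scope: str) -> SpectraSet:
    if scope == "combined":
        return data
    rows = np.flatnonzero(np.asarray(data.adulterant) == scope)
    if rows.size == 0:
        raise ValueError(f"no samples with adulterant '{scope}'")
    return data.subset(rows)


def evaluate_cell(data: SpectraSet, model: str, strategy: str, scope: str,
                  config: ExperimentConfig, variant: str = "full") -> EvalReport:
    """Run one matrix cell: split, preprocess, select, fit, score."""
    sub = _scope_subset(data, scope)
    split: SplitResult = split_multi(sub, config.split_fraction)
    cal = sub.subset(split.calibration_idx)
    pred = sub.subset(split.prediction_idx)

    prep_kinds, selector = _strategy_parts(strategy)
    chain = fit_transform_chain(cal, prep_kinds)
    cal_p = apply_transform_chain(chain, cal)
    pred_p = apply_transform_chain(chain, pred)
    subset = _select_variables(selector, cal_p, config.seed, config.selector_kwargs)
    if subset is not None:
        cal_p = cal_p.select_columns(subset.indices)
        pred_p = pred_p.select_columns(subset.indices)

    net_cfg = config.net_config
    if model == "incepspect_cbam" and variant != "full":
        net_cfg = replace(net_cfg or NetConfig(), variant=variant)
    _, predict_fn = _fit_predictor(model, cal_p, config.seed, net_cfg)

    cal_pred = predict_fn(cal_p)
    pre_pred = predict_fn(pred_p)
    rmsep_val = rmse(pred.target, pre_pred)
    cv = (rmsecv(model, cal, strategy, config.folds, config.seed, net_cfg,
                 config.selector_kwargs)
          if config.compute_rmsecv else float("nan"))
    rpd_val = rpd(pred.target, pre_pred)
    label = model if variant == "full" else f"{model}:{variant}"
    return EvalReport(
        model=label,
        strategy=strategy,
        scope=scope,
        rc2=r2(cal.target, cal_pred),
        rmsecv=cv,
        rp2=r2(pred.target, pre_pred),
        rmsep=rmsep_val,
        rpd=rpd_val,
        rpd_band=rpd_label(rpd_val),
        n_calibration=cal.n_samples,
        n_prediction=pred.n_samples,
        extra={"residuals": residual_table(pre_pred, pred.target),
               "selected_variables": None if subset is None
               else subset.indices.tolist()},
    )


def run_experiment(config: ExperimentConfig) -> list[EvalReport]:
    """Execute the full matrix; per-cell failures are recorded in the report
    list (as ``extra['error']``) rather than aborting the run."""
    data = _load_data(config)
    reports: list[EvalReport] = []
    for scope in config.scopes:
        for strategy in config.strategies:
            for model in config.models:
                variants = config.variants if model == "incepspect_cbam" else ("full",)
                for variant in variants:
                    try:
                        reports.append(
                            evaluate_cell(data, model, strategy, scope, config, variant)
                        )
                    except Exception as e:  # noqa: BLE001 - matrix keeps going
                        reports.append(EvalReport(
                            model=model if variant == "full" else f"{model}:{variant}",
                            strategy=strategy, scope=scope,
                            rc2=float("nan"), rmsecv=float("nan"),
                            rp2=float("nan"), rmsep=0.0, rpd=float("inf"),
                            rpd_band="", extra={"error": repr(e)},
                        ))
    return reports


def reports_to_rows(reports: list[EvalReport]) -> list[dict]:
    """Flat rows for CSV output (one per matrix cell)."""
    return [
        {
            "model": r.model, "strategy": r.strategy, "scope": r.scope,
            "RC2": r.rc2, "RMSECV": r.rmsecv, "RP2": r.rp2,
            "RMSEP": r.rmsep, "RPD": r.rpd, "band": r.rpd_band,
            "n_cal": r.n_calibration, "n_pred": r.n_prediction,
        }
        for r in reports
    ]
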