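"""Cross-method aggregation: PLS vs ANN vs DNN vs CNN per food type.

Each method is evaluated per food type on the dish-averaged dataset with
the target (moisture) min-max normalized to [0, 1], so RMSE values are on
the normalized scale.  Per-method results are aggregated across food types
as arithmetic mean and population standard deviation, and methods are
ranked by mean validation RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemometrics import (
    FitMetrics,
    SplitSpec,
    evaluate_fit,
    lv_sweep,
    pls1_fit,
    pls1_predict,
    split_train_val,
)
from .neural import (
    ANN_NODE_GRID,
    CNN_FILTER_GRID,
    DNN_NODE_GRID,
    TrainConfig,
    architecture_sweep,
    build_ann,
    build_cnn,
    build_dnn,
    predict,
    train,
)
from .preprocess import PreprocessConfig, minmax_normalize, preprocess_for_pls
from .spectra import SpectralDataset, average_dishes

METHODS = ("pls", "ann", "dnn", "cnn")

#: default network sizes used in the bundled comparison (representative
#: optima of the architecture sweeps: ~200 dense nodes, 6 conv filters)
DEFAULT_NN_PARAMS = {"ann": 200, "dnn": 200, "cnn": 6, "cnn_dense": 200}

_AGG_FIELDS = ("rmsec", "rmsev", "r2_cal", "r2_val")


@dataclass
class MethodReport:
    """Per-method metrics: per-food values plus across-food mean and SD."""

    method: str
    per_food: dict  # food type -> FitMetrics
    mean: dict  # metric name -> mean over food types
    sd: dict  # metric name -> population SD over food types


def aggregate_methods(reports: dict) -> list[MethodReport]:
    """Aggregate per-food metrics into per-method mean +/- SD reports.

    ``reports`` maps method -> {food type -> FitMetrics}; every method must
    cover the same food-type set.  The returned list is ranked by mean
    validation RMSE (best first); ranking does not depend on food order.
    """
    food_sets = {m: frozenset(d) for m, d in reports.items()}
    if len(set(food_sets.values())) > 1:
        raise ValueError(f"methods cover different food-type sets: {food_sets}")
    out = []
    for method, per_food in reports.items():
        mean, sd = {}, {}
        for name in _AGG_FIELDS:
            vals = np.array([getattr(per_food[f], name) for f in sorted(per_food)])
            mean[name] = float(vals.mean())
            sd[name] = float(vals.std())  # population SD over the food types
        out.append(MethodReport(method, dict(per_food), mean, sd))
    out.sort(key=lambda r: r.mean["rmsev"])
    return out


def _prepare_food(ds_food: SpectralDataset, target: str):
    y_raw = ds_food.meta[target].to_numpy(dtype=float)
    y, y_scale = minmax_normalize(y_raw)
    return y, y_scale


def evaluate_pls(
    ds_food: SpectralDataset,
    target: str = "moisture_true",
    split: SplitSpec | None = None,
    preprocess: PreprocessConfig | None = None,
    lv_range=None,
) -> tuple[FitMetrics, int]:
    """PLS pipeline on one food type: preprocess, sweep LVs, report the
    metrics at the validation-optimal latent-variable count."""
    split = SplitSpec() if split is None else split
    pp = preprocess_for_pls(ds_food, preprocess)
    y, _ = _prepare_food(ds_food, target)
    sweep = lv_sweep(pp.absorbance, y, split, lv_range)
    best = sweep.best_lv_rmsev
    row = sweep.table.loc[sweep.table["n_lv"] == best].iloc[0]
    metrics = FitMetrics(
        rmsec=float(row["rmsec"]),
        rmsev=float(row["rmsev"]),
        r2_cal=float(row["r2_cal"]),
        r2_val=float(row["r2_val"]),
        r2_adj=float(row["r2_adj"]),
        n_obs=len(y),
        n_params=best,
    )
    return metrics, best


def evaluate_network(
    ds_food: SpectralDataset,
    arch: str,
    target: str = "moisture_true",
    split: SplitSpec | None = None,
    train_config: TrainConfig | None = None,
    nn_params: dict | None = None,
) -> FitMetrics:
    """Neural pipeline on one food type: global min-max scaling of spectra
    and target, train the architecture, report calibration/validation fit."""
    split = SplitSpec() if split is None else split
    train_config = TrainConfig() if train_config is None else train_config
    params = dict(DEFAULT_NN_PARAMS)
    if nn_params:
        params.update(nn_params)
    X, _ = minmax_normalize(ds_food.absorbance)
    y, _ = _prepare_food(ds_food, target)
    cal, val = split_train_val(len(y), split)
    seed = int(train_config.seed) % (2**31)
    if arch == "ann":
        net = build_ann(params["ann"], input_dim=X.shape[1], seed=seed)
    elif arch == "dnn":
        net = build_dnn(params["dnn"], input_dim=X.shape[1], seed=seed)
    elif arch == "cnn":
        net = build_cnn(params["cnn"], dense_nodes=params["cnn_dense"], input_dim=X.shape[1], seed=seed)
    else:
        raise ValueError(f"unknown architecture {arch!r}")
    fitted, _ = train(net, X[cal], y[cal], train_config)
    return evaluate_fit(
        y[cal], predict(fitted, X[cal]), y[val], predict(fitted, X[val]),
        n_params=fitted.n_parameters(),
    )


_NN_GRIDS = {"ann": ANN_NODE_GRID, "dnn": DNN_NODE_GRID, "cnn": CNN_FILTER_GRID}
_NN_BUILDERS = {"ann": build_ann, "dnn": build_dnn, "cnn": build_cnn}

#: coarse subsamples of the standard size grids used by the bundled
#: comparison's selection phase (full grids stay available via sweep-nn /
#: architecture_sweep)
SELECTION_GRIDS = {
    "ann": (100, 200, 400, 700, 1000),
    "dnn": (100, 200, 400, 700, 1000),
    "cnn": (2, 6, 10, 14, 18),
}


def select_nn_size(
    ds_food: SpectralDataset,
    arch: str,
    target: str = "moisture_true",
    split: SplitSpec | None = None,
    train_config: TrainConfig | None = None,
    grid=None,
    selection_epochs: int = 100,
) -> int:
    """Sweep the architecture's size grid on one food type and return the
    validation-RMSE-optimal size (hidden nodes for dense nets, filters for
    the CNN).

    The selection sweep trains at ``selection_epochs`` (default 100, the
    minimum of the training protocol); the chosen size is then typically
    re-trained at the full epoch count by the caller.
    """
    split = SplitSpec() if split is None else split
    train_config = TrainConfig() if train_config is None else train_config
    grid = _NN_GRIDS[arch] if grid is None else grid
    X, _ = minmax_normalize(ds_food.absorbance)
    y, _ = _prepare_food(ds_food, target)
    cfg = replace(train_config, epochs=min(train_config.epochs, selection_epochs))
    if arch == "cnn":
        def builder(p, input_dim, seed):
            return build_cnn(p, dense_nodes=DEFAULT_NN_PARAMS["cnn_dense"], input_dim=input_dim, seed=seed)
    else:
        builder = _NN_BUILDERS[arch]
    table = architecture_sweep(builder, grid, X, y, split, cfg)
    by_size = table.groupby("parameter")["rmsev"].mean()
    return int(by_size.idxmin())


@dataclass
class ComparisonBundle:
    """Everything the comparison experiment produced."""

    cells: pd.DataFrame  # method x food x seed metrics (and errors, if any)
    method_table: pd.DataFrame  # aggregated mean/SD per method, ranked
    reports: list  # MethodReport list, ranked by mean validation RMSE


def comparison_report(
    ds: SpectralDataset,
    methods=METHODS,
    seeds=(0, 1, 2, 3, 4),
    target: str = "moisture_true",
    train_config: TrainConfig | None = None,
    preprocess: PreprocessConfig | None = None,
    nn_params: dict | None = None,
    lv_range=None,
    already_averaged: bool = False,
    nn_selection: str = "sweep",
    selection_epochs: int = 100,
) -> ComparisonBundle:
    """End-to-end comparison: preprocess -> fit -> evaluate per method, food
    type and seed.

    Every method enters at its per-food sweep-optimal configuration: PLS at
    the validation-optimal latent-variable count (re-swept per seed, it is
    cheap), each network at the size selected once per food type by
    :func:`select_nn_size` using the first seed (``nn_selection="sweep"``;
    pass ``"fixed"`` to use ``nn_params`` / the defaults directly).

    Seeds drive both the random split and the network initialization.  A
    failing cell is recorded with its error message and the partial report
    is still emitted.  The aggregated report averages each method's per-food
    mean (over seeds) across food types.
    """
    if nn_selection not in ("sweep", "fixed"):
        raise ValueError("nn_selection must be 'sweep' or 'fixed'")
    train_config = TrainConfig() if train_config is None else train_config
    work = ds if already_averaged else average_dishes(ds)
    rows = []
    for food in work.food_types:
        ds_food = work.for_food_type(food)
        sizes = {}
        for method in methods:
            if method == "pls":
                continue
            if nn_selection == "sweep":
                sel_cfg = replace(train_config, seed=int(seeds[0]))
                sizes[method] = select_nn_size(
                    ds_food, method, target, SplitSpec(seed=int(seeds[0])), sel_cfg,
                    grid=SELECTION_GRIDS[method], selection_epochs=selection_epochs,
                )
            else:
                sizes[method] = (nn_params or DEFAULT_NN_PARAMS)[method]
        for seed in seeds:
            split = SplitSpec(seed=int(seed))
            for method in methods:
                rec = {"method": method, "food_type": food, "seed": int(seed), "error": ""}
                try:
                    if method == "pls":
                        m, best = evaluate_pls(ds_food, target, split, preprocess, lv_range)
                        rec["n_lv"] = best
                    else:
                        cfg = replace(train_config, seed=int(seed))
                        cell_params = dict(nn_params or {})
                        cell_params[method] = sizes[method]
                        rec["size"] = sizes[method]
                        m = evaluate_network(ds_food, method, target, split, cfg, cell_params)
                    rec.update(
                        rmsec=m.rmsec, rmsev=m.rmsev, r2_cal=m.r2_cal,
                        r2_val=m.r2_val, r2_adj=m.r2_adj,
                    )
                except Exception as exc:  # record and continue
                    rec["error"] = str(exc)
                rows.append(rec)
    cells = pd.DataFrame(rows)

    per_method: dict[str, dict[str, FitMetrics]] = {}
    ok = cells[cells["error"] == ""]
    for method in methods:
        per_food = {}
        for food in work.food_types:
            sub = ok[(ok["method"] == method) & (ok["food_type"] == food)]
            if sub.empty:
                continue
            per_food[food] = FitMetrics(
                rmsec=float(sub["rmsec"].mean()),
                rmsev=float(sub["rmsev"].mean()),
                r2_cal=float(sub["r2_cal"].mean()),
                r2_val=float(sub["r2_val"].mean()),
                r2_adj=float(sub["r2_adj"].mean()),
                n_obs=int(len(sub)),
                n_params=0,
            )
        if per_food:
            per_method[method] = per_food

    reports = aggregate_methods(per_method) if per_method else []
    method_rows = [
        {
            "method": r.method,
            **{f"mean_{k}": r.mean[k] for k in _AGG_FIELDS},
            **{f"sd_{k}": r.sd[k] for k in _AGG_FIELDS},
        }
        for r in reports
    ]
    return ComparisonBundle(cells, pd.DataFrame(method_rows), reports)


def save_report(bundle: ComparisonBundle, outdir, figures: bool = True) -> None:
    """Write comparison.csv, per-cell metrics and (optionally) bar charts."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.method_table.to_csv(outdir / "comparison.csv", index=False)
    bundle.cells.to_csv(outdir / "comparison_cells.csv", index=False)
    if not figures or bundle.method_table.empty:
        return
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    for quantity, label in (("rmse", "RMSE"), ("r2", "R$^2$")):
        fig, ax = plt.subplots(figsize=(6, 4))
        tbl = bundle.method_table
        x = np.arange(len(tbl))
        if quantity == "rmse":
            series = [("mean_rmsec", "sd_rmsec", "calibration"), ("mean_rmsev", "sd_rmsev", "validation")]
        else:
            series = [("mean_r2_cal", "sd_r2_cal", "calibration"), ("mean_r2_val", "sd_r2_val", "validation")]
        for k, (mcol, scol, name) in enumerate(series):
            ax.bar(x + (k - 0.5) * 0.35, tbl[mcol], 0.35, yerr=tbl[scol], capsize=3, label=name)
        ax.set_xticks(x)
        ax.set_xticklabels(tbl["method"].str.upper())
        ax.set_ylabel(f"{label} (mean over food types $\\pm$ SD)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"comparison_{quantity}.png", dpi=150)
        plt.close(fig)
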