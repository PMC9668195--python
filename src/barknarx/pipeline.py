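"""Experiment orchestration: the architecture/trainer grid and the
three-model comparison.

``run_experiment`` sweeps network size (hidden units), delay-window length
and trainer over a dataset, training each configuration from several random
restarts, and reports per-split MSE and Pearson R for one restart drawn at
random (the reference protocol) together with restart mean/sd.

``compare_models`` evaluates the trained network against the two polynomial
baselines (printed or refitted coefficients) with the RMSE/ME/EF/MAE
statistics, on the whole series or the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import Dataset
from .metrics import evaluate
from .narx import (
    NarxConfig,
    NarxModel,
    TrainReport,
    init_nguyen_widrow,
    narx_predict,
    train_narx,
)
from .series import SplitIndices, build_series, fit_series_scalers, series_to_frame, split_series
from .taper import (
    TaperError,
    breast_height_info,
    fit_taper_coefficients,
    predict_stat1,
    predict_stat2,
    printed_coefficients,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "format_grid_table",
    "train_restarts",
    "compare_models",
    "reproduce_reference_comparison",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid definition and shared training settings."""

    hidden: tuple[int, ...] = (10, 20)
    delays: tuple[int, ...] = (1, 2)
    trainers: tuple[str, ...] = ("BR", "LM", "SCG")
    restarts: int = 10
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    max_epochs: int = 200
    patience: int = 6
    ef_variant: str = "observed_mean"

    def __post_init__(self) -> None:
        if not (self.hidden and self.delays and self.trainers):
            raise ValueError("experiment grid must be non-empty")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class RestartResult:
    model: NarxModel
    report: TrainReport
    seed: int


def train_restarts(
    frame: pd.DataFrame,
    split: SplitIndices,
    config: NarxConfig,
    restarts: int,
    seed: int = 0,
) -> tuple[list[RestartResult], int]:
    """Train ``restarts`` networks from different starting weights.

    Returns the results and the index of the randomly selected restart (the
    reported network is drawn uniformly, matching the reference protocol of
    training many nets and presenting a random one).
    """
    rng = np.random.default_rng(seed)
    init_seeds = rng.integers(0, 2**31 - 1, size=restarts)
    scalers = fit_series_scalers(frame, rows=split.learning)
    results = []
    for s in init_seeds:
        cfg = replace(config, seed=int(s))
        model = init_nguyen_widrow(cfg, scalers=scalers)
        fitted, report = train_narx(model, frame, split, cfg)
        results.append(RestartResult(model=fitted, report=report, seed=int(s)))
    chosen = int(rng.integers(restarts))
    return results, chosen


def run_experiment(ds: Dataset, config: ExperimentConfig) -> pd.DataFrame:
    """Sweep the full grid; one tidy row per (configuration, split).

    Columns: ``config`` (e.g. ``"2(1)-10-1 BR"``), ``split``, ``mse``, ``r``
    of the randomly chosen restart, plus restart ``mse_mean``/``mse_sd`` of
    the training objective across restarts.
    """
    frame = series_to_frame(build_series(ds))
    K = len(frame)
    split = split_series(K, config.fractions, seed=config.seed)
    rows = []
    cell_seed = np.random.default_rng(config.seed).integers(0, 2**31 - 1)
    for n_hidden in config.hidden:
        for delay in config.delays:
            for trainer in config.trainers:
                cfg = NarxConfig(
                    n_hidden=n_hidden,
                    delay=delay,
                    trainer=trainer,
                    max_epochs=config.max_epochs,
                    patience=config.patience,
                )
                try:
                    results, chosen = train_restarts(
                        frame, split, cfg, config.restarts, seed=int(cell_seed)
                    )
                except Exception as exc:
                    raise RuntimeError(f"grid cell {cfg.label} failed: {exc}") from exc
                picked = results[chosen]
                train_mses = [r.report.mse["training"] for r in results]
                for part in ("training", "validation", "testing"):
                    rows.append(
                        {
                            "config": cfg.label,
                            "n_hidden": n_hidden,
                            "delay": delay,
                            "trainer": trainer.upper(),
                            "split": part,
                            "mse": picked.report.mse[part],
                            "r": picked.report.r[part],
                            "restart_mse_mean": float(np.mean(train_mses)),
                            "restart_mse_sd": float(np.std(train_mses)),
                            "restarts": config.restarts,
                        }
                    )
    return pd.DataFrame(rows)


def format_grid_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy grid into the reference layout: rows Training/
    Validation/Testing, one (MSE, R) column pair per configuration."""
    out = grid.pivot_table(
        index="split", columns="config", values=["mse", "r"], sort=False
    )
    order = ["training", "validation", "testing"]
    return out.reindex(order)


def _stat_predictions(
    frame: pd.DataFrame,
    ds: Dataset,
    species: str,
    coefficients: str,
) -> dict[str, np.ndarray | None]:
    """STAT1/STAT2 predictions over the series; None when inputs are missing."""
    avg_d = frame["avg_d"].to_numpy()
    hb = frame["Hb"].to_numpy()
    h = frame["H"].to_numpy()
    dbt = frame["DBT"].to_numpy()

    ratios = {}
    missing_bh = []
    for tree in ds.trees:
        try:
            ratios[tree.tree_id] = breast_height_info(tree).ratio
        except TaperError:
            missing_bh.append(tree.tree_id)
    ratio_col = (
        None
        if missing_bh
        else frame["tree_id"].map(ratios).to_numpy(dtype=float)
    )

    if coefficients == "printed":
        c1 = printed_coefficients("STAT1", species)
        c2 = printed_coefficients("STAT2", species)
    elif coefficients == "refit":
        c1, _ = fit_taper_coefficients(avg_d, hb, h, dbt, model="STAT1", species=species)
        c2 = None
        if ratio_col is not None:
            c2, _ = fit_taper_coefficients(
                avg_d, hb, h, dbt, model="STAT2", ratio=ratio_col, species=species
            )
    else:
        raise ValueError("coefficients must be 'printed' or 'refit'")

    preds: dict[str, np.ndarray | None] = {
        "STAT1": np.asarray(predict_stat1(avg_d, hb, h, c1))
    }
    if ratio_col is None or c2 is None:
        preds["STAT2"] = None  # reported as unavailable, never silently skipped
    else:
        preds["STAT2"] = np.asarray(predict_stat2(avg_d, hb, h, ratio_col, c2))
    return preds


def compare_models(
    ds: Dataset,
    ann_config: NarxConfig | None = None,
    ann_model: NarxModel | None = None,
    scope: str = "all",
    coefficients: str = "printed",
    restarts: int = 10,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    ef_variant: str = "observed_mean",
    prediction_mode: str = "open_loop",
) -> pd.DataFrame:
    """RMSE/ME/EF/MAE of the network and the two polynomial baselines.

    ``scope`` is ``'all'`` (every sample) or ``'test'`` (test split only);
    the evaluation scope and coefficient provenance are stamped into the
    result's attrs.  A missing breast-height section makes the STAT2 column
    NaN (flagged in attrs) rather than silently dropping the model.
    """
    if scope not in ("all", "test"):
        raise ValueError("scope must be 'all' or 'test'")
    frame = series_to_frame(build_series(ds))
    K = len(frame)
    split = split_series(K, fractions, seed=seed)

    if ann_model is None:
        cfg = ann_config or NarxConfig(n_hidden=20, delay=1, trainer="BR")
        results, chosen = train_restarts(frame, split, cfg, restarts, seed=seed)
        ann_model = results[chosen].model
    ann_pred = narx_predict(ann_model, frame, mode=prediction_mode)

    preds = _stat_predictions(frame, ds, ds.species, coefficients)
    preds["ANN"] = ann_pred

    obs = frame["DBT"].to_numpy()
    if scope == "test":
        mask = np.zeros(K, dtype=bool)
        mask[split.test - 1] = True
    else:
        mask = np.ones(K, dtype=bool)

    table = {}
    for name in ("ANN", "STAT1", "STAT2"):
        p = preds[name]
        if p is None:
            table[name] = {m: float("nan") for m in ("RMSE", "ME", "EF", "MAE", "MEAN")}
            continue
        rep = evaluate(obs[mask], p[mask], ef_variant=ef_variant)
        table[name] = rep.as_dict()
    out = pd.DataFrame(table).loc[["RMSE", "ME", "EF", "MAE", "MEAN"]]
    out.attrs["scope"] = scope
    out.attrs["coefficients"] = coefficients
    out.attrs["ef_variant"] = ef_variant
    out.attrs["prediction_mode"] = prediction_mode
    out.attrs["stat2_unavailable"] = preds["STAT2"] is None
    return out


def reproduce_reference_comparison(
    pine_path=None,
    oak_path=None,
    column_map=None,
    seed: int = 0,
    restarts: int = 10,
    ann_config: NarxConfig | None = None,
):
    """Run the full comparison on externally supplied field data.

    Loads one stem-measurement workbook/CSV per species (e.g. the deposited
    field data) and returns ``{species: {scope: comparison table}}``,
    evaluating under both scopes since the reference evaluation subset is
    ambiguous.  Missing paths are skipped.
    """
    from .io_model import load_measurements

    out = {}
    cfg = ann_config or NarxConfig(n_hidden=20, delay=1, trainer="BR", max_epochs=200)
    for species, path in (("pine", pine_path), ("oak", oak_path)):
        if path is None:
            continue
        ds = load_measurements(path, column_map=column_map)
        out[species] = {
            scope: compare_models(
                ds, ann_config=cfg, scope=scope, coefficients="printed",
                restarts=restarts, seed=seed,
            )
            for scope in ("all", "test")
        }
    return out
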