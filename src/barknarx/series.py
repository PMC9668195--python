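"""Flattening stem measurements into the pseudo-time-series the NARX model consumes.

Sections are ordered tree by tree (trees in dataset order, sections from the
stump upward), giving one long series indexed by ``k = 1..K``.  Within each
tree the distance to the tree top ``DTT = H - Hb`` decreases strictly, so the
series is a train of descending ramps that restarts at every tree boundary —
the "pseudo-time" structure the recurrent model exploits.  Per sample the
exogenous input is ``[avg_d, DTT]`` and the target is the double bark
thickness ``DBT = k1 + k2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Dataset

__all__ = [
    "SeriesSample",
    "ScalerParams",
    "SplitIndices",
    "build_series",
    "series_to_frame",
    "write_series",
    "fit_scaler",
    "apply_scaler",
    "fit_apply_scaler",
    "fit_series_scalers",
    "split_series",
    "split_sizes",
]

SERIES_COLUMNS = ("k", "tree_id", "avg_d", "DTT", "DBT", "Hb", "H")


@dataclass(frozen=True)
class SeriesSample:
    """One index of the flattened series.

    ``avg_d`` is the mean outside-bark diameter at the section (cm), ``DTT``
    the distance to the tree top (m), ``DBT`` the double bark thickness (cm).
    ``Hb``/``H`` are carried along for the polynomial baselines.
    """

    k: int
    tree_id: str
    avg_d: float
    DTT: float
    DBT: float
    Hb: float
    H: float


def build_series(ds: Dataset) -> list[SeriesSample]:
    """Flatten a dataset into the ordered series, ``k`` running 1..K."""
    if ds is None or not ds.trees:
        raise ValueError("cannot build a series from an empty dataset")
    samples: list[SeriesSample] = []
    k = 0
    for tree in ds.trees:
        for s in tree.sections:
            k += 1
            samples.append(
                SeriesSample(
                    k=k,
                    tree_id=tree.tree_id,
                    avg_d=s.DOB,
                    DTT=tree.H - s.Hb,
                    DBT=s.k1 + s.k2,
                    Hb=s.Hb,
                    H=tree.H,
                )
            )
    # weakly increasing avg_d within a tree would mean the stem widens upward;
    # possible on rough-barked real stems, suspicious in simulated ones
    frame = series_to_frame(samples)
    for tree_id, grp in frame.groupby("tree_id", sort=False):
        d = grp["avg_d"].to_numpy()
        if np.any(np.diff(d) > 1e-9):
            warnings.warn(
                f"tree {tree_id}: outside-bark diameter increases with height",
                stacklevel=2,
            )
    return samples


def series_to_frame(samples: list[SeriesSample]) -> pd.DataFrame:
    """Tabular view with columns ``k, tree_id, avg_d, DTT, DBT, Hb, H``."""
    return pd.DataFrame([s.__dict__ for s in samples], columns=list(SERIES_COLUMNS))


def write_series(samples: list[SeriesSample], path) -> None:
    series_to_frame(samples).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Min-Max scaling


@dataclass(frozen=True)
class ScalerParams:
    """Fitted Min-Max parameters: ``minimum`` maps to 0, ``maximum`` to 1."""

    name: str
    minimum: float
    maximum: float

    def forward(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.minimum) / (
            self.maximum - self.minimum
        )

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * (self.maximum - self.minimum) + self.minimum


def fit_scaler(values, name: str = "variable") -> ScalerParams:
    values = np.asarray(values, dtype=float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise ValueError(
            f"constant variable {name!r} (min == max == {lo}); Min-Max scaling undefined"
        )
    return ScalerParams(name=name, minimum=lo, maximum=hi)


def apply_scaler(
    values, params: ScalerParams, direction: str = "forward"
) -> np.ndarray:
    if direction == "forward":
        return params.forward(values)
    if direction == "inverse":
        return params.inverse(values)
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


def fit_apply_scaler(
    values,
    params: ScalerParams | None = None,
    direction: str = "forward",
    name: str = "variable",
):
    """Scale (or unscale) one variable; fits on the data when ``params`` is None.

    Returns ``(scaled, params)`` when fitting, otherwise the transformed array.
    Out-of-range values extrapolate linearly outside [0, 1].
    """
    if params is None:
        if direction != "forward":
            raise ValueError("inverse transform requires fitted ScalerParams")
        params = fit_scaler(values, name=name)
        return params.forward(values), params
    return apply_scaler(values, params, direction)


def fit_series_scalers(
    frame: pd.DataFrame, rows: np.ndarray | None = None
) -> dict[str, ScalerParams]:
    """Fit Min-Max scalers for ``avg_d``, ``DTT`` and ``DBT``.

    ``rows`` restricts fitting to a subset of 1-based sample indices ``k``
    (e.g. the learning portion of a split); by default all samples are used.
    """
    sub = frame if rows is None else frame[frame["k"].isin(np.asarray(rows))]
    return {
        var: fit_scaler(sub[var].to_numpy(), name=var) for var in ("avg_d", "DTT", "DBT")
    }


# ---------------------------------------------------------------------------
# Train / validation / test splitting


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint 1-based sample index sets covering 1..K."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    fractions: tuple[float, float, float]

    @property
    def K(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)

    @property
    def learning(self) -> np.ndarray:
        """Train + validation pooled (the 'learning' portion)."""
        return np.sort(np.concatenate([self.train, self.validation]))


def split_sizes(K: int, fractions=(0.70, 0.15, 0.15)) -> tuple[int, int, int]:
    """Deterministic split sizes: validation and test get ``floor(f*K)``
    samples each, training the remainder.

    With the 70/15/15 default this reproduces the reference sample counts
    for both study species: K=1840 -> (1288, 276, 276) and
    K=11796 -> (8258, 1769, 1769).
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be positive and sum to 1, got {fractions}")
    n_val = int(np.floor(f_val * K))
    n_test = int(np.floor(f_test * K))
    n_train = K - n_val - n_test
    return n_train, n_val, n_test


def split_series(
    K: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitIndices:
    """Random subsampling split of sample indices 1..K.

    Membership is uniformly random given ``seed``; sizes follow
    :func:`split_sizes`.
    """
    if K < 3:
        raise ValueError(f"need at least 3 samples to split, got K={K}")
    n_train, n_val, n_test = split_sizes(K, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.arange(1, K + 1))
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
        seed=seed,
        fractions=tuple(fractions),
    )


def split_series_by_tree(
    frame: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitIndices:
    """Tree-wise split: whole trees are assigned to one partition.

    Statistically cleaner than the sample-wise default (no tree straddles
    partitions) but does not reproduce the reference per-sample counts.
    """
    tree_ids = list(dict.fromkeys(frame["tree_id"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tree_ids))
    sizes = frame.groupby("tree_id", sort=False)["k"].count()
    K = int(sizes.sum())
    n_train, n_val, _ = split_sizes(K, fractions)

    buckets: dict[str, list[str]] = {"train": [], "validation": [], "test": []}
    cum = 0
    for idx in order:
        tid = tree_ids[idx]
        if cum < n_train:
            buckets["train"].append(tid)
        elif cum < n_train + n_val:
            buckets["validation"].append(tid)
        else:
            buckets["test"].append(tid)
        cum += int(sizes[tid])
    ks = {
        part: np.sort(frame.loc[frame["tree_id"].isin(ids), "k"].to_numpy())
        for part, ids in buckets.items()
    }
    return SplitIndices(
        train=ks["train"],
        validation=ks["validation"],
        test=ks["test"],
        seed=seed,
        fractions=tuple(fractions),
    )
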