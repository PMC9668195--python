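"""Synthetic stem-section datasets emulating the sectional measurement protocol.

A generated tree follows the field procedure: sections at 0.0, 0.5, 1.3 and
2.0 m, then every 2 m up to the tip; at each section an outside-bark diameter
and two perpendicular bark-gauge readings.  The stem profile is a smooth
strictly-decreasing power-law taper anchored at the breast-height diameter;
the bark ground truth comes from a declared model (a polynomial taper with
chosen coefficients, or a known NARX network), so recovery experiments can
compare fits against the exact generating mechanism.

Observed bark readings are built from the true double bark thickness as

    k1 = DBT/2 * (1 + asymmetry) + noise,   k2 = DBT/2 * (1 - asymmetry) + noise

(directional asymmetry mimics the north/south bark difference), then
quantized to the gauge resolution and floored at the species' minimum
readable bark.  Sections whose diameter falls below the species' minimum
recorded diameter are not measured, mirroring the published variable ranges.
All randomness flows from explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import Dataset, SectionMeasurement, TreeRecord, SPECIES_RANGES
from .narx import NarxModel
from .series import ScalerParams
from .taper import TaperCoefficients, predict_stat1, predict_stat2, printed_coefficients

__all__ = [
    "SyntheticProfile",
    "GeneratedTree",
    "GeneratedDataset",
    "SyntheticDataError",
    "measurement_heights",
    "generate_tree",
    "generate_dataset",
    "default_narx_truth_model",
    "write_generated",
]

#: per-species defaults kept inside the published variable ranges
_SPECIES_DEFAULTS = {
    "pine": {"h_range": (18.30, 32.70), "dbh_range": (15.0, 52.0), "k_floor": 0.05},
    "oak": {"h_range": (13.90, 35.90), "dbh_range": (12.0, 85.0), "k_floor": 0.01},
}


class SyntheticDataError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticProfile:
    """Study conditions for one simulated species sample.

    ``truth`` selects the bark ground-truth mechanism: ``'stat1'`` /
    ``'stat2'`` evaluate a polynomial taper (printed coefficients of the
    species unless ``coefficients`` overrides them), ``'narx'`` runs a known
    network along the flattened series.  ``noise_sd`` (cm) is the Gaussian
    reading error of a single bark-gauge reading, ``asymmetry`` the
    directional bark fraction, ``gauge_quantum`` the instrument resolution
    (cm; 0 disables quantization), ``k_floor`` the smallest recordable
    reading, ``min_dob`` the smallest diameter still measured (cm).
    """

    species: str = "pine"
    h_range: tuple[float, float] | None = None
    dbh_range: tuple[float, float] | None = None
    taper_exponent_range: tuple[float, float] = (0.6, 1.0)
    truth: str = "stat1"
    coefficients: TaperCoefficients | None = None
    narx_model: NarxModel | None = None
    noise_sd: float = 0.1
    asymmetry: float = 0.10
    gauge_quantum: float = 0.01
    k_floor: float | None = None
    min_dob: float | None = None

    def __post_init__(self) -> None:
        if self.species not in _SPECIES_DEFAULTS:
            raise SyntheticDataError(f"unknown species {self.species!r}")
        if self.truth not in ("stat1", "stat2", "narx"):
            raise SyntheticDataError(f"unknown truth mode {self.truth!r}")

    # ---- resolved settings -------------------------------------------------

    @property
    def heights_range(self) -> tuple[float, float]:
        return self.h_range or _SPECIES_DEFAULTS[self.species]["h_range"]

    @property
    def diameters_range(self) -> tuple[float, float]:
        return self.dbh_range or _SPECIES_DEFAULTS[self.species]["dbh_range"]

    @property
    def bark_floor(self) -> float:
        if self.k_floor is not None:
            return self.k_floor
        return _SPECIES_DEFAULTS[self.species]["k_floor"]

    @property
    def dob_floor(self) -> float:
        if self.min_dob is not None:
            return self.min_dob
        if self.truth == "narx":
            # the network truth is not tied to the stem profile, so thin tip
            # sections are skipped to keep bark < diameter by construction
            return 4.0
        return SPECIES_RANGES[self.species]["DOB"][0]

    def truth_coefficients(self) -> TaperCoefficients:
        if self.coefficients is not None:
            return self.coefficients
        model = "STAT1" if self.truth == "stat1" else "STAT2"
        return printed_coefficients(model, self.species)

    def truth_network(self, seed: int = 0) -> NarxModel:
        if self.narx_model is not None:
            return self.narx_model
        return default_narx_truth_model(self.species, seed=seed)


@dataclass(frozen=True)
class GeneratedTree:
    """A measured tree plus its noise-free ground-truth bark per section."""

    tree: TreeRecord
    true_dbt: np.ndarray


@dataclass(frozen=True)
class GeneratedDataset:
    dataset: Dataset
    trees: tuple[GeneratedTree, ...]

    @property
    def ground_truth(self) -> pd.DataFrame:
        rows = [
            {"tree_id": g.tree.tree_id, "Hb": s.Hb, "true_DBT": t}
            for g in self.trees
            for s, t in zip(g.tree.sections, g.true_dbt)
        ]
        return pd.DataFrame(rows, columns=["tree_id", "Hb", "true_DBT"])


def measurement_heights(H: float) -> np.ndarray:
    """Protocol heights: 0.0, 0.5, 1.3, 2.0, then every 2 m, all below H."""
    fixed = [0.0, 0.5, 1.3, 2.0]
    upper = np.arange(4.0, H, 2.0)
    heights = np.array([h for h in fixed if h < H] + list(upper))
    return heights


def default_narx_truth_model(
    species: str = "pine", delay: int = 1, n_hidden: int = 10, seed: int = 0
) -> NarxModel:
    """A known, well-behaved network to use as generating mechanism.

    Each hidden unit reads mainly one input channel (a delayed diameter,
    distance-to-top or bark tap, assigned cyclically) with a positive gain
    and a bias placing its active region inside the scaled data range, plus
    small seeded jitter on the remaining weights; the output weights are
    positive and sum to 0.55 with an offset of 0.1, so the scaled prediction
    stays inside (0.1, 0.65) while still responding monotonically to its
    inputs.  With the attached bark scaler of 0-3 cm the generated DBT is
    always positive and below the measured diameters.
    """
    rng = np.random.default_rng(seed)
    n_in = 3 * delay
    gains = rng.uniform(2.0, 5.0, size=n_hidden)
    centers = rng.uniform(0.2, 0.8, size=n_hidden)
    W1 = rng.normal(0.0, 0.1, size=(n_hidden, n_in))
    for j in range(n_hidden):
        W1[j, j % n_in] = gains[j]
    b1 = -gains * centers
    w2 = rng.uniform(0.3, 1.0, size=n_hidden)
    w2 *= 0.55 / np.sum(w2)
    h_max = _SPECIES_DEFAULTS[species]["h_range"][1]
    d_max = _SPECIES_DEFAULTS[species]["dbh_range"][1] * 1.2
    scalers = {
        "avg_d": ScalerParams("avg_d", 0.0, d_max),
        "DTT": ScalerParams("DTT", 0.0, h_max),
        "DBT": ScalerParams("DBT", 0.0, 3.0),
    }
    return NarxModel(
        W1=W1, b1=b1, w2=w2, b2=0.1, delay=delay, activation="logistic",
        scalers=scalers, seed=seed,
    )


# ---------------------------------------------------------------------------
# geometry and observation


def _tree_geometry(profile: SyntheticProfile, rng: np.random.Generator):
    """Sample (H, heights, DOB) with a strictly decreasing power-law taper."""
    h_lo, h_hi = profile.heights_range
    d_lo, d_hi = profile.diameters_range
    H = float(rng.uniform(h_lo, h_hi))
    dbh = float(rng.uniform(d_lo, d_hi))
    p = float(rng.uniform(*profile.taper_exponent_range))
    heights = measurement_heights(H)
    rel = (1.0 - heights / H) / (1.0 - 1.3 / H)
    dob = dbh * rel**p
    keep = dob >= profile.dob_floor
    return H, heights[keep], dob[keep]


def _truth_dbt(
    profile: SyntheticProfile,
    dob: np.ndarray,
    heights: np.ndarray,
    H: float,
) -> np.ndarray:
    if profile.truth == "stat1":
        return np.asarray(predict_stat1(dob, heights, H, profile.truth_coefficients()))
    if profile.truth == "stat2":
        coef = profile.truth_coefficients()
        c = coef.b
        i_bh = int(np.argmin(np.abs(heights - 1.3)))
        dob_bh = dob[i_bh]
        q_bh = heights[i_bh] / H
        base = c[0] + c[1] * q_bh + c[2] * q_bh**2 + c[3] * H
        # the breast-height quotient depends on the breast-height DBT itself;
        # the model is linear in it, so solve the fixed point in closed form
        dbt_bh = (dob_bh * (base + c[4]) + c[5]) / (1.0 + c[4])
        ratio = 1.0 - dbt_bh / dob_bh
        return np.asarray(predict_stat2(dob, heights, H, ratio, coef))
    raise SyntheticDataError("network truth is generated along the flattened series")


def _observe_section(
    dbt_true: float,
    dob: float,
    profile: SyntheticProfile,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[float, float]:
    """Turn a true DBT into two gauge readings honouring k1 + k2 < DOB."""
    half = dbt_true / 2.0
    base = np.array([half * (1.0 + profile.asymmetry), half * (1.0 - profile.asymmetry)])
    q = profile.gauge_quantum
    for _ in range(max_tries):
        reading = base + rng.normal(0.0, profile.noise_sd, size=2)
        if q > 0:
            reading = np.round(reading / q) * q
        reading = np.maximum(reading, profile.bark_floor)
        if reading.sum() < dob:
            return float(reading[0]), float(reading[1])
        if profile.noise_sd == 0:
            break
    raise SyntheticDataError(
        f"cannot satisfy k1 + k2 < DOB at DOB={dob:.3f} with true DBT={dbt_true:.3f}"
    )


def _build_tree(
    tree_id: str,
    species: str,
    H: float,
    heights: np.ndarray,
    dob: np.ndarray,
    dbt_true: np.ndarray,
    profile: SyntheticProfile,
    rng: np.random.Generator,
) -> GeneratedTree:
    sections = []
    for hb, d, t in zip(heights, dob, dbt_true):
        k1, k2 = _observe_section(float(t), float(d), profile, rng)
        sections.append(SectionMeasurement(Hb=float(hb), DOB=float(d), k1=k1, k2=k2))
    record = TreeRecord(
        tree_id=tree_id, species=species, H=H, sections=tuple(sections)
    )
    return GeneratedTree(tree=record, true_dbt=np.asarray(dbt_true, dtype=float))


def generate_tree(
    profile: SyntheticProfile, rng: np.random.Generator | int, tree_id: str = "t1"
) -> GeneratedTree:
    """Generate one tree.

    With ``truth='narx'`` the network recursion is primed per tree (the first
    ``delay`` sections carry the primer value); use :func:`generate_dataset`
    for the continuous cross-tree recursion.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    H, heights, dob = _tree_geometry(profile, rng)
    if profile.truth == "narx":
        model = profile.truth_network()
        dbt_true = _narx_truth_series(
            model, dob, H - heights, primer=0.3
        )
    else:
        dbt_true = _truth_dbt(profile, dob, heights, H)
    return _build_tree(tree_id, profile.species, H, heights, dob, dbt_true, profile, rng)


def _narx_truth_series(model: NarxModel, dob, dtt, primer: float) -> np.ndarray:
    """Run the known network closed-loop over (avg_d, DTT), scaled space."""
    from .narx import _forward_vec, pack_params  # local: private helpers

    a = model.scalers["avg_d"].forward(np.asarray(dob, dtype=float))
    t = model.scalers["DTT"].forward(np.asarray(dtt, dtype=float))
    d = model.delay
    n = len(a)
    y = np.empty(n)
    y[:d] = primer
    w = pack_params(model)
    shape = (model.n_hidden, model.n_inputs)
    lags = np.arange(1, d + 1)
    for i in range(d, n):
        x = np.concatenate([a[i - lags], t[i - lags], y[i - lags]])
        pred, *_ = _forward_vec(w, x[None, :], shape, model.activation)
        y[i] = pred[0]
    return model.scalers["DBT"].inverse(y)


def generate_dataset(
    profile: SyntheticProfile, n_trees: int, seed: int = 0
) -> GeneratedDataset:
    """Generate ``n_trees`` independent trees under one profile.

    For the network truth the recursion runs continuously across tree
    boundaries (only the very first ``delay`` samples of the flattened series
    are primed), matching how the recurrent model treats the data.
    """
    if n_trees < 1:
        raise SyntheticDataError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    generated: list[GeneratedTree] = []

    if profile.truth == "narx":
        model = profile.truth_network(seed=seed)
        geoms = [_tree_geometry(profile, rng) for _ in range(n_trees)]
        dob_all = np.concatenate([g[2] for g in geoms])
        dtt_all = np.concatenate([g[0] - g[1] for g in geoms])
        dbt_all = _narx_truth_series(model, dob_all, dtt_all, primer=0.3)
        offset = 0
        for i, (H, heights, dob) in enumerate(geoms, start=1):
            n = len(heights)
            generated.append(
                _build_tree(
                    f"sim{i:04d}", profile.species, H, heights, dob,
                    dbt_all[offset : offset + n], profile, rng,
                )
            )
            offset += n
    else:
        for i in range(1, n_trees + 1):
            generated.append(generate_tree(profile, rng, tree_id=f"sim{i:04d}"))

    dataset = Dataset(trees=tuple(g.tree for g in generated), species=profile.species)
    return GeneratedDataset(dataset=dataset, trees=tuple(generated))


def write_generated(gen: GeneratedDataset, path: str | Path) -> None:
    """Canonical measurement CSV plus a ``*.truth.csv`` ground-truth sidecar."""
    from .io_model import write_measurements

    path = Path(path)
    write_measurements(gen.dataset, path)
    gen.ground_truth.to_csv(path.with_suffix(".truth.csv"), index=False)


def noiseless(profile: SyntheticProfile) -> SyntheticProfile:
    """The same study conditions with every observation artefact switched off."""
    return replace(profile, noise_sd=0.0, asymmetry=0.0, gauge_quantum=0.0, k_floor=0.0)
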