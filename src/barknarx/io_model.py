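"""Stem-section measurement records and tabular readers/writers.

The field protocol behind these records: felled trees are measured with
calipers at fixed heights along the bole (0.0, 0.5, 1.3, 2.0 m, then every
2 m to the tip), and bark thickness is taken with a bark gauge in two
perpendicular directions at each section.  One row of input = one section
of one tree.  Diameters and bark readings are in centimetres, heights in
metres; no unit auto-detection is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SectionMeasurement",
    "TreeRecord",
    "Dataset",
    "ValidationIssue",
    "ValidationReport",
    "ConfigurationError",
    "MeasurementParseError",
    "MeasurementValidationError",
    "DEFAULT_COLUMNS",
    "SPECIES_RANGES",
    "load_measurements",
    "write_measurements",
    "validate_dataset",
]

#: canonical column names of the tabular format
DEFAULT_COLUMNS = ("tree_id", "species", "H", "Hb", "DOB", "k1", "k2")

#: published per-species variable ranges (cm for diameters/bark, m for heights)
#: used as default plausibility bounds by :func:`validate_dataset`
SPECIES_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "pine": {
        "k1": (0.05, 6.50),
        "k2": (0.05, 6.50),
        "DBT": (0.10, 13.00),
        "H": (18.30, 32.70),
        "Hb": (0.00, 32.00),
        "DOB": (0.60, 75.55),
    },
    "oak": {
        "k1": (0.01, 5.50),
        "k2": (0.01, 5.40),
        "DBT": (0.03, 10.91),
        "H": (13.90, 35.90),
        "Hb": (0.00, 36.00),
        "DOB": (0.25, 129.25),
    },
}

HB_TOLERANCE = 1e-9


class ConfigurationError(ValueError):
    """A column mapping or option does not match the input file."""


class MeasurementParseError(ValueError):
    """A cell could not be parsed as a number."""


class MeasurementValidationError(ValueError):
    """A row violates a hard physical invariant."""


@dataclass(frozen=True)
class SectionMeasurement:
    """One measurement point on the bole.

    Attributes
    ----------
    Hb : float
        Height along the bole from the ground, m.
    DOB : float
        Stem diameter outside bark at ``Hb`` (mean of the two perpendicular
        caliper readings when both were taken), cm.
    k1, k2 : float
        The two perpendicular bark-gauge readings, cm.
    """

    Hb: float
    DOB: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.Hb < 0:
            raise MeasurementValidationError(f"Hb must be >= 0, got {self.Hb}")
        if self.DOB <= 0:
            raise MeasurementValidationError(f"DOB must be > 0, got {self.DOB}")
        if self.k1 < 0 or self.k2 < 0:
            raise MeasurementValidationError(
                f"bark readings must be >= 0, got k1={self.k1}, k2={self.k2}"
            )
        if self.k1 + self.k2 >= self.DOB:
            raise MeasurementValidationError(
                f"double bark thickness {self.k1 + self.k2} must be smaller "
                f"than the outside-bark diameter {self.DOB}"
            )

    @property
    def dbt(self) -> float:
        """Double bark thickness k1 + k2, cm."""
        return self.k1 + self.k2


@dataclass(frozen=True)
class TreeRecord:
    """A tree with its ordered stem sections (ascending ``Hb``)."""

    tree_id: str
    species: str
    H: float
    sections: tuple[SectionMeasurement, ...]

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise MeasurementValidationError(
                f"tree {self.tree_id}: total height must be > 0, got {self.H}"
            )
        hbs = [s.Hb for s in self.sections]
        if any(b <= a for a, b in zip(hbs, hbs[1:])):
            raise MeasurementValidationError(
                f"tree {self.tree_id}: sections must be strictly ascending in Hb"
            )
        # sections above nominal total height occur in real inventories
        # (H is measured independently of the section tape); keep, but warn
        above = [hb for hb in hbs if hb > self.H + HB_TOLERANCE]
        if above:
            warnings.warn(
                f"tree {self.tree_id}: section height(s) {above} exceed total "
                f"height H={self.H}; rows retained",
                stacklevel=2,
            )

    @property
    def n_sections(self) -> int:
        return len(self.sections)


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of trees sharing one species tag."""

    trees: tuple[TreeRecord, ...]
    species: str

    def __post_init__(self) -> None:
        if not self.trees:
            raise MeasurementValidationError("dataset must contain at least one tree")
        bad = [t.tree_id for t in self.trees if t.species != self.species]
        if bad:
            raise MeasurementValidationError(
                f"trees {bad} do not match the dataset species tag {self.species!r}"
            )

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_sections(self) -> int:
        return sum(t.n_sections for t in self.trees)


@dataclass(frozen=True)
class ValidationIssue:
    tree_id: str
    kind: str
    detail: str


@dataclass
class ValidationReport:
    n_trees: int
    n_sections: int
    section_counts: dict[str, int] = field(default_factory=dict)
    issues: list[ValidationIssue] = field(default_factory=list)
    fatal: bool = False

    @property
    def ok(self) -> bool:
        return not self.fatal and not self.issues


def _numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise MeasurementParseError(
            f"non-numeric value {series[row]!r} in column {column!r} at row {row}"
        )
    if out.isna().any():
        row = int(out.isna().idxmax())
        raise MeasurementParseError(f"missing value in column {column!r} at row {row}")
    return out.astype(float)


def _read_table(path: Path, fmt: str | None, sheet: int | str) -> pd.DataFrame:
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if fmt == "csv":
        return pd.read_csv(path, float_precision="round_trip")
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=sheet)
    raise ConfigurationError(f"unknown format {fmt!r}, expected 'csv' or 'xlsx'")


def dataset_from_frame(
    frame: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> Dataset:
    """Build a :class:`Dataset` from a table of one row per section.

    ``column_map`` maps canonical names (``tree_id``, ``species``, ``H``,
    ``Hb``, ``DOB``, ``k1``, ``k2``) to the columns of ``frame``.  Two
    perpendicular diameter readings may be supplied instead of ``DOB`` by
    mapping ``d1`` and ``d2``; their mean is stored as the section diameter.
    """
    cmap = {name: name for name in DEFAULT_COLUMNS}
    if column_map:
        cmap.update(column_map)

    use_two_diams = "d1" in cmap and "d2" in cmap and "DOB" not in (column_map or {})
    use_two_diams = use_two_diams and cmap.get("d1") in frame.columns
    required = ["tree_id", "species", "H", "Hb", "k1", "k2"]
    required += ["d1", "d2"] if use_two_diams else ["DOB"]
    missing = [cmap[name] for name in required if cmap[name] not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) {missing} not present in input "
            f"(available: {list(frame.columns)})"
        )

    df = pd.DataFrame(index=frame.index)
    df["tree_id"] = frame[cmap["tree_id"]].astype(str)
    df["species"] = frame[cmap["species"]].astype(str).str.strip().str.lower()
    for name in ("H", "Hb", "k1", "k2"):
        df[name] = _numeric(frame[cmap[name]], cmap[name])
    if use_two_diams:
        d1 = _numeric(frame[cmap["d1"]], cmap["d1"])
        d2 = _numeric(frame[cmap["d2"]], cmap["d2"])
        df["DOB"] = (d1 + d2) / 2.0
    else:
        df["DOB"] = _numeric(frame[cmap["DOB"]], cmap["DOB"])

    dup = df.duplicated(subset=["tree_id", "Hb"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["tree_id", "Hb"]].drop_duplicates().values.tolist()
        raise MeasurementValidationError(
            f"duplicate (tree, Hb) measurement pair(s): {pairs}"
        )
    bark_bad = df["k1"] + df["k2"] >= df["DOB"]
    if bark_bad.any():
        rows = list(df.index[bark_bad])
        raise MeasurementValidationError(
            f"bark exceeds stem diameter (k1+k2 >= DOB) at row(s) {rows}"
        )

    species = sorted(df["species"].unique())
    if len(species) > 1:
        raise MeasurementValidationError(
            f"dataset mixes species {species}; load one species at a time"
        )

    trees: list[TreeRecord] = []
    for tree_id, grp in df.groupby("tree_id", sort=False):
        grp = grp.sort_values("Hb")
        h_vals = grp["H"].unique()
        if len(h_vals) > 1:
            raise MeasurementValidationError(
                f"tree {tree_id}: inconsistent total heights {sorted(h_vals)}"
            )
        sections = tuple(
            SectionMeasurement(Hb=r.Hb, DOB=r.DOB, k1=r.k1, k2=r.k2)
            for r in grp.itertuples()
        )
        trees.append(
            TreeRecord(
                tree_id=str(tree_id),
                species=species[0],
                H=float(h_vals[0]),
                sections=sections,
            )
        )
    return Dataset(trees=tuple(trees), species=species[0])


def load_measurements(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: int | str = 0,
) -> Dataset:
    """Read stem-section measurements from CSV or XLSX.

    Parameters
    ----------
    path : path to the input table (one row per section).
    format : ``'csv'`` or ``'xlsx'``; inferred from the suffix when ``None``.
    column_map : canonical-name -> file-column mapping; see
        :func:`dataset_from_frame`.
    sheet : workbook sheet (XLSX only), first sheet by default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return dataset_from_frame(_read_table(path, format, sheet), column_map)


def dataset_to_frame(ds: Dataset) -> pd.DataFrame:
    rows = [
        {
            "tree_id": t.tree_id,
            "species": t.species,
            "H": t.H,
            "Hb": s.Hb,
            "DOB": s.DOB,
            "k1": s.k1,
            "k2": s.k2,
        }
        for t in ds.trees
        for s in t.sections
    ]
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))


def write_measurements(ds: Dataset, path: str | Path) -> None:
    """Write the canonical CSV (default column names, dot decimals)."""
    dataset_to_frame(ds).to_csv(path, index=False)


def validate_dataset(
    ds: Dataset | None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> ValidationReport:
    """Audit a dataset against structural and plausibility rules.

    Reporting only — nothing is raised or dropped.  ``bounds`` overrides the
    per-variable plausibility ranges; defaults are the published per-species
    ranges (:data:`SPECIES_RANGES`).
    """
    if ds is None or not getattr(ds, "trees", ()):
        return ValidationReport(n_trees=0, n_sections=0, fatal=True)

    limits = dict(SPECIES_RANGES.get(ds.species, {}))
    if bounds:
        limits.update(bounds)

    report = ValidationReport(
        n_trees=ds.n_trees,
        n_sections=ds.n_sections,
        section_counts={t.tree_id: t.n_sections for t in ds.trees},
    )
    for tree in ds.trees:
        hbs = [s.Hb for s in tree.sections]
        for a, b in zip(hbs, hbs[1:]):
            if b <= a:  # unreachable for TreeRecord-built data, kept for audits
                report.issues.append(
                    ValidationIssue(tree.tree_id, "non_monotonic_Hb", f"{a} -> {b}")
                )
        for s in tree.sections:
            if s.Hb > tree.H + HB_TOLERANCE:
                report.issues.append(
                    ValidationIssue(
                        tree.tree_id,
                        "Hb_exceeds_H",
                        f"Hb={s.Hb} exceeds H={tree.H}",
                    )
                )
            values = {"Hb": s.Hb, "DOB": s.DOB, "k1": s.k1, "k2": s.k2, "DBT": s.dbt}
            for var, val in values.items():
                if var in limits:
                    lo, hi = limits[var]
                    if not lo <= val <= hi:
                        report.issues.append(
                            ValidationIssue(
                                tree.tree_id,
                                "range_excursion",
                                f"{var}={val} outside [{lo}, {hi}] at Hb={s.Hb}",
                            )
                        )
        if "H" in limits:
            lo, hi = limits["H"]
            if not lo <= tree.H <= hi:
                report.issues.append(
                    ValidationIssue(
                        tree.tree_id, "range_excursion", f"H={tree.H} outside [{lo}, {hi}]"
                    )
                )
    return report


def concat_datasets(datasets: Iterable[Dataset]) -> Dataset:
    """Concatenate datasets of the same species, preserving tree order."""
    datasets = list(datasets)
    species = {d.species for d in datasets}
    if len(species) != 1:
        raise MeasurementValidationError(f"cannot concatenate species {sorted(species)}")
    trees: list[TreeRecord] = []
    for d in datasets:
        trees.extend(d.trees)
    return Dataset(trees=tuple(trees), species=species.pop())
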