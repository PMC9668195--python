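"""Polynomial bark-thickness baselines of the Cao–Pepper / Li–Weiskittel family.

Both models predict double bark thickness (DBT, cm) at a section from the
outside-bark diameter ``avg_d`` (cm), the relative height ``Hb/H`` and the
total height ``H`` (m):

    STAT1:  DBT = avg_d * (b1 + b2 q + b3 q^2 + b4 H) + b5,         q = Hb/H
    STAT2:  DBT = avg_d * (c1 + c2 q + c3 q^2 + c4 H + c5 rho) + c6

where ``rho`` is the inside/outside-bark diameter ratio at breast height
(1.3 m): ``rho = (DOB_1.3 - DBT_1.3) / DOB_1.3``.  The extra quotient term in
STAT2 reduces bias at the cost of needing the breast-height bark measurement.
Both forms are linear in the coefficients, so refitting is an ordinary
least-squares solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import TreeRecord

__all__ = [
    "TaperCoefficients",
    "BreastHeightInfo",
    "TaperError",
    "printed_coefficients",
    "predict_stat1",
    "predict_stat2",
    "breast_height_info",
    "fit_taper_coefficients",
    "save_coefficients",
    "load_coefficients",
]

N_COEF = {"STAT1": 5, "STAT2": 6}


class TaperError(ValueError):
    pass


@dataclass(frozen=True)
class TaperCoefficients:
    """An ordered coefficient vector of one model for one species."""

    model: str  # "STAT1" | "STAT2"
    species: str
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        model = self.model.upper()
        if model not in N_COEF:
            raise TaperError(f"model must be STAT1 or STAT2, got {self.model!r}")
        if len(self.b) != N_COEF[model]:
            raise TaperError(
                f"{model} takes {N_COEF[model]} coefficients, got {len(self.b)}"
            )
        if not all(np.isfinite(self.b)):
            raise TaperError(f"non-finite coefficient in {self.b}")
        object.__setattr__(self, "model", model)


@dataclass(frozen=True)
class BreastHeightInfo:
    """Perpendicular diameter and bark readings at 1.3 m, cm."""

    d1_bh: float
    d2_bh: float
    k1_bh: float
    k2_bh: float

    def __post_init__(self) -> None:
        if (self.d1_bh + self.d2_bh) / 2.0 <= self.k1_bh + self.k2_bh:
            raise TaperError(
                "breast-height bark exceeds the breast-height diameter"
            )

    @property
    def ratio(self) -> float:
        """Inside/outside-bark diameter ratio at breast height."""
        dob = (self.d1_bh + self.d2_bh) / 2.0
        return (dob - (self.k1_bh + self.k2_bh)) / dob


def _coef_fixture_path() -> Path:
    return Path(str(resources.files("barknarx").joinpath("data/taper_coefficients.tsv")))


def printed_coefficients(model: str, species: str) -> TaperCoefficients:
    """Published coefficients of the two models for pine and oak."""
    table = load_coefficients(_coef_fixture_path())
    key = (model.upper(), species.lower())
    if key not in table:
        raise TaperError(f"no printed coefficients for model={model}, species={species}")
    return table[key]


def predict_stat1(avg_d, Hb, H, coef: TaperCoefficients):
    """Five-coefficient bark taper (no breast-height quotient)."""
    if coef.model != "STAT1":
        raise TaperError(f"expected STAT1 coefficients, got {coef.model}")
    avg_d = np.asarray(avg_d, dtype=float)
    Hb = np.asarray(Hb, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise TaperError("total height H must be positive")
    b1, b2, b3, b4, b5 = coef.b
    q = Hb / H
    return avg_d * (b1 + b2 * q + b3 * q * q + b4 * H) + b5


def predict_stat2(avg_d, Hb, H, bh, coef: TaperCoefficients):
    """Six-coefficient bark taper with the breast-height diameter quotient.

    ``bh`` is a :class:`BreastHeightInfo`, or directly the inside/outside-bark
    diameter ratio at 1.3 m (scalar or per-sample array).
    """
    if coef.model != "STAT2":
        raise TaperError(f"expected STAT2 coefficients, got {coef.model}")
    avg_d = np.asarray(avg_d, dtype=float)
    Hb = np.asarray(Hb, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise TaperError("total height H must be positive")
    ratio = bh.ratio if isinstance(bh, BreastHeightInfo) else np.asarray(bh, dtype=float)
    c1, c2, c3, c4, c5, c6 = coef.b
    q = Hb / H
    return avg_d * (c1 + c2 * q + c3 * q * q + c4 * H + c5 * ratio) + c6


BREAST_HEIGHT = 1.3
_BH_TOL = 1e-6


def breast_height_info(tree: TreeRecord, interpolate: bool = False) -> BreastHeightInfo:
    """Breast-height readings of a tree, from its 1.3 m section.

    The measurement protocol guarantees a 1.3 m section, so interpolation
    between flanking sections is only done when explicitly requested.
    """
    for s in tree.sections:
        if abs(s.Hb - BREAST_HEIGHT) <= _BH_TOL:
            return BreastHeightInfo(d1_bh=s.DOB, d2_bh=s.DOB, k1_bh=s.k1, k2_bh=s.k2)
    if not interpolate:
        raise TaperError(
            f"tree {tree.tree_id}: no section at breast height ({BREAST_HEIGHT} m)"
        )
    below = [s for s in tree.sections if s.Hb < BREAST_HEIGHT]
    above = [s for s in tree.sections if s.Hb > BREAST_HEIGHT]
    if not below or not above:
        raise TaperError(
            f"tree {tree.tree_id}: cannot interpolate breast height "
            f"(no flanking sections)"
        )
    lo, hi = below[-1], above[0]
    wgt = (BREAST_HEIGHT - lo.Hb) / (hi.Hb - lo.Hb)
    dob = (1 - wgt) * lo.DOB + wgt * hi.DOB
    k1 = (1 - wgt) * lo.k1 + wgt * hi.k1
    k2 = (1 - wgt) * lo.k2 + wgt * hi.k2
    return BreastHeightInfo(d1_bh=dob, d2_bh=dob, k1_bh=k1, k2_bh=k2)


def _design_matrix(avg_d, Hb, H, ratio, model: str) -> np.ndarray:
    q = Hb / H
    cols = [avg_d, avg_d * q, avg_d * q * q, avg_d * H]
    if model == "STAT2":
        cols.append(avg_d * ratio)
    cols.append(np.ones_like(avg_d))
    return np.column_stack(cols)


def fit_taper_coefficients(
    avg_d,
    Hb,
    H,
    DBT,
    model: str = "STAT1",
    ratio=None,
    species: str = "unknown",
):
    """Ordinary least-squares refit of a taper model.

    Both models are linear in their coefficients, so the fit is an exact
    linear solve.  Returns ``(TaperCoefficients, diagnostics)`` where the
    diagnostics carry the residual variance and per-coefficient standard
    errors (from ``(X'X)^-1 * s^2``).
    """
    model = model.upper()
    if model not in N_COEF:
        raise TaperError(f"model must be STAT1 or STAT2, got {model!r}")
    avg_d = np.asarray(avg_d, dtype=float)
    Hb = np.asarray(Hb, dtype=float)
    H = np.asarray(H, dtype=float)
    DBT = np.asarray(DBT, dtype=float)
    if model == "STAT2":
        if ratio is None:
            raise TaperError("STAT2 refit requires the breast-height ratio per sample")
        ratio = np.broadcast_to(np.asarray(ratio, dtype=float), avg_d.shape)
    p = N_COEF[model]
    n = avg_d.size
    if n < p + 1:
        raise TaperError(f"need at least {p + 1} samples to fit {model}, got {n}")

    X = _design_matrix(avg_d, Hb, H, ratio, model)
    coef, _, rank, _ = np.linalg.lstsq(X, DBT, rcond=None)
    if rank < p:
        raise TaperError(
            f"rank-deficient design (rank {rank} < {p}); "
            "the samples do not span the model terms"
        )
    resid = DBT - X @ coef
    dof = n - p
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    diagnostics = {
        "residual_variance": s2,
        "standard_errors": se,
        "n": n,
        "dof": dof,
    }
    return TaperCoefficients(model=model, species=species, b=tuple(coef)), diagnostics


# ---------------------------------------------------------------------------
# keyed text format for coefficient files


def save_coefficients(table: dict[tuple[str, str], TaperCoefficients], path) -> None:
    lines = ["model\tspecies\tcoefficients"]
    for (model, species), coef in sorted(table.items()):
        values = "\t".join(repr(v) for v in coef.b)
        lines.append(f"{model}\t{species}\t{values}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_coefficients(path) -> dict[tuple[str, str], TaperCoefficients]:
    table: dict[tuple[str, str], TaperCoefficients] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        model, species, *values = line.split("\t")
        table[(model.upper(), species.lower())] = TaperCoefficients(
            model=model, species=species, b=tuple(float(v) for v in values)
        )
    return table
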