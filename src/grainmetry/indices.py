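"""The catalogue of image-derived grain-weight indices and their ranking.

The catalogue holds every evaluated index: the 12 basic descriptors,
20 synthesized ratios/products of them, plus the power-law control
``Kim index = Area^1.32`` (computed on mm^2; a power law is not
unit-covariant, so it is only reported when a physical scale is known).

Two algebraic identities tie the best-performing products back to the
area/perimeter ratio and hold for every grain by construction::

    Area  x Circ. = 4*pi * (Area/Perim.)^2
    Perim. x Circ. = 4*pi * (Area/Perim.)

Ranking correlates each per-sample-mean index with MGW (Pearson R) and
flags the indices that beat both controls (``Area`` and ``Kim index``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "IndexRecord",
    "BASIC_INDICES",
    "CATALOGUE",
    "SELECTED_INDICES",
    "KIM_EXPONENT",
    "kim_index",
    "compute_catalogue",
    "catalogue_table",
    "rank_indices",
]

KIM_EXPONENT = 1.32

BASIC_INDICES = [
    "Area",
    "Perim.",
    "Major",
    "Minor",
    "Circ.",
    "Feret",
    "Skew",
    "Kurt",
    "MinFeret",
    "AR",
    "Round",
    "Solidity",
]

# name -> lambda over the basic-descriptor mapping; `x` may hold scalars
# (one grain) or aligned numpy/pandas columns (a whole table).
_SYNTHESIZED = {
    "Minor/Major": lambda x: x["Minor"] / x["Major"],
    "MinF/Feret": lambda x: x["MinFeret"] / x["Feret"],
    "Area/MinF": lambda x: x["Area"] / x["MinFeret"],
    "Area/Minor": lambda x: x["Area"] / x["Minor"],
    "MinF/Minor": lambda x: x["MinFeret"] / x["Minor"],
    "Area/Perim.": lambda x: x["Area"] / x["Perim."],
    "Minor/Perim.": lambda x: x["Minor"] / x["Perim."],
    "MinF/Perim.": lambda x: x["MinFeret"] / x["Perim."],
    "Area/Perim.^2": lambda x: x["Area"] / x["Perim."] ** 2,  # == Circ./(4*pi); kept verbatim
    "MinF x Area/Perim.": lambda x: x["MinFeret"] * x["Area"] / x["Perim."],
    "Circ. x Solidity": lambda x: x["Circ."] * x["Solidity"],
    "Area x Circ.": lambda x: x["Area"] * x["Circ."],
    "MinF x Circ.": lambda x: x["MinFeret"] * x["Circ."],
    "Minor/Solidity": lambda x: x["Minor"] / x["Solidity"],
    "MinF/Solidity": lambda x: x["MinFeret"] / x["Solidity"],
    "Feret/Solidity": lambda x: x["Feret"] / x["Solidity"],
    "Area x Solidity": lambda x: x["Area"] * x["Solidity"],
    "Feret x MinF x Solidity": lambda x: x["Feret"] * x["MinFeret"] * x["Solidity"],
    "Perim. x Circ.": lambda x: x["Perim."] * x["Circ."],
    "A1": lambda x: x["Area"] * x["Perim."] * x["Circ."] * x["Solidity"] * x["MinFeret"],
    "A2": lambda x: x["Area"] * x["Perim."] * x["Circ."] * x["Solidity"] * x["Minor"],
}

#: All preliminary index names (basic + synthesized), excluding the Kim control.
CATALOGUE = BASIC_INDICES + list(_SYNTHESIZED)

#: The indices retained for model fitting (the catalogue winners plus the
#: two controls, Area and Kim index).
SELECTED_INDICES = [
    "Area",
    "Minor",
    "MinFeret",
    "Area/Perim.",
    "Area x Circ.",
    "Minor/Solidity",
    "MinF/Solidity",
    "Area x Solidity",
    "Perim. x Circ.",
    "A1",
    "A2",
    "Kim index",
]

#: Control indices that a candidate must beat to be selected.
CONTROL_INDICES = ("Area", "Kim index")

# pixel-column -> mm-column substitutions for the mm-basis catalogue
_MM_MAP = {
    "Area": "Area_mm2",
    "Perim.": "Perim._mm",
    "Major": "Major_mm",
    "Minor": "Minor_mm",
    "Feret": "Feret_mm",
    "MinFeret": "MinFeret_mm",
}


@dataclass
class IndexRecord:
    """Catalogue values for one grain or one sample mean."""

    values: dict[str, float]
    basis: str = "per-grain"  # or "per-sample-mean"
    unit_system: str = "pixel"  # or "mm"


def kim_index(area_mm2):
    """Power-law weight control: ``Area^1.32`` on the mm^2 scale."""
    area_mm2 = np.asarray(area_mm2, dtype=float)
    if np.any(area_mm2 <= 0):
        raise ParameterError("Kim index requires a positive area (mm^2)")
    out = area_mm2**KIM_EXPONENT
    return float(out) if out.ndim == 0 else out


class _Basis:
    """Adapter exposing pixel- or mm-basis basic descriptors of a row/table."""

    def __init__(self, source, unit_system: str):
        self.source = source
        self.unit_system = unit_system

    def __getitem__(self, name: str):
        col = _MM_MAP.get(name, name) if self.unit_system == "mm" else name
        try:
            return self.source[col]
        except KeyError as exc:
            raise ParameterError(
                f"descriptor {col!r} missing; cannot compute catalogue "
                f"in {self.unit_system} units"
            ) from exc


def _evaluate(basis: _Basis, with_kim: bool) -> dict:
    values = {name: basis[name] for name in BASIC_INDICES}
    for name, fn in _SYNTHESIZED.items():
        values[name] = fn(basis)
    if with_kim:
        values["Kim index"] = kim_index(basis.source["Area_mm2"])
    return values


def compute_catalogue(descriptors, unit_system: str = "pixel") -> IndexRecord:
    """Evaluate every catalogue entry for one grain.

    ``descriptors`` is a :class:`~grainmetry.descriptors.GrainDescriptors`
    or an equivalent mapping of descriptor columns.  The Kim index is
    included when the mm^2 area is available (always in the mm unit
    system, and in the pixel system too when a scale is attached).
    Division by zero in any ratio raises an error naming the index.
    """
    row = descriptors.to_row() if hasattr(descriptors, "to_row") else dict(descriptors)
    if unit_system not in ("pixel", "mm"):
        raise ParameterError(f"unit_system must be 'pixel' or 'mm', got {unit_system!r}")
    if unit_system == "mm" and "Area_mm2" not in row:
        raise ParameterError("mm-basis catalogue requires mm descriptors (set a scale)")
    basis = _Basis(row, unit_system)
    with np.errstate(divide="raise", invalid="raise"):
        try:
            values = _evaluate(basis, with_kim="Area_mm2" in row)
        except (FloatingPointError, ZeroDivisionError) as exc:
            label = row.get("Label", "?")
            raise ParameterError(f"division by zero in catalogue for grain {label}") from exc
    values = {k: (float(v) if not isinstance(v, str) else v) for k, v in values.items()}
    return IndexRecord(values=values, basis="per-grain", unit_system=unit_system)


def catalogue_table(table: pd.DataFrame, unit_system: str = "pixel") -> pd.DataFrame:
    """Vectorised catalogue over a per-grain (or per-sample) table.

    Returns a DataFrame with one column per catalogue entry, preserving a
    ``Label`` column if present.  The Kim index column is added whenever
    ``Area_mm2`` is available.
    """
    if unit_system not in ("pixel", "mm"):
        raise ParameterError(f"unit_system must be 'pixel' or 'mm', got {unit_system!r}")
    if unit_system == "mm" and "Area_mm2" not in table.columns:
        raise ParameterError("mm-basis catalogue requires mm descriptor columns")
    basis = _Basis(table, unit_system)
    values = _evaluate(basis, with_kim="Area_mm2" in table.columns)
    out = pd.DataFrame(values)
    if "Label" in table.columns:
        out.insert(0, "Label", table["Label"].to_numpy())
    return out


def rank_indices(
    samples: pd.DataFrame,
    mgw_col: str = "MGW",
    controls: tuple[str, ...] = CONTROL_INDICES,
    index_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Rank per-sample-mean indices by |Pearson R| with MGW.

    Returns a DataFrame with columns ``index``, ``R``, ``abs_R``,
    ``zero_variance`` and ``selected`` sorted by ``abs_R`` descending.
    ``selected`` marks indices whose |R| strictly exceeds the largest
    control |R| (controls present in the table; at least ``Area``).
    A zero-variance index gets R = 0 and a flag.  Requires >= 3 samples
    with MGW; the result does not depend on sample order.
    """
    if mgw_col not in samples.columns:
        raise ParameterError(f"samples table has no {mgw_col!r} column")
    data = samples.dropna(subset=[mgw_col])
    if len(data) < 3:
        raise ParameterError(f"need >= 3 samples with {mgw_col}, have {len(data)}")
    if index_cols is None:
        index_cols = [
            c
            for c in data.columns
            if c != mgw_col and pd.api.types.is_numeric_dtype(data[c])
        ]
    y = data[mgw_col].to_numpy(dtype=float)
    rows = []
    for name in index_cols:
        x = data[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"index": name, "R": 0.0, "zero_variance": True})
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"index": name, "R": r, "zero_variance": False})
    out = pd.DataFrame(rows)
    out["abs_R"] = out["R"].abs()
    present_controls = [c for c in controls if c in set(out["index"])]
    if present_controls:
        bar = out.loc[out["index"].isin(present_controls), "abs_R"].max()
        out["selected"] = (out["abs_R"] > bar) & ~out["index"].isin(present_controls)
    else:
        out["selected"] = False
    out = out.sort_values(
        ["abs_R", "index"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out[["index", "R", "abs_R", "zero_variance", "selected"]]
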