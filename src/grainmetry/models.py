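"""Sample aggregation, linear MGW models, cross-validation, prediction.

A *sample* is one image: the grains' descriptor/index columns are
averaged arithmetically, and the observed mean grain weight (MGW, mg) is
the weighed sample mass divided by the grain count.  MGW is then
predicted from a single per-sample-mean index by ordinary least squares,
validated with seeded k-fold cross-validation, or computed directly from
the published slope/intercept pairs shipped with the package (12 indices
at three unit scales: original pixels, 10x-enhanced pixels, and SI).
RMSE is the population form (divide by n).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LookupError_, ParameterError
from .indices import SELECTED_INDICES

__all__ = [
    "SampleMeasurement",
    "LinearModel",
    "CVResult",
    "percent_difference",
    "aggregate_sample",
    "samples_table",
    "fit_linear",
    "kfold_cv",
    "load_published_coefficients",
    "predict_published",
    "correlation_report",
]

UNIT_SYSTEMS = ("original-pixel", "enhanced-pixel", "SI")


def percent_difference(reference: float, value: float) -> float:
    """Percent reduction of ``value`` relative to ``reference``:
    ``100 * (reference - value) / reference``."""
    if reference == 0:
        raise ParameterError("percent difference undefined for zero reference")
    return 100.0 * (reference - value) / reference


@dataclass
class SampleMeasurement:
    """One image's aggregate measurement."""

    sample_id: str
    grain_count: int
    means: pd.Series  # arithmetic mean of each descriptor/index column
    sample_weight: float | None = None  # mg
    mgw: float | None = None  # mg
    group: dict = field(default_factory=dict)  # e.g. {"year": 1, "irrigation": "WI"}

    def __post_init__(self) -> None:
        if self.grain_count < 1:
            raise ParameterError("grain_count must be >= 1")
        if self.mgw is None and self.sample_weight is not None:
            self.mgw = self.sample_weight / self.grain_count

    def to_row(self) -> dict:
        row = {"sample_id": self.sample_id, "grain_count": self.grain_count}
        row.update(self.group)
        row.update(self.means.to_dict())
        if self.sample_weight is not None:
            row["sample_weight"] = self.sample_weight
        if self.mgw is not None:
            row["MGW"] = self.mgw
        return row


@dataclass
class LinearModel:
    """A fitted (or transcribed) one-index linear MGW predictor."""

    index_name: str
    slope: float
    intercept: float
    unit_system: str = "pixel"
    r2: float = float("nan")
    rmse: float = float("nan")  # mg, population form
    n: int = 0
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_json(self, path, seed: int | None = None) -> None:
        payload = asdict(self)
        if seed is not None:
            payload["seed"] = seed
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class CVResult:
    """k-fold cross-validation summary for one index."""

    index_name: str
    k: int
    seed: int
    rmse_mean: float
    rmse_sd: float
    fold_models: list[LinearModel]
    fold_rmse: np.ndarray


def aggregate_sample(
    grains: pd.DataFrame,
    sample_weight: float | None = None,
    sample_id: str = "",
    group: dict | None = None,
) -> SampleMeasurement:
    """Average a per-grain table into one :class:`SampleMeasurement`.

    Every numeric column except ``Label`` is averaged arithmetically;
    MGW = sample_weight / grain_count when a weight (mg) is given,
    otherwise the sample is emitted with MGW unset.
    """
    if len(grains) < 1:
        raise ParameterError("aggregate_sample needs at least one grain row")
    numeric = grains.select_dtypes(include=[np.number]).drop(
        columns=["Label"], errors="ignore"
    )
    return SampleMeasurement(
        sample_id=sample_id,
        grain_count=len(grains),
        means=numeric.mean(),
        sample_weight=sample_weight,
        group=dict(group or {}),
    )


def samples_table(samples: list[SampleMeasurement]) -> pd.DataFrame:
    """Stack sample aggregates into one per-sample table."""
    return pd.DataFrame([s.to_row() for s in samples])


def _xy(samples: pd.DataFrame, index_name: str, mgw_col: str):
    for col in (index_name, mgw_col):
        if col not in samples.columns:
            raise ParameterError(f"samples table has no column {col!r}")
    data = samples.dropna(subset=[index_name, mgw_col])
    x = data[index_name].to_numpy(dtype=float)
    y = data[mgw_col].to_numpy(dtype=float)
    return x, y


def fit_linear(
    samples: pd.DataFrame,
    index_name: str,
    mgw_col: str = "MGW",
    unit_system: str = "pixel",
) -> LinearModel:
    """Ordinary least squares ``MGW = slope * index + intercept``.

    Reports R^2 and the population RMSE over all fitted samples.
    Requires >= 3 samples with MGW and non-zero index variance.
    """
    x, y = _xy(samples, index_name, mgw_col)
    if len(x) < 3:
        raise ParameterError(f"need >= 3 samples to fit, have {len(x)}")
    if np.ptp(x) == 0:
        raise ParameterError(f"index {index_name!r} has zero variance")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    return LinearModel(
        index_name=index_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        unit_system=unit_system,
        r2=float(res.rvalue**2),
        rmse=rmse,
        n=len(x),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def kfold_cv(
    samples: pd.DataFrame,
    index_name: str,
    k: int = 10,
    seed: int = 0,
    mgw_col: str = "MGW",
    unit_system: str = "pixel",
) -> CVResult:
    """Seeded k-fold cross-validation of the one-index linear model.

    A single random permutation (recorded ``seed``) splits the n samples
    into k near-equal folds; each fold is predicted by the model fitted
    on the remaining folds and scored by held-out RMSE.  Reports the mean
    and sd of the k fold RMSEs.
    """
    x, y = _xy(samples, index_name, mgw_col)
    n = len(x)
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    if k > n:
        raise ParameterError(f"k = {k} exceeds the number of samples n = {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    fold_models: list[LinearModel] = []
    fold_rmse = np.empty(k)
    for i, test_idx in enumerate(folds):
        train = np.setdiff1d(perm, test_idx, assume_unique=True)
        df_train = pd.DataFrame({index_name: x[train], mgw_col: y[train]})
        model = fit_linear(df_train, index_name, mgw_col=mgw_col, unit_system=unit_system)
        resid = y[test_idx] - model.predict(x[test_idx])
        fold_rmse[i] = np.sqrt(np.mean(resid**2))
        fold_models.append(model)
    return CVResult(
        index_name=index_name,
        k=k,
        seed=seed,
        rmse_mean=float(fold_rmse.mean()),
        rmse_sd=float(fold_rmse.std(ddof=1)),
        fold_models=fold_models,
        fold_rmse=fold_rmse,
    )


def load_published_coefficients() -> pd.DataFrame:
    """The packaged table of published slopes/intercepts.

    12 indices x 3 unit systems ('original-pixel', 'enhanced-pixel',
    'SI'); SI units are mm for lengths and mm^2 for areas, MGW in mg.
    """
    with resources.files("grainmetry.data").joinpath("published_models.csv").open() as fh:
        return pd.read_csv(fh)


def predict_published(
    index_value,
    index_name: str,
    unit_system: str = "SI",
    coeffs: pd.DataFrame | None = None,
):
    """Predict MGW (mg) from one index value with published coefficients."""
    if coeffs is None:
        coeffs = load_published_coefficients()
    hit = coeffs[(coeffs["index"] == index_name) & (coeffs["unit_system"] == unit_system)]
    if len(hit) != 1:
        available = sorted(
            f"({name}, {unit})"
            for name, unit in zip(coeffs["index"], coeffs["unit_system"])
        )
        raise LookupError_(
            f"no published coefficients for ({index_name!r}, {unit_system!r}); "
            f"available pairs: {', '.join(available)}"
        )
    slope = float(hit["slope"].iloc[0])
    intercept = float(hit["intercept"].iloc[0])
    out = slope * np.asarray(index_value, dtype=float) + intercept
    return float(out) if out.ndim == 0 else out


def correlation_report(
    samples: pd.DataFrame,
    group_cols: list[str] | None = None,
    index_cols: list[str] | None = None,
    mgw_col: str = "MGW",
) -> pd.DataFrame:
    """Pearson R of each retained index vs MGW, overall and per group.

    Rows are indices; the first data column is ``overall`` and one column
    is added per level combination of ``group_cols``.  Groups with fewer
    than 3 samples are skipped with a warning.
    """
    if index_cols is None:
        index_cols = [c for c in SELECTED_INDICES if c in samples.columns]
    if not index_cols:
        raise ParameterError("no index columns found in samples table")

    def _col(data: pd.DataFrame) -> pd.Series:
        y = data[mgw_col].to_numpy(dtype=float)
        vals = {}
        for name in index_cols:
            x = data[name].to_numpy(dtype=float)
            vals[name] = (
                0.0 if np.ptp(x) == 0 or np.ptp(y) == 0 else float(np.corrcoef(x, y)[0, 1])
            )
        return pd.Series(vals)

    data = samples.dropna(subset=[mgw_col])
    if len(data) < 3:
        raise ParameterError("need >= 3 samples with MGW")
    report = pd.DataFrame({"overall": _col(data)})
    if group_cols:
        for key, grp in data.groupby(group_cols, sort=True):
            if len(grp) < 3:
                warnings.warn(f"group {key} has < 3 samples; skipped", stacklevel=2)
                continue
            name = key if isinstance(key, str) else "/".join(str(v) for v in key)
            report[str(name)] = _col(grp)
    report.index.name = "index"
    return report
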