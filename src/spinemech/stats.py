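"""Pairwise shape–performance regressions and packaged reference tables.

The puncture study's printed summary tables ship with the package as CSV
fixtures: per-species spine properties (snout–vent length, spine count,
largest spine volume, highest structural curvature) and per-spine tested
performance (tip angle, normalized tip radius, puncture range, lowest and
average puncture force).  ``shape_performance_screen`` runs the study's
pairwise ordinary-least-squares models of a performance response against
each shape predictor, with an explicit, logged cohort policy: broken
spines are excluded everywhere, and spines that never punctured (missing
force fields) drop out of force models by listwise deletion while keeping
their 0° range in range models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, SpinemechError

__all__ = [
    "LMResult",
    "FixtureTable",
    "CohortPolicy",
    "ols",
    "load_fixtures",
    "shape_performance_screen",
]


RESPONSES = {
    "average_force": "average_force_N",
    "puncture_range": "puncture_range_deg",
    "lowest_force": "lowest_force_N",
}


@dataclass(frozen=True)
class LMResult:
    """Ordinary least squares y = intercept + slope·x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ParameterError("r_squared outside [0, 1]")
        if self.n < 3:
            raise ParameterError("OLS needs at least 3 complete pairs")


@dataclass(frozen=True)
class FixtureTable:
    """The packaged transcriptions of the study's printed tables."""

    table1: pd.DataFrame  # per-species spine properties
    table2: pd.DataFrame  # per-spine puncture performance


@dataclass(frozen=True)
class CohortPolicy:
    """Which spines enter which regression.

    ``exclude_broken``: drop spines flagged broken (one spine broke during
    testing and was excluded from all performance analyses).
    ``zero_range_in_range_models``: keep never-puncturing spines (range 0)
    in puncture-range models; they always drop out of force models because
    their force fields are missing.
    """

    exclude_broken: bool = True
    zero_range_in_range_models: bool = True


def ols(y: Sequence[float], x: Sequence[float]) -> LMResult:
    """OLS with intercept after listwise deletion of missing pairs.

    The p-value is the two-sided t test on the slope with n − 2 degrees of
    freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ParameterError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ParameterError(f"only {n} complete pairs; OLS needs >= 3")
    if np.ptp(x) == 0:
        raise ParameterError("predictor has zero variance")
    res = sps.linregress(x, y)
    return LMResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _data_dir() -> Path:
    return Path(resources.files("spinemech") / "data")


def load_fixtures(data_dir: str | Path | None = None) -> FixtureTable:
    """Load the packaged reference tables, verifying their checksums.

    Raises
    ------
    SpinemechError
        When a fixture file does not match its manifest checksum.
    """
    root = Path(data_dir) if data_dir is not None else _data_dir()
    manifest = json.loads((root / "manifest.json").read_text())
    frames = {}
    for name, entry in manifest["files"].items():
        payload = (root / name).read_bytes()
        digest = hashlib.sha256(payload).hexdigest()
        if digest != entry["sha256"]:
            raise SpinemechError(
                f"fixture {name} fails its checksum "
                f"(expected {entry['sha256'][:12]}…, got {digest[:12]}…)"
            )
        frames[name] = pd.read_csv(root / name)
    t2 = frames["table2.csv"]
    if len(t2) != 13:
        raise SpinemechError("table2 fixture must have 13 spine rows")
    return FixtureTable(table1=frames["table1.csv"], table2=t2)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def shape_performance_screen(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    cohort: CohortPolicy | None = None,
) -> pd.DataFrame:
    """Pairwise linear models of one performance response on each predictor.

    Parameters
    ----------
    table
        Per-spine table with at least ``spine_id``, the response column and
        the predictor columns; a boolean ``broken`` column marks spines to
        exclude under the default cohort policy.
    response
        One of ``average_force``, ``puncture_range``, ``lowest_force`` (or
        a raw column name).
    predictors
        Column names regressed against the response, one model each.

    Returns
    -------
    DataFrame
        One row per predictor: slope, intercept, r², p, n, a
        Benjamini–Hochberg column (the study reports unadjusted marginal
        p-values; the adjusted column is additional), and the exact cohort
        (included spine ids) for audit.
    """
    pol = cohort or CohortPolicy()
    resp_col = RESPONSES.get(response, response)
    if resp_col not in table.columns:
        raise ParameterError(f"response column {resp_col!r} not in table")
    df = table.copy()
    excluded: dict[str, str] = {}
    if pol.exclude_broken and "broken" in df.columns:
        for sid in df.loc[df["broken"].astype(bool), "spine_id"]:
            excluded[str(sid)] = "broken"
        df = df.loc[~df["broken"].astype(bool)]
    if resp_col == "puncture_range_deg" and not pol.zero_range_in_range_models:
        zero = (df[resp_col] == 0) & df[
            ["lowest_force_N", "average_force_N"]
        ].isna().all(axis=1)
        for sid in df.loc[zero, "spine_id"]:
            excluded[str(sid)] = "never punctured"
        df = df.loc[~zero]

    rows = []
    for pred in predictors:
        if pred not in df.columns:
            raise ParameterError(f"predictor column {pred!r} not in table")
        y = df[resp_col].to_numpy(float)
        x = df[pred].to_numpy(float)
        keep = ~(np.isnan(x) | np.isnan(y))
        fit = ols(y[keep], x[keep])
        dropped = sorted(
            set(df.loc[~keep, "spine_id"].astype(str)) if (~keep).any() else set()
        )
        rows.append(
            {
                "response": resp_col,
                "predictor": pred,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "n": fit.n,
                "cohort": ",".join(sorted(df.loc[keep, "spine_id"].astype(str))),
                "excluded": ";".join(
                    [f"{k}:{v}" for k, v in sorted(excluded.items())]
                    + [f"{s}:missing {resp_col}" for s in dropped]
                ),
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = _bh_adjust(out["p_value"].to_numpy())
    return out
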