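"""Power-law growth model for the loss of species-level resolution.

As a database of size ``X`` grows, the number of sequences ``Y`` caught
in multi-species clusters is modelled as

    Y = c * X^m,

estimated by ordinary least squares of ``log Y`` on ``log X``: ``m`` is
the slope (the *rate*; ``m > 1`` means super-linear resolution loss) and
``c = exp(intercept)``.  Natural logs are used internally; ``m`` is
invariant to the log base.  Points with ``Y = 0`` carry no information in
log space and are dropped (and counted), rather than shifted by an
arbitrary pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RateFit", "fit_rate", "fit_all", "rate_table"]


@dataclass(frozen=True)
class RateFit:
    """Estimated (c, m) of Y = c * X^m with log-log OLS diagnostics."""

    marker_id: str
    threshold: float
    c: float
    m: float
    r_squared: float
    n_points_used: int
    n_points_dropped_zero: int

    @property
    def defined(self) -> bool:
        return self.n_points_used >= 2 and math.isfinite(self.m)


def _undefined(marker_id: str, threshold: float, used: int, dropped: int) -> RateFit:
    return RateFit(marker_id, threshold, math.nan, math.nan, math.nan, used, dropped)


def fit_rate(
    points: Iterable[tuple[float, float]],
    marker_id: str = "",
    threshold: float = math.nan,
) -> RateFit:
    """Fit Y = c * X^m to (X, Y) points by OLS in log-log space.

    All X must be positive; points with Y <= 0 are excluded and counted
    in ``n_points_dropped_zero``.  With fewer than two positive-Y points
    (or no variation in X) the fit is reported undefined (NaN
    parameters), not raised.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if any(x <= 0 for x, _ in pts):
        raise ValueError("all X (database sizes) must be positive")
    pos = [(x, y) for x, y in pts if y > 0]
    dropped = len(pts) - len(pos)
    if len(pos) < 2:
        return _undefined(marker_id, threshold, len(pos), dropped)
    lx = np.log([x for x, _ in pos])
    ly = np.log([y for _, y in pos])
    if np.ptp(lx) == 0:
        return _undefined(marker_id, threshold, len(pos), dropped)
    res = sps.linregress(lx, ly)
    r2 = float(res.rvalue**2) if math.isfinite(res.rvalue) else 1.0
    return RateFit(
        marker_id=marker_id,
        threshold=threshold,
        c=float(np.exp(res.intercept)),
        m=float(res.slope),
        r_squared=r2,
        n_points_used=len(pos),
        n_points_dropped_zero=dropped,
    )


def fit_all(table: pd.DataFrame, on: str = "median") -> list[RateFit]:
    """One power-law fit per (marker, threshold) group of a stats table.

    ``on="median"`` (default) first takes the per-size median of
    ``n_sequences_in_msc`` across replicates, mirroring how bootstrap
    medians are reported; ``on="all"`` fits every replicate point,
    which is useful for variance estimation.  Degenerate groups yield an
    undefined fit instead of aborting the others.
    """
    if on not in ("median", "all"):
        raise ValueError("on must be 'median' or 'all'")
    required = {"marker_id", "threshold", "db_size", "n_sequences_in_msc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"stats table lacks columns: {sorted(missing)}")
    fits: list[RateFit] = []
    for (marker, thr), grp in table.groupby(["marker_id", "threshold"], sort=True):
        if on == "median":
            agg = grp.groupby("db_size", as_index=False)["n_sequences_in_msc"].median()
            pts = list(zip(agg["db_size"], agg["n_sequences_in_msc"]))
        else:
            pts = list(zip(grp["db_size"], grp["n_sequences_in_msc"]))
        fits.append(fit_rate(pts, marker_id=str(marker), threshold=float(thr)))
    return fits


def rate_table(fits: Sequence[RateFit]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": f.marker_id,
            "threshold": f.threshold,
            "c": f.c,
            "m": f.m,
            "r_squared": f.r_squared,
            "n_points_used": f.n_points_used,
            "n_points_dropped_zero": f.n_points_dropped_zero,
        }
        for f in fits
    ]
    return pd.DataFrame(
        rows,
        columns=["marker_id", "threshold", "c", "m", "r_squared", "n_points_used", "n_points_dropped_zero"],
    )


def write_rate_tsv(fits: Sequence[RateFit], path: str | Path) -> None:
    rate_table(fits).to_csv(path, sep="\t", index=False)
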