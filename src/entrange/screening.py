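"""Predictor screening: Pearson collinearity + contribution-based retention.

The retention rule: variables contributing nothing to the model are dropped
outright; then highly correlated pairs (|r| above a threshold, default 0.7)
are resolved greedily in decreasing |r| order, keeping the member with the
larger model contribution.  The report records every decision and the
partner that triggered it, so a screening run is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rasters import PredictorStack


@dataclass
class ScreeningReport:
    correlation_matrix: pd.DataFrame
    contributions: dict[str, float] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)
    dropped: list[tuple[str, str, str]] = field(default_factory=list)  # name, reason, partner
    zero_variance: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": n, "decision": "kept", "reason": "", "partner": ""}
                for n in self.kept]
        rows += [{"variable": n, "decision": "dropped", "reason": r, "partner": p}
                 for n, r, p in self.dropped]
        return pd.DataFrame(rows)


def pearson_matrix(stack: PredictorStack, sample_rows: np.ndarray,
                   sample_cols: np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    """Pearson r between all layer pairs over the given sample cells.

    Returns (matrix, zero_variance_names).  Zero-variance layers get NaN
    off-diagonal entries rather than spurious correlations; samples where
    any layer is nodata are excluded for all pairs (shared-valid samples).
    """
    names = stack.names
    X = stack.table(sample_rows, sample_cols)
    valid = np.all(np.isfinite(X), axis=1)
    X = X[valid]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 valid sample points")
    if X.shape[0] == 0 or np.all(~np.isfinite(X)):
        raise ValueError("all samples are nodata")
    sd = X.std(axis=0)
    zero_var = [n for n, s in zip(names, sd) if s < 1e-12]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 1.0)
    for i, n in enumerate(names):
        if n in zero_var:
            r[i, :] = np.nan
            r[:, i] = np.nan
            r[i, i] = 1.0
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=names, columns=names), zero_var


def screen_variables(contributions: dict[str, float],
                     correlation_matrix: pd.DataFrame,
                     r_threshold: float = 0.7,
                     min_contribution: float = 0.0) -> ScreeningReport:
    """Resolve collinearity by contribution.

    1. Drop variables with contribution <= ``min_contribution`` (default 0:
       only non-contributing variables go).
    2. Scan pairs with |r| >= ``r_threshold`` in decreasing |r| (ties broken
       alphabetically); when both members are still alive, drop the one
       with the lower contribution (contribution ties: drop the
       alphabetically later name).
    """
    names = list(correlation_matrix.index)
    missing = [n for n in names if n not in contributions]
    if missing:
        raise ValueError(f"no contribution value for: {missing}")

    report = ScreeningReport(correlation_matrix=correlation_matrix,
                             contributions=dict(contributions))
    alive = set(names)
    for n in sorted(names):
        if contributions[n] <= min_contribution:
            alive.discard(n)
            report.dropped.append((n, "zero_contribution" if min_contribution == 0
                                   else f"contribution<={min_contribution}", ""))

    R = correlation_matrix.to_numpy()
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rij = R[i, j]
            if np.isfinite(rij) and abs(rij) >= r_threshold:
                a, b = sorted((names[i], names[j]))
                pairs.append((abs(rij), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    for rabs, a, b in pairs:
        if a in alive and b in alive:
            ca, cb = contributions[a], contributions[b]
            if ca > cb:
                loser, winner = b, a
            elif cb > ca:
                loser, winner = a, b
            else:
                loser, winner = max(a, b), min(a, b)
            alive.discard(loser)
            report.dropped.append((loser, f"|r|={rabs:.3f}>= {r_threshold}", winner))

    report.kept = [n for n in names if n in alive]
    dropped_names = {n for n, _, _ in report.dropped}
    assert alive | dropped_names == set(names)
    return report
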