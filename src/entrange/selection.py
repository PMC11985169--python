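"""Grid search over regularization multipliers and feature classes.

Candidate settings are scored by cross-validated mean AUC, mean 10%
omission rate (OR10), mean train-test AUC difference, and small-sample
AICc on a full-data refit; the selected setting minimizes delta-AICc with
omission rate, AUC and parsimony as tie-breakers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .maxent import MaxentModel, cross_validate

DEFAULT_FC_VALUES = ["L", "LQ", "H", "LQH", "LQHP", "LQHPT"]


def default_grid() -> tuple[list[float], list[str]]:
    """The canonical tuning grid: rm 0.1..4.0 in steps of 0.1 (40 values)
    times six feature-class combinations = 240 candidate settings.

    rm values are enumerated as integer tenths so the grid is decimal-safe
    (no 0.30000000000000004 artifacts).
    """
    rm_values = [float(Fraction(i, 10)) for i in range(1, 41)]
    return rm_values, list(DEFAULT_FC_VALUES)


@dataclass
class TuningGrid:
    rm_values: list[float]
    fc_values: list[str]
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: fc, rm, mean_auc, mean_or10, avg_diff_auc, aicc, delta_aicc,
    #          k, aicc_defined, failed

    def __post_init__(self):
        if not self.records.empty:
            expected = len(self.rm_values) * len(self.fc_values)
            if len(self.records) != expected:
                raise ValueError(
                    f"records count {len(self.records)} != grid size {expected}")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_grid(presences: pd.DataFrame, background: pd.DataFrame,
             rm_values=None, fc_values=None, folds: int = 10, seed: int = 0,
             n_knots: int = 50, categorical=(), max_iter: int = 500,
             ) -> TuningGrid:
    """Fit and evaluate every (fc, rm) combination.

    All combinations share one seeded fold assignment so their
    cross-validation metrics are comparable; AICc comes from a full-data
    refit.  A failure in one combination is recorded, not fatal.
    """
    if rm_values is None or fc_values is None:
        d_rm, d_fc = default_grid()
        rm_values = d_rm if rm_values is None else list(rm_values)
        fc_values = d_fc if fc_values is None else list(fc_values)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    fold_assignment = rng.permutation(len(presences)) % folds

    rows = []
    for fc in fc_values:
        for rm in rm_values:
            rec = {"fc": fc, "rm": rm, "failed": False}
            try:
                cv = cross_validate(presences, background, fc=fc, rm=rm,
                                    folds=folds, n_knots=n_knots,
                                    categorical=categorical,
                                    fold_assignment=fold_assignment,
                                    max_iter=max_iter)
                mean = cv[cv["fold"] == "mean"].iloc[0]
                full = MaxentModel(presences, background, fc=fc, rm=rm,
                                   n_knots=n_knots, categorical=categorical
                                   ).fit(max_iter=max_iter)
                aicc, defined = full.aicc()
                rec.update(mean_auc=float(mean["auc_test"]),
                           mean_or10=float(mean["or10"]),
                           avg_diff_auc=float(mean["diff_auc"]),
                           aicc=aicc, aicc_defined=defined,
                           k=full.n_nonzero)
            except Exception as exc:  # pragma: no cover - defensive
                rec.update(failed=True, error=str(exc), aicc=np.nan,
                           aicc_defined=False, mean_auc=np.nan,
                           mean_or10=np.nan, avg_diff_auc=np.nan, k=-1)
            rows.append(rec)
    records = pd.DataFrame(rows)
    ok = records["aicc_defined"] & ~records["failed"]
    if ok.any():
        records["delta_aicc"] = records["aicc"] - records.loc[ok, "aicc"].min()
    else:
        records["delta_aicc"] = np.nan
    records.loc[~ok, "delta_aicc"] = np.nan
    return TuningGrid(rm_values=list(rm_values), fc_values=list(fc_values),
                      records=records)


def select_best(grid: TuningGrid) -> tuple[str, float]:
    """argmin delta-AICc among defined records; ties resolved by lower
    mean OR10, then higher mean AUC, then smaller rm."""
    rec = grid.records
    ok = rec["aicc_defined"] & ~rec["failed"]
    if not ok.any():
        raise ValueError("no record has a defined AICc")
    cand = rec[ok].copy()
    cand = cand.sort_values(
        by=["delta_aicc", "mean_or10", "mean_auc", "rm"],
        ascending=[True, True, False, True], kind="mergesort")
    best = cand.iloc[0]
    return str(best["fc"]), float(best["rm"])


def improvement_report(default_record: dict, optimized_record: dict) -> tuple[float, float]:
    """Relative improvement of the optimized setting over the default.

    Returns (auc_change_pct, or10_reduction_pct), both rounded to two
    decimals: (AUC_opt - AUC_def)/AUC_def * 100 and
    (OR_def - OR_opt)/OR_def * 100.
    """
    auc_def = float(default_record["mean_auc"])
    auc_opt = float(optimized_record["mean_auc"])
    or_def = float(default_record["mean_or10"])
    or_opt = float(optimized_record["mean_or10"])
    auc_change = round((auc_opt - auc_def) / auc_def * 100.0, 2)
    or_reduction = round((or_def - or_opt) / or_def * 100.0, 2) if or_def else 0.0
    return auc_change, or_reduction
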