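"""Presence-background maximum-entropy species distribution model.

The model estimates a Gibbs density q(x) = exp(lambda . f(x)) / Z over the
landscape (represented by a background sample of cells), constrained so the
expected feature values under q stay within an L1 budget of their empirical
means at the presence cells.  Equivalently, ``fit`` minimizes the
regularized presence log-loss

    J(lambda) = -mean_presence[eta(x)] + log sum_background exp(eta(x))
                + sum_j beta_j |lambda_j|,        eta = lambda . f

by cyclic coordinate-wise proximal Newton descent with soft-thresholding,
which yields the sparse solutions characteristic of maximum-entropy SDMs.

Features are the classical five classes — linear (L), quadratic (Q),
product (P), forward/reverse hinge (H) and threshold (T) — built on
variables rescaled to [0, 1] by their training-background range.  Per-class
regularization follows the published default tables, interpolated in the
presence count and scaled by the regularization multiplier (rm).

Usage follows the Model/Results convention::

    model = MaxentModel(presence_df, background_df, fc="LQH", rm=1.0)
    res = model.fit()
    res.summary()
    scores = res.predict(new_df, mode="logistic")
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .rasters import PredictorStack

__all__ = [
    "FeatureDef", "FeatureSet", "build_features", "MaxentModel",
    "MaxentResults", "EvalMetrics", "evaluate_scores", "auc_rank",
    "cross_validate", "jackknife_gain", "mtsps_threshold",
    "sample_background",
]

VALID_FC_LETTERS = set("LQHPT")


# ---------------------------------------------------------------------------
# Feature construction

@dataclass(frozen=True)
class FeatureDef:
    kind: str                      # linear|quadratic|product|hinge_fwd|hinge_rev|threshold|indicator
    variables: tuple[str, ...]
    knot: float | None = None      # in scaled [0,1] units
    level: float | None = None     # for categorical indicators

    @property
    def name(self) -> str:
        v = "*".join(self.variables)
        if self.kind in ("hinge_fwd", "hinge_rev", "threshold"):
            return f"{self.kind}({v}@{self.knot:.4f})"
        if self.kind == "indicator":
            return f"indicator({v}={self.level:g})"
        return f"{self.kind}({v})"


class FeatureSet:
    """Feature definitions plus the background scaling that makes every
    feature land in [0, 1] (with clamping)."""

    def __init__(self, variables: list[str], defs: list[FeatureDef],
                 var_min: dict[str, float], var_max: dict[str, float],
                 categorical: set[str]):
        self.variables = list(variables)
        self.defs = list(defs)
        self.var_min = dict(var_min)
        self.var_max = dict(var_max)
        self.categorical = set(categorical)

    def __len__(self) -> int:
        return len(self.defs)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def _scaled(self, X: pd.DataFrame, clamp: bool) -> dict[str, np.ndarray]:
        z = {}
        for v in self.variables:
            x = X[v].to_numpy(dtype=float)
            if v in self.categorical:
                z[v] = x
                continue
            lo, hi = self.var_min[v], self.var_max[v]
            span = hi - lo if hi > lo else 1.0
            s = (x - lo) / span
            z[v] = np.clip(s, 0.0, 1.0) if clamp else s
        return z

    def transform(self, X: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """(n, n_features) design matrix for a table of variable values."""
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise KeyError(f"missing variables: {missing}")
        z = self._scaled(X, clamp)
        cols = np.empty((len(X), len(self.defs)))
        for j, d in enumerate(self.defs):
            if d.kind == "linear":
                cols[:, j] = z[d.variables[0]]
            elif d.kind == "quadratic":
                cols[:, j] = z[d.variables[0]] ** 2
            elif d.kind == "product":
                cols[:, j] = z[d.variables[0]] * z[d.variables[1]]
            elif d.kind == "hinge_fwd":
                k = d.knot
                cols[:, j] = np.clip((z[d.variables[0]] - k) / max(1.0 - k, 1e-12), 0.0, 1.0)
            elif d.kind == "hinge_rev":
                k = d.knot
                cols[:, j] = np.clip((k - z[d.variables[0]]) / max(k, 1e-12), 0.0, 1.0)
            elif d.kind == "threshold":
                cols[:, j] = (z[d.variables[0]] > d.knot).astype(float)
            elif d.kind == "indicator":
                cols[:, j] = (z[d.variables[0]] == d.level).astype(float)
            else:  # pragma: no cover
                raise ValueError(d.kind)
        return cols


def build_features(background: pd.DataFrame, fc: str = "LQH",
                   n_knots: int = 50,
                   categorical: set[str] | frozenset[str] = frozenset()
                   ) -> FeatureSet:
    """Deterministic feature list for the requested classes.

    Hinge and threshold knots sit at ``n_knots`` equally spaced background
    quantiles of each scaled variable, restricted to the open interval
    (0, 1).  Categorical variables contribute one indicator per observed
    level regardless of fc.
    """
    fc = fc.upper()
    bad = set(fc) - VALID_FC_LETTERS
    if bad:
        raise ValueError(f"unknown feature-class letters: {sorted(bad)}")
    variables = list(background.columns)
    categorical = set(categorical) & set(variables)
    continuous = [v for v in variables if v not in categorical]

    var_min = {v: float(np.nanmin(background[v])) for v in continuous}
    var_max = {v: float(np.nanmax(background[v])) for v in continuous}

    defs: list[FeatureDef] = []
    if "L" in fc:
        defs += [FeatureDef("linear", (v,)) for v in continuous]
    if "Q" in fc:
        defs += [FeatureDef("quadratic", (v,)) for v in continuous]
    if "P" in fc:
        for i in range(len(continuous)):
            for j in range(i + 1, len(continuous)):
                defs.append(FeatureDef("product", (continuous[i], continuous[j])))

    def knots_for(v: str) -> np.ndarray:
        lo, hi = var_min[v], var_max[v]
        span = hi - lo if hi > lo else 1.0
        z = np.clip((background[v].to_numpy(dtype=float) - lo) / span, 0.0, 1.0)
        qs = np.linspace(0, 1, n_knots + 2)[1:-1]
        k = np.quantile(z, qs)
        k = np.clip(k, 1e-6, 1 - 1e-6)
        # keep requested count even when quantiles coincide: nudge duplicates
        return k + np.arange(len(k)) * 1e-12

    if "H" in fc:
        for v in continuous:
            for k in knots_for(v):
                defs.append(FeatureDef("hinge_fwd", (v,), knot=float(k)))
            for k in knots_for(v):
                defs.append(FeatureDef("hinge_rev", (v,), knot=float(k)))
    if "T" in fc:
        for v in continuous:
            for k in knots_for(v):
                defs.append(FeatureDef("threshold", (v,), knot=float(k)))
    for v in categorical:
        for level in np.unique(background[v].to_numpy(dtype=float)):
            defs.append(FeatureDef("indicator", (v,), level=float(level)))
    return FeatureSet(variables, defs, var_min, var_max, categorical)


# ---------------------------------------------------------------------------
# Regularization: published default tables, interpolated in presence count

_BETA_TABLES = {
    "lqp": ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05]),
    "categorical": ([0, 10, 17], [0.65, 0.5, 0.25]),
    "threshold": ([0, 100], [2.0, 1.0]),
    "hinge": ([0], [0.5]),
}

_KIND_TO_TABLE = {
    "linear": "lqp", "quadratic": "lqp", "product": "lqp",
    "hinge_fwd": "hinge", "hinge_rev": "hinge",
    "threshold": "threshold", "indicator": "categorical",
}


def _beta_base(kind: str, n_presence: int) -> float:
    xs, ys = _BETA_TABLES[_KIND_TO_TABLE[kind]]
    return float(np.interp(n_presence, xs, ys))


def regularization_vector(feature_set: FeatureSet, presence_F: np.ndarray,
                          rm: float, n_presence: int) -> np.ndarray:
    """beta_j = rm * class_base(m) * max(sd_j, 1e-3) / sqrt(m)."""
    sd = presence_F.std(axis=0)
    sd = np.maximum(sd, 1e-3)
    base = np.array([_beta_base(d.kind, n_presence) for d in feature_set.defs])
    return rm * base * sd / np.sqrt(max(n_presence, 1))


# ---------------------------------------------------------------------------
# Background sampling and stack extraction helpers

def sample_background(stack: PredictorStack, size: int = 10_000,
                      seed: int = 0) -> pd.DataFrame:
    """Uniform seeded sample of valid cells as a variable table."""
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    n = len(rows)
    if n == 0:
        raise ValueError("stack has no valid cells")
    rng = np.random.default_rng(seed)
    if size < n:
        pick = rng.choice(n, size=size, replace=False)
        rows, cols = rows[pick], cols[pick]
    return pd.DataFrame(stack.table(rows, cols), columns=stack.names)


def presences_to_table(stack: PredictorStack, longitude, latitude
                       ) -> pd.DataFrame:
    """Extract stack values at occurrence coordinates (cell lookup).

    Points outside the grid or on nodata cells are dropped.
    """
    g = stack.geometry
    lon = np.asarray(longitude, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    col = np.floor((lon - g.xll) / g.cellsize).astype(int)
    top = g.yll + g.rows * g.cellsize
    row = np.floor((top - lat) / g.cellsize).astype(int)
    ok = (row >= 0) & (row < g.rows) & (col >= 0) & (col < g.cols)
    row, col = row[ok], col[ok]
    X = stack.table(row, col)
    valid = np.all(np.isfinite(X), axis=1)
    return pd.DataFrame(X[valid], columns=stack.names)


# ---------------------------------------------------------------------------
# Model

class MaxentModel:
    """Maximum-entropy presence-background model.

    Parameters
    ----------
    presences, background : DataFrame
        Variable tables (one column per predictor).  Presence rows are
        appended to the background for the normalization constant, the
        usual presence-background convention.
    fc : str
        Feature classes, a subset of "LQHPT".
    rm : float
        Regularization multiplier scaling every beta_j.
    n_knots : int
        Hinge/threshold knots per variable (background quantiles).
    categorical : iterable of str
        Variables to treat as categorical (indicator features only).
    """

    def __init__(self, presences: pd.DataFrame, background: pd.DataFrame,
                 fc: str = "LQH", rm: float = 1.0, n_knots: int = 50,
                 categorical=()):
        if len(presences) < 2:
            raise ValueError("need at least 2 presence records")
        if list(presences.columns) != list(background.columns):
            presences = presences[background.columns]
        self.presences = presences.reset_index(drop=True)
        self.background = background.reset_index(drop=True)
        self.fc = fc.upper()
        self.rm = float(rm)
        self.n_knots = int(n_knots)
        self.categorical = set(categorical)
        self.feature_set = build_features(self.background, self.fc,
                                          n_knots=self.n_knots,
                                          categorical=self.categorical)
        # training background = background + presences (normalization set)
        self._bg_all = pd.concat([self.background, self.presences],
                                 ignore_index=True)
        self._Fp = self.feature_set.transform(self.presences)
        self._Fb = self.feature_set.transform(self._bg_all)
        if self._Fb.std(axis=0).max() < 1e-12:
            raise ValueError("zero-variance feature set: no feature varies "
                             "over the background")
        self.beta = regularization_vector(self.feature_set, self._Fp,
                                          self.rm, len(self.presences))

    @classmethod
    def from_stack(cls, stack: PredictorStack, occurrences, fc: str = "LQH",
                   rm: float = 1.0, n_knots: int = 50,
                   background_size: int = 10_000, seed: int = 0,
                   categorical=()) -> "MaxentModel":
        """Build from a raster stack and an OccurrenceSet (or lon/lat pair)."""
        if hasattr(occurrences, "longitude"):
            lon, lat = occurrences.longitude, occurrences.latitude
        else:
            lon, lat = occurrences
        pres = presences_to_table(stack, lon, lat)
        bg = sample_background(stack, size=background_size, seed=seed)
        cat = set(categorical) | set(stack.categorical)
        return cls(pres, bg, fc=fc, rm=rm, n_knots=n_knots, categorical=cat)

    # -- objective pieces ---------------------------------------------------

    def _objective(self, eta_p: np.ndarray, eta_b: np.ndarray) -> float:
        return float(-eta_p.mean() + logsumexp(eta_b))

    def fit(self, max_iter: int = 500, tol: float = 1e-5,
            step_cap: float = 2.0) -> "MaxentResults":
        """Cyclic coordinate-wise proximal Newton descent.

        Each coordinate takes a soft-thresholded Newton step (capped at
        ``step_cap``) with backtracking; convergence is declared when a
        full sweep improves the penalized objective by less than ``tol``.
        Per-variable objective-improvement credit is accumulated during
        the fit and later normalized into percent contributions.
        """
        Fp, Fb, beta = self._Fp, self._Fb, self.beta
        K = Fp.shape[1]
        lam = np.zeros(K)
        eta_p = np.zeros(len(Fp))
        eta_b = np.zeros(len(Fb))
        mean_fp = Fp.mean(axis=0)
        credit: dict[str, float] = {v: 0.0 for v in self.feature_set.variables}

        J = self._objective(eta_p, eta_b)  # penalty is 0 at lam=0
        converged = False
        n_sweeps = 0
        for sweep in range(max_iter):
            n_sweeps = sweep + 1
            J_start = J
            w = np.exp(eta_b - logsumexp(eta_b))
            for j in range(K):
                fj = Fb[:, j]
                Ej = float(w @ fj)
                grad = Ej - mean_fp[j]
                hess = float(w @ (fj * fj)) - Ej * Ej
                if hess < 1e-10:
                    continue
                target = lam[j] - grad / hess
                new = np.sign(target) * max(abs(target) - beta[j] / hess, 0.0)
                d = np.clip(new - lam[j], -step_cap, step_cap)
                if d == 0.0:
                    continue
                pen_old = beta[j] * abs(lam[j])
                accepted = False
                for _ in range(6):
                    cand = lam[j] + d
                    eb = eta_b + d * fj
                    ep = eta_p + d * Fp[:, j]
                    J_new = self._objective(ep, eb)
                    if J_new + beta[j] * abs(cand) <= J + pen_old + 1e-12:
                        drop = (J + pen_old) - (J_new + beta[j] * abs(cand))
                        lam[j] = cand
                        eta_b, eta_p, J = eb, ep, J_new
                        w = np.exp(eta_b - logsumexp(eta_b))
                        vars_ = self.feature_set.defs[j].variables
                        for v in vars_:
                            credit[v] += drop / len(vars_)
                        accepted = True
                        break
                    d *= 0.5
                if not accepted:
                    continue
            if J_start - J < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"maxent fit did not converge in {max_iter} sweeps",
                          RuntimeWarning)
        return MaxentResults(self, lam, converged=converged, n_iter=n_sweeps,
                             contribution_credit=credit)


@dataclass
class EvalMetrics:
    auc_train: float
    auc_test: float
    or10: float
    aicc: float
    n_train: int
    n_test: int
    k: int
    aicc_defined: bool = True

    @property
    def diff_auc(self) -> float:
        return self.auc_train - self.auc_test


def auc_rank(presence_scores, background_scores) -> float:
    """ROC AUC by the Mann-Whitney rank statistic, ties averaged."""
    from scipy.stats import rankdata
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("empty score set")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:len(p)].sum() - len(p) * (len(p) + 1) / 2.0
    return float(u / (len(p) * len(b)))


class MaxentResults:
    """Fitted maximum-entropy model: weights, normalizers, diagnostics."""

    def __init__(self, model: MaxentModel, lam: np.ndarray, converged: bool,
                 n_iter: int, contribution_credit: dict[str, float]):
        self.model = model
        self.params = pd.Series(lam, index=model.feature_set.names)
        self.converged = converged
        self.n_iter = n_iter
        self._credit = contribution_credit

        eta_b = model._Fb @ lam
        self.linear_predictor_normalizer = float(eta_b.max())
        w = np.exp(eta_b - self.linear_predictor_normalizer)
        self.density_normalizer = float(w.sum())
        raw = w / self.density_normalizer
        self.entropy = float(-(raw * np.log(np.maximum(raw, 1e-300))).sum())
        self._raw_background = raw
        self._train_presence_raw = self._raw_from_eta(model._Fp @ lam)

    # -- prediction ---------------------------------------------------------

    def _raw_from_eta(self, eta: np.ndarray) -> np.ndarray:
        return np.exp(eta - self.linear_predictor_normalizer) / self.density_normalizer

    def predict(self, X, mode: str = "logistic", clamp: bool = True):
        """Score a variable table (DataFrame) or a PredictorStack.

        raw: Gibbs density normalized over the training background.
        logistic: tau=0.5 calibrated transform, exp(H)*raw/(1+exp(H)*raw).
        """
        if mode not in ("raw", "logistic"):
            raise ValueError(mode)
        if isinstance(X, PredictorStack):
            return self._predict_stack(X, mode, clamp)
        F = self.model.feature_set.transform(X, clamp=clamp)
        raw = self._raw_from_eta(F @ self.params.to_numpy())
        if mode == "raw":
            return raw
        eh = np.exp(self.entropy)
        return eh * raw / (1.0 + eh * raw)

    def _predict_stack(self, stack: PredictorStack, mode: str,
                       clamp: bool) -> np.ndarray:
        missing = [v for v in self.model.feature_set.variables if v not in stack]
        if missing:
            raise KeyError(f"stack lacks model variables: {missing}")
        mask = stack.valid_mask()
        rows, cols = np.nonzero(mask)
        X = pd.DataFrame(stack.table(rows, cols), columns=stack.names)
        scores = self.predict(X[self.model.feature_set.variables], mode=mode,
                              clamp=clamp)
        out = np.full(stack.geometry.shape, np.nan)
        out[rows, cols] = scores
        return out

    # -- diagnostics --------------------------------------------------------

    @property
    def n_nonzero(self) -> int:
        return int((self.params.to_numpy() != 0).sum())

    def training_gain(self) -> float:
        """log(background size) minus presence log-loss; 0 for the uniform
        (no-feature) model."""
        B = len(self.model._bg_all)
        return float(np.log(B) + np.mean(np.log(self._train_presence_raw)))

    def log_likelihood(self, presence_X: pd.DataFrame | None = None) -> float:
        """Sum of log raw densities at presences (AICc convention)."""
        if presence_X is None:
            raw = self._train_presence_raw
        else:
            raw = self.predict(presence_X, mode="raw")
        return float(np.log(np.maximum(raw, 1e-300)).sum())

    def aicc(self) -> tuple[float, bool]:
        """(AICc, defined?) with k = nonzero weights, n = presence count."""
        n = len(self.model.presences)
        k = self.n_nonzero
        if n - k - 1 <= 0:
            return float("nan"), False
        ll = self.log_likelihood()
        return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1), True

    def evaluate(self, test_presences: pd.DataFrame,
                 train_presences: pd.DataFrame | None = None) -> EvalMetrics:
        """AUC (train/test), OR10 and AICc against the model background.

        OR10 uses the 10th percentile of *training* presence logistic
        scores as the omission threshold, applied to test presences.
        """
        if len(test_presences) == 0:
            raise ValueError("empty test set")
        if train_presences is None:
            train_presences = self.model.presences
        bg_scores = self.predict(self.model.background, mode="logistic")
        train_scores = self.predict(train_presences, mode="logistic")
        test_scores = self.predict(test_presences, mode="logistic")
        thr = np.percentile(train_scores, 10)
        or10 = float(np.mean(test_scores < thr))
        aicc, defined = self.aicc()
        return EvalMetrics(
            auc_train=auc_rank(train_scores, bg_scores),
            auc_test=auc_rank(test_scores, bg_scores),
            or10=or10, aicc=aicc, aicc_defined=defined,
            n_train=len(train_presences), n_test=len(test_presences),
            k=self.n_nonzero)

    def percent_contribution(self) -> pd.Series:
        """Objective-improvement credit per variable, normalized to 100."""
        s = pd.Series(self._credit, dtype=float)
        total = s.sum()
        if total <= 0:
            return s * 0.0
        return 100.0 * s / total

    def permutation_importance(self, seed: int = 0) -> pd.Series:
        """Training-AUC drop per shuffled variable, normalized to 100."""
        rng = np.random.default_rng(seed)
        pres, bg = self.model.presences, self.model.background
        base_auc = auc_rank(self.predict(pres), self.predict(bg))
        n_p = len(pres)
        combined = pd.concat([pres, bg], ignore_index=True)
        drops = {}
        for v in self.model.feature_set.variables:
            shuffled = combined.copy()
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
            s = self.predict(shuffled)
            drops[v] = max(0.0, base_auc - auc_rank(s[:n_p], s[n_p:]))
        ser = pd.Series(drops)
        total = ser.sum()
        return 100.0 * ser / total if total > 0 else ser * 0.0

    def response_curve(self, variable: str, mode: str = "marginal",
                       n_points: int = 100) -> pd.DataFrame:
        """(value, logistic) pairs across the variable's training range.

        marginal: vary one variable, others held at their background mean
        (mode for categoricals).  univariate: refit using only this
        variable and the model's feature classes.
        """
        fs = self.model.feature_set
        if variable not in fs.variables:
            raise KeyError(variable)
        bg = self.model.background
        lo = fs.var_min.get(variable, float(bg[variable].min()))
        hi = fs.var_max.get(variable, float(bg[variable].max()))
        grid = np.linspace(lo, hi, n_points)
        if mode == "marginal":
            base = {}
            for v in fs.variables:
                if v in fs.categorical:
                    base[v] = float(bg[v].mode().iloc[0])
                else:
                    base[v] = float(bg[v].mean())
            X = pd.DataFrame({v: np.full(n_points, val)
                              for v, val in base.items()})
            X[variable] = grid
            y = self.predict(X[fs.variables], mode="logistic")
        elif mode == "univariate":
            sub_m = MaxentModel(self.model.presences[[variable]],
                                self.model.background[[variable]],
                                fc=self.model.fc, rm=self.model.rm,
                                n_knots=self.model.n_knots,
                                categorical=self.model.categorical & {variable})
            sub = sub_m.fit()
            y = sub.predict(pd.DataFrame({variable: grid}), mode="logistic")
        else:
            raise ValueError(mode)
        return pd.DataFrame({"value": grid, "logistic": y})

    def plot_response(self, variable: str, mode: str = "marginal", ax=None):
        """Response curve plot (matplotlib axis returned)."""
        import matplotlib.pyplot as plt
        curve = self.response_curve(variable, mode=mode)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["value"], curve["logistic"])
        ax.set_xlabel(variable)
        ax.set_ylabel("logistic suitability")
        ax.set_title(f"{mode} response: {variable}")
        return ax

    def summary(self) -> str:
        ev = None
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 46,
            f"feature classes:        {self.model.fc}",
            f"regularization mult.:   {self.model.rm}",
            f"presences / background: {len(self.model.presences)} / "
            f"{len(self.model.background)}",
            f"features (nonzero):     {len(self.params)} ({self.n_nonzero})",
            f"converged:              {self.converged} ({self.n_iter} sweeps)",
            f"entropy (nats):         {self.entropy:.4f}",
            f"training gain:          {self.training_gain():.4f}",
            "-" * 46,
            "percent contribution:",
        ]
        pc = self.percent_contribution().sort_values(ascending=False)
        for v, c in pc.items():
            lines.append(f"  {v:<20s} {c:6.1f}%")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_lambdas(self, path) -> None:
        """Self-describing plain-text lambdas-style dump."""
        fs = self.model.feature_set
        with open(path, "w") as fh:
            fh.write(f"# entrange maxent model fc={self.model.fc} rm={self.model.rm}\n")
            fh.write(f"linearPredictorNormalizer, {self.linear_predictor_normalizer!r}\n")
            fh.write(f"densityNormalizer, {self.density_normalizer!r}\n")
            fh.write(f"numBackgroundPoints, {len(self.model._bg_all)}\n")
            fh.write(f"entropy, {self.entropy!r}\n")
            for d, lam in zip(fs.defs, self.params.to_numpy()):
                vmins = [fs.var_min.get(v, 0.0) for v in d.variables]
                vmaxs = [fs.var_max.get(v, 1.0) for v in d.variables]
                fh.write(f"{d.name}, {lam!r}, {min(vmins)!r}, {max(vmaxs)!r}\n")


# ---------------------------------------------------------------------------
# Evaluation utilities above the Results object

def evaluate_scores(presence_scores, background_scores) -> float:
    return auc_rank(presence_scores, background_scores)


def mtsps_threshold(test_presence_scores, background_scores) -> float:
    """Maximum test sensitivity plus specificity threshold.

    A point is "suitable" when its score strictly exceeds the threshold
    (matching the <=-is-unsuitable classification convention).  All unique
    observed scores are scanned; ties resolve to the lowest threshold.
    """
    p = np.asarray(test_presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("empty score set")
    candidates = np.unique(np.concatenate([[0.0], p, b]))
    if len(np.unique(np.concatenate([p, b]))) == 1:
        warnings.warn("degenerate score set: single unique score",
                      RuntimeWarning)
        return float(p[0])
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        sens = np.mean(p > t)
        spec = np.mean(b <= t)
        val = sens + spec
        if val > best_val + 1e-12:
            best_val, best_t = val, t
    return float(best_t)


def cross_validate(presences: pd.DataFrame, background: pd.DataFrame,
                   fc: str = "LQH", rm: float = 1.0, folds: int = 10,
                   seed: int = 0, n_knots: int = 50, categorical=(),
                   fold_assignment: np.ndarray | None = None,
                   max_iter: int = 500) -> pd.DataFrame:
    """k-fold cross-validation of a (fc, rm) setting.

    Returns one row per fold plus a "mean" row; fold assignment is a
    seeded random partition, reusable across settings via
    ``fold_assignment``.
    """
    n = len(presences)
    if folds > n:
        raise ValueError("more folds than presences")
    if fold_assignment is None:
        rng = np.random.default_rng(seed)
        fold_assignment = rng.permutation(n) % folds
    rows = []
    for f in range(folds):
        test_idx = fold_assignment == f
        train = presences[~test_idx]
        test = presences[test_idx]
        if len(test) == 0 or len(train) < 2:
            continue
        res = MaxentModel(train, background, fc=fc, rm=rm, n_knots=n_knots,
                          categorical=categorical).fit(max_iter=max_iter)
        m = res.evaluate(test)
        rows.append({"fold": f, "auc_train": m.auc_train,
                     "auc_test": m.auc_test, "diff_auc": m.diff_auc,
                     "or10": m.or10, "k": m.k})
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean()
    mean["fold"] = "mean"
    return pd.concat([df, mean.to_frame().T], ignore_index=True)


def jackknife_gain(presences: pd.DataFrame, background: pd.DataFrame,
                   fc: str = "LQH", rm: float = 1.0, n_knots: int = 50,
                   categorical=(), max_iter: int = 500) -> pd.DataFrame:
    """Leave-one-out and with-only training gains per variable."""
    variables = list(background.columns)
    full = MaxentModel(presences, background, fc=fc, rm=rm, n_knots=n_knots,
                       categorical=categorical).fit(max_iter=max_iter)
    full_gain = full.training_gain()
    rows = []
    for v in variables:
        only = MaxentModel(presences[[v]], background[[v]], fc=fc, rm=rm,
                           n_knots=n_knots,
                           categorical=set(categorical) & {v}).fit(max_iter=max_iter)
        others = [u for u in variables if u != v]
        if others:
            without = MaxentModel(presences[others], background[others],
                                  fc=fc, rm=rm, n_knots=n_knots,
                                  categorical=set(categorical) & set(others)
                                  ).fit(max_iter=max_iter)
            gain_without = without.training_gain()
        else:
            gain_without = 0.0  # zero-variable model is uniform
        rows.append({"variable": v, "gain_with_only": only.training_gain(),
                     "gain_without": gain_without, "full_gain": full_gain})
    return pd.DataFrame(rows)
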