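"""Presence-background Maxent and the logistic GLM baseline.

The maximum-entropy model treats the fire days of a regime as presence
samples drawn from the background of all in-regime days, and fits the
Gibbs distribution

    q_lambda(x) = exp(lambda . f(x)) / Z(lambda),   Z = sum over background,

that maximises the L1-penalised mean presence log-likelihood

    mean_presence[lambda . f] - log Z(lambda) - sum_j beta_j |lambda_j|.

Features f are the classic Maxent transforms of the environmental
variables (linear, quadratic, product, hinge, threshold), min-max rescaled
so every feature maps the background into [0, 1]; the feature classes are
auto-selected from the presence count and the per-feature penalty widths
beta_j follow the published Maxent default regularisation tables. At the
optimum the KKT conditions pin each feature's expectation under q within
beta_j of its presence-sample mean, which is the "lie in a range around
the empirical data" behaviour of the original software.

The baseline is an ordinary maximum-likelihood logistic regression of the
fire-day indicator on the raw variables (fire days = 1, all other days =
0), with a tiny-ridge fallback when the data are separable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBasis",
    "MaxentModel",
    "LogisticModel",
    "build_feature_basis",
    "fit_maxent",
    "fit_logistic",
    "auto_feature_classes",
    "default_beta",
]

# published Maxent default regularisation tables: per feature class, the
# tuning value as a piecewise-linear function of presence count
_REG_TABLES = {
    "linear": [(10.0, 1.0), (30.0, 0.2), (100.0, 0.05)],
    "quadratic": [(17.0, 1.3), (30.0, 0.8), (100.0, 0.05)],
    "product": [(8.0, 2.6), (10.0, 1.6), (15.0, 1.4), (30.0, 1.0), (100.0, 0.05)],
    "hinge": [(0.0, 0.5), (1.0, 0.5)],
    "threshold": [(7.0, 2.0), (100.0, 1.0)],
}


def auto_feature_classes(n_presence: int) -> set[str]:
    """Feature classes enabled by presence count (Maxent auto-features)."""
    classes = {"linear"}
    if n_presence >= 10:
        classes.add("quadratic")
    if n_presence >= 15:
        classes.add("hinge")
    if n_presence >= 80:
        classes.update({"product", "threshold"})
    return classes


def _interp_table(table: list[tuple[float, float]], n: float) -> float:
    xs = np.array([x for x, _ in table])
    ys = np.array([y for _, y in table])
    return float(np.interp(n, xs, ys))


def default_beta(
    feature_kinds: Sequence[str],
    presence_features: np.ndarray,
    reg_multiplier: float = 1.0,
) -> np.ndarray:
    """Per-feature L1 penalty widths beta_j.

    beta_j = multiplier * r_class(m) * s_j / sqrt(m), with m the presence
    count, r_class the tuned default table and s_j the presence-sample
    standard deviation of the feature (floored to keep near-constant
    features from becoming penalty-free).
    """
    m = presence_features.shape[0]
    sd = presence_features.std(axis=0, ddof=0)
    beta = np.empty(len(feature_kinds))
    for j, kind in enumerate(feature_kinds):
        r = _interp_table(_REG_TABLES[kind], m)
        s = max(sd[j], 0.05 if kind in ("hinge", "threshold") else 1e-3)
        beta[j] = reg_multiplier * r * s / np.sqrt(max(m, 1))
    return np.maximum(beta, 1e-6)


# ---------------------------------------------------------------------------
# feature basis


@dataclasses.dataclass
class FeatureBasis:
    """Expanded feature basis over min-max rescaled variables.

    ``features`` is a list of definitions: ``("linear", i)``,
    ``("quadratic", i)``, ``("product", i, j)``, ``("hinge", i, knot,
    direction)`` with direction +1 (forward) or -1 (reverse), and
    ``("threshold", i, knot)``; knots are in rescaled [0, 1] units.
    """

    variables: list[str]
    lower: np.ndarray  # per-variable background min
    upper: np.ndarray  # per-variable background max
    features: list[tuple]
    classes: set[str]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def kinds(self) -> list[str]:
        return [f[0] for f in self.features]

    def rescale(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Min-max rescale raw variable columns to [0, 1].

        Values outside the training background range are clamped to the
        range bound (the Maxent clamping convention).
        """
        span = np.where(self.upper > self.lower, self.upper - self.lower, 1.0)
        Z = (np.asarray(X, float) - self.lower) / span
        if clamp:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    def transform(self, X) -> np.ndarray:
        """Map raw rows (n x n_variables) to the feature matrix (n x J)."""
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(float)
        Z = self.rescale(np.atleast_2d(np.asarray(X, float)))
        cols = np.empty((Z.shape[0], len(self.features)))
        for j, f in enumerate(self.features):
            kind = f[0]
            if kind == "linear":
                cols[:, j] = Z[:, f[1]]
            elif kind == "quadratic":
                cols[:, j] = Z[:, f[1]] ** 2
            elif kind == "product":
                cols[:, j] = Z[:, f[1]] * Z[:, f[2]]
            elif kind == "hinge":
                _, i, knot, direction = f
                if direction > 0:
                    denom = 1.0 - knot if knot < 1.0 else 1.0
                    cols[:, j] = np.maximum(Z[:, i] - knot, 0.0) / denom
                else:
                    denom = knot if knot > 0.0 else 1.0
                    cols[:, j] = np.maximum(knot - Z[:, i], 0.0) / denom
            elif kind == "threshold":
                cols[:, j] = (Z[:, f[1]] > f[2]).astype(float)
            else:  # pragma: no cover
                raise ValueError(f"unknown feature kind {kind!r}")
        return cols

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "features": [list(f) for f in self.features],
            "classes": sorted(self.classes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureBasis":
        return cls(
            variables=list(d["variables"]),
            lower=np.asarray(d["lower"], float),
            upper=np.asarray(d["upper"], float),
            features=[tuple(f) for f in d["features"]],
            classes=set(d["classes"]),
        )


def build_feature_basis(
    background: pd.DataFrame,
    n_presence: int,
    classes: str | set[str] = "auto",
    n_knots: int = 50,
) -> FeatureBasis:
    """Build the feature basis over a background variable matrix.

    ``classes="auto"`` selects feature classes from the presence count per
    the Maxent defaults (linear below 10 presences, +quadratic from 10,
    +hinge from 15, +product +threshold from 80). Hinge/threshold knots are
    placed at background quantiles, ``n_knots`` per variable per direction.
    Binary (two-valued) variables contribute their indicator as a linear
    feature only. Constant variables are dropped with a warning.
    """
    if classes == "auto":
        classes = auto_feature_classes(n_presence)
    elif isinstance(classes, str):
        classes = {classes}
    unknown = classes - set(_REG_TABLES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")

    names = list(background.columns)
    X = background.to_numpy(float)
    lower, upper = X.min(axis=0), X.max(axis=0)
    keep = upper > lower
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        names = [n for n, k in zip(names, keep) if k]
        X, lower, upper = X[:, keep], lower[keep], upper[keep]
    if not names:
        raise ValueError("no non-constant variables to build features from")

    is_binary = [np.unique(X[:, i]).size <= 2 for i in range(X.shape[1])]
    Z = (X - lower) / np.where(upper > lower, upper - lower, 1.0)

    features: list[tuple] = []
    for i in range(len(names)):
        features.append(("linear", i))
    if "quadratic" in classes:
        for i in range(len(names)):
            if not is_binary[i]:
                features.append(("quadratic", i))
    if "product" in classes:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                features.append(("product", i, j))
    qs = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
    if "hinge" in classes:
        for i in range(len(names)):
            if is_binary[i]:
                continue
            knots = np.unique(np.round(np.quantile(Z[:, i], qs), 12))
            knots = knots[(knots > 0.0) & (knots < 1.0)]
            for k in knots:
                features.append(("hinge", i, float(k), 1))
                features.append(("hinge", i, float(k), -1))
    if "threshold" in classes:
        for i in range(len(names)):
            if is_binary[i]:
                continue
            knots = np.unique(np.round(np.quantile(Z[:, i], qs), 12))
            knots = knots[(knots > 0.0) & (knots < 1.0)]
            for k in knots:
                features.append(("threshold", i, float(k)))

    return FeatureBasis(variables=names, lower=lower, upper=upper, features=features, classes=set(classes))


# ---------------------------------------------------------------------------
# Maxent fit


@dataclasses.dataclass
class MaxentModel:
    """A fitted maximum-entropy presence-background model."""

    basis: FeatureBasis
    coef: np.ndarray  # lambda, one per feature
    beta: np.ndarray  # per-feature penalty widths
    log_z: float  # log normaliser over the training background
    entropy: float  # entropy of q over the training background
    converged: bool
    n_iter: int
    gain: float  # unpenalised gain over the uniform background model

    def scores(self, X, output: str = "raw") -> np.ndarray:
        """Score rows; ``raw`` sums to 1 over the training background,
        ``logistic`` is the standard Maxent logistic transform, ``link``
        is the linear predictor lambda . f(x). All are strictly monotone
        transforms of one another, so rank-based metrics agree."""
        F = self.basis.transform(X)
        eta = F @ self.coef
        if output == "link":
            return eta
        raw = np.exp(eta - self.log_z)
        if output == "raw":
            return raw
        if output == "logistic":
            v = raw * np.exp(self.entropy)
            return v / (1.0 + v)
        raise ValueError(f"unknown output {output!r}")

    def kkt_violation(self, presence_features: np.ndarray, background_features: np.ndarray) -> float:
        """Max violation of |E_q[f_j] - presence mean_j| <= beta_j."""
        eta = background_features @ self.coef
        q = np.exp(eta - logsumexp(eta))
        gap = np.abs(q @ background_features - presence_features.mean(axis=0))
        return float(np.max(gap - self.beta))

    def to_dict(self) -> dict:
        return {
            "family": "maxent",
            "basis": self.basis.to_dict(),
            "coef": self.coef.tolist(),
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "gain": self.gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxentModel":
        return cls(
            basis=FeatureBasis.from_dict(d["basis"]),
            coef=np.asarray(d["coef"], float),
            beta=np.asarray(d["beta"], float),
            log_z=float(d["log_z"]),
            entropy=float(d["entropy"]),
            converged=bool(d["converged"]),
            n_iter=int(d["n_iter"]),
            gain=float(d["gain"]),
        )


def fit_maxent(
    presence: pd.DataFrame | np.ndarray,
    background: pd.DataFrame | np.ndarray,
    basis: FeatureBasis | None = None,
    reg_multiplier: float = 1.0,
    classes: str | set[str] = "auto",
    n_knots: int = 50,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> MaxentModel:
    """Fit the L1-penalised Gibbs distribution by proximal gradient (FISTA).

    ``presence`` rows should be a subset of ``background`` rows (in the
    temporal niche, fire days are background days). The fit starts from
    lambda = 0 (the uniform distribution) and stops when the penalised
    objective improves by less than ``tol`` between iterations, or after
    ``max_iter`` iterations, mirroring the original software's defaults.
    """
    if isinstance(background, np.ndarray):
        background = pd.DataFrame(np.atleast_2d(background))
        background.columns = [str(c) for c in background.columns]
    if isinstance(presence, np.ndarray):
        presence = pd.DataFrame(np.atleast_2d(presence), columns=background.columns)
    m = len(presence)
    if m < 2:
        raise ValueError("need at least 2 presences")
    if basis is None:
        basis = build_feature_basis(background, n_presence=m, classes=classes, n_knots=n_knots)

    F_bg = basis.transform(background)
    F_pr = basis.transform(presence)
    if F_bg.shape[1] == 0:
        raise ValueError("degenerate (empty) feature basis")
    p_mean = F_pr.mean(axis=0)
    beta = default_beta(basis.kinds, F_pr, reg_multiplier)
    n_bg = F_bg.shape[0]

    def smooth(lam):
        eta = F_bg @ lam
        lz = logsumexp(eta)
        return lz - p_mean @ lam, eta, lz

    def grad(eta, lz, lam):
        q = np.exp(eta - lz)
        return F_bg.T @ q - p_mean

    lam = np.zeros(F_bg.shape[1])
    y = lam.copy()
    t_mom = 1.0
    L = 1.0
    f_y, eta_y, lz_y = smooth(y)
    obj_prev = f_y + beta @ np.abs(lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = grad(eta_y, lz_y, y)
        # backtracking line search on the smooth part
        while True:
            lam_new = np.sign(y - g / L) * np.maximum(np.abs(y - g / L) - beta / L, 0.0)
            f_new, eta_new, lz_new = smooth(lam_new)
            d = lam_new - y
            if f_new <= f_y + g @ d + 0.5 * L * d @ d + 1e-12:
                break
            L *= 2.0
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        y = lam_new + (t_mom - 1.0) / t_next * (lam_new - lam)
        # restart momentum if the objective went up
        obj_new = f_new + beta @ np.abs(lam_new)
        if obj_new > obj_prev:
            y = lam_new.copy()
            t_next = 1.0
        lam, t_mom = lam_new, t_next
        f_y, eta_y, lz_y = smooth(y)
        L = max(L / 1.5, 1e-3)
        if abs(obj_prev - obj_new) < tol:
            converged = True
            obj_prev = obj_new
            break
        obj_prev = obj_new
    if not converged:
        warnings.warn(f"maxent did not converge in {max_iter} iterations", stacklevel=2)

    eta = F_bg @ lam
    lz = logsumexp(eta)
    q = np.exp(eta - lz)
    entropy = float(-(q @ (eta - lz)))
    gain = float(p_mean @ lam - lz + np.log(n_bg))
    return MaxentModel(
        basis=basis,
        coef=lam,
        beta=beta,
        log_z=float(lz),
        entropy=entropy,
        converged=converged,
        n_iter=it,
        gain=gain,
    )


# ---------------------------------------------------------------------------
# logistic baseline


@dataclasses.dataclass
class LogisticModel:
    """Maximum-likelihood logistic regression of fire day on variables."""

    variables: list[str]
    intercept: float
    coef: np.ndarray
    converged: bool
    separation_fallback: bool = False

    def scores(self, X, output: str = "probability") -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.variables].to_numpy(float)
        eta = self.intercept + np.atleast_2d(np.asarray(X, float)) @ self.coef
        return eta if output == "link" else expit(eta)

    def to_dict(self) -> dict:
        return {
            "family": "logistic",
            "variables": self.variables,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "converged": self.converged,
            "separation_fallback": self.separation_fallback,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            variables=list(d["variables"]),
            intercept=float(d["intercept"]),
            coef=np.asarray(d["coef"], float),
            converged=bool(d["converged"]),
            separation_fallback=bool(d.get("separation_fallback", False)),
        )


def fit_logistic(labels, variables: pd.DataFrame) -> LogisticModel:
    """Unpenalised logit fit; tiny-ridge fallback under separation."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(labels, float)
    if y.min() == y.max():
        raise ValueError("need at least one presence and one absence")
    names = list(variables.columns)
    X = variables.to_numpy(float)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, float)
        huge = np.abs(params).max() > 30.0
        if not res.mle_retvals.get("converged", True) or huge or not np.isfinite(params).all():
            raise PerfectSeparationError("suspected separation")
        return LogisticModel(names, float(params[0]), params[1:], converged=True)
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning, Exception) as exc:
        if not isinstance(exc, (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning)):
            # statsmodels wraps separation in several exception types
            if "eparation" not in str(exc) and "singular" not in str(exc).lower():
                raise
        logger.warning("logistic fit fell back to tiny ridge: %s", exc)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(penalty="l2", C=1e4, max_iter=2000)
        lr.fit(X, y.astype(int))
        return LogisticModel(
            names,
            float(lr.intercept_[0]),
            lr.coef_[0].astype(float),
            converged=True,
            separation_fallback=True,
        )


def save_model(model, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path):
    with open(path) as fh:
        d = json.load(fh)
    return MaxentModel.from_dict(d) if d["family"] == "maxent" else LogisticModel.from_dict(d)
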