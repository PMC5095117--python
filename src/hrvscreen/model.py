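"""Logistic-regression screening core.

The screen is a plain nine-variable logistic regression: the logit score
b0 + b1*x1 + ... + b9*x9 over the canonical feature order, mapped to the
probability of major depressive disorder by the logistic sigmoid, and
thresholded at a cutoff (0.28 by default, the published operating point).
Fitting is by unpenalized maximum likelihood via iteratively reweighted
least squares (IRLS) with step-halving; goodness of fit is summarized by
the Cox-Snell and Nagelkerke pseudo-R-squared.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .paradigm import FEATURE_NAMES, FeatureVector

__all__ = [
    "DEFAULT_CUTOFF",
    "LogisticModel",
    "ScreenResult",
    "PseudoR2",
    "SeparationError",
    "published_model",
    "PUBLISHED_SCREENING_EXAMPLES",
    "logit_score",
    "probability",
    "classify",
    "fit_lra",
    "pseudo_r2",
    "save_model",
    "load_model",
]

#: Published operating point on the logit scale.
DEFAULT_CUTOFF = 0.28

#: Published SDS screening cutoff (score >= 50 flags depression).
SDS_CUTOFF = 50


class SeparationError(RuntimeError):
    """Maximum-likelihood estimate does not exist (separated data)."""


@dataclass
class FitInfo:
    n: int
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    iterations: int


@dataclass
class LogisticModel:
    """Intercept plus named coefficients; optionally carries fit metadata."""

    intercept: float
    coef: dict[str, float]
    fit: FitInfo | None = None

    def __post_init__(self):
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        for name, v in self.coef.items():
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name} must be finite")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.coef)

    def coef_array(self) -> np.ndarray:
        return np.array(list(self.coef.values()), dtype=float)


def published_model() -> LogisticModel:
    """The published nine-coefficient screening model.

    Coefficients act on raw (unstandardized) features: HR in bpm, HF in
    ms^2, LF/HF dimensionless, per experimental state.  No fit metadata is
    attached — the training cohort is not redistributable.
    """
    return LogisticModel(
        intercept=-5.062,
        coef={
            "hr_before": 0.201,
            "hr_task": -0.053,
            "hr_after": -0.086,
            "hf_before": -0.019,
            "hf_task": 0.012,
            "hf_after": 0.007,
            "lfhf_before": 0.094,
            "lfhf_task": -0.087,
            "lfhf_after": 0.312,
        },
    )


#: Published per-subject screening examples: (diagnosis, logit score, SDS
#: score), sorted by descending logit.  Useful for exercising the cutoff
#: logic on real reported values.
PUBLISHED_SCREENING_EXAMPLES: tuple[tuple[str, float, int], ...] = (
    ("MDD", 2.7, 62),
    ("MDD", 2.2, 42),
    ("MDD", 1.7, 51),
    ("MDD", 1.3, 47),
    ("MDD", 0.8, 56),
    ("MDD", 0.8, 65),
    ("MDD", 0.7, 58),
    ("MDD", 0.3, 59),
    ("MDD", -1.1, 43),
    ("healthy", 0.7, 50),
    ("healthy", 0.5, 57),
    ("healthy", 0.4, 51),
    ("healthy", 0.2, 48),
    ("healthy", -3.1, 38),
    ("healthy", -3.3, 32),
    ("healthy", -4.6, 45),
    ("healthy", -5.2, 33),
    ("healthy", -8.4, 50),
    ("healthy", -15.3, 48),
    ("healthy", -15.6, 56),
)


@dataclass
class ScreenResult:
    """Score and call for one subject at a given cutoff."""

    logit: float
    probability: float
    label: str
    cutoff: float


@dataclass
class PseudoR2:
    cox_snell: float
    nagelkerke: float


def _features_array(fv) -> np.ndarray:
    if isinstance(fv, FeatureVector):
        return fv.as_array()
    arr = np.asarray(fv, dtype=float)
    if arr.shape[-1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features")
    return arr


def logit_score(model: LogisticModel, fv) -> float:
    """Linear predictor b0 + sum(bk * xk) over the canonical order."""
    x = _features_array(fv)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    b = np.array([model.coef[n] for n in FEATURE_NAMES], dtype=float)
    return float(model.intercept + x @ b)


def probability(model: LogisticModel, fv) -> float:
    """Sigmoid of the logit: the modeled probability of depression."""
    return float(expit(logit_score(model, fv)))


def classify(logit: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Screening call: "MDD" when the logit meets the cutoff (>=)."""
    if not np.isfinite(logit):
        raise ValueError("logit must be finite")
    return "MDD" if logit >= cutoff else "healthy"


def screen(model: LogisticModel, fv, cutoff: float = DEFAULT_CUTOFF) -> ScreenResult:
    z = logit_score(model, fv)
    return ScreenResult(
        logit=z, probability=float(expit(z)), label=classify(z, cutoff), cutoff=cutoff
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe: log(1+exp) via logaddexp
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_lra(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> LogisticModel:
    """Fit the logistic screen by maximum likelihood (IRLS).

    Parameters
    ----------
    features : (n, p) array of raw feature values.
    labels : (n,) binary array; 1 = depressed, 0 = healthy.
    ridge : optional L2 penalty (excluding the intercept) for degenerate
        fixtures; 0 gives the plain maximum-likelihood fit.

    Convergence requires |delta log-likelihood| < ``tol``; the gradient at
    the optimum is checked to be < 1e-6 per component.  Complete or
    quasi-complete separation (coefficients diverging past 1e3, or fitted
    probabilities pinned at the labels) raises :class:`SeparationError`.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n, p) matching labels")
    n, p = X.shape
    if len(feature_names) != p:
        raise ValueError("feature_names must match feature count")
    if n < 20:
        raise ValueError(f"need at least 20 subjects, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.any(np.ptp(X, axis=0) == 0):
        import warnings

        warnings.warn("constant feature column detected", stacklevel=2)

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    eta = Xd @ beta
    ll = _bernoulli_ll(y, eta) - 0.5 * float(pen @ beta**2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = Xd.T @ (y - mu) - pen * beta
        hess = (Xd * w[:, None]).T @ Xd + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_ll(y, Xd @ cand) - 0.5 * float(pen @ cand**2)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        eta = Xd @ beta
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "coefficients diverging: data are (quasi-)completely separated"
            )
        delta = ll_new - ll
        ll = ll_new
        if abs(delta) < tol:
            converged = True
            break
    mu = expit(eta)
    if ridge == 0.0 and (np.all(np.abs(y - mu)[y == 1] < 1e-8) and np.all(mu[y == 0] < 1e-8)):
        raise SeparationError("fitted probabilities pinned at labels: separation")

    p1 = y.mean()
    ll0 = float(n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1)))
    return LogisticModel(
        intercept=float(beta[0]),
        coef={nm: float(b) for nm, b in zip(feature_names, beta[1:])},
        fit=FitInfo(
            n=n,
            log_likelihood=_bernoulli_ll(y, eta),
            null_log_likelihood=ll0,
            converged=converged,
            iterations=it,
        ),
    )


def pseudo_r2(model: LogisticModel, features=None, labels=None) -> PseudoR2:
    """Cox-Snell and Nagelkerke R-squared from the stored likelihoods.

    cox_snell  = 1 - exp((2/n) * (LL0 - LL1))
    nagelkerke = cox_snell / (1 - exp((2/n) * LL0))
    """
    if model.fit is None:
        raise ValueError("model has no stored fit likelihoods")
    info = model.fit
    n, ll1, ll0 = info.n, info.log_likelihood, info.null_log_likelihood
    cs = 1.0 - math.exp((2.0 / n) * (ll0 - ll1))
    max_cs = 1.0 - math.exp((2.0 / n) * ll0)
    return PseudoR2(cox_snell=cs, nagelkerke=cs / max_cs if max_cs > 0 else 0.0)


# ---------------------------------------------------------------------------
# Serialization: key-value text, named coefficients


_SCHEMA = "hrvscreen-model/1"


def save_model(model: LogisticModel, path, cutoff: float = DEFAULT_CUTOFF) -> None:
    lines = [
        f"schema: {_SCHEMA}",
        f"intercept: {float(model.intercept)!r}",
        f"cutoff: {float(cutoff)!r}",
    ]
    for name, v in model.coef.items():
        lines.append(f"coef.{name}: {float(v)!r}")
    if model.fit is not None:
        f = model.fit
        lines += [
            f"fit.n: {f.n}",
            f"fit.log_likelihood: {f.log_likelihood!r}",
            f"fit.null_log_likelihood: {f.null_log_likelihood!r}",
            f"fit.converged: {f.converged}",
            f"fit.iterations: {f.iterations}",
        ]
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> tuple[LogisticModel, float]:
    """Load a serialized model; returns (model, cutoff)."""
    kv: dict[str, str] = {}
    with open(os.fspath(path)) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            key, _, val = raw.partition(":")
            kv[key.strip()] = val.strip()
    if kv.get("schema") != _SCHEMA:
        raise ValueError(f"unsupported model schema {kv.get('schema')!r}")
    coef = {
        k[len("coef."):]: float(v) for k, v in kv.items() if k.startswith("coef.")
    }
    fit = None
    if "fit.n" in kv:
        fit = FitInfo(
            n=int(kv["fit.n"]),
            log_likelihood=float(kv["fit.log_likelihood"]),
            null_log_likelihood=float(kv["fit.null_log_likelihood"]),
            converged=kv["fit.converged"] == "True",
            iterations=int(kv["fit.iterations"]),
        )
    model = LogisticModel(intercept=float(kv["intercept"]), coef=coef, fit=fit)
    return model, float(kv.get("cutoff", DEFAULT_CUTOFF))
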