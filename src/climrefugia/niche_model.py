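"""Maximum-entropy suitability model with linear + quadratic features.

The presence-background model: given presence feature vectors and a background
sample, find coefficients λ maximizing the per-presence penalized
log-likelihood

    L(λ) = mean_presence[λ·f] − ln Z(λ) − Σ_j β_j |λ_j|,
    Z(λ) = Σ_background w · exp(λ·f),

i.e. the Gibbs distribution over the background whose feature expectations
match the presence means up to the per-feature regularization budget β_j
(KKT: |E_model[f_j] − mean_presence[f_j]| ≤ β_j, with equality where
λ_j ≠ 0). The problem is convex; we solve it with split-variable L-BFGS-B
(λ = u − v, u,v ≥ 0 turns the L1 penalty into a smooth bound-constrained
objective) and, when the penalty is zero, polish with Newton steps on the
exact gradient E_model[f] − mean_presence[f].

Features are MaxEnt's "linear" and "quadratic": each raw variable v yields
(v − min)/(max − min) and (v² − min v²)/(max v² − min v²), bounds taken from
the training background; projection values are clamped to the training
bounds first.

Regularization follows the published MaxEnt default schedule for
linear/quadratic features: β_j = βmult · b(m) · s_j/√m with s_j the presence
standard deviation of feature j and b(m) piecewise-linear through
(10, 1.0), (17, 0.6), (30, 0.5), (100, 0.25), clamped outside.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "CandidateSet",
    "ConvergenceError",
    "CandidateCapError",
    "build_features",
    "default_regularization",
    "fit_maxent",
    "predict_raw",
    "predict_logistic",
    "aicc",
    "compute_vif",
    "enumerate_candidate_sets",
    "select_variables",
    "tune_beta_multiplier",
    "BETA_GRID",
]

#: The β-multiplier selection grid: 0 to 15 in steps of 0.5 (31 values).
BETA_GRID: np.ndarray = np.arange(0.0, 15.0 + 1e-9, 0.5)


class ConvergenceError(RuntimeError):
    pass


class CandidateCapError(RuntimeError):
    pass


@dataclass
class FeatureSpec:
    """Linear + quadratic features of a variable subset with normalization
    bounds learned from the training background."""

    variables: list[str]
    v_min: np.ndarray   # per variable, over background
    v_max: np.ndarray
    v2_min: np.ndarray  # bounds of v² over background
    v2_max: np.ndarray

    @property
    def n_features(self) -> int:
        return 2 * len(self.variables)

    @property
    def feature_names(self) -> list[str]:
        return [f"{v}:linear" for v in self.variables] + [
            f"{v}:quadratic" for v in self.variables
        ]

    def featurize(self, values: np.ndarray, clamp: bool = True) -> np.ndarray:
        """(n, k) raw variable values -> (n, 2k) features in [0, 1].

        ``clamp`` (projection behavior) clips raw values to the training
        bounds before normalizing; training data lies inside the bounds so
        clamping is a no-op there.
        """
        v = np.asarray(values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if clamp:
            v = np.clip(v, self.v_min, self.v_max)
        lin = (v - self.v_min) / (self.v_max - self.v_min)
        v2 = v ** 2
        if clamp:
            v2 = np.clip(v2, self.v2_min, self.v2_max)
        quad = (v2 - self.v2_min) / (self.v2_max - self.v2_min)
        return np.hstack([lin, quad])


@dataclass
class MaxentModel:
    """A fitted maximum-entropy niche model for one species."""

    features: FeatureSpec
    lambdas: np.ndarray
    beta_multiplier: float
    beta_j: np.ndarray
    log_z: float          # ln of the training-background normalizer
    entropy: float        # entropy H of the raw distribution over background
    n_presence: int

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": self.features.variables,
                "v_min": self.features.v_min.tolist(),
                "v_max": self.features.v_max.tolist(),
                "v2_min": self.features.v2_min.tolist(),
                "v2_max": self.features.v2_max.tolist(),
                "lambdas": self.lambdas.tolist(),
                "beta_multiplier": self.beta_multiplier,
                "beta_j": self.beta_j.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "n_presence": self.n_presence,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        spec = FeatureSpec(
            variables=d["variables"],
            v_min=np.array(d["v_min"]),
            v_max=np.array(d["v_max"]),
            v2_min=np.array(d["v2_min"]),
            v2_max=np.array(d["v2_max"]),
        )
        return cls(
            features=spec,
            lambdas=np.array(d["lambdas"]),
            beta_multiplier=d["beta_multiplier"],
            beta_j=np.array(d["beta_j"]),
            log_z=d["log_z"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
        )


@dataclass
class CandidateSet:
    """A variable subset that survived the collinearity filters."""

    subset: tuple[str, ...]
    max_abs_pairwise_r: float
    max_vif: float
    aicc: float = field(default=np.nan)


def build_features(
    subset: list[str],
    background_values: np.ndarray,
    presence_values: np.ndarray | None = None,
):
    """Learn normalization bounds from the background and featurize.

    Returns ``(FeatureSpec, background_features, presence_features)``;
    presence features are None when no presence values are given.
    """
    bg = np.asarray(background_values, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != len(subset):
        raise ValueError("background_values must be (n, |subset|)")
    if not np.all(np.isfinite(bg)):
        raise ValueError("non-finite background values")
    v_min = bg.min(axis=0)
    v_max = bg.max(axis=0)
    for name, lo, hi in zip(subset, v_min, v_max):
        if lo == hi:
            raise ValueError(f"variable {name!r} is constant over the background")
    bg2 = bg ** 2
    spec = FeatureSpec(
        variables=list(subset),
        v_min=v_min,
        v_max=v_max,
        v2_min=bg2.min(axis=0),
        v2_max=bg2.max(axis=0),
    )
    bg_feat = spec.featurize(bg, clamp=False)
    pres_feat = None
    if presence_values is not None:
        pres_feat = spec.featurize(np.asarray(presence_values, float), clamp=True)
    return spec, bg_feat, pres_feat


def default_regularization(presence_features: np.ndarray, beta_multiplier: float) -> np.ndarray:
    """Per-feature β_j under the MaxEnt linear/quadratic default schedule."""
    m = presence_features.shape[0]
    b = np.interp(m, [10.0, 17.0, 30.0, 100.0], [1.0, 0.6, 0.5, 0.25])
    s = presence_features.std(axis=0, ddof=1) if m > 1 else np.zeros(
        presence_features.shape[1]
    )
    # a feature constant across presences still gets a small budget so its
    # coefficient is bounded (MaxEnt uses a variance floor); use min spread
    s = np.maximum(s, 1e-4)
    return beta_multiplier * b * s / np.sqrt(m)


def _neg_penalized_loglik(lam, pres_mean, bg_feat, log_w, beta):
    eta = bg_feat @ lam + log_w
    log_z = logsumexp(eta)
    q = np.exp(eta - log_z)
    e_model = q @ bg_feat
    nll = log_z - pres_mean @ lam
    return nll, e_model - pres_mean, log_z, q


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta_multiplier: float = 1.0,
    bias_weights: np.ndarray | None = None,
    feature_spec: FeatureSpec | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
    beta_j: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> MaxentModel:
    """Fit λ by maximizing the penalized per-presence log-likelihood.

    ``bias_weights`` (optional, per background point) enter the normalizer
    Z = Σ w·exp(λ·f). ``beta_j`` overrides the default regularization
    schedule; ``x0`` warm-starts the optimizer.
    """
    pres = np.asarray(presence_features, dtype=float)
    bg = np.asarray(background_features, dtype=float)
    if pres.ndim != 2 or bg.ndim != 2 or pres.shape[1] != bg.shape[1]:
        raise ValueError("presence/background feature matrices are inconsistent")
    if not (np.all(np.isfinite(pres)) and np.all(np.isfinite(bg))):
        raise ValueError("non-finite feature values")
    m, k = pres.shape
    if m < 1:
        raise ValueError("need at least one presence")
    if beta_j is None:
        beta_j = default_regularization(pres, beta_multiplier)
    beta_j = np.asarray(beta_j, dtype=float)
    if bias_weights is None:
        log_w = np.zeros(bg.shape[0])
    else:
        w = np.asarray(bias_weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("bias weights must be positive")
        log_w = np.log(w)
    pres_mean = pres.mean(axis=0)

    # split λ = u − v, u,v >= 0: the L1 penalty becomes linear.
    def obj(z):
        lam = z[:k] - z[k:]
        nll, grad, _, _ = _neg_penalized_loglik(lam, pres_mean, bg, log_w, beta_j)
        val = nll + beta_j @ (z[:k] + z[k:])
        g = np.concatenate([grad + beta_j, -grad + beta_j])
        return val, g

    z0 = np.zeros(2 * k)
    if x0 is not None:
        z0[:k] = np.maximum(x0, 0)
        z0[k:] = np.maximum(-x0, 0)
    res = minimize(
        obj,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * k),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    lam = res.x[:k] - res.x[k:]

    if np.all(beta_j == 0):
        # smooth convex problem: Newton-polish to drive the gradient
        # (= E_model[f] − mean_presence[f]) to ~1e-10
        for _ in range(100):
            nll, grad, log_z, q = _neg_penalized_loglik(
                lam, pres_mean, bg, log_w, beta_j
            )
            gnorm = np.max(np.abs(grad))
            if gnorm < 1e-10:
                break
            centered = bg - q @ bg
            hess = (centered * q[:, None]).T @ centered
            hess[np.diag_indices_from(hess)] += 1e-12
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # backtracking on the convex objective
            t = 1.0
            for _bt in range(60):
                cand = lam - t * step
                nll_new, _, _, _ = _neg_penalized_loglik(
                    cand, pres_mean, bg, log_w, beta_j
                )
                if nll_new <= nll - 1e-4 * t * (grad @ step) or nll_new < nll:
                    lam = cand
                    break
                t *= 0.5
            else:
                break
        nll, grad, log_z, q = _neg_penalized_loglik(lam, pres_mean, bg, log_w, beta_j)
        if np.max(np.abs(grad)) > 1e-5:
            raise ConvergenceError(
                f"optimizer stalled; final gradient norm {np.max(np.abs(grad)):.3e}"
            )
    else:
        _, grad, log_z, q = _neg_penalized_loglik(lam, pres_mean, bg, log_w, beta_j)
        kkt = np.abs(grad) - beta_j
        if np.max(kkt) > 1e-4:
            # cold restart with a bigger budget before giving up
            res = minimize(
                obj,
                np.zeros(2 * k),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0, None)] * (2 * k),
                options={"maxiter": 5 * max_iter, "ftol": 1e-15, "gtol": tol / 10},
            )
            lam = res.x[:k] - res.x[k:]
            _, grad, log_z, q = _neg_penalized_loglik(
                lam, pres_mean, bg, log_w, beta_j
            )
            kkt = np.abs(grad) - beta_j
            if np.max(kkt) > 1e-4:
                raise ConvergenceError(
                    f"KKT violation {np.max(kkt):.3e} exceeds tolerance"
                )

    with np.errstate(divide="ignore"):
        entropy = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
    return MaxentModel(
        features=feature_spec
        if feature_spec is not None
        else FeatureSpec(
            variables=[f"f{j}" for j in range(k // 2 or k)],
            v_min=np.zeros(max(k // 2, 1)),
            v_max=np.ones(max(k // 2, 1)),
            v2_min=np.zeros(max(k // 2, 1)),
            v2_max=np.ones(max(k // 2, 1)),
        ),
        lambdas=lam,
        beta_multiplier=float(beta_multiplier),
        beta_j=beta_j,
        log_z=float(log_z),
        entropy=entropy,
        n_presence=m,
    )


def predict_raw(
    model: MaxentModel, features: np.ndarray, renormalize: bool = False
) -> np.ndarray:
    """Gibbs (raw) output exp(λ·f)/Z.

    With the training background features this sums to 1. For projection to
    another scenario set ``renormalize=True`` to recompute Z over the given
    cells.
    """
    eta = np.asarray(features, dtype=float) @ model.lambdas
    if renormalize:
        return np.exp(eta - logsumexp(eta))
    return np.exp(eta - model.log_z)


def predict_logistic(model: MaxentModel, features: np.ndarray) -> np.ndarray:
    """MaxEnt logistic output: r·e^H/(1 + r·e^H) with r the raw output and H
    the training entropy — σ(λ·f + H − ln Z), a per-cell monotone transform
    of raw that is 0.5 everywhere under the uniform (λ = 0) model."""
    eta = np.asarray(features, dtype=float) @ model.lambdas
    x = eta + model.entropy - model.log_z
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def aicc(model: MaxentModel, presence_features: np.ndarray) -> float:
    """Small-sample-corrected AIC of the raw likelihood at the presences.

    K counts nonzero coefficients; returns +inf when n − K − 1 ≤ 0
    (inadmissible model).
    """
    pres = np.asarray(presence_features, dtype=float)
    n = pres.shape[0]
    k = model.n_nonzero
    if n - k - 1 <= 0:
        return float("inf")
    lnl = float(np.sum(pres @ model.lambdas - model.log_z))
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def compute_vif(values: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column regressed (with intercept)
    on the others; +inf on perfect collinearity."""
    x = np.asarray(values, dtype=float)
    n, k = x.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} sample points, got {n}")
    if k == 1:
        return np.array([1.0])
    out = np.empty(k)
    for j in range(k):
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def enumerate_candidate_sets(
    sample_values: np.ndarray,
    variable_names: list[str],
    r_threshold: float = 0.70,
    vif_threshold: float = 5.0,
    min_size: int = 2,
    max_candidates: int = 10_000,
) -> list[CandidateSet]:
    """All variable subsets free of collinearity.

    A subset qualifies iff it is an independent set in the graph joining
    pairs with |r| ≥ ``r_threshold`` and every within-subset VIF is below
    ``vif_threshold``. Output is ordered lexicographically by variable name.
    """
    x = np.asarray(sample_values, dtype=float)
    if x.shape[1] != len(variable_names):
        raise ValueError("sample columns and variable names disagree")
    order = sorted(range(len(variable_names)), key=lambda i: variable_names[i])
    corr = np.corrcoef(x, rowvar=False)
    out: list[CandidateSet] = []
    for size in range(min_size, len(variable_names) + 1):
        for combo in itertools.combinations(order, size):
            sub_r = np.abs(corr[np.ix_(combo, combo)])
            iu = np.triu_indices(size, k=1)
            max_r = float(sub_r[iu].max()) if iu[0].size else 0.0
            if max_r >= r_threshold:
                continue
            vifs = compute_vif(x[:, combo])
            max_vif = float(np.max(vifs))
            if max_vif >= vif_threshold:
                continue
            out.append(
                CandidateSet(
                    subset=tuple(variable_names[i] for i in combo),
                    max_abs_pairwise_r=max_r,
                    max_vif=max_vif,
                )
            )
            if len(out) > max_candidates:
                raise CandidateCapError(
                    f"more than {max_candidates} candidate subsets; raise the "
                    "cap or tighten r/VIF thresholds"
                )
    out.sort(key=lambda c: (len(c.subset), c.subset))
    return out


def _fit_candidate(
    subset,
    presence_values,
    background_values,
    variable_names,
    beta_multiplier,
    bias_weights=None,
    x0=None,
):
    idx = [variable_names.index(v) for v in subset]
    spec, bg_feat, pres_feat = build_features(
        list(subset), background_values[:, idx], presence_values[:, idx]
    )
    model = fit_maxent(
        pres_feat,
        bg_feat,
        beta_multiplier=beta_multiplier,
        bias_weights=bias_weights,
        feature_spec=spec,
        x0=x0,
    )
    return model, pres_feat


def select_variables(
    candidates: list[CandidateSet],
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    bias_weights: np.ndarray | None = None,
) -> CandidateSet:
    """AICc-best candidate subset at β-multiplier 0 (no penalty).

    Ties break toward the smaller subset, then lexicographically.
    """
    if not candidates:
        raise ValueError("no candidate subsets to select from")
    best: CandidateSet | None = None
    for cand in candidates:
        model, pres_feat = _fit_candidate(
            cand.subset,
            presence_values,
            background_values,
            variable_names,
            beta_multiplier=0.0,
            bias_weights=bias_weights,
        )
        cand.aicc = aicc(model, pres_feat)
        if best is None or (
            (cand.aicc, len(cand.subset), cand.subset)
            < (best.aicc, len(best.subset), best.subset)
        ):
            best = cand
    if not np.isfinite(best.aicc):
        raise ValueError(
            "every candidate is inadmissible (AICc infinite) at this sample size"
        )
    return best


def tune_beta_multiplier(
    subset,
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    bias_weights: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> tuple[float, MaxentModel]:
    """Refit the chosen subset at each β-multiplier on the grid (default
    0–15 by 0.5, 31 values); return the AICc-argmin, ties to the smaller β."""
    if grid is None:
        grid = BETA_GRID
    best_beta, best_model, best_aicc = None, None, np.inf
    x0 = None
    for beta in grid:
        model, pres_feat = _fit_candidate(
            subset,
            presence_values,
            background_values,
            variable_names,
            beta_multiplier=float(beta),
            bias_weights=bias_weights,
            x0=x0,
        )
        x0 = model.lambdas
        a = aicc(model, pres_feat)
        if a < best_aicc:
            best_beta, best_model, best_aicc = float(beta), model, a
    if best_model is None:
        best_beta = float(grid[0])
        best_model, _ = _fit_candidate(
            subset,
            presence_values,
            background_values,
            variable_names,
            beta_multiplier=best_beta,
            bias_weights=bias_weights,
        )
    return best_beta, best_model
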