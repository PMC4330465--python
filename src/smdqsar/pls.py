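"""Single-response partial least squares (PLS1) with full validation machinery.

The engine is a from-scratch NIPALS implementation.  X and y are centered
and scaled to unit variance before fitting; components are extracted by
iterating weight/score/loading updates with X-deflation, giving mutually
orthogonal score vectors.  Model quality is summarised by

* R²Y and adjusted R²Y — fraction of response variance described by the fit,
* RMSEE = sqrt( Σ (y_meas − y_est)² / (N − 1 − A) ) — estimation error,
* Q² = 1 − PRESS/SS from leave-one-out cross-validation (scaling re-estimated
  inside every fold),
* jack-knife coefficient confidence intervals from the LOO submodels,
* a y-scrambling permutation test against chance correlation, and
* DModX, the normalised distance of an observation to the model's X-subspace,
  used with a critical value DCrit(α) as an applicability-domain boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemio import ScalingParams, apply_scaling, autoscale

__all__ = [
    "PLSModel",
    "CVResult",
    "CoefficientCI",
    "DModXResult",
    "PermutationReport",
    "fit",
    "rmsee",
    "loo_cv",
    "select_components",
    "jackknife_ci",
    "permutation_test",
    "predict",
    "rmsep",
]

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    if hasattr(X, "values") and hasattr(X, "column_names"):  # DescriptorMatrix
        return X.to_numpy(), list(X.column_names)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


@dataclass
class PLSModel:
    A: int
    weights: np.ndarray      # K×A, unit-norm per component
    x_loadings: np.ndarray   # K×A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # N×A
    coefficients: np.ndarray  # K, scaled space
    x_scaling: ScalingParams
    y_scaling: ScalingParams
    r2y: float
    adj_r2y: float
    rmsee: float
    fitted: np.ndarray       # N, response units
    s0: float                # pooled X-residual s.d. (DModX denominator)
    N: int
    K: int
    column_names: list[str] | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable model state (no binary pickles)."""
        return {
            "A": self.A,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_means": self.x_scaling.column_means.tolist(),
            "x_scales": self.x_scaling.column_scales.tolist(),
            "y_mean": float(self.y_scaling.column_means[0]),
            "y_scale": float(self.y_scaling.column_scales[0]),
            "r2y": self.r2y,
            "adj_r2y": self.adj_r2y,
            "rmsee": self.rmsee,
            "s0": self.s0,
            "N": self.N,
            "K": self.K,
            "column_names": self.column_names,
        }


@dataclass
class CVResult:
    q2: float
    press: float
    ss: float
    loo_predictions: np.ndarray
    submodels: list[PLSModel]
    full_model: PLSModel
    #: cumulative Q² at 1..A components (total-PRESS read-out)
    q2_per_component: list[float] = field(default_factory=list)


@dataclass
class CoefficientCI:
    names: list[str]
    b: np.ndarray
    half_width: np.ndarray
    level: float

    @property
    def significant(self) -> np.ndarray:
        """True where the CI excludes zero."""
        return np.abs(self.b) > self.half_width

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"b": self.b, "half_width": self.half_width, "significant": self.significant},
            index=self.names,
        )


@dataclass
class DModXResult:
    dmodx: np.ndarray       # with correction factor v (training rows)
    dmodx_ps: np.ndarray    # v = 1 (prediction rows)
    dcrit: float
    alpha: float
    residuals: np.ndarray   # N×K scaled-space X-residuals
    outside_ad: np.ndarray  # boolean, dmodx_ps > dcrit


@dataclass
class PermutationReport:
    n_perm: int
    correlations: np.ndarray  # |corr(y_perm, y)|
    r2y: np.ndarray
    q2: np.ndarray
    original_r2y: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float
    verdict: str  # "pass" | "fail"


def _nipals(Xs: np.ndarray, ys: np.ndarray, A: int):
    """NIPALS component extraction on pre-scaled data."""
    N, K = Xs.shape
    E, f = Xs.copy(), ys.copy()
    W = np.zeros((K, A))
    P = np.zeros((K, A))
    C = np.zeros(A)
    T = np.zeros((N, A))
    for a in range(A):
        u = f.copy()
        w = E.T @ u
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise np.linalg.LinAlgError(
                f"component {a + 1}: residual X carries no covariance with y"
            )
        w /= nw
        for _ in range(NIPALS_MAX_ITER):
            t = E @ w
            c = float(f @ t / (t @ t))
            u = f * c  # single-response: u update is a scalar multiple of y
            w_new = E.T @ u
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        else:
            raise np.linalg.LinAlgError(f"component {a + 1}: NIPALS did not converge")
        t = E @ w
        tt = float(t @ t)
        p = E.T @ t / tt
        c = float(f @ t / tt)
        E = E - np.outer(t, p)
        f = f - c * t
        W[:, a], P[:, a], C[a], T[:, a] = w, p, c, t
    return W, P, C, T, E


def fit(X, y, A: int, divisor_mode: str = "population") -> PLSModel:
    """Fit a PLS1 model with ``A`` components on autoscaled X and y."""
    Xa, names = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    N, K = Xa.shape
    if ya.size != N:
        raise ValueError(f"X has {N} rows but y has {ya.size} values")
    if A < 1:
        raise ValueError("need at least one component")
    if N < A + 2:
        raise ValueError(f"N={N} too small for A={A} components")
    Xs, x_scaling = autoscale(Xa, divisor_mode=divisor_mode)
    ys, y_scaling = autoscale(ya[:, None], divisor_mode=divisor_mode)
    ys = ys.ravel()

    W, P, C, T, E = _nipals(Xs, ys, A)
    # b maps scaled X to scaled y: b = W (P'W)^{-1} c
    b = W @ np.linalg.solve(P.T @ W, C)
    fitted_scaled = Xs @ b
    fitted = fitted_scaled * y_scaling.column_scales[0] + y_scaling.column_means[0]

    ss_res = float(np.sum((ya - fitted) ** 2))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2y = 1.0 - ss_res / ss_tot
    adj_r2y = 1.0 - (1.0 - r2y) * (N - 1) / (N - 1 - A)
    rmsee_val = math.sqrt(ss_res / (N - 1 - A))
    dof = (N - A - 1) * (K - A)
    s0 = math.sqrt(float(np.sum(E**2)) / dof) if dof > 0 else float("nan")

    return PLSModel(
        A=A, weights=W, x_loadings=P, y_loadings=C, scores=T, coefficients=b,
        x_scaling=x_scaling, y_scaling=y_scaling, r2y=r2y, adj_r2y=adj_r2y,
        rmsee=rmsee_val, fitted=fitted, s0=s0, N=N, K=K, column_names=names,
    )


def rmsee(model: PLSModel) -> float:
    """Root-mean-square error of estimation, divisor N − 1 − A."""
    return model.rmsee


def rmsep(y_measured, y_predicted) -> float:
    """Root-mean-square error of prediction, divisor N (no dof correction)."""
    ym = np.asarray(y_measured, dtype=float).ravel()
    yp = np.asarray(y_predicted, dtype=float).ravel()
    if ym.size == 0:
        raise ValueError("empty input")
    if ym.size != yp.size:
        raise ValueError(f"length mismatch: {ym.size} vs {yp.size}")
    return math.sqrt(float(np.mean((ym - yp) ** 2)))


def _predict_scaled(model: PLSModel, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (ŷ response units, scaled X residuals) for pre-scaled rows."""
    yhat_scaled = Xs @ model.coefficients
    yhat = yhat_scaled * model.y_scaling.column_scales[0] + model.y_scaling.column_means[0]
    T = Xs @ model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    E = Xs - T @ model.x_loadings.T
    return yhat, E


def dcrit(model: PLSModel, alpha: float = 0.05) -> float:
    """Critical normalized DModX at level alpha via the squared-DModX F ratio."""
    d1 = model.K - model.A
    d2 = (model.N - model.A - 1) * (model.K - model.A)
    return math.sqrt(stats.f.ppf(1.0 - alpha, d1, d2))


def predict(model: PLSModel, X_new, training: bool = False,
            alpha: float = 0.05) -> tuple[np.ndarray, DModXResult]:
    """Predict responses and assess applicability-domain membership.

    Training-set scaling is applied to the new rows (never refit).  DModX of
    row i is sqrt(Σ_k e_ik²/(K−A)) / s0 times a correction factor
    v = sqrt(N/(N−A−1)) — compensating for training rows fitting themselves —
    while DModXPS uses v = 1 and is the read-out for genuinely new rows.
    Rows with DModXPS above DCrit(alpha) are flagged outside the
    applicability domain.
    """
    Xa, names = _as_matrix(X_new)
    if Xa.shape[1] != model.K:
        raise ValueError(f"column mismatch: model has {model.K}, input has {Xa.shape[1]}")
    if names is not None and model.column_names is not None and names != model.column_names:
        raise ValueError("descriptor names do not match the model's columns")
    Xs = apply_scaling(Xa, model.x_scaling)
    yhat, E = _predict_scaled(model, Xs)
    row_ms = np.sum(E**2, axis=1) / (model.K - model.A)
    base = np.sqrt(row_ms) / model.s0
    v = math.sqrt(model.N / (model.N - model.A - 1))
    dm = DModXResult(
        dmodx=base * v,
        dmodx_ps=base,
        dcrit=dcrit(model, alpha),
        alpha=alpha,
        residuals=E,
        outside_ad=(base * v if training else base) > dcrit(model, alpha),
    )
    return yhat, dm


def loo_cv(X, y, A: int, divisor_mode: str = "population") -> CVResult:
    """Leave-one-out cross-validation: Q² = 1 − PRESS/SS.

    Every fold refits centering and scaling on its N−1 rows; PRESS sums the
    squared out-of-fold prediction errors and SS the squared deviations of y
    from the all-row mean.  The N submodels are retained for jack-knifing.
    A constant column arising inside a fold is a hard error — silently
    skipping folds would bias PRESS.
    """
    Xa, _ = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    N = Xa.shape[0]
    if N < A + 3:
        raise ValueError(f"N={N} too small for LOO at A={A}")
    full_model = fit(Xa, ya, A, divisor_mode=divisor_mode)

    press_terms = np.zeros(N)
    preds = np.zeros(N)
    submodels: list[PLSModel] = []
    for i in range(N):
        keep = np.ones(N, dtype=bool)
        keep[i] = False
        sub = fit(Xa[keep], ya[keep], A, divisor_mode=divisor_mode)
        Xs_i = apply_scaling(Xa[i][None, :], sub.x_scaling)
        yhat_i, _ = _predict_scaled(sub, Xs_i)
        preds[i] = yhat_i[0]
        press_terms[i] = (ya[i] - yhat_i[0]) ** 2
        submodels.append(sub)
    press = float(press_terms.sum())
    ss = float(np.sum((ya - ya.mean()) ** 2))
    return CVResult(
        q2=1.0 - press / ss, press=press, ss=ss,
        loo_predictions=preds, submodels=submodels, full_model=full_model,
    )


def select_components(X, y, A_max: int = 3, q2_gain_limit: float = 0.05,
                      divisor_mode: str = "population") -> int:
    """Smallest component count justified by cross-validation.

    Component a+1 is accepted only when it raises Q² by more than
    ``q2_gain_limit``; a hard cap of ``A_max`` (default 3) reflects the rule
    of thumb that a single-response PLS model should need one, at most two
    to three, components.
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    q2s = []
    for A in range(1, A_max + 1):
        try:
            q2s.append(loo_cv(X, y, A, divisor_mode=divisor_mode).q2)
        except (ValueError, np.linalg.LinAlgError):
            break
    if not q2s:
        raise ValueError("could not cross-validate even one component")
    A = 1
    for a in range(1, len(q2s)):
        if q2s[a] - q2s[a - 1] > q2_gain_limit:
            A = a + 1
        else:
            break
    return A


def jackknife_ci(cv: CVResult, level: float = 0.90) -> CoefficientCI:
    """Jack-knife confidence intervals for the scaled regression coefficients.

    SE_k = sqrt( (N−1)/N · Σ_i (b_k^(−i) − b̄_k)² ) over the N leave-one-out
    submodels, with CI half-width t_{1−(1−level)/2, N−1} · SE_k around the
    full-model coefficient.  A coefficient is significant when its CI
    excludes zero.
    """
    if not cv.submodels:
        raise ValueError("CV result carries no submodels")
    As = {m.A for m in cv.submodels}
    if len(As) != 1 or cv.full_model.A not in As:
        raise ValueError(f"submodels disagree on component count: {sorted(As)}")
    B = np.stack([m.coefficients for m in cv.submodels])  # N×K
    n = B.shape[0]
    se = np.sqrt((n - 1) / n * np.sum((B - B.mean(axis=0)) ** 2, axis=0))
    tcrit = stats.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1)
    names = cv.full_model.column_names or [f"x{j}" for j in range(B.shape[1])]
    return CoefficientCI(
        names=names, b=cv.full_model.coefficients.copy(),
        half_width=tcrit * se, level=level,
    )


def permutation_test(X, y, A: int, n_perm: int = 200, seed: int = 0,
                     divisor_mode: str = "population") -> PermutationReport:
    """y-scrambling validation against chance correlation.

    The response order is permuted ``n_perm`` times; each scramble is refit
    at the same component count and its R²Y and Q² recorded against the
    absolute correlation between scrambled and original y.  The model passes
    when the intercepts (at |corr| = 0) of the regression lines of R²Y and
    Q² versus |corr| — fit through the permuted points plus the original
    model at |corr| = 1 — fall below the original values, and no permuted
    Q² reaches the original Q².
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    ya = np.asarray(y, dtype=float).ravel()
    if np.ptp(ya) == 0:
        raise ValueError("constant response: SS = 0, nothing to validate")
    rng = np.random.default_rng(seed)
    cv0 = loo_cv(X, ya, A, divisor_mode=divisor_mode)
    r2_0, q2_0 = cv0.full_model.r2y, cv0.q2

    cors = np.zeros(n_perm)
    r2s = np.zeros(n_perm)
    q2s = np.zeros(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(ya)
        cors[p] = abs(float(np.corrcoef(yp, ya)[0, 1]))
        cvp = loo_cv(X, yp, A, divisor_mode=divisor_mode)
        r2s[p] = cvp.full_model.r2y
        q2s[p] = cvp.q2

    xx = np.append(cors, 1.0)
    r2_line = np.polyfit(xx, np.append(r2s, r2_0), 1)
    q2_line = np.polyfit(xx, np.append(q2s, q2_0), 1)
    r2_icpt, q2_icpt = float(r2_line[1]), float(q2_line[1])
    verdict = "pass" if (
        r2_icpt < r2_0 and q2_icpt < q2_0 and q2s.max() < q2_0
    ) else "fail"
    return PermutationReport(
        n_perm=n_perm, correlations=cors, r2y=r2s, q2=q2s,
        original_r2y=r2_0, original_q2=q2_0,
        r2_intercept=r2_icpt, q2_intercept=q2_icpt, verdict=verdict,
    )
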