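"""Quasibinomial GAMs with cyclic-month smooths, and hierarchical (Shapley)
partitioning of explained deviance.

The model for a behaviour's daily proportion y_it (individual i, day t,
prior weight = the day's burst count) is

    logit E[y] = beta_0 + f_month(month) + f_ndvi(NDVI) + f_temp(T) + b_i,
    Var[y] = phi mu (1 - mu) / w,

with f_month a cyclic cubic regression spline (value and first two
derivatives matching across the December-January boundary), f_ndvi and
f_temp natural cubic regression splines (k = 10 basis functions each), and
b_i ridge-penalized individual intercepts (the random-effect smooth).  The
fit is penalized IRLS; each smoothing parameter is chosen by GCV
(coordinate-wise grid search plus golden-section refinement).  Hierarchical
partitioning refits every non-empty subset of the predictor groups (each
with its own GCV smoothing) and averages the gains in explained deviance
over orderings (the Shapley decomposition), giving per-group independent,
unique, and shared contributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

__all__ = [
    "SmoothSpec",
    "FittedGam",
    "HpResult",
    "cyclic_cubic_basis",
    "natural_cubic_basis",
    "fit_gam",
    "explained_deviance",
    "hierarchical_partition",
    "shapley_from_subsets",
    "concurvity",
    "default_terms",
    "DEFAULT_GROUPS",
]

_EPS_MU = 1e-10
_ETA_CLIP = 30.0


@dataclass(frozen=True)
class SmoothSpec:
    """One model term: kind 'cc' (cyclic cubic), 'cr' (natural cubic) or
    're' (ridge-penalized factor intercepts)."""

    name: str
    kind: str
    column: str
    k: int = 10
    # for 'cc': the period [lo, hi) with hi identified with lo
    period: tuple[float, float] | None = None


def default_terms() -> list[SmoothSpec]:
    """The study's model: cyclic month smooth, NDVI and temperature
    smooths (k = 10 each), individual random intercepts."""
    return [
        SmoothSpec("month", "cc", "month", k=10, period=(1.0, 13.0)),
        SmoothSpec("ndvi", "cr", "ndvi", k=10),
        SmoothSpec("temperature", "cr", "temp_mean_c", k=10),
        SmoothSpec("individual", "re", "individual_id"),
    ]


DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "month": ("month",),
    "ndvi": ("ndvi",),
    "temperature": ("temperature",),
    "individual": ("individual",),
}


# ---------------------------------------------------------------------------
# Spline bases
# ---------------------------------------------------------------------------

def _interval_index(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    j = np.searchsorted(knots, x, side="right") - 1
    return np.clip(j, 0, len(knots) - 2)


def cyclic_cubic_basis(
    x: np.ndarray, k: int = 10, period: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cyclic cubic regression spline basis and its curvature penalty.

    Knots are ``k`` evenly spaced points on the period with the last
    identified with the first, leaving ``k - 1`` free coefficients (the
    spline's values at the free knots).  Any fitted function satisfies
    f, f', f'' continuity across the period boundary; the penalty is the
    integrated squared second derivative in quadratic form.  Returns
    (design, penalty, knots).
    """
    if k < 4:
        raise ValueError("cyclic cubic basis needs k >= 4")
    x = np.asarray(x, dtype=float)
    if period is None:
        lo, hi = float(np.min(x)), float(np.max(x))
        hi = hi + (hi - lo) / max(len(np.unique(x)) - 1, 1)
    else:
        lo, hi = period
    knots = np.linspace(lo, hi, k)
    n_free = k - 1
    h = np.diff(knots)  # k-1 interval widths; last wraps to the first knot
    B = np.zeros((n_free, n_free))
    D = np.zeros((n_free, n_free))
    for i in range(n_free):
        h_prev = h[(i - 1) % n_free]
        h_next = h[i]
        B[i, i] = (h_prev + h_next) / 3.0
        B[i, (i + 1) % n_free] += h_next / 6.0
        B[i, (i - 1) % n_free] += h_prev / 6.0
        D[i, i] = -1.0 / h_prev - 1.0 / h_next
        D[i, (i + 1) % n_free] += 1.0 / h_next
        D[i, (i - 1) % n_free] += 1.0 / h_prev
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0

    xr = lo + np.mod(x - lo, hi - lo)
    j = _interval_index(xr, knots)
    t = xr - knots[j]
    hj = h[j]
    right = knots[j + 1] - xr
    A_g = np.zeros((len(x), n_free))
    A_m = np.zeros((len(x), n_free))
    jp1 = (j + 1) % n_free
    rows = np.arange(len(x))
    A_g[rows, j] += right / hj
    A_g[rows, jp1] += t / hj
    A_m[rows, j] += right**3 / (6.0 * hj) - hj * right / 6.0
    A_m[rows, jp1] += t**3 / (6.0 * hj) - hj * t / 6.0
    X = A_g + A_m @ Binv_D
    return X, S, knots


def natural_cubic_basis(
    x: np.ndarray, knots: np.ndarray | int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural ('cr') cubic regression spline basis and penalty.

    Coefficients are the spline's values at the ``k`` knots (placed at
    quantiles when an integer is given); second derivatives vanish at the
    end knots.  Values outside the knot range are evaluated by linear
    extension, as a natural spline does.  Returns (design, penalty, knots).
    """
    x = np.asarray(x, dtype=float)
    if np.isscalar(knots) or isinstance(knots, int):
        k = int(knots)
        if k < 3:
            raise ValueError("natural cubic basis needs k >= 3")
        qs = np.linspace(0, 1, k)
        kn = np.unique(np.quantile(x, qs))
        # near-coincident knots make the curvature penalty blow up as 1/h^3;
        # enforce a minimum spacing relative to the data range
        if len(kn) >= 2 and kn[-1] > kn[0]:
            min_gap = (kn[-1] - kn[0]) * 1e-3
            kept = [kn[0]]
            for v in kn[1:]:
                if v - kept[-1] >= min_gap:
                    kept.append(v)
            kn = np.asarray(kept)
        if len(kn) < 3:
            raise ValueError("too few distinct values for a cubic spline")
        knots = kn
    else:
        knots = np.asarray(knots, dtype=float)
    k = len(knots)
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    Binv_D = np.linalg.solve(B, D)
    S = D.T @ Binv_D
    S = (S + S.T) / 2.0

    xc = np.clip(x, knots[0], knots[-1])
    j = _interval_index(xc, knots)
    t = xc - knots[j]
    hj = h[j]
    right = knots[j + 1] - xc
    rows = np.arange(len(x))
    A_g = np.zeros((len(x), k))
    A_m = np.zeros((len(x), k))
    A_g[rows, j] += right / hj
    A_g[rows, j + 1] += t / hj
    A_m[rows, j] += right**3 / (6.0 * hj) - hj * right / 6.0
    A_m[rows, j + 1] += t**3 / (6.0 * hj) - hj * t / 6.0
    m_map = np.zeros((k, k))
    m_map[1:-1, :] = Binv_D  # natural: m_1 = m_k = 0
    X = A_g + A_m @ m_map

    # linear extension beyond the knot range
    below = x < knots[0]
    above = x > knots[-1]
    if below.any() or above.any():
        eps = (knots[-1] - knots[0]) * 1e-6
        for mask, x0, sgn in ((below, knots[0], 1.0), (above, knots[-1], -1.0)):
            if not mask.any():
                continue
            b, _, _ = natural_cubic_basis(np.array([x0, x0 + sgn * eps]), knots)
            deriv = (b[1] - b[0]) / (sgn * eps)
            X[mask] = b[0][None, :] + (x[mask] - x0)[:, None] * deriv[None, :]
    return X, S, knots


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    spec: SmoothSpec
    sl: slice
    S: np.ndarray  # penalty in the constrained parametrization
    Z: np.ndarray | None  # constraint transform (None for 're')
    knots: np.ndarray | None
    levels: tuple | None

    def design(self, data: pd.DataFrame) -> np.ndarray:
        spec = self.spec
        if spec.kind == "re":
            codes = pd.Categorical(data[spec.column], categories=self.levels).codes
            X = np.zeros((len(data), len(self.levels)))
            ok = codes >= 0
            X[np.arange(len(data))[ok], codes[ok]] = 1.0
            return X
        if spec.kind == "cc":
            X, _, _ = cyclic_cubic_basis(
                data[spec.column].to_numpy(dtype=float), spec.k, period=spec.period
            )
        elif spec.kind == "cr":
            X, _, _ = natural_cubic_basis(data[spec.column].to_numpy(dtype=float), self.knots)
        else:
            raise ValueError(f"unknown term kind {spec.kind!r}")
        return X @ self.Z if self.Z is not None else X


def _build_blocks(data: pd.DataFrame, specs: list[SmoothSpec]) -> tuple[np.ndarray, list[_Block]]:
    """Full design matrix (intercept first) and the per-term blocks, each
    sum-to-zero constrained (smooths) so the intercept is identifiable."""
    n = len(data)
    cols = [np.ones((n, 1))]
    blocks: list[_Block] = []
    start = 1
    for spec in specs:
        if spec.kind == "re":
            levels = tuple(pd.unique(data[spec.column]))
            X = pd.get_dummies(
                pd.Categorical(data[spec.column], categories=levels)
            ).to_numpy(dtype=float)
            S = np.eye(len(levels))
            blk = _Block(spec, slice(start, start + X.shape[1]), S, None, None, levels)
        else:
            if spec.kind == "cc":
                X0, S0, knots = cyclic_cubic_basis(
                    data[spec.column].to_numpy(dtype=float), spec.k, period=spec.period
                )
            elif spec.kind == "cr":
                X0, S0, knots = natural_cubic_basis(data[spec.column].to_numpy(dtype=float), spec.k)
            else:
                raise ValueError(f"unknown term kind {spec.kind!r}")
            C = X0.sum(axis=0, keepdims=True)  # 1'X, the sum-to-zero constraint
            Z = null_space(C)
            X = X0 @ Z
            S = Z.T @ S0 @ Z
            # clip to exact PSD and normalise to unit Frobenius norm so the
            # penalized objective is monotone-safe and lambdas of different
            # terms live on comparable scales
            vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
            S = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            nrm = np.linalg.norm(S)
            if nrm > 0:
                S = S / nrm
            blk = _Block(spec, slice(start, start + X.shape[1]), (S + S.T) / 2, Z, knots, None)
        cols.append(X)
        blocks.append(blk)
        start += X.shape[1]
    return np.concatenate(cols, axis=1), blocks


@dataclass
class FittedGam:
    """A fitted (quasi)binomial or Gaussian penalized additive model."""

    specs: list[SmoothSpec]
    blocks: list[_Block]
    beta: np.ndarray
    lam: dict[str, float]
    phi: float
    deviance: float
    null_deviance: float
    edf: dict[str, float]
    edf_total: float
    family: str
    n: int
    X: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    gcv: float = math.nan
    iterations: int = 0

    def term_contribution(self, name: str, data: pd.DataFrame) -> np.ndarray:
        """The fitted term's contribution f_term evaluated on new data."""
        for blk in self.blocks:
            if blk.spec.name == name:
                return blk.design(data) @ self.beta[blk.sl]
        raise KeyError(name)

    def predict(self, data: pd.DataFrame, kind: str = "response") -> np.ndarray:
        eta = np.full(len(data), self.beta[0])
        for blk in self.blocks:
            eta = eta + blk.design(data) @ self.beta[blk.sl]
        if kind == "link" or self.family == "gaussian":
            return eta
        return _expit(eta)


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def _binom_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    mu = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _penalty_matrix(blocks: list[_Block], lam: dict[str, float], p: int) -> np.ndarray:
    S = np.zeros((p, p))
    for blk in blocks:
        S[blk.sl, blk.sl] += lam[blk.spec.name] * blk.S
    return S


def _pirls(
    X: np.ndarray,
    blocks: list[_Block],
    y: np.ndarray,
    w: np.ndarray,
    lam: dict[str, float],
    family: str,
    max_iter: int = 200,
    tol: float = 1e-8,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float, dict[str, float], int]:
    """Penalized IRLS.  Returns (beta, mu, deviance, edf_total, edf, iters)."""
    n, p = X.shape
    S = _penalty_matrix(blocks, lam, p)

    if family == "gaussian":
        A = X.T @ (X * w[:, None])
        beta = np.linalg.solve(A + S + 1e-12 * np.eye(p), X.T @ (w * y))
        mu = X @ beta
        dev = float(np.sum(w * (y - mu) ** 2))
        F = np.linalg.solve(A + S + 1e-12 * np.eye(p), A)
        edf = {blk.spec.name: float(np.trace(F[blk.sl, blk.sl])) for blk in blocks}
        return beta, mu, dev, float(np.trace(F)), edf, 1

    mu = (w * y + 0.5) / (w + 1.0)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros(p) if beta0 is None else beta0
    dev = _binom_deviance(y, mu, w)
    pen_dev = dev + float(beta @ S @ beta)
    trace = [dev]
    pen_trace = [pen_dev]
    for it in range(1, max_iter + 1):
        mu_c = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
        var = mu_c * (1 - mu_c)
        z = eta + (y - mu_c) / var
        W = w * var
        A = X.T @ (X * W[:, None])
        beta_new = np.linalg.solve(A + S + 1e-12 * np.eye(p), X.T @ (W * z))
        # step-halve toward the previous coefficients if the penalized
        # deviance does not decrease (guards against eta-clipping cycles)
        step = beta_new - beta
        for _ in range(30):
            beta_try = beta + step
            eta_try = np.clip(X @ beta_try, -_ETA_CLIP, _ETA_CLIP)
            mu_try = _expit(eta_try)
            new_dev = _binom_deviance(y, mu_try, w)
            new_pen = new_dev + float(beta_try @ S @ beta_try)
            if new_pen <= pen_dev * (1 + 1e-12) + 1e-12 or it == 1:
                break
            step = step / 2.0
        beta, eta, mu = beta_try, eta_try, mu_try
        trace.append(new_dev)
        pen_trace.append(new_pen)
        if abs(new_pen - pen_dev) < tol * (abs(new_pen) + 0.1):
            pen_dev, dev = new_pen, new_dev
            break
        pen_dev, dev = new_pen, new_dev
    else:
        # at the iteration cap: quasi-separable rows can make the penalized
        # objective creep or sustain tiny clipping cycles; accept the fit if
        # it is still making only negligible progress, error on divergence
        rel = abs(pen_trace[-1] - pen_trace[-2]) / (abs(pen_trace[-1]) + 0.1)
        if rel > 1e-3 or not np.all(np.isfinite(beta)):
            raise RuntimeError(
                f"PIRLS did not converge in {max_iter} iterations; penalized "
                f"deviance trace {pen_trace[-5:]}"
            )
        warnings.warn(
            f"PIRLS stopped at the {max_iter}-iteration cap with relative "
            f"penalized-deviance change {rel:.2e}; accepting the quasi-converged fit"
        )
    mu_c = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
    W = w * mu_c * (1 - mu_c)
    A = X.T @ (X * W[:, None])
    F = np.linalg.solve(A + S + 1e-12 * np.eye(p), A)
    edf = {blk.spec.name: float(np.trace(F[blk.sl, blk.sl])) for blk in blocks}
    return beta, mu, dev, float(np.trace(F)), edf, it


#: GCV effective-degrees-of-freedom inflation; values around 1.4 are the
#: standard guard against GCV's tendency to undersmooth on flat profiles.
GCV_GAMMA = 1.4


def _gcv_score(n: int, dev: float, edf_total: float, gamma: float = GCV_GAMMA) -> float:
    denom = max(n - gamma * edf_total, 1e-3)
    return n * dev / denom**2


def fit_gam(
    data: pd.DataFrame,
    specs: list[SmoothSpec] | None = None,
    response: str = "proportion",
    weights: str | None = "n_bursts",
    family: str = "quasibinomial",
    lam: dict[str, float] | float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FittedGam:
    """Fit the penalized additive model.

    With ``lam=None`` each term's smoothing parameter is chosen by GCV
    (``n D / (n - edf)^2``): two coordinate-descent sweeps over the terms,
    each a coarse log-spaced grid followed by golden-section refinement.
    A scalar or dict ``lam`` fixes the smoothing parameters instead.
    """
    if specs is None:
        specs = default_terms()
    y = data[response].to_numpy(dtype=float)
    if family != "gaussian" and (np.any(y < 0) or np.any(y > 1)):
        raise ValueError("response must lie in [0, 1] for a (quasi)binomial fit")
    w_raw = (
        data[weights].to_numpy(dtype=float)
        if weights is not None and weights in data.columns
        else np.ones(len(y))
    )
    if np.any(w_raw <= 0):
        raise ValueError("prior weights must be positive")
    # prior weights are known only up to proportionality in a
    # quasi-likelihood: normalise to mean 1 so a common rescaling leaves
    # the coefficients (and the smoothing-parameter geometry) unchanged
    # and only the dispersion phi absorbs the scale
    w_scale = float(w_raw.mean())
    w = w_raw / w_scale
    X, blocks = _build_blocks(data, specs)
    n = len(y)

    if lam is None:
        lam_d = {s.name: 1.0 for s in specs}
        grid = np.logspace(-3, 6, 7)
        gold = (math.sqrt(5) - 1) / 2

        def score(l: dict[str, float]) -> float:
            _, _, dev, edf_t, _, _ = _pirls(X, blocks, y, w, l, family, max_iter, tol)
            return _gcv_score(n, dev, edf_t)

        for _ in range(2):
            for s in specs:
                best_v, best_l = math.inf, lam_d[s.name]
                for cand in grid:
                    trial = dict(lam_d, **{s.name: float(cand)})
                    v = score(trial)
                    if v < best_v:
                        best_v, best_l = v, float(cand)
                # golden-section refinement on log10 lambda
                lo = math.log10(best_l) - 1.5
                hi = math.log10(best_l) + 1.5
                a, b = lo, hi
                c = b - gold * (b - a)
                d = a + gold * (b - a)
                fc = score(dict(lam_d, **{s.name: 10.0**c}))
                fd = score(dict(lam_d, **{s.name: 10.0**d}))
                while b - a > 0.15:
                    if fc < fd:
                        b, d, fd = d, c, fc
                        c = b - gold * (b - a)
                        fc = score(dict(lam_d, **{s.name: 10.0**c}))
                    else:
                        a, c, fc = c, d, fd
                        d = a + gold * (b - a)
                        fd = score(dict(lam_d, **{s.name: 10.0**d}))
                lam_d[s.name] = 10.0 ** ((a + b) / 2)
        lam = lam_d
    elif np.isscalar(lam):
        lam = {s.name: float(lam) for s in specs}

    beta, mu, dev, edf_total, edf, iters = _pirls(X, blocks, y, w, lam, family, max_iter, tol)

    # dispersion (on the raw prior-weight scale) and null deviance
    if family == "gaussian":
        phi = w_scale * dev / max(n - edf_total, 1e-3)
        ybar = float(np.sum(w * y) / np.sum(w))
        null_dev = float(np.sum(w * (y - ybar) ** 2))
    else:
        mu_c = np.clip(mu, _EPS_MU, 1 - _EPS_MU)
        pearson = float(np.sum(w_raw * (y - mu) ** 2 / (mu_c * (1 - mu_c))))
        phi = pearson / max(n - edf_total, 1e-3)
        ybar = float(np.sum(w * y) / np.sum(w))
        null_dev = _binom_deviance(y, np.full(n, ybar), w)

    return FittedGam(
        specs=specs,
        blocks=blocks,
        beta=beta,
        lam=dict(lam),
        phi=phi,
        deviance=dev,
        null_deviance=null_dev,
        edf=edf,
        edf_total=edf_total,
        family=family,
        n=n,
        X=X,
        w=w,
        y=y,
        mu=mu,
        gcv=_gcv_score(n, dev, edf_total),
        iterations=iters,
    )


def explained_deviance(fit: FittedGam) -> float:
    """Proportion of (quasi)deviance explained, 1 - D/D0; 0 if the
    response is constant (D0 = 0, flagged)."""
    if fit.null_deviance <= 1e-8:
        warnings.warn("null deviance is zero (constant response); explained deviance set to 0")
        return 0.0
    return 1.0 - fit.deviance / fit.null_deviance


# ---------------------------------------------------------------------------
# Hierarchical partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HpResult:
    """Per-group independent (Shapley), unique and shared contributions to
    the full model's explained deviance."""

    groups: tuple[str, ...]
    independent: dict[str, float]
    unique: dict[str, float]
    shared: dict[str, float]
    r_full: float
    subset_r: dict[frozenset, float]


def shapley_from_subsets(groups: list[str], r: dict[frozenset, float]) -> HpResult:
    """Shapley decomposition from a table of subset goodness-of-fit values.

    ``r`` maps each non-empty frozenset of groups to its explained
    deviance; R(empty) = 0.  The independent contribution of group g
    averages R(S + g) - R(S) over orderings; unique is R(full) - R(full
    minus g); shared = independent - unique.
    """
    G = len(groups)
    full = frozenset(groups)

    def R(s: frozenset) -> float:
        return 0.0 if not s else r[s]

    independent, unique, shared = {}, {}, {}
    for g in groups:
        others = [x for x in groups if x != g]
        total = 0.0
        for size in range(G):
            coef = math.factorial(size) * math.factorial(G - size - 1) / math.factorial(G)
            for comb in itertools.combinations(others, size):
                s = frozenset(comb)
                total += coef * (R(s | {g}) - R(s))
        independent[g] = total
        unique[g] = R(full) - R(full - {g})
        shared[g] = independent[g] - unique[g]
        if shared[g] < -1e-9:
            warnings.warn(
                f"negative shared contribution for group {g!r} ({shared[g]:.4g}); reported as-is"
            )
    return HpResult(
        groups=tuple(groups),
        independent=independent,
        unique=unique,
        shared=shared,
        r_full=R(full),
        subset_r=dict(r),
    )


def hierarchical_partition(
    data: pd.DataFrame,
    specs: list[SmoothSpec] | None = None,
    groups: dict[str, tuple[str, ...]] | None = None,
    response: str = "proportion",
    weights: str | None = "n_bursts",
    family: str = "quasibinomial",
    lam: dict[str, float] | float | None = None,
) -> HpResult:
    """Fit all 2^G - 1 non-empty predictor-group subsets and Shapley-average
    the explained-deviance gains.

    Each subset is refit as a legitimate GAM with its own GCV smoothing
    selection (pass ``lam`` to fix smoothing instead).  A subset-fit
    failure aborts with the failing subset named.
    """
    if specs is None:
        specs = default_terms()
    if groups is None:
        groups = {k: v for k, v in DEFAULT_GROUPS.items() if any(s.name in v for s in specs)}
    names = list(groups)
    if not (1 <= len(names) <= 6):
        raise ValueError("hierarchical partitioning supports 1-6 groups")
    spec_of = {s.name: s for s in specs}
    r: dict[frozenset, float] = {}
    for size in range(1, len(names) + 1):
        for comb in itertools.combinations(names, size):
            subset_specs = [
                spec_of[t] for g in comb for t in groups[g] if t in spec_of
            ]
            try:
                fit = fit_gam(
                    data, subset_specs, response=response, weights=weights,
                    family=family, lam=lam,
                )
            except Exception as exc:  # noqa: BLE001 - re-raise with subset named
                raise RuntimeError(f"subset fit failed for groups {comb}: {exc}") from exc
            r[frozenset(comb)] = explained_deviance(fit)
    return shapley_from_subsets(names, r)


# ---------------------------------------------------------------------------
# Concurvity
# ---------------------------------------------------------------------------

def concurvity(fit: FittedGam, data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise concurvity: for ordered terms (i, j), the proportion of
    term i's fitted contribution lying in term j's basis column space,
    ||P_j f_i||^2 / ||f_i||^2 in [0, 1].  A zero-norm term reports 0."""
    names = [blk.spec.name for blk in fit.blocks]
    out = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    designs = {blk.spec.name: blk.design(data) for blk in fit.blocks}
    contribs = {
        blk.spec.name: designs[blk.spec.name] @ fit.beta[blk.sl] for blk in fit.blocks
    }
    for i in names:
        f = contribs[i]
        norm2 = float(f @ f)
        if norm2 <= 1e-300:
            warnings.warn(f"term {i!r} has zero-norm contribution; concurvity reported as 0")
            continue
        for j in names:
            if i == j:
                out.loc[i, j] = 1.0
                continue
            Xj = designs[j]
            coef, *_ = np.linalg.lstsq(Xj, f, rcond=None)
            proj = Xj @ coef
            out.loc[i, j] = min(1.0, float(proj @ proj) / norm2)
    return out
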