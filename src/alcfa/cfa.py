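"""Maximum-likelihood covariance-structure estimation for hierarchical factor models.

The model class implemented here is the second-order confirmatory factor
model: observed indicators load on first-order factors (one factor per
indicator), and the first-order factors load on one or more second-order
factors.  With ``Lambda`` the (p x m) indicator-loading matrix, ``Gamma`` the
(m x k) second-order loading matrix, ``Psi`` the diagonal matrix of
first-order disturbance variances and ``Theta`` the diagonal matrix of unique
variances, the model-implied covariance matrix is

    Sigma(theta) = Lambda (Gamma Gamma' + Psi) Lambda' + Theta

where the second-order factors are standardized: unit variances, zero mutual
covariances (``Phi = I``).  Under this identification convention every
indicator loading, second-order loading, disturbance variance and unique
variance is a free parameter, which reproduces the conventional
parameter-counting arithmetic of hierarchical EQS-style models.

Parameters are estimated by minimizing the Wishart maximum-likelihood
discrepancy

    F(S, Sigma) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

and the model chi-square is (N - 1) * F_min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.optimize
import scipy.stats
import yaml

__all__ = [
    "FactorSpec",
    "SecondOrderSpec",
    "ModelSpec",
    "ParameterSet",
    "FitResult",
    "CovarianceInput",
    "degrees_of_freedom",
    "effective_degrees_of_freedom",
    "implied_covariance",
    "ml_discrepancy",
    "start_values",
    "fit_model",
    "baseline_model",
]

VARIANCE_FLOOR = 1e-6


class ModelError(ValueError):
    """Invalid model specification or parameter set."""


class InadmissibleParameters(FloatingPointError):
    """Sigma(theta) is singular / not positive definite."""


@dataclass(frozen=True)
class FactorSpec:
    """A first-order factor: a named group of observed indicators.

    ``anchor`` (default: the first indicator) fixes the rotation of the
    standardized solution: the anchor's standardized loading is oriented to
    have sign ``anchor_sign``.  ``anchor_sign`` is -1 for factors whose
    natural marker runs against the factor's direction of risk (HDL within
    dyslipidemia; reciprocal-transformed IL-6 within inflammation).
    """

    name: str
    indicators: tuple[str, ...]
    anchor: str | None = None
    anchor_sign: int = 1

    def __post_init__(self):
        if not self.indicators:
            raise ModelError(f"factor {self.name!r} has no indicators")
        if self.anchor is None:
            object.__setattr__(self, "anchor", self.indicators[0])
        if self.anchor not in self.indicators:
            raise ModelError(f"anchor {self.anchor!r} not an indicator of {self.name!r}")
        if self.anchor_sign not in (-1, 1):
            raise ModelError("anchor_sign must be +1 or -1")


@dataclass(frozen=True)
class SecondOrderSpec:
    """A second-order factor: a named set of first-order factors loading on it."""

    name: str
    factors: tuple[str, ...]

    def __post_init__(self):
        if not self.factors:
            raise ModelError(f"second-order factor {self.name!r} has no edges")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a hierarchical factor model.

    Every indicator belongs to exactly one first-order factor; a first-order
    factor may load on several second-order factors (cross-loadings).
    Second-order factor variances are fixed to 1 and their covariances to 0.
    """

    name: str
    first_order: tuple[FactorSpec, ...]
    second_order: tuple[SecondOrderSpec, ...]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for f in self.first_order:
            for ind in f.indicators:
                if ind in seen:
                    raise ModelError(
                        f"indicator {ind!r} assigned to both {seen[ind]!r} and {f.name!r}"
                    )
                seen[ind] = f.name
        fnames = [f.name for f in self.first_order]
        if len(set(fnames)) != len(fnames):
            raise ModelError("duplicate first-order factor names")
        for s in self.second_order:
            for fname in s.factors:
                if fname not in fnames:
                    raise ModelError(f"unknown first-order factor {fname!r} in {s.name!r}")

    # -- derived structure ---------------------------------------------------

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(ind for f in self.first_order for ind in f.indicators)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.first_order)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """(first-order factor, second-order factor) pairs, in spec order."""
        return tuple((f, s.name) for s in self.second_order for f in s.factors)

    @property
    def n_free(self) -> int:
        """Free parameters: loadings + uniquenesses + edges + disturbances.

        Without a second-order layer the first-order factor variances are
        fixed to 1 for identification, so the disturbance block is not free.
        """
        p, m = self.n_indicators, len(self.first_order)
        if not self.second_order:
            return 2 * p
        return 2 * p + len(self.edges) + m

    def factor_of(self, indicator: str) -> str:
        for f in self.first_order:
            if indicator in f.indicators:
                return f.name
        raise KeyError(indicator)

    def free_parameter_labels(self) -> frozenset[tuple[str, ...]]:
        """Structural labels of the free parameters, for nesting checks."""
        labels: set[tuple[str, ...]] = set()
        for ind in self.indicators:
            labels.add(("lambda", ind))
            labels.add(("theta", ind))
        if self.second_order:
            for f in self.factor_names:
                labels.add(("zeta", f))
        for f, s in self.edges:
            labels.add(("gamma", f, s))
        return frozenset(labels)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "first_order": [
                {
                    "name": f.name,
                    "indicators": list(f.indicators),
                    "anchor": f.anchor,
                    "anchor_sign": f.anchor_sign,
                }
                for f in self.first_order
            ],
            "second_order": [
                {"name": s.name, "factors": list(s.factors)} for s in self.second_order
            ],
            "fixed": {"second_order_variances": 1.0, "second_order_covariances": 0.0},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"],
            first_order=tuple(
                FactorSpec(
                    name=f["name"],
                    indicators=tuple(f["indicators"]),
                    anchor=f.get("anchor"),
                    anchor_sign=f.get("anchor_sign", 1),
                )
                for f in d["first_order"]
            ),
            second_order=tuple(
                SecondOrderSpec(name=s["name"], factors=tuple(s["factors"]))
                for s in d["second_order"]
            ),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class ParameterSet:
    """Free parameters of a hierarchical factor model.

    lam        -- indicator loadings, one per indicator (spec order)
    gamma      -- second-order loadings, one per (first-order, second-order) edge
    zeta       -- first-order disturbance variances
    theta_eps  -- unique (error) variances, one per indicator
    """

    lam: np.ndarray
    gamma: np.ndarray
    zeta: np.ndarray
    theta_eps: np.ndarray

    def validate(self, spec: ModelSpec) -> None:
        p, m, e = spec.n_indicators, len(spec.first_order), len(spec.edges)
        if (len(self.lam), len(self.gamma), len(self.zeta), len(self.theta_eps)) != (p, e, m, p):
            raise ModelError("parameter block lengths do not match the model spec")
        if np.any(self.zeta < 0) or np.any(self.theta_eps < 0):
            raise ModelError("variances must be non-negative")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.lam, self.gamma, self.zeta, self.theta_eps])

    @classmethod
    def unpack(cls, spec: ModelSpec, x: np.ndarray) -> "ParameterSet":
        p, m, e = spec.n_indicators, len(spec.first_order), len(spec.edges)
        if len(x) != 2 * p + e + m:
            raise ModelError("parameter vector has wrong length")
        return cls(
            lam=np.asarray(x[:p], dtype=float).copy(),
            gamma=np.asarray(x[p : p + e], dtype=float).copy(),
            zeta=np.asarray(x[p + e : p + e + m], dtype=float).copy(),
            theta_eps=np.asarray(x[p + e + m :], dtype=float).copy(),
        )


@dataclass(frozen=True)
class CovarianceInput:
    """A sample covariance matrix with its sample size and variable names."""

    S: np.ndarray
    N: int
    names: tuple[str, ...]

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "names", tuple(self.names))
        p = len(self.names)
        if S.shape != (p, p):
            raise ModelError("covariance matrix shape does not match names")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ModelError("covariance matrix is not symmetric")
        if np.any(np.diag(S) <= 0):
            raise ModelError("covariance diagonal must be strictly positive")
        if self.N < p + 1:
            raise ModelError(f"sample size N={self.N} too small for p={p} variables")

    def subset(self, names: tuple[str, ...] | list[str]) -> "CovarianceInput":
        idx = [self.names.index(n) for n in names]
        return CovarianceInput(self.S[np.ix_(idx, idx)], self.N, tuple(names))


@dataclass
class FitResult:
    """Outcome of fitting a hierarchical factor model by maximum likelihood."""

    model: str
    spec: ModelSpec | None
    theta_hat: ParameterSet | None
    F_min: float
    chi_square: float
    df: int
    p_value: float
    N: int
    converged: bool
    n_iterations: int
    heywood: list[str] = field(default_factory=list)
    implied: np.ndarray | None = None
    standardized: dict | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "F_min": self.F_min,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "N": self.N,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "heywood": list(self.heywood),
            "standardized": self.standardized,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ---------------------------------------------------------------------------
# structural arithmetic
# ---------------------------------------------------------------------------


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Model degrees of freedom: p(p+1)/2 unique moments minus free parameters.

    This is the conventional EQS-style count under the free-loading
    identification and is the value reported alongside the chi-square (it
    matches published hierarchical-model dfs).  For the statistic's actual
    sampling reference see :func:`effective_degrees_of_freedom`.
    """
    p = spec.n_indicators
    return p * (p + 1) // 2 - spec.n_free


def effective_degrees_of_freedom(spec: ModelSpec) -> int:
    """Moments minus the dimension of the implied-covariance manifold.

    Under the free-loading convention every first-order block carries a scale
    trade-off (loadings versus factor variance) that leaves Sigma unchanged,
    so the manifold dimension is 2p + E (E = number of second-order edges),
    one less per first-order factor than the naive free-parameter count.
    The minimized chi-square is asymptotically chi-square with *this* df,
    which is what simulation calibration should be judged against.
    """
    p = spec.n_indicators
    dim = 2 * p + len(spec.edges)
    return p * (p + 1) // 2 - dim


def _matrices(spec: ModelSpec, params: ParameterSet):
    """Dense (Lambda, Gamma, zeta, theta) from the packed parameter blocks."""
    p, m, k = spec.n_indicators, len(spec.first_order), len(spec.second_order)
    Lam = np.zeros((p, m))
    inds = spec.indicators
    fnames = spec.factor_names
    for i, ind in enumerate(inds):
        Lam[i, fnames.index(spec.factor_of(ind))] = params.lam[i]
    Gam = np.zeros((m, k))
    snames = [s.name for s in spec.second_order]
    for g, (f, s) in zip(params.gamma, spec.edges):
        Gam[fnames.index(f), snames.index(s)] = g
    return Lam, Gam, params.zeta, params.theta_eps


def implied_covariance(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Sigma(theta) = Lambda (Gamma Gamma' + Psi) Lambda' + Theta."""
    params.validate(spec)
    Lam, Gam, zeta, theta = _matrices(spec, params)
    M = Gam @ Gam.T + np.diag(zeta)
    Sigma = Lam @ M @ Lam.T + np.diag(theta)
    return (Sigma + Sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML discrepancy  ln|Sigma| - ln|S| + tr(S Sigma^-1) - p."""
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    if Sigma.shape != S.shape:
        raise ModelError("S and Sigma must have the same dimension")
    try:
        c, low = sla.cho_factor(Sigma, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise InadmissibleParameters("implied covariance not positive definite") from exc
    except sla.LinAlgError as exc:
        raise InadmissibleParameters("implied covariance not positive definite") from exc
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ModelError("sample covariance not positive definite")
    trace_term = np.trace(sla.cho_solve((c, low), S))
    F = logdet_sigma - logdet_s + trace_term - p
    if F < -1e-12 * max(1.0, abs(trace_term)):
        raise InadmissibleParameters(f"discrepancy negative beyond tolerance: {F}")
    return float(F)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def start_values(spec: ModelSpec, S: np.ndarray) -> ParameterSet:
    """Deterministic starting parameters.

    Loadings start at sqrt(s_ii/2) and uniquenesses at s_ii/2 (an even split of
    each indicator's variance); second-order loadings start at +-0.5 with the
    sign of the correlation between block mean-composites; disturbances at 0.5.
    """
    S = np.asarray(S, dtype=float)
    d = np.diag(S)
    lam = np.sqrt(d / 2.0)
    theta = d / 2.0
    m = len(spec.first_order)
    zeta = np.full(m, 0.5)
    # composite direction per factor: mean of standardized indicators
    Dinv = 1.0 / np.sqrt(d)
    R = S * np.outer(Dinv, Dinv)
    inds = list(spec.indicators)
    blocks = [[inds.index(i) for i in f.indicators] for f in spec.first_order]
    comp_cov = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            comp_cov[a, b] = np.mean(R[np.ix_(blocks[a], blocks[b])])
    ref = 0  # first factor anchors the composite sign convention
    gamma = np.empty(len(spec.edges))
    fnames = spec.factor_names
    for e, (f, _s) in enumerate(spec.edges):
        j = fnames.index(f)
        sign = 1.0 if (j == ref or comp_cov[j, ref] >= 0) else -1.0
        gamma[e] = 0.5 * sign
    return ParameterSet(lam=lam, gamma=gamma, zeta=zeta, theta_eps=theta)


def _objective_and_grad(spec: ModelSpec, S: np.ndarray):
    """Closure returning (F, dF/dx) for the packed parameter vector."""
    p = spec.n_indicators
    m = len(spec.first_order)
    inds = spec.indicators
    fnames = spec.factor_names
    find = np.array([fnames.index(spec.factor_of(i)) for i in inds])
    snames = [s.name for s in spec.second_order]
    edge_idx = np.array(
        [(fnames.index(f), snames.index(s)) for f, s in spec.edges], dtype=int
    )
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ModelError("sample covariance not positive definite")

    def fun(x: np.ndarray):
        params = ParameterSet.unpack(spec, x)
        Lam, Gam, zeta, theta = _matrices(spec, params)
        M = Gam @ Gam.T + np.diag(zeta)
        Sigma = Lam @ M @ Lam.T + np.diag(theta)
        try:
            c, low = sla.cho_factor(Sigma, lower=True)
        except (np.linalg.LinAlgError, sla.LinAlgError):
            return np.inf, np.zeros_like(x)
        logdet_sigma = 2.0 * np.sum(np.log(np.diag(c)))
        Sigma_inv = sla.cho_solve((c, low), np.eye(p))
        F = logdet_sigma - logdet_s + np.sum(Sigma_inv * S) - p
        # dF = tr(G dSigma), G = Sigma^-1 (Sigma - S) Sigma^-1
        G = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        GLM = G @ Lam @ M
        d_lam = 2.0 * GLM[np.arange(p), find]
        LGL = Lam.T @ G @ Lam
        d_gamma_mat = 2.0 * LGL @ Gam
        d_gamma = d_gamma_mat[edge_idx[:, 0], edge_idx[:, 1]] if len(edge_idx) else np.empty(0)
        d_zeta = np.diag(LGL).copy()
        d_theta = np.diag(G).copy()
        grad = np.concatenate([d_lam, d_gamma, d_zeta, d_theta])
        return F, grad

    return fun


def fit_model(
    spec: ModelSpec,
    data: CovarianceInput,
    *,
    max_restarts: int = 10,
    seed: int = 0,
    variance_floor: float = VARIANCE_FLOOR,
    gtol: float = 1e-8,
    maxiter: int = 5000,
) -> FitResult:
    """Fit a hierarchical factor model to a sample covariance matrix.

    Minimizes the ML discrepancy over loadings, second-order loadings,
    disturbance variances and unique variances (variances floored at
    ``variance_floor``; floored estimates are flagged as Heywood cases).
    On convergence failure the deterministic start is jittered with a seeded
    RNG for up to ``max_restarts`` additional attempts.

    Returns chi-square = (N - 1) * F_min with degrees of freedom from the
    declarative spec and a p-value from the central chi-square distribution.
    """
    missing = set(spec.indicators) - set(data.names)
    if missing:
        raise ModelError(f"data lacks indicators required by the model: {sorted(missing)}")
    data_sub = data.subset(spec.indicators) if data.names != spec.indicators else data
    S_raw, N = data_sub.S, data_sub.N
    if np.linalg.slogdet(S_raw)[0] <= 0:
        raise ModelError("sample covariance is singular")
    # F_ML is invariant to per-variable rescaling for this model family
    # (free loadings and uniquenesses); optimizing on the correlation scale
    # conditions the problem, parameters are mapped back afterwards
    sd = np.sqrt(np.diag(S_raw))
    S = S_raw / np.outer(sd, sd)

    p, m, e = spec.n_indicators, len(spec.first_order), len(spec.edges)
    fun = _objective_and_grad(spec, S)
    # without a second-order layer, first-order factor variances are pinned
    # to 1 for identification
    zeta_bounds = (
        [(variance_floor, None)] * m if spec.second_order else [(1.0, 1.0)] * m
    )
    bounds = (
        [(None, None)] * p
        + [(None, None)] * e
        + zeta_bounds
        + [(variance_floor, None)] * p
    )
    x0 = start_values(spec, S).pack()
    if not spec.second_order:
        x0[p + e : p + e + m] = 1.0
    rng = np.random.default_rng(seed)

    best_any = None
    best_ok = None
    n_total_iter = 0
    for attempt in range(max_restarts + 1):
        xa = x0 if attempt == 0 else x0 * rng.uniform(0.5, 1.5, size=x0.shape)
        if attempt > 0:  # keep jittered variances admissible
            xa[p + e :] = np.maximum(xa[p + e :], 10 * variance_floor)
        res = scipy.optimize.minimize(
            fun,
            xa,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        n_total_iter += res.nit
        if np.isfinite(res.fun) and (best_any is None or res.fun < best_any.fun):
            best_any = res
        if res.success and np.isfinite(res.fun):
            best_ok = res
            break
    converged = best_ok is not None
    best = best_ok if best_ok is not None else best_any
    if best is None:
        raise InadmissibleParameters("optimization produced no finite discrepancy")

    params = ParameterSet.unpack(spec, best.x)
    # back to the covariance scale of the input data
    params.lam *= sd
    params.theta_eps *= sd**2
    F_min = float(best.fun)
    heywood = []
    var_block = best.x[p + e :]
    for name, v in zip(
        [f"zeta:{f}" for f in spec.factor_names] + [f"theta:{i}" for i in spec.indicators],
        var_block,
    ):
        if v <= variance_floor * 1.001:
            heywood.append(name)

    df = degrees_of_freedom(spec)
    chi2 = (N - 1) * F_min
    p_value = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    implied = implied_covariance(spec, params)
    standardized = _standardize(spec, params, implied) if converged else None
    return FitResult(
        model=spec.name,
        spec=spec,
        theta_hat=params,
        F_min=F_min,
        chi_square=float(chi2),
        df=df,
        p_value=p_value,
        N=N,
        converged=converged,
        n_iterations=n_total_iter,
        heywood=heywood,
        implied=implied,
        standardized=standardized,
    )


def _standardize(spec: ModelSpec, params: ParameterSet, Sigma: np.ndarray) -> dict:
    """Standardized solution with deterministic sign orientation.

    Indicator loadings are rescaled to unit factor and indicator variances;
    second-order loadings to unit first-order factor variances.  Each
    first-order factor is oriented so its anchor's standardized loading has
    the sign declared in the spec; each second-order factor is oriented so
    the largest-magnitude standardized loading in its column is positive.
    """
    Lam, Gam, zeta, theta = _matrices(spec, params)
    m = len(spec.first_order)
    M = Gam @ Gam.T + np.diag(zeta)
    fvar = np.maximum(np.diag(M), 1e-300)
    inds = spec.indicators
    fnames = spec.factor_names
    find = np.array([fnames.index(spec.factor_of(i)) for i in inds])
    sd_x = np.sqrt(np.diag(Sigma))
    lam_std = params.lam * np.sqrt(fvar[find]) / sd_x
    gam_std = Gam / np.sqrt(fvar)[:, None]

    flip = np.ones(m)
    for j, f in enumerate(spec.first_order):
        a = inds.index(f.anchor)
        if lam_std[a] * f.anchor_sign < 0:
            flip[j] = -1.0
    lam_std = lam_std * flip[find]
    gam_std = gam_std * flip[:, None]
    for kk in range(gam_std.shape[1]):
        col = gam_std[:, kk]
        if np.any(col != 0) and col[np.argmax(np.abs(col))] < 0:
            gam_std[:, kk] = -col

    snames = [s.name for s in spec.second_order]
    return {
        "loadings": {
            ind: {"factor": fnames[find[i]], "value": float(lam_std[i])}
            for i, ind in enumerate(inds)
        },
        "second_order": {
            f: {s: float(gam_std[fnames.index(f), snames.index(s)]) for fs, s in spec.edges if fs == f}
            for f in fnames
        },
        "disturbances": {
            f: float(zeta[j] / fvar[j]) for j, f in enumerate(fnames)
        },
        "uniquenesses": {
            ind: float(theta[i] / Sigma[i, i]) for i, ind in enumerate(inds)
        },
        "factor_variances": {f: float(fvar[j]) for j, f in enumerate(fnames)},
    }


def baseline_model(data: CovarianceInput) -> FitResult:
    """Independence (null) model: Sigma = diag(S); the CFI reference point."""
    S, N = data.S, data.N
    p = S.shape[0]
    F_B = ml_discrepancy(S, np.diag(np.diag(S)))
    df_B = p * (p - 1) // 2
    chi2_B = (N - 1) * F_B
    return FitResult(
        model="baseline",
        spec=None,
        theta_hat=None,
        F_min=float(F_B),
        chi_square=float(chi2_B),
        df=df_B,
        p_value=float(scipy.stats.chi2.sf(chi2_B, df_B)) if df_B > 0 else 1.0,
        N=N,
        converged=True,
        n_iterations=0,
        implied=np.diag(np.diag(S)),
    )
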