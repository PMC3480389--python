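"""Independent reference implementation used only as a cross-check in tests.

Deliberately shares no code path with the package engine:

* the implied covariance is assembled element-by-element from the path
  (tracing) rules rather than by matrix algebra;
* the model is identified by the conventional marker-variable scheme (first
  loading of every factor fixed to 1, factor variances free) instead of the
  engine's fixed-second-order-variance scheme -- the two parameterizations
  span the same covariance manifold, so the minimized discrepancy, the
  chi-square and the CFI must agree;
* optimization uses numerically differentiated gradients.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize


def path_implied_cov(spec, params) -> np.ndarray:
    """Sigma(theta) from explicit path tracing over every indicator pair.

    cov(x_i, x_j) = lam_i lam_j [ sum_k gamma_{f(i),k} gamma_{f(j),k}
                                  + [f(i)=f(j)] zeta_{f(i)} ]
                    + [i=j] theta_i
    with unit-variance, mutually orthogonal second-order factors.
    """
    inds = list(spec.indicators)
    fnames = list(spec.factor_names)
    snames = [s.name for s in spec.second_order]
    gam = {}
    for g, (f, s) in zip(params.gamma, spec.edges):
        gam[(f, s)] = g
    p = len(inds)
    Sigma = np.zeros((p, p))
    for i in range(p):
        fi = spec.factor_of(inds[i])
        for j in range(i, p):
            fj = spec.factor_of(inds[j])
            acc = 0.0
            for s in snames:
                acc += gam.get((fi, s), 0.0) * gam.get((fj, s), 0.0)
            if fi == fj:
                acc += params.zeta[fnames.index(fi)]
            val = params.lam[i] * params.lam[j] * acc
            if i == j:
                val += params.theta_eps[i]
            Sigma[i, j] = Sigma[j, i] = val
    return Sigma


def _discrepancy(S, Sigma):
    sign, ld_sigma = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return np.inf
    _, ld_s = np.linalg.slogdet(S)
    return ld_sigma - ld_s + np.trace(S @ np.linalg.inv(Sigma)) - S.shape[0]


class _MarkerModel:
    """Marker-variable parameterization of a hierarchical factor model."""

    def __init__(self, spec):
        self.spec = spec
        self.inds = list(spec.indicators)
        self.fnames = list(spec.factor_names)
        self.snames = [s.name for s in spec.second_order]
        self.p = len(self.inds)
        # free loadings: all but the first indicator of each factor
        self.free_lam = [
            self.inds.index(ind)
            for f in spec.first_order
            for ind in f.indicators[1:]
        ]
        # free second-order edges: all but the first factor of each second-order
        self.free_gam = []
        self.fixed_gam = []
        for s in spec.second_order:
            self.fixed_gam.append((s.factors[0], s.name))
            self.free_gam.extend((f, s.name) for f in s.factors[1:])
        self.k = len(self.snames)
        self.m = len(self.fnames)
        self.n_par = (
            len(self.free_lam) + len(self.free_gam) + self.k + self.m + self.p
        )

    def split(self, x):
        a, b = len(self.free_lam), len(self.free_gam)
        lam_free = x[:a]
        gam_free = x[a : a + b]
        phi = x[a + b : a + b + self.k]          # second-order variances
        zeta = x[a + b + self.k : a + b + self.k + self.m]
        theta = x[a + b + self.k + self.m :]
        return lam_free, gam_free, phi, zeta, theta

    def implied(self, x):
        lam_free, gam_free, phi, zeta, theta = self.split(x)
        lam = np.ones(self.p)
        for v, i in zip(lam_free, self.free_lam):
            lam[i] = v
        gam = {pair: 1.0 for pair in self.fixed_gam}
        for v, pair in zip(gam_free, self.free_gam):
            gam[pair] = v
        Sigma = np.zeros((self.p, self.p))
        for i in range(self.p):
            fi = self.spec.factor_of(self.inds[i])
            for j in range(i, self.p):
                fj = self.spec.factor_of(self.inds[j])
                acc = 0.0
                for kk, s in enumerate(self.snames):
                    acc += gam.get((fi, s), 0.0) * gam.get((fj, s), 0.0) * phi[kk]
                if fi == fj:
                    acc += zeta[self.fnames.index(fi)]
                val = lam[i] * lam[j] * acc
                if i == j:
                    val += theta[i]
                Sigma[i, j] = Sigma[j, i] = val
        return Sigma

    def start(self, R):
        x0 = []
        for f in self.spec.first_order:
            marker = self.inds.index(f.indicators[0])
            for ind in f.indicators[1:]:
                i = self.inds.index(ind)
                r = R[i, marker]
                x0.append(r / max(abs(r), 0.4) * 0.8)
        # composite correlations give the second-order start signs
        blocks = {
            f.name: [self.inds.index(i) for i in f.indicators]
            for f in self.spec.first_order
        }
        for f, s in self.free_gam:
            anchor_f = [a for a, b in self.fixed_gam if b == s][0]
            r = np.mean(R[np.ix_(blocks[f], blocks[anchor_f])])
            x0.append(0.8 * np.sign(r) if r != 0 else 0.5)
        x0.extend([0.3] * self.k)   # phi
        x0.extend([0.3] * self.m)   # zeta
        x0.extend([0.5] * self.p)   # theta
        return np.array(x0)


def reference_fit(spec, S, N, *, n_starts=8, seed=1234):
    """ML fit under marker identification; returns (chi2, F_min, chi2_baseline).

    Works on the correlation scale (the discrepancy is invariant to
    per-variable rescaling for this model family).
    """
    S = np.asarray(S, dtype=float)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    model = _MarkerModel(spec)
    a, b = len(model.free_lam), len(model.free_gam)
    bounds = (
        [(None, None)] * (a + b)
        + [(1e-6, None)] * model.k
        + [(1e-6, None)] * model.m
        + [(1e-6, None)] * model.p
    )
    rng = np.random.default_rng(seed)
    x0 = model.start(R)
    best = None
    vals = []
    for trial in range(n_starts):
        if trial == 0:
            xt = x0
        else:
            xt = x0 * rng.uniform(0.6, 1.4, size=x0.shape)
            # marker-sign starts can be wrong under arbitrary sign patterns;
            # randomize the signs of the free loadings and edges
            xt[: a + b] *= rng.choice([-1.0, 1.0], size=a + b)
        res = scipy.optimize.minimize(
            lambda x: _discrepancy(R, model.implied(x)),
            xt,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 4000, "ftol": 1e-14, "gtol": 1e-9},
        )
        vals.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-10:
            break
        # two independent starts landing on the same minimum is good evidence
        # it is global; stop early
        if sum(1 for v in vals if v < best.fun + 1e-8) >= 2:
            break
    F_min = float(best.fun)
    chi2 = (N - 1) * F_min
    # independence baseline: Sigma = diag -> F_B = -ln det R
    F_B = float(-np.linalg.slogdet(R)[1])
    chi2_B = (N - 1) * F_B
    return chi2, F_min, chi2_B
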