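"""Independent full-information maximum-likelihood fitter for recursive
path models, used only as a cross-check oracle in tests.

Unlike the package's equation-wise OLS, this minimizes the multivariate-
normal ML discrepancy F(theta) = ln|Sigma(theta)| - ln|S| +
tr(S Sigma(theta)^-1) - p jointly over all path coefficients, residual
variances (log-parameterized), and the Cholesky factor of the exogenous
covariance block, by numerical optimization.  For recursive observed-
variable models the two routes are known to coincide at the optimum,
which is exactly what the cross-check asserts.
"""

import numpy as np
from scipy import optimize


def fiml_fit(equations, exog, S):
    """Fit by direct ML-discrepancy minimization.

    ``equations`` is an ordered (topological) list of ``(child, parents)``;
    ``exog`` the exogenous variable names; ``S`` a DataFrame sample
    covariance/correlation over all variables.  Returns a dict
    ``(parent, child) -> coefficient`` at the ML optimum.
    """
    names = list(exog) + [c for c, _ in equations]
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    Smat = S.loc[names, names].to_numpy()
    k = len(exog)

    slots = [(idx[c], idx[par]) for c, parents in equations for par in parents]
    nb, ne = len(slots), len(equations)
    tril = [(i, j) for i in range(k) for j in range(i + 1)]
    L0 = np.linalg.cholesky(Smat[:k, :k])

    theta0 = np.concatenate([
        np.zeros(nb), np.zeros(ne),
        np.array([L0[i, j] for i, j in tril])])

    def sigma_of(theta):
        B = np.zeros((p, p))
        for s, (ci, pi) in enumerate(slots):
            B[ci, pi] = theta[s]
        E = np.zeros((p, p))
        for e, (child, _) in enumerate(equations):
            E[idx[child], idx[child]] = np.exp(theta[nb + e])
        L = np.zeros((k, k))
        for s, (i, j) in enumerate(tril):
            L[i, j] = theta[nb + ne + s]
        E[:k, :k] = L @ L.T
        inv = np.linalg.inv(np.eye(p) - B)
        return inv @ E @ inv.T

    _, logdet_s = np.linalg.slogdet(Smat)

    def objective(theta):
        sigma = sigma_of(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e6
        return logdet - logdet_s + float(
            np.trace(Smat @ np.linalg.inv(sigma))) - p

    res = optimize.minimize(objective, theta0, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 10000})
    coefficients = {}
    s = 0
    for child, parents in equations:
        for par in parents:
            coefficients[(par, child)] = float(res.x[s])
            s += 1
    return coefficients, float(res.fun)
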