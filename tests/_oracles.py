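"""Independent brute-force oracles used by unit and acceptance tests."""

from math import lgamma, log

import numpy as np


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided HWE exact p by direct enumeration over all heterozygote
    counts conditional on the allele counts (log-gamma arithmetic)."""
    n = n_AA + n_Aa + n_aa
    rare = 2 * min(n_AA, n_aa) + n_Aa
    logps = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        if hom_r < 0 or hom_c < 0:
            continue
        logps[het] = (
            lgamma(n + 1)
            - lgamma(hom_r + 1)
            - lgamma(het + 1)
            - lgamma(hom_c + 1)
            + het * log(2.0)
        )
    shift = max(logps.values())
    probs = {h: np.exp(lp - shift) for h, lp in logps.items()}
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total


def partial_corr_oracle(X: np.ndarray) -> np.ndarray:
    """Partial correlations via the regression-residual definition."""
    n, p = X.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            Z = np.column_stack([np.ones(n)] + [X[:, k] for k in others])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def multistart_one_factor_loglik(model, n_starts: int = 20, seed: int = 0):
    """Best ML discrepancy found by derivative-free search from random
    starts — an optimiser-independent check on the quasi-Newton fit."""
    from scipy import optimize

    p = model.k_endog
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = np.concatenate(
            [rng.uniform(-1.5, 1.5, p), rng.uniform(0.05, 2.0, p)]
        )
        res = optimize.minimize(
            lambda t: model.discrepancy(np.concatenate(
                [t[:p], np.clip(t[p:], 1e-6, None)]
            ))[0],
            x0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        best = min(best, res.fun)
    return best
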