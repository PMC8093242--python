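"""Questionnaire preprocessing and data-driven model specification.

Delta scores (after - before per item), category aggregation, the pairwise
partial-correlation matrix, Gaussian-graphical-model covariance selection
by backward AIC search, and PCA of the items in partial-correlation space.
Likert deltas (ordinal -6..+6) are treated as continuous throughout, so all
machinery is Pearson-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

from .datasets import (
    CATEGORY_ORDER,
    ITEM_CATEGORIES,
    ITEMS,
    DataValidationError,
    QuestionnaireData,
)

ItemMap = dict[str, str]

DEFAULT_ITEM_MAP: ItemMap = dict(ITEM_CATEGORIES)


# ---------------------------------------------------------------------------
# preprocessing


def delta_scores(responses: QuestionnaireData) -> pd.DataFrame:
    """Per-item delta = after - before, one column per item (range -6..+6)."""
    df = responses.responses
    for cond in ("before", "after"):
        block = df[[f"{q}_{cond}" for q in ITEMS]]
        bad = (block < 1) | (block > 7) | block.isna()
        if bad.any().any():
            col = bad.any()[bad.any()].index[0]
            subj = bad[col][bad[col]].index[0]
            raise DataValidationError(
                f"Likert value outside 1-7 for subject {subj!r}, item {col!r}"
            )
    deltas = pd.DataFrame(index=df.index)
    for q in ITEMS:
        deltas[q] = df[f"{q}_after"] - df[f"{q}_before"]
    return deltas


def category_scores(
    deltas: pd.DataFrame, item_map: ItemMap | None = None
) -> pd.DataFrame:
    """Average member-item deltas into the four symptom-category columns."""
    item_map = item_map or DEFAULT_ITEM_MAP
    missing = [q for q in item_map if q not in deltas.columns]
    if missing:
        raise DataValidationError(f"delta table lacks item columns {missing}")
    cats = pd.DataFrame(index=deltas.index)
    for cat in CATEGORY_ORDER:
        members = [q for q, c in item_map.items() if c == cat]
        cats[cat] = deltas[members].mean(axis=1)
    return cats


# ---------------------------------------------------------------------------
# partial correlations


@dataclass
class PartialCorrelationNetwork:
    """Partial-correlation matrix plus, after selection, the fitted graph."""

    partial_corr: pd.DataFrame
    adjacency: pd.DataFrame | None = None
    precision: np.ndarray | None = None
    aic_trace: list[float] | None = None

    def edge_list(self) -> pd.DataFrame:
        """Long-format (item_i, item_j, partial_r) for the upper triangle,
        restricted to selected edges when an adjacency is present."""
        names = list(self.partial_corr.columns)
        rows = []
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                if self.adjacency is not None and not self.adjacency.loc[a, b]:
                    continue
                rows.append({"item_i": a, "item_j": b,
                             "partial_r": self.partial_corr.loc[a, b]})
        return pd.DataFrame(rows, columns=["item_i", "item_j", "partial_r"])


def _partial_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def partial_correlation_matrix(
    data: pd.DataFrame, ridge: float | None = None
) -> PartialCorrelationNetwork:
    """Pairwise partial correlations, each pair conditioned on all other
    columns: rho_ij.rest = -Omega_ij / sqrt(Omega_ii Omega_jj) with Omega
    the inverse correlation matrix.

    ``ridge`` adds epsilon to the correlation diagonal when the matrix is
    numerically singular (pass e.g. 1e-6); by default singularity raises.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than variables ({p})")
    corr = np.corrcoef(X, rowvar=False)
    if ridge:
        corr = corr + ridge * np.eye(p)
    try:
        omega = linalg.inv(corr)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; retry with ridge=1e-6"
        ) from exc
    rho = _partial_from_precision(omega)
    names = [str(c) for c in data.columns]
    return PartialCorrelationNetwork(
        partial_corr=pd.DataFrame(rho, index=names, columns=names)
    )


# ---------------------------------------------------------------------------
# Gaussian graphical model MLE (iterative proportional fitting)


class IpfConvergenceError(RuntimeError):
    pass


def ggm_mle(
    S: np.ndarray,
    adjacency: np.ndarray,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """MLE (precision, covariance) of a Gaussian graphical model.

    Matches the sample covariance S on the diagonal and on graph edges
    while zeroing the precision elsewhere, via iterative proportional
    fitting over the maximal cliques of the graph.
    """
    p = S.shape[0]
    A = np.asarray(adjacency, bool).copy()
    np.fill_diagonal(A, False)
    G = nx.from_numpy_array(A)
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    K = np.diag(1.0 / np.diag(S))
    constrained = A | np.eye(p, dtype=bool)
    scale = np.abs(S).max()
    for _ in range(max_sweeps):
        for c in cliques:
            idx = np.ix_(c, c)
            sigma = linalg.inv(K)
            K[idx] += linalg.inv(S[idx]) - linalg.inv(sigma[idx])
        sigma = linalg.inv(K)
        err = np.abs((sigma - S)[constrained]).max()
        if err <= tol * scale:
            return K, sigma
    raise IpfConvergenceError(
        f"IPF did not converge in {max_sweeps} sweeps (residual {err:.3e})"
    )


def _ggm_loglik(K: np.ndarray, S: np.ndarray, n: int) -> float:
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    return 0.5 * n * (logdet - np.sum(K * S) - p * np.log(2.0 * np.pi))


def _aic(K: np.ndarray, S: np.ndarray, n: int, n_edges: int) -> float:
    p = S.shape[0]
    n_free = p + n_edges  # precision diagonal + free off-diagonals
    return -2.0 * _ggm_loglik(K, S, n) + 2.0 * n_free


def covariance_selection(
    sample_cov: np.ndarray | pd.DataFrame,
    n: int,
    tol: float = 1e-8,
) -> PartialCorrelationNetwork:
    """Backward covariance selection minimising AIC.

    Starting from the saturated graph, repeatedly remove the edge with the
    smallest |partial correlation| in the current fitted model, refit the
    graphical-model MLE under the zero constraints, and accept the removal
    only if AIC decreases; stop at the first increase.  Returns the final
    adjacency, fitted precision and the AIC trace of accepted models.
    """
    names = (
        [str(c) for c in sample_cov.columns]
        if isinstance(sample_cov, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(sample_cov).shape[0])]
    )
    S = np.asarray(sample_cov, dtype=float)
    p = S.shape[0]
    sign, _ = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance must be positive definite")

    adj = ~np.eye(p, dtype=bool)
    K = linalg.inv(S)  # saturated MLE
    n_edges = p * (p - 1) // 2
    trace = [_aic(K, S, n, n_edges)]
    while n_edges > 0:
        rho = np.abs(_partial_from_precision(K))
        rho[~adj] = np.inf
        np.fill_diagonal(rho, np.inf)
        i, j = np.unravel_index(np.argmin(rho), rho.shape)
        cand = adj.copy()
        cand[i, j] = cand[j, i] = False
        K_cand, _ = ggm_mle(S, cand, tol=tol)
        aic_cand = _aic(K_cand, S, n, n_edges - 1)
        if aic_cand >= trace[-1]:
            break
        adj, K, n_edges = cand, K_cand, n_edges - 1
        trace.append(aic_cand)

    return PartialCorrelationNetwork(
        partial_corr=pd.DataFrame(
            _partial_from_precision(K), index=names, columns=names
        ),
        adjacency=pd.DataFrame(adj.astype(int), index=names, columns=names),
        precision=K,
        aic_trace=trace,
    )


def find_cliques_above(
    network: PartialCorrelationNetwork, threshold: float = 0.2
) -> list[list[str]]:
    """Maximal cliques (size >= 3) whose edges all exceed the threshold in
    |partial correlation| — a diagnostic for extra latent factors."""
    if network.adjacency is None:
        raise ValueError("run covariance_selection first")
    names = list(network.adjacency.columns)
    strong = (
        (np.abs(network.partial_corr.to_numpy()) > threshold)
        & network.adjacency.to_numpy().astype(bool)
    )
    G = nx.from_numpy_array(strong)
    return [
        [names[i] for i in sorted(c)]
        for c in nx.find_cliques(G)
        if len(c) >= 3
    ]


# ---------------------------------------------------------------------------
# item PCA


def item_pca(
    partial_corr: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Eigendecomposition of the partial-correlation matrix.

    Returns (eigenvalues descending, item coordinates on the first two
    components scaled by sqrt(eigenvalue), variance shares).
    """
    names = (
        [str(c) for c in partial_corr.columns]
        if isinstance(partial_corr, pd.DataFrame)
        else [f"x{i}" for i in range(np.asarray(partial_corr).shape[0])]
    )
    M = np.asarray(partial_corr, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    vals, vecs = linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # deterministic sign: largest-magnitude coordinate positive
    for k in range(vecs.shape[1]):
        imax = np.argmax(np.abs(vecs[:, k]))
        if vecs[imax, k] < 0:
            vecs[:, k] = -vecs[:, k]
    shares = vals / vals.sum() if vals.sum() != 0 else np.full_like(vals, np.nan)
    coords = vecs[:, :2] * np.sqrt(np.clip(vals[:2], 0.0, None))
    coords_df = pd.DataFrame(coords, index=names, columns=["pc1", "pc2"])
    return vals, coords_df, shares
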