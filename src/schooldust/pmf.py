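"""Uncertainty-weighted positive matrix factorization (PMF) receptor model.

PMF decomposes a site × element concentration matrix X into nonnegative
source contributions G (site × k) and source profiles F (k × element) by
minimising the uncertainty-weighted objective

    Q = sum_ij ( (x_ij - (G F)_ij) / u_ij )^2

subject to G >= 0, F >= 0, where u_ij is the measurement uncertainty of
x_ij.  Heavily uncertain observations therefore carry little weight, which
is what distinguishes PMF from plain nonnegative matrix factorisation.

The solver uses weighted multiplicative updates (Lee–Seung style with
weights w_ij = 1/u_ij^2), which keep the factors nonnegative and make Q
monotone non-increasing.  Because the objective is non-convex, each fit is
restarted from multiple random nonnegative initialisations (one per seed)
and the lowest-Q run is kept.  Factor-count selection compares the best Q
per candidate k against the expected value of a chi-square-like statistic,
Q_expected = n*m - k*(n+m) (data points minus fitted parameters), choosing
the k whose Q/Q_expected is closest to 1.

Rotational ambiguity (FPEAK-style exploration) is not implemented; see the
methods note for the resulting caveats when interpreting single solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .datamodel import ConcentrationMatrix, ValidationError

__all__ = [
    "build_uncertainty",
    "fit_pmf",
    "select_factor_count",
    "summarize_factors",
    "q_statistic",
    "match_factors",
    "FactorModel",
    "DEFAULT_ERROR_FRACTIONS",
]

#: Default per-element analytical error fractions.  The XRF accuracy classes
#: are 10% for Cr, Cu, Zn, Zr, Sr, Rb, Fe and 20% for As and Pb; V and Sc
#: have no stated class and default to the conservative 20% (overridable).
DEFAULT_ERROR_FRACTIONS: dict[str, float] = {
    "Cr": 0.10, "Cu": 0.10, "Zn": 0.10, "Zr": 0.10, "Sr": 0.10,
    "Rb": 0.10, "Fe": 0.10,
    "As": 0.20, "Pb": 0.20, "V": 0.20, "Sc": 0.20,
}

_EPS = 1e-12


def build_uncertainty(
    conc: ConcentrationMatrix,
    error_fractions: dict[str, float] | None = None,
    mdl: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-cell measurement uncertainty u_ij, mg/kg.

    Standard EPA-convention combination of a proportional analytical error
    and a detection-limit floor:

        u_ij = sqrt( (f_j * c_ij)^2 + (0.5 * mdl_j)^2 )

    ``error_fractions`` defaults to the 10%/20% accuracy classes; ``mdl``
    (method detection limit) defaults to 0 for every element.
    """
    fractions = dict(DEFAULT_ERROR_FRACTIONS)
    if error_fractions:
        fractions.update(error_fractions)
    mdl = dict(mdl or {})
    u = pd.DataFrame(index=conc.data.index, columns=conc.data.columns, dtype=float)
    for el in conc.element_symbols:
        f = fractions.get(el)
        if f is None:
            raise ValidationError(f"no error fraction for element {el!r}")
        if not 0 < f <= 1:
            raise ValidationError(f"error fraction for {el!r} must be in (0, 1], got {f}")
        m = float(mdl.get(el, 0.0))
        if m < 0:
            raise ValidationError(f"mdl for {el!r} must be >= 0, got {m}")
        u[el] = np.sqrt((f * conc.data[el]) ** 2 + (0.5 * m) ** 2)
    return u


@dataclass
class FactorModel:
    """Fitted PMF solution: X ≈ G F with Q diagnostics."""

    k: int
    contributions: pd.DataFrame  # site × factor, >= 0
    profiles: pd.DataFrame  # factor × element, >= 0
    q_value: float
    seed: int
    converged: bool
    n_iter: int
    q_history: np.ndarray

    @property
    def reconstruction(self) -> pd.DataFrame:
        return self.contributions @ self.profiles


def q_statistic(X: np.ndarray, U: np.ndarray, G: np.ndarray, F: np.ndarray) -> float:
    """Directly-coded Q = sum(((X - G F) / U)^2)."""
    return float((((np.asarray(X) - np.asarray(G) @ np.asarray(F)) / np.asarray(U)) ** 2).sum())


def _run_single(
    X: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    n, m = X.shape
    scale = np.sqrt(X.mean() / max(k, 1))
    G = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    F = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    WX = W * X
    q_prev = q_statistic(X, U, G, F)
    history = [q_prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WR = W * (G @ F)
        G *= (WX @ F.T) / np.maximum(WR @ F.T, _EPS)
        WR = W * (G @ F)
        F *= (G.T @ WX) / np.maximum(G.T @ WR, _EPS)
        q = q_statistic(X, U, G, F)
        history.append(q)
        if q_prev > 0 and abs(q_prev - q) / q_prev < tol:
            converged = True
            q_prev = q
            break
        q_prev = q
    return G, F, q_prev, converged, it, np.asarray(history)


def fit_pmf(
    conc: ConcentrationMatrix,
    unc: pd.DataFrame,
    k: int,
    n_seeds: int = 20,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> FactorModel:
    """Fit PMF with ``k`` factors; best of ``n_seeds`` random restarts.

    Restart s uses the deterministic stream seeded by ``(seed, s)``, so
    results are fully reproducible.  Factors in the returned model are
    ordered by decreasing mean contribution.
    """
    X = conc.values.astype(float)
    n, m = X.shape
    if not 1 <= k < min(n, m):
        raise ValidationError(f"k must satisfy 1 <= k < {min(n, m)}, got {k}")
    U = unc.loc[conc.data.index, conc.data.columns].to_numpy(dtype=float)
    if not np.isfinite(X).all() or not np.isfinite(U).all():
        raise ValidationError("non-finite concentration or uncertainty values")
    if (U <= 0).any():
        raise ValidationError("all uncertainties must be strictly positive")
    W = 1.0 / U**2
    best: tuple | None = None
    for s in range(n_seeds):
        rng = np.random.default_rng([seed, s])
        G, F, q, conv, it, hist = _run_single(X, W, U, k, rng, max_iter, tol)
        if best is None or q < best[2]:
            best = (G, F, q, conv, it, hist, s)
    G, F, q, conv, it, hist, s = best
    order = np.argsort(-G.mean(axis=0))
    G, F = G[:, order], F[order, :]
    factors = [f"F{i + 1}" for i in range(k)]
    return FactorModel(
        k=k,
        contributions=pd.DataFrame(G, index=conc.data.index, columns=factors),
        profiles=pd.DataFrame(F, index=factors, columns=conc.data.columns),
        q_value=q,
        seed=s,
        converged=conv,
        n_iter=it,
        q_history=hist,
    )


def select_factor_count(
    conc: ConcentrationMatrix,
    unc: pd.DataFrame,
    k_candidates=(3, 4, 5),
    n_seeds: int = 20,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> tuple[int, pd.DataFrame]:
    """Fit each candidate k and select by Q/Q_expected closest to 1.

    Returns the selected k and a diagnostics table with one row per
    candidate: best Q, Q_expected = n*m - k*(n+m), their ratio, and the
    run-to-run dispersion (standard deviation of Q over restarts).  Ties in
    |Q/Q_expected - 1| go to the smaller k.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks:
        raise ValidationError("empty candidate set")
    n, m = conc.shape
    X = conc.values.astype(float)
    U = unc.loc[conc.data.index, conc.data.columns].to_numpy(dtype=float)
    W = 1.0 / U**2
    rows = []
    for k in ks:
        if not 2 <= k < min(n, m):
            raise ValidationError(f"candidate k={k} out of range [2, {min(n, m) - 1}]")
        qs = [
            _run_single(X, W, U, k, np.random.default_rng([seed, s]), max_iter, tol)[2]
            for s in range(n_seeds)
        ]
        q_best = min(qs)
        q_exp = n * m - k * (n + m)
        rows.append(
            {
                "k": k,
                "q_best": q_best,
                "q_expected": q_exp,
                "q_ratio": q_best / q_exp if q_exp > 0 else np.inf,
                "q_sd": float(np.std(qs)),
            }
        )
    table = pd.DataFrame(rows)
    dist = (table["q_ratio"] - 1.0).abs()
    k_selected = int(table.loc[dist.idxmin(), "k"])
    return k_selected, table


def summarize_factors(model: FactorModel) -> tuple[pd.DataFrame, pd.Series]:
    """Normalised profiles and mean contribution shares.

    Returns ``(profile_pct, contribution_share)``: ``profile_pct`` rescales
    each element's column of F to percentages summing to 100 (how much of
    each element every factor explains); ``contribution_share`` is each
    factor's mean share of the total site contribution.
    """
    F = model.profiles
    col_sums = F.sum(axis=0)
    profile_pct = 100.0 * F / col_sums.replace(0, np.nan)
    G = model.contributions
    row_tot = G.sum(axis=1)
    share = (G.div(row_tot.replace(0, np.nan), axis=0)).mean(axis=0)
    share.name = "mean_contribution_share"
    return profile_pct, share


def match_factors(
    estimated: pd.DataFrame, planted: pd.DataFrame, normalize: bool = True
) -> pd.DataFrame:
    """Optimal assignment of estimated to planted profiles by cosine similarity.

    Rows of both frames are factor profiles over the same element columns.
    With ``normalize=True`` (default) each element column is first divided
    by the planted profiles' column sum, i.e. profiles are compared in
    fraction-of-element space — the scale on which receptor-model profiles
    are conventionally read — so abundant elements (Fe, Zn) do not dominate
    the similarity.  Returns a table with one row per planted factor: the
    matched estimated factor and the cosine similarity of the pair
    (Hungarian assignment maximising total cosine).
    """
    planted = planted.astype(float)
    estimated = estimated.loc[:, planted.columns].astype(float)
    if normalize:
        scale = planted.sum(axis=0)
        scale[scale <= 0] = 1.0
        planted = planted / scale
        estimated = estimated / scale
    A = planted.to_numpy()
    B = estimated.to_numpy()
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    cos = (A / np.maximum(na, _EPS)) @ (B / np.maximum(nb, _EPS)).T
    ri, ci = linear_sum_assignment(-cos)
    return pd.DataFrame(
        {
            "planted": [planted.index[i] for i in ri],
            "estimated": [estimated.index[j] for j in ci],
            "cosine": [cos[i, j] for i, j in zip(ri, ci)],
        }
    )
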