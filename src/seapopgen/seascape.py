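"""Mantel tests linking genetic differentiation to geography and ocean
transport.

The isolation-by-distance hypothesis predicts a positive correlation
between linearized genetic differentiation (x/(1-x)) and geographic
(shipping) distance; the seascape hypothesis predicts a negative
correlation with oceanographic connectivity (well-connected localities
should differentiate less).  Both are tested with Mantel permutation tests
on the off-diagonal elements of labeled symmetric matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .io import MatrixTable
from .mtdna import slatkin_linearize


class MantelError(ValueError):
    pass


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str  # "greater", "less" or "two-sided"


def _offdiag_vec(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel(
    A: MatrixTable,
    B: MatrixTable,
    n_perm: int = 1000,
    tail: str = "two-sided",
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test of matrix correlation.

    Pearson r over the n(n-1)/2 off-diagonal pairs; row/column order of B is
    permuted jointly; p carries the +1 correction so it never reaches 0.
    ``tail``: "greater" (r* >= r), "less" (r* <= r) or "two-sided"
    (|r*| >= |r|).
    """
    if tail not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if A.labels != B.labels:
        raise MantelError("matrix labels differ")
    n = len(A.labels)
    if n < 4:
        raise MantelError("Mantel test needs >= 4 localities")
    MA = np.asarray(A.values, dtype=float)
    MB = np.asarray(B.values, dtype=float)
    if not np.allclose(MA, MA.T) or not np.allclose(MB, MB.T):
        raise MantelError("matrices must be symmetric")
    va = _offdiag_vec(MA)
    if va.std() == 0 or _offdiag_vec(MB).std() == 0:
        raise MantelError("constant matrix: correlation undefined")

    def corr(M: np.ndarray) -> float:
        vb = _offdiag_vec(M)
        if vb.std() == 0:
            return 0.0
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(MB)
    rng = np.random.default_rng(seed)
    hits = 0
    order = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(order)
        r_star = corr(MB[np.ix_(order, order)])
        if tail == "greater":
            hits += r_star >= r_obs - 1e-12
        elif tail == "less":
            hits += r_star <= r_obs + 1e-12
        else:
            hits += abs(r_star) >= abs(r_obs) - 1e-12
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_perm=n_perm, tail=tail)


def _linearized(genetic: MatrixTable, already_linearized: bool) -> MatrixTable:
    if already_linearized:
        return genetic
    V = np.vectorize(slatkin_linearize)(np.asarray(genetic.values, dtype=float))
    np.fill_diagonal(V, 0.0)
    return MatrixTable(labels=list(genetic.labels), values=V, symmetric=True)


def _pair_table(A: MatrixTable, B: MatrixTable, a_name: str, b_name: str) -> pd.DataFrame:
    labels = A.labels
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {"pop_a": labels[i], "pop_b": labels[j],
                 a_name: A.values[i, j], b_name: B.values[i, j]}
            )
    return pd.DataFrame(rows)


def ibd_report(
    genetic: MatrixTable,
    geographic: MatrixTable,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "greater",
    already_linearized: bool = True,
) -> tuple[MantelResult, pd.DataFrame]:
    """Isolation-by-distance: linearized genetic distance vs km distance.

    One-tailed in the hypothesized positive direction by default; also
    returns the pair table behind the scatter.
    """
    gen = _linearized(genetic, already_linearized)
    res = mantel(gen, geographic, n_perm=n_perm, tail=tail, seed=seed)
    return res, _pair_table(gen, geographic, "linearized_fst", "distance_km")


def connectivity_report(
    genetic: MatrixTable,
    connectivity: MatrixTable,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "less",
    already_linearized: bool = True,
    log_connectivity: bool = False,
) -> tuple[MantelResult, pd.DataFrame]:
    """Linearized genetic distance vs (min-symmetrized) connectivity.

    The hypothesized direction is negative (more exchange, less
    differentiation), hence the default lower tail.  ``log_connectivity``
    applies log10 to positive entries (raw connectivity is the default,
    matching the scatter axis of the study's figures).
    """
    gen = _linearized(genetic, already_linearized)
    C = connectivity
    if log_connectivity:
        V = np.asarray(connectivity.values, dtype=float).copy()
        pos = V > 0
        floor = V[pos].min() / 10 if pos.any() else 1e-12
        V = np.log10(np.where(pos, V, floor))
        np.fill_diagonal(V, 0.0)
        C = MatrixTable(labels=list(connectivity.labels), values=V, symmetric=True)
    res = mantel(gen, C, n_perm=n_perm, tail=tail, seed=seed)
    return res, _pair_table(gen, C, "linearized_fst", "connectivity")
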