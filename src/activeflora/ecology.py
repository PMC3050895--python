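"""Richness, diversity and ordination on family × sample count tables.

Analytic (hypergeometric) rarefaction, the Chao1 and ACE nonparametric
richness estimators with standard errors, the Shannon index (natural
log), and correspondence analysis of the contingency table.  All
estimators operate on a plain vector of per-family counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=np.int64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    return c


def rarefaction(counts, depths) -> np.ndarray:
    """Expected number of families observed in a random subsample.

    E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)], evaluated in log-gamma
    arithmetic; exact (hypergeometric), not Monte-Carlo.
    """
    c = _counts(counts)
    N = int(c.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths < 0).any() or (depths > N).any():
        raise ValueError("depths must be within [0, total count]")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(depths.size, dtype=float)
    for j, n in enumerate(depths):
        miss = np.zeros(c.size)
        ok = (N - c) >= n
        miss[ok] = np.exp(log_choose(N - c[ok], n) - log_choose(N, n))
        out[j] = float((1.0 - miss).sum())
    return out


def rarefaction_mc(counts, depth: int, n_iter: int = 200, seed: int = 0) -> float:
    """Seeded Monte-Carlo rarefaction, for cross-checking the analytic form."""
    c = _counts(counts)
    pool = np.repeat(np.arange(c.size), c)
    rng = np.random.default_rng(seed)
    vals = [np.unique(rng.choice(pool, size=depth, replace=False)).size
            for _ in range(n_iter)]
    return float(np.mean(vals))


def chao1(counts) -> tuple[float, float, str]:
    """Chao1 richness estimate, its standard error and the branch used.

    With doubletons present: S_obs + F1²/(2·F2); otherwise the
    bias-corrected form S_obs + F1(F1−1)/2.  The variance follows the
    classical formulas matching each branch.
    """
    c = _counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        est = s_obs + f1 ** 2 / (2.0 * f2)
        r = f1 / f2
        var = f2 * (r ** 2 / 2.0 + r ** 3 + r ** 4 / 4.0)
        branch = "classic"
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
        var = (f1 * (f1 - 1) / 2.0 + f1 * (2 * f1 - 1) ** 2 / 4.0
               - f1 ** 4 / (4.0 * est)) if f1 > 0 else 0.0
        branch = "bias_corrected"
    return float(est), float(np.sqrt(max(var, 0.0))), branch


def ace(counts, rare_cutoff: int = 10, se_bootstrap: int = 200,
        seed: int = 0) -> tuple[float, float, bool]:
    """Abundance-based coverage estimator (ACE) with a bootstrap SE.

    Families with ≤ ``rare_cutoff`` reads form the rare group; sample
    coverage C = 1 − F1/N_rare; the rare-group CV correction is
    γ² = max(S_rare·Σ i(i−1)F_i / (C·N_rare·(N_rare−1)) − 1, 0) and the
    estimate S_abund + S_rare/C + F1·γ²/C.  When every rare family is a
    singleton (C = 0) the estimator is undefined and the Chao1 value is
    returned with the fallback flag set.  The standard error is a seeded
    multinomial bootstrap over reads.
    """
    c = _counts(counts)
    est, fallback = _ace_point(c, rare_cutoff)
    if se_bootstrap <= 0:
        return est, float("nan"), fallback
    rng = np.random.default_rng(seed)
    n = int(c.sum())
    p = c / n
    reps = np.empty(se_bootstrap)
    for i in range(se_bootstrap):
        bc = rng.multinomial(n, p)
        bc = bc[bc > 0]
        reps[i] = _ace_point(bc, rare_cutoff)[0]
    return est, float(reps.std(ddof=1)), fallback


def _ace_point(c: np.ndarray, rare_cutoff: int) -> tuple[float, bool]:
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund), False
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    cov = 1.0 - f1 / n_rare
    if cov == 0.0:
        return chao1(c)[0], True
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([(rare == k).sum() for k in i])
    if n_rare > 1:
        gamma2 = max(s_rare * float((i * (i - 1) * fi).sum())
                     / (cov * n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return float(s_abund + s_rare / cov + f1 * gamma2 / cov), False


def shannon(counts) -> float:
    """Shannon index H = −Σ p_i ln p_i (natural log; 0·ln 0 = 0)."""
    c = _counts(counts).astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class DiversityStats:
    """Per-sample richness/diversity summary."""
    sample: str
    s_obs: int
    chao1: float
    chao1_se: float
    chao1_branch: str
    ace: float
    ace_se: float
    ace_fallback: bool
    shannon: float
    f1: int
    f2: int


def diversity_table(counts_table: pd.DataFrame, rare_cutoff: int = 10,
                    seed: int = 0) -> pd.DataFrame:
    """Diversity estimators for every sample column of a family × sample
    count table (layout of the published per-sample estimator table)."""
    rows = []
    for sample in counts_table.columns:
        c = counts_table[sample].to_numpy()
        c = c[c > 0]
        ch, ch_se, branch = chao1(c)
        a, a_se, fb = ace(c, rare_cutoff=rare_cutoff, seed=seed)
        rows.append(DiversityStats(sample, int(c.size), ch, ch_se, branch,
                                   a, a_se, fb, shannon(c),
                                   int((c == 1).sum()), int((c == 2).sum())))
    return pd.DataFrame([vars(r) for r in rows]).set_index("sample")


@dataclass
class OrdinationResult:
    """Correspondence analysis output.

    Principal coordinates for rows and columns, singular values of the
    standardized residual matrix, per-axis inertia fractions and the total
    inertia (= Pearson χ²/N of the table).
    """
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    inertia_fractions: np.ndarray
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame) -> OrdinationResult:
    """Correspondence analysis of a family × sample count table.

    P = table/N; S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}; the SVD of S gives
    principal coordinates D^{-1/2} U Σ (rows) and D^{-1/2} V Σ (columns).
    All-zero rows/columns are dropped with a warning.  Axis signs are
    fixed by making the first nonzero row loading of each axis positive.
    """
    t = table.to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        import warnings
        warnings.warn("dropping all-zero rows/columns before ordination")
    t = t[np.ix_(keep_r, keep_c)]
    if t.size == 0 or t.sum() == 0:
        raise ValueError("rank-0 table")
    rows = table.index[keep_r]
    cols = table.columns[keep_c]
    total = t.sum()
    P = t / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # drop the (numerically) null trailing dimension of the residual space
    k = min(t.shape) - 1
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k, :]
    for ax in range(k):
        nz = np.flatnonzero(np.abs(U[:, ax]) > 1e-12)
        if nz.size and U[nz[0], ax] < 0:
            U[:, ax] = -U[:, ax]
            Vt[ax, :] = -Vt[ax, :]
    row_pc = (U * sv) / np.sqrt(r)[:, None]
    col_pc = (Vt.T * sv) / np.sqrt(c)[:, None]
    inertia = float((sv ** 2).sum())
    frac = (sv ** 2) / inertia if inertia > 0 else np.zeros(k)
    axes = [f"CA{i + 1}" for i in range(k)]
    return OrdinationResult(pd.DataFrame(row_pc, index=rows, columns=axes),
                            pd.DataFrame(col_pc, index=cols, columns=axes),
                            sv, frac, inertia)
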