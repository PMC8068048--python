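"""Statistical stage: method error, paired side comparison, correlation tables,
principal-component loadings with Varimax rotation, and paired-design power.

The paired comparison operates on a cohort table whose columns are
``<variable>_DS`` / ``<variable>_NDS`` (deviated / non-deviated side).  The
power analysis uses the paired (one-sample-on-differences) noncentral-t model:
for effect size dz = mean(diff)/sd(diff), the test statistic under the
alternative is noncentral t with df = n - 1 and noncentrality dz * sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (ConstantColumn, DegenerateVariance, InvalidSpec,
                     LengthMismatch, NonConvergence, RankDeficient)

#: Full per-side variable vocabulary of the study (craniofacial morphology,
#: TMJ morphometry, TMJ function), in report order.
CM_VARIABLES = ["MxH", "RH", "FRI", "LRI", "BL"]
TM_VARIABLES = ["APCP", "TCP", "VCP", "AJS", "SJS", "PJS", "MJS", "LJS",
                "ACA", "AES", "PES", "MES", "LES"]
TF_VARIABLES = ["OCPL", "PCPL", "SCI", "TCI", "BA", "NCPL", "NIPL"]
ALL_VARIABLES = CM_VARIABLES + TM_VARIABLES + TF_VARIABLES

#: Default 16-variable subset entering the factor analysis (extracapsular
#: posture and the posterior/lateral space and steepness variables excluded).
FACTOR_VARIABLES = ["MxH", "RH", "FRI", "LRI", "BL",
                    "AJS", "SJS", "MJS", "ACA", "AES", "MES",
                    "OCPL", "PCPL", "SCI", "NIPL", "NCPL"]


def dahlberg_error(first, second) -> float:
    """Dahlberg method error ``sqrt(sum d_i^2 / (2 n))`` for duplicate measurements."""
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise LengthMismatch("first/second must be 1-d arrays of equal length")
    if a.size < 2:
        raise LengthMismatch("need at least 2 paired measurements")
    d = a - b
    return float(np.sqrt(np.sum(d * d) / (2.0 * d.size)))


@dataclass(frozen=True)
class PairedResult:
    variable: str
    n: int
    mean_ds: float
    sd_ds: float
    mean_nds: float
    sd_nds: float
    t: float
    p: float
    normality_p: float

    @property
    def mean_diff(self) -> float:
        return self.mean_ds - self.mean_nds


def paired_compare(cohort: pd.DataFrame, variables=None) -> list[PairedResult]:
    """Paired t-test (DS vs NDS) per variable, with Shapiro-Wilk normality p on
    the differences reported alongside (not used as a gate)."""
    if variables is None:
        variables = [v for v in ALL_VARIABLES if f"{v}_DS" in cohort.columns]
    out = []
    for var in variables:
        ds = cohort[f"{var}_DS"].to_numpy(dtype=float)
        nds = cohort[f"{var}_NDS"].to_numpy(dtype=float)
        if np.any(np.isnan(ds)) or np.any(np.isnan(nds)):
            raise ValueError(f"missing DS/NDS pair for {var}")
        diff = ds - nds
        if np.std(diff, ddof=1) < 1e-12:
            if np.max(np.abs(diff)) < 1e-12:  # identical sides: no evidence
                out.append(PairedResult(var, diff.size,
                                        float(np.mean(ds)), float(np.std(ds, ddof=1)),
                                        float(np.mean(nds)), float(np.std(nds, ddof=1)),
                                        0.0, 1.0, float("nan")))
                continue
            raise DegenerateVariance(f"constant nonzero DS-NDS differences for {var}")
        t, p = sps.ttest_rel(ds, nds)
        sw = sps.shapiro(diff).pvalue if diff.size >= 3 else np.nan
        out.append(PairedResult(var, diff.size,
                                float(np.mean(ds)), float(np.std(ds, ddof=1)),
                                float(np.mean(nds)), float(np.std(nds, ddof=1)),
                                float(t), float(p), float(sw)))
    return out


def correlation_table(cohort: pd.DataFrame, row_vars, col_vars, side: str
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for each (row, col) pair on one side's columns.

    p is from ``t = r sqrt((n-2)/(1-r^2))`` with n-2 degrees of freedom.
    """
    if side not in ("DS", "NDS"):
        raise ValueError("side must be 'DS' or 'NDS'")
    r_mat = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    p_mat = pd.DataFrame(index=row_vars, columns=col_vars, dtype=float)
    for rv in row_vars:
        x = cohort[f"{rv}_{side}"].to_numpy(dtype=float)
        if np.std(x) < 1e-12:
            raise ConstantColumn(f"{rv}_{side} is constant")
        for cv in col_vars:
            y = cohort[f"{cv}_{side}"].to_numpy(dtype=float)
            if np.std(y) < 1e-12:
                raise ConstantColumn(f"{cv}_{side} is constant")
            r, p = sps.pearsonr(x, y)
            r_mat.loc[rv, cv] = r
            p_mat.loc[rv, cv] = p
    return r_mat, p_mat


@dataclass
class FactorModel:
    loadings: pd.DataFrame          # variables x components
    eigenvalues: np.ndarray         # all eigenvalues, descending
    n_components: int
    rotation: str = "none"
    kaiser_normalized: bool = False
    n_eigen_gt1: int = 0
    rotation_matrix: np.ndarray | None = None

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)


def _fix_column_signs(L: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive (sign is arbitrary)."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def pca_loadings(X: pd.DataFrame, k: int = 4) -> FactorModel:
    """Principal-component loadings of the correlation matrix of ``X``.

    Loadings are eigenvectors scaled by sqrt(eigenvalue), first ``k`` by
    descending eigenvalue.  The count of eigenvalues > 1 (the Kaiser criterion
    the scree inspection would use) is reported alongside.
    """
    Xv = X.to_numpy(dtype=float)
    if np.any(np.std(Xv, axis=0) < 1e-12):
        raise ConstantColumn("constant column in factor-analysis input")
    C = np.corrcoef(Xv, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    if evals.min() < -1e-8:
        raise RankDeficient("correlation matrix not PSD within tolerance")
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(k, len(evals))
    L = evecs[:, :k] * np.sqrt(evals[:k])
    L = _fix_column_signs(L)
    cols = [f"C{j + 1}" for j in range(k)]
    return FactorModel(pd.DataFrame(L, index=list(X.columns), columns=cols),
                       eigenvalues=evals, n_components=k,
                       n_eigen_gt1=int(np.sum(evals > 1.0)))


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: sum over components of the variance of squared loadings."""
    sq = L ** 2
    return float(np.sum(np.mean(sq ** 2, axis=0) - np.mean(sq, axis=0) ** 2))


def varimax(loadings, kaiser_normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by sequential pairwise planar rotations.

    With ``kaiser_normalize`` the rows are scaled to unit communality before
    rotation and rescaled after (Kaiser normalization).  Returns the rotated
    loadings and the orthogonal rotation matrix ``T`` with ``rotated = L @ T``.
    Communalities are preserved exactly by orthogonality (asserted).
    """
    L0 = np.asarray(loadings, dtype=float)
    p, k = L0.shape
    h = np.sqrt(np.sum(L0 ** 2, axis=1))
    if kaiser_normalize:
        if np.any(h < 1e-12):
            raise ValueError("zero-communality row cannot be Kaiser-normalized")
        W = L0 / h[:, None]
    else:
        W = L0.copy()
    T = np.eye(k)
    if k >= 2:
        for _ in range(max_iter):
            old = varimax_criterion(W)
            for i in range(k - 1):
                for j in range(i + 1, k):
                    x, y = W[:, i], W[:, j]
                    u = x ** 2 - y ** 2
                    v = 2.0 * x * y
                    # closed-form optimal planar angle (Kaiser 1958)
                    num = 2.0 * (p * np.sum(u * v) - np.sum(u) * np.sum(v))
                    den = p * np.sum(u ** 2 - v ** 2) - (np.sum(u) ** 2 - np.sum(v) ** 2)
                    phi = 0.25 * np.arctan2(num, den)
                    if abs(phi) < 1e-14:
                        continue
                    c, s = np.cos(phi), np.sin(phi)
                    G = np.array([[c, -s], [s, c]])
                    W[:, [i, j]] = W[:, [i, j]] @ G
                    T[:, [i, j]] = T[:, [i, j]] @ G
            if abs(varimax_criterion(W) - old) < tol:
                break
        else:
            raise NonConvergence(f"varimax did not converge in {max_iter} sweeps")
    R = W * h[:, None] if kaiser_normalize else W
    # orthogonal rotation preserves row communalities; guard numerically
    assert np.allclose(np.sum(R ** 2, axis=1), np.sum(L0 ** 2, axis=1), atol=1e-9)
    return R, T


def rotate_factors(model: FactorModel, kaiser_normalize: bool = True) -> FactorModel:
    """Varimax-rotate a factor model, ordering components by explained variance
    and fixing column signs for determinism."""
    R, T = varimax(model.loadings.to_numpy(), kaiser_normalize=kaiser_normalize)
    order = np.argsort(np.sum(R ** 2, axis=0))[::-1]
    R = _fix_column_signs(R[:, order])
    cols = [f"C{j + 1}" for j in range(R.shape[1])]
    return FactorModel(pd.DataFrame(R, index=model.loadings.index, columns=cols),
                       eigenvalues=model.eigenvalues,
                       n_components=model.n_components, rotation="varimax",
                       kaiser_normalized=kaiser_normalize,
                       n_eigen_gt1=model.n_eigen_gt1, rotation_matrix=T[:, order])


def power_paired_t(dz: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at effect size dz and n pairs.

    ``P(|T'| > t_{1-alpha/2, n-1})`` where T' is noncentral t with df = n - 1
    and noncentrality dz * sqrt(n); both tails are included.
    """
    if n < 2:
        raise InvalidSpec("need n >= 2")
    if not 0 < alpha < 1:
        raise InvalidSpec("alpha must be in (0, 1)")
    df = n - 1
    nc = dz * np.sqrt(n)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    upper = sps.nct.sf(tc, df, nc)
    lower = sps.nct.cdf(-tc, df, nc)
    if np.isnan(lower):  # far tail at large noncentrality: numerically zero
        lower = 0.0
    return float(upper + lower)


def min_n_paired_t(dz: float, target_power: float = 0.80, alpha: float = 0.05,
                   n_max: int = 100000) -> int:
    """Smallest n >= 2 whose paired-t power reaches ``target_power`` (exact search)."""
    if dz <= 0:
        raise InvalidSpec("effect size must be positive")
    n = 2
    while power_paired_t(dz, n, alpha) < target_power:
        n += 1
        if n > n_max:
            raise InvalidSpec("no n below n_max reaches the target power")
    return n


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values (optional; the primary reports are unadjusted)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
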