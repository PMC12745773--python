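"""Fixed-effects least squares with cluster-robust inference.

The regression absorbs department-by-year and department-by-day-of-year fixed
effects by alternating within-group demeaning (Frisch-Waugh-Lovell: the
resulting slopes equal explicit dummy-variable OLS), computes a CR1 cluster
sandwich covariance with departments as clusters, and propagates coefficient
uncertainty by drawing from the multivariate normal implied by the point
estimates and that covariance (500 draws by default).

Degrees of freedom count the absorbed fixed effects: K = kept regressors +
G1 + G2 - (connected components of the two grouping factors), the standard
small-sample accounting for two-way within estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .design import DesignInfo, DesignMatrix
from .errors import NumericalError

_FE_COLLINEAR_RMS = 1e-6  # on unit-RMS-scaled columns: variance below 1e-12


def _demean(
    Z: np.ndarray,
    groups: list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, int]:
    """Residualize the columns of Z on every grouping by alternating
    within-group demeaning, iterated until the largest group mean of any
    column falls below ``tol``."""
    Z = np.array(Z, dtype=float, copy=True)
    mats = []
    for codes in groups:
        n_g = int(codes.max()) + 1
        S = sparse.csr_matrix(
            (np.ones(len(codes)), (codes, np.arange(len(codes)))),
            shape=(n_g, len(codes)),
        )
        cnt = np.bincount(codes, minlength=n_g).astype(float)
        if (cnt == 0).any():
            raise NumericalError("fixed-effect group with zero rows")
        mats.append((S, cnt, codes))
    last = np.inf
    for it in range(1, max_iter + 1):
        last = 0.0
        for S, cnt, codes in mats:
            m = (S @ Z) / cnt[:, None]
            Z -= m[codes]
            last = max(last, float(np.abs(m).max()))
        if last < tol:
            return Z, it
    raise NumericalError(
        f"fixed-effect absorption did not converge in {max_iter} iterations "
        f"(final change {last:.3e})"
    )


def absorb_fixed_effects(
    design: DesignMatrix, tol: float = 1e-10, max_iter: int = 10_000
) -> DesignMatrix:
    """Return a copy of the design with outcome and regressors residualized
    on both fixed-effect dimensions.

    Columns are internally scaled to unit RMS during the sweeps so the
    absolute tolerance is meaningful for every column, then unscaled.
    """
    scale = np.sqrt(np.mean(design.X**2, axis=0))
    scale[scale == 0] = 1.0
    Z = np.hstack([design.y[:, None], design.X / scale])
    Zd, _ = _demean(Z, list(design.fe_codes), tol=tol, max_iter=max_iter)
    out = DesignMatrix(
        X=Zd[:, 1:] * scale,
        y=Zd[:, 0],
        columns=list(design.columns),
        fe_codes=design.fe_codes,
        fe_sizes=design.fe_sizes,
        clusters=design.clusters,
        cluster_ids=list(design.cluster_ids),
        index=design.index,
        n_dropped_missing_lags=design.n_dropped_missing_lags,
        n_dropped_zero_deaths=design.n_dropped_zero_deaths,
        info=design.info,
    )
    return out


def _n_connected_components(fe1: np.ndarray, fe2: np.ndarray, sizes: tuple[int, int]) -> int:
    g1, g2 = sizes
    A = sparse.coo_matrix(
        (np.ones(len(fe1)), (fe1, fe2)), shape=(g1, g2)
    ).tocsr()
    graph = sparse.bmat([[None, A], [A.T, None]], format="csr")
    n, _ = connected_components(graph, directed=False)
    return int(n)


def cluster_robust_vcov(
    X: np.ndarray,
    resid: np.ndarray,
    clusters: np.ndarray,
    dof_k: int,
) -> np.ndarray:
    """CR1 sandwich on an (already demeaned) design.

    (X'X)^-1 (sum_g X_g' u_g u_g' X_g) (X'X)^-1 scaled by
    G/(G-1) * (N-1)/(N-K), with K counting absorbed fixed effects.
    """
    from ._kernels import cluster_scores

    labels = np.unique(clusters)
    G, N = len(labels), len(resid)
    if G < 2:
        raise NumericalError("cluster-robust covariance needs >= 2 clusters")
    XtX_inv = np.linalg.inv(X.T @ X)
    clusters = np.ascontiguousarray(clusters, dtype=np.int64)
    H = cluster_scores(X, resid, clusters, int(clusters.max()) + 1)
    meat = H.T @ H
    scale = (G / (G - 1)) * ((N - 1) / (N - dof_k))
    return scale * XtX_inv @ meat @ XtX_inv


@dataclass
class FittedModel:
    """Point estimates, covariances, and metadata of one fitted regression."""

    params: pd.Series
    vcov: pd.DataFrame  # cluster-robust (CR1, clustered by department)
    vcov_classical: pd.DataFrame
    n_obs: int
    n_clusters: int
    fe_sizes: tuple[int, int]
    n_components: int
    dof_k: int
    dropped_columns: list[str]
    info: DesignInfo
    period: tuple[int, int] | None
    n_absorb_iter: int
    resid: np.ndarray = field(repr=False)

    @property
    def spec(self):
        return self.info.spec

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def save_bundle(self, prefix: str | Path) -> list[Path]:
        """Write coefficients and covariance as plain CSV for external tools."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        coef_path = prefix.with_suffix(".coef.csv")
        vcov_path = prefix.with_suffix(".vcov.csv")
        self.params.rename("estimate").to_csv(coef_path, index_label="term")
        self.vcov.to_csv(vcov_path, index_label="term")
        return [coef_path, vcov_path]


def fit(
    design: DesignMatrix,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FittedModel:
    """Estimate the design by least squares with two-way FE absorption.

    Columns demeaned to (numerically) zero are collinear with the fixed
    effects and are dropped with a warning; genuine rank deficiency among the
    remaining regressors raises an error naming the offending set.
    """
    from ._kernels import demean_sweep, pooled

    n, K = design.X.shape
    scale = np.sqrt(np.mean(design.X**2, axis=0))
    degenerate = scale == 0
    scale_safe = np.where(degenerate, 1.0, scale)
    Z = pooled("fit_Z", (n, K + 1))
    Z[:, 0] = design.y
    np.divide(design.X, scale_safe[None, :], out=Z[:, 1:])

    sweeps = []
    for gi, codes in enumerate(design.fe_codes):
        codes = np.ascontiguousarray(codes, dtype=np.int64)
        n_g = int(codes.max()) + 1
        cnt = np.bincount(codes, minlength=n_g).astype(float)
        if (cnt == 0).any():
            raise NumericalError("fixed-effect group with zero rows")
        m = pooled(f"fit_m{gi}", (n_g, K + 1))
        sweeps.append((codes, cnt, m))
    n_iter = 0
    for it in range(1, max_iter + 1):
        last = 0.0
        for codes, cnt, m in sweeps:
            last = max(last, demean_sweep(Z, codes, cnt, m))
        n_iter = it
        if last < tol:
            break
    else:
        raise NumericalError(
            f"fixed-effect absorption did not converge in {max_iter} iterations "
            f"(final change {last:.3e})"
        )
    yd, Xd = Z[:, 0], Z[:, 1:]

    demeaned_rms = np.sqrt(np.mean(Xd**2, axis=0))
    keep = (~degenerate) & (demeaned_rms > _FE_COLLINEAR_RMS)
    dropped = [c for c, k in zip(design.columns, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} column(s) collinear with fixed effects: {dropped}",
            stacklevel=2,
        )
    Xk = Xd if keep.all() else np.ascontiguousarray(Xd[:, keep])
    names = [c for c, k in zip(design.columns, keep) if k]
    if Xk.shape[1] == 0:
        raise NumericalError("no regressors survive fixed-effect absorption")

    XtX = Xk.T @ Xk
    eigvals = np.linalg.eigvalsh(XtX)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1.0):
        # identify the collinear set via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(Xk, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise NumericalError(f"rank-deficient design; collinear columns: {bad}")

    beta_s = np.linalg.solve(XtX, Xk.T @ yd)
    resid = yd - Xk @ beta_s

    fe1, fe2 = design.fe_codes
    g1, g2 = design.fe_sizes
    n_comp = _n_connected_components(fe1, fe2, design.fe_sizes)
    dof_k = Xk.shape[1] + g1 + g2 - n_comp
    N = len(yd)
    G = len(np.unique(design.clusters))

    V_s = cluster_robust_vcov(Xk, resid, design.clusters, dof_k)
    XtX_inv = np.linalg.inv(XtX)
    sigma2 = float(resid @ resid) / (N - dof_k)
    Vc_s = sigma2 * XtX_inv

    s = scale[keep]
    beta = beta_s / s
    V = V_s / np.outer(s, s)
    Vc = Vc_s / np.outer(s, s)

    return FittedModel(
        params=pd.Series(beta, index=names),
        vcov=pd.DataFrame(V, index=names, columns=names),
        vcov_classical=pd.DataFrame(Vc, index=names, columns=names),
        n_obs=N,
        n_clusters=G,
        fe_sizes=design.fe_sizes,
        n_components=n_comp,
        dof_k=dof_k,
        dropped_columns=dropped,
        info=design.info,
        period=design.info.period,
        n_absorb_iter=n_iter,
        resid=resid,
    )


@dataclass
class CoefficientSamples:
    """Multivariate-normal draws of the coefficient vector (default n=500)."""

    draws: pd.DataFrame  # n_samples x K
    seed: int | None
    fitted: FittedModel

    @property
    def n_samples(self) -> int:
        return len(self.draws)

    @property
    def draw_ids(self) -> np.ndarray:
        return self.draws.index.to_numpy()

    @property
    def info(self) -> DesignInfo:
        return self.fitted.info

    @property
    def spec(self):
        return self.fitted.spec

    @property
    def period(self):
        return self.fitted.period

    def save(self, path: str | Path) -> None:
        self.draws.to_csv(path, index_label="draw")


def sample_coefficients(
    fitted: FittedModel, n: int = 500, seed: int | None = None
) -> CoefficientSamples:
    """Draw n coefficient vectors from MVN(beta-hat, V-hat).

    The covariance is symmetrized and its eigenvalues clipped at zero before
    the symmetric square-root factorization, so a PSD-up-to-noise matrix is
    accepted; non-finite entries are an error.
    """
    V = fitted.vcov.to_numpy()
    if not np.isfinite(V).all():
        raise NumericalError("covariance matrix has non-finite entries")
    Vs = (V + V.T) / 2.0
    vals, vecs = np.linalg.eigh(Vs)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(vals)))
    draws = fitted.params.to_numpy()[None, :] + z @ root.T
    return CoefficientSamples(
        draws=pd.DataFrame(draws, columns=fitted.params.index, index=pd.RangeIndex(n)),
        seed=seed,
        fitted=fitted,
    )
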