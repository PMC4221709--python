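"""Kinship-corrected mixed linear models for genome scans.

The model is the standard single-component animal model

    y = X b + u + e,   u ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I)

with K a genomic relationship matrix.  Variance components are estimated by
REML, profiling the likelihood over the heritability ratio
h2 = sigma2_g / (sigma2_g + sigma2_e) on a grid refined by golden-section
search — a derivative-free strategy that is robust for this one-parameter
profile.  Per-SNP association uses the score test: genotypes are projected
against the covariates in the metric of the fitted inverse covariance and
tested against the null-model residuals, so no per-SNP variance re-fit is
required.

`PolygenicModel.fit()` returns a `PolygenicResults` object carrying the
variance components, heritability, fixed effects, null residuals and the
spectral decomposition needed for scanning; `PolygenicResults.score_scan()`
produces an `AssocResult` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "genomic_kinship",
    "PolygenicModel",
    "PolygenicResults",
    "AssocResult",
    "fit_polygenic",
    "score_scan",
]

_EPS = 1e-10


class DegenerateInputError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with its sample index."""

    values: np.ndarray
    ids: list[str]
    autosomal_only: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("kinship matrix / id index shape mismatch")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        try:
            rows = np.array([pos[i] for i in ids])
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} absent from kinship matrix")
        return KinshipMatrix(
            self.values[np.ix_(rows, rows)].copy(), list(ids), self.autosomal_only
        )


def genomic_kinship(
    g: GenotypeMatrix, autosomes_only: bool = True
) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    Dosages are centred by twice the sample allele frequency and the
    cross-product scaled by sum(2 p (1-p)); monomorphic SNPs (and, with
    ``autosomes_only``, sex-chromosome SNPs) are excluded.  Missing dosages
    are mean-imputed for this computation only.
    """
    mask = g.autosomal_mask() if autosomes_only else np.ones(g.n_snps, dtype=bool)
    d = g.dosages_float()[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise DegenerateInputError("all SNPs monomorphic; kinship undefined")
    d, p = d[:, poly], p[poly]
    if g.n_samples < 2 or d.shape[1] < 10:
        raise DegenerateInputError(
            f"need >= 2 samples and >= 10 usable SNPs, have "
            f"{g.n_samples} x {d.shape[1]}"
        )
    Z = np.where(np.isnan(d), 0.0, d - 2 * p)  # NaN -> mean == centred 0
    denom = float((2 * p * (1 - p)).sum())
    K = (Z @ Z.T) / denom
    K = 0.5 * (K + K.T)
    return KinshipMatrix(K, list(g.samples["iid"]), autosomal_only=autosomes_only)


class PolygenicModel:
    """Single-component polygenic model for one trait in one stratum.

    Parameters
    ----------
    y : trait values (n,), no missing entries
    X : fixed-effect design (n, p), full rank, should include an intercept
    kinship : KinshipMatrix aligned with y (or an (n, n) array)
    ids : sample ids; required to align when kinship has its own index
    """

    def __init__(self, y, X, kinship, ids: list[str] | None = None):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        if isinstance(kinship, KinshipMatrix):
            if ids is not None and list(ids) != list(kinship.ids):
                kinship = kinship.submatrix(list(ids))
            K = kinship.values
        else:
            K = np.asarray(kinship, dtype=float)
        n = y.size
        if K.shape != (n, n) or X.shape[0] != n:
            raise ValueError("y, X and kinship dimensions disagree")
        if np.isnan(y).any():
            raise ValueError("y contains missing values; drop them first")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate design is rank deficient")
        self.y, self.X, self.K = y, X, K
        self.ids = list(ids) if ids is not None else None
        self.n, self.p = n, X.shape[1]
        if self.n - self.p < 5:
            raise DegenerateInputError("too few residual degrees of freedom")
        s, U = np.linalg.eigh(K)
        self._s = np.maximum(s, 0.0)
        self._U = U
        self._yt = U.T @ y
        self._Xt = U.T @ X

    # -- REML profile ------------------------------------------------------

    def _profile(self, h2: float):
        """REML quantities at a fixed heritability ratio."""
        ll, sigma2_p, b, XtWX = profile_reml(h2, self._s, self._Xt, self._yt)
        d = np.maximum(h2 * self._s + (1.0 - h2), _EPS)
        return ll, sigma2_p, b, XtWX, d

    def reml_loglike(self, h2: float) -> float:
        """Profile REML log-likelihood (constants dropped) at h2."""
        return self._profile(h2)[0]

    def fit(
        self,
        h2: float | None = None,
        total_variance: float | None = None,
        n_grid: int = 50,
        tol: float = 1e-6,
    ) -> "PolygenicResults":
        """Estimate variance components by REML.

        ``h2`` fixes the heritability ratio instead of estimating it;
        ``total_variance`` fixes sigma2_g + sigma2_e (useful when the
        covariance is known exactly, e.g. oracle comparisons).  The profile
        is bracketed on an ``n_grid``-point grid over [0, 1) and refined by
        golden-section search to ``tol``.
        """
        boundary = False
        identifiable = True
        if h2 is None:
            grid = np.linspace(0.0, 0.999, n_grid)
            lls = np.array([self._profile(x)[0] for x in grid])
            if not np.all(np.isfinite(lls)):
                raise ConvergenceError(
                    f"non-finite REML profile at grid points "
                    f"{grid[~np.isfinite(lls)][:3]}"
                )
            if lls.max() - lls.min() < 1e-8:
                identifiable = False  # flat profile: K carries no signal
                h2_hat = 0.0
            else:
                k = int(np.argmax(lls))
                lo = grid[max(k - 1, 0)]
                hi = grid[min(k + 1, n_grid - 1)]
                h2_hat = _golden_section(lambda x: self._profile(x)[0], lo, hi, tol)
            if h2_hat < 1e-3 or h2_hat > 0.99:
                boundary = True
        else:
            if not 0.0 <= h2 < 1.0:
                raise ValueError("h2 must lie in [0, 1)")
            h2_hat = float(h2)
        ll, sigma2_p, b, XtWX, d = self._profile(h2_hat)
        if total_variance is not None:
            sigma2_p = float(total_variance)
        fe_cov = np.linalg.inv(XtWX) * sigma2_p
        resid = self.y - self.X @ b
        return PolygenicResults(
            model=self,
            h2=float(h2_hat),
            sigma2_g=float(h2_hat * sigma2_p),
            sigma2_e=float((1.0 - h2_hat) * sigma2_p),
            fe_params=b,
            fe_se=np.sqrt(np.diag(fe_cov)),
            llf=float(ll),
            resid_null=resid,
            boundary=boundary,
            identifiable=identifiable,
            _d=d,
            _sigma2_p=float(sigma2_p),
        )


@dataclass
class PolygenicResults:
    """REML fit of the polygenic model.

    Carries the variance components, heritability, fixed effects with
    standard errors, the null-model residuals, and the spectral factors of
    the fitted covariance used by `score_scan`.
    """

    model: PolygenicModel
    h2: float
    sigma2_g: float
    sigma2_e: float
    fe_params: np.ndarray
    fe_se: np.ndarray
    llf: float
    resid_null: np.ndarray
    boundary: bool
    identifiable: bool
    _d: np.ndarray = field(repr=False, default=None)
    _sigma2_p: float = field(repr=False, default=np.nan)

    @property
    def converged(self) -> bool:
        return np.isfinite(self.llf)

    def summary(self) -> str:
        lines = [
            "Polygenic model (REML)",
            "=" * 46,
            f"{'n observations':<28}{self.model.n:>18}",
            f"{'fixed effects':<28}{self.model.p:>18}",
            f"{'sigma2_g (genetic)':<28}{self.sigma2_g:>18.6g}",
            f"{'sigma2_e (residual)':<28}{self.sigma2_e:>18.6g}",
            f"{'h2':<28}{self.h2:>18.4f}",
            f"{'REML log-likelihood':<28}{self.llf:>18.4f}",
        ]
        if self.boundary:
            lines.append("warning: estimate at parameter boundary")
        if not self.identifiable:
            lines.append("warning: flat profile; variance split unidentifiable")
        lines.append("-" * 46)
        lines.append(f"{'coef':<10}{'estimate':>18}{'se':>18}")
        for j, (b, se) in enumerate(zip(self.fe_params, self.fe_se)):
            lines.append(f"{'x' + str(j):<10}{b:>18.6g}{se:>18.6g}")
        return "\n".join(lines)

    def score_scan(self, g: GenotypeMatrix) -> "AssocResult":
        """Kinship-corrected score test for every SNP.

        For SNP genotype vector g, centred and projected against the
        covariates in the V^-1 metric (V the fitted covariance):

            beta = g~' V^-1 r / (g~' V^-1 g~),  se = (g~' V^-1 g~)^(-1/2)

        with r the null-model residuals; (beta/se)^2 is referred to
        chi-square(1).  Missing dosages are mean-imputed inside the
        statistic; n counts non-missing calls.  Monomorphic SNPs are
        flagged untested.
        """
        mdl = self.model
        if mdl.ids is not None and list(g.samples["iid"]) != mdl.ids:
            pos = {iid: i for i, iid in enumerate(g.samples["iid"])}
            rows = np.array([pos[i] for i in mdl.ids])
            g = g.subset(samples=rows)
        if g.n_samples != mdl.n:
            raise ValueError("genotype samples not aligned with the fit")

        D = g.dosages_float()
        n_obs = (~np.isnan(D)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(D, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        G = np.where(np.isnan(D), 2 * freq, D) - 2 * freq  # centred, imputed

        w = 1.0 / (self._sigma2_p * self._d)
        Gt = mdl._U.T @ G
        WG = Gt * w[:, None]
        rt = mdl._U.T @ self.resid_null
        num = WG.T @ rt
        XtWG = mdl._Xt.T @ WG
        XtWX = mdl._Xt.T @ (mdl._Xt * w[:, None])
        den = np.einsum("ij,ij->j", Gt, WG) - np.einsum(
            "ij,ij->j", XtWG, np.linalg.solve(XtWX, XtWG)
        )

        tested = (maf > 0) & np.isfinite(maf) & (den > _EPS) & (n_obs > 0)
        beta = np.full(g.n_snps, np.nan)
        se = np.full(g.n_snps, np.nan)
        chisq = np.full(g.n_snps, np.nan)
        pval = np.full(g.n_snps, np.nan)
        beta[tested] = num[tested] / den[tested]
        se[tested] = 1.0 / np.sqrt(den[tested])
        chisq[tested] = num[tested] ** 2 / den[tested]
        pval[tested] = stats.chi2.sf(chisq[tested], df=1)
        reason = np.where(tested, "", "monomorphic_or_degenerate")

        table = pd.DataFrame(
            {
                "chrom": g.snps["chrom"].to_numpy(),
                "snp": g.snps["snp"].to_numpy(),
                "bp": g.snps["bp"].to_numpy(),
                "beta": beta,
                "se": se,
                "chisq": chisq,
                "p": pval,
                "maf": maf,
                "n": n_obs,
                "tested": tested,
                "reason": reason,
            }
        )
        return AssocResult(table)


@dataclass
class AssocResult:
    """Per-SNP association scan results.

    Columns: chrom, snp, bp, beta, se, chisq, p, maf, n, tested, reason.
    """

    table: pd.DataFrame

    def significant(self, threshold: float) -> pd.DataFrame:
        t = self.table
        return t[t["tested"] & (t["p"] < threshold)]

    def min_p(self) -> float:
        p = self.table.loc[self.table["tested"], "p"]
        return float(p.min()) if len(p) else np.nan

    def manhattan_table(self) -> pd.DataFrame:
        t = self.table[self.table["tested"]]
        return pd.DataFrame(
            {
                "snp": t["snp"],
                "chrom": t["chrom"],
                "bp": t["bp"],
                "neglog10p": -np.log10(np.maximum(t["p"], 1e-300)),
            }
        )

    def write(self, path) -> None:
        out = self.table.rename(
            columns={
                "chrom": "CHR", "snp": "SNP", "bp": "BP", "beta": "BETA",
                "se": "SE", "chisq": "CHISQ", "p": "P", "maf": "MAF",
                "n": "N", "tested": "TESTED", "reason": "REASON",
            }
        )
        out.to_csv(path, sep="\t", index=False)


def profile_reml(h2: float, s: np.ndarray, Xt: np.ndarray, yt: np.ndarray):
    """REML profile quantities at heritability ratio h2, given the kinship
    spectrum.

    ``s`` are the eigenvalues of K; ``Xt`` and ``yt`` the design and trait
    rotated into the eigenbasis.  Returns (loglike, sigma2_p, b, XtWX) with
    sigma2_p the profiled total variance.  Exposed so batch procedures
    (e.g. permutation tests over many traits) can reuse one decomposition.
    """
    n, p = Xt.shape
    d = np.maximum(h2 * s + (1.0 - h2), _EPS)
    w = 1.0 / d
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    L = np.linalg.cholesky(XtWX)
    b = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ b
    rss = float(np.sum(w * r * r))
    nm = n - p
    sigma2_p = rss / nm
    logdet_xtwx = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (nm * np.log(sigma2_p) + float(np.log(d).sum()) + logdet_xtwx + nm)
    return ll, sigma2_p, b, XtWX


def reml_h2(s: np.ndarray, Xt: np.ndarray, yt: np.ndarray,
            n_grid: int = 50, tol: float = 1e-6) -> float:
    """Maximise the REML profile over h2 in [0, 1): grid bracket plus
    golden-section refinement.  Spectrum-space companion of
    `PolygenicModel.fit` for batch callers."""
    grid = np.linspace(0.0, 0.999, n_grid)
    lls = np.array([profile_reml(x, s, Xt, yt)[0] for x in grid])
    if not np.all(np.isfinite(lls)):
        raise ConvergenceError("non-finite REML profile")
    if lls.max() - lls.min() < 1e-8:
        return 0.0
    k = int(np.argmax(lls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    return _golden_section(lambda x: profile_reml(x, s, Xt, yt)[0], lo, hi, tol)


def _golden_section(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section maximisation of a unimodal f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def fit_polygenic(y, covariates, K, ids=None, **kwargs) -> PolygenicResults:
    """Convenience wrapper: build a PolygenicModel and fit it."""
    return PolygenicModel(y, covariates, K, ids=ids).fit(**kwargs)


def score_scan(fit: PolygenicResults, g: GenotypeMatrix) -> AssocResult:
    """Convenience wrapper over `PolygenicResults.score_scan`."""
    return fit.score_scan(g)
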