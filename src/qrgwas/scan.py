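"""Per-marker association scans: quantile regression and the general linear model.

Both methods fit, marker by marker, the single-marker model

    Y = μ + α_j·SNP_j + Σ_k β_k·CP_k + ε

with the leading principal components CP of the genomic relationship
matrix as fixed-effect structure covariates.

Quantile regression estimates θ at quantile τ by minimising the check
loss ρ_τ(ε) = τε for ε ≥ 0 and (τ − 1)ε otherwise, solved as a linear
program.  Marker significance comes from the regression rank-score test:
the τ-quantile fit of the covariate-only model yields rank scores
b_i = τ − 1{ε̂_i < 0} (taken exactly from the LP dual, so Z′b = 0), and
the statistic T_j = x̃_j′ b / sqrt(τ(1−τ)·x̃_j′x̃_j) — with x̃_j the
marker residualised on the covariates — is referred to N(0, 1).
Only the covariate model has to be fitted per (data, τ), which makes a
2000-marker scan a single LP plus matrix products.

The general linear model is ordinary least squares with the usual t-test
on α_j, computed through Frisch–Waugh residualisation (numerically equal
to the full OLS fit, verified in the tests against statsmodels).

All marker p-values of a scan are corrected jointly by the
Benjamini–Hochberg step-up adjustment (Storey's π₀-estimated q-value is
available as an option); markers are called significant at q ≤ α = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.optimize import linprog
from statsmodels.stats.multitest import multipletests

DEFAULT_TAUS = (0.10, 0.50, 0.90)
DEFAULT_ALPHA = 0.01


# ---------------------------------------------------------------------------
# primitives

def check_loss(residual, tau: float):
    """Check-function loss ρ_τ(ε): τε if ε ≥ 0, (τ − 1)ε if ε < 0."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (0, 1)")
    eps = np.asarray(residual, float)
    return np.where(eps >= 0, tau * eps, (tau - 1.0) * eps)


@dataclass(frozen=True)
class QuantRegFit:
    """Solution of the check-loss linear program."""

    params: np.ndarray
    objective: float
    residuals: np.ndarray
    rank_scores: np.ndarray   # LP duals: b_i = τ − 1{ε̂_i < 0}, X′b = 0
    tau: float


def fit_quantile_model(y: np.ndarray, X: np.ndarray, tau: float) -> QuantRegFit:
    """Minimise Σ ρ_τ(y_i − x_i′θ) by linear programming (HiGHS).

    Standard primal form with split positive/negative residuals:
    min τ·1′u⁺ + (1−τ)·1′u⁻ subject to Xθ + u⁺ − u⁻ = y, u± ≥ 0.
    The equality-constraint duals are the regression rank scores.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (0, 1)")
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    A = sp.hstack([sp.csc_matrix(X), sp.eye(n, format="csc"),
                   -sp.eye(n, format="csc")], format="csc")
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A, b_eq=y, bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"quantile LP did not converge: {res.message}")
    theta = res.x[:p]
    resid = y - X @ theta
    duals = np.asarray(res.eqlin.marginals, float)
    # LP sign convention: rank scores must equal tau - 1{eps<0} off the
    # basis; flip if the solver reports negated marginals.
    nz = np.abs(resid) > 1e-9
    expect = tau - (resid[nz] < 0)
    if np.abs(duals[nz] - expect).sum() > np.abs(duals[nz] + expect).sum():
        duals = -duals
    return QuantRegFit(params=theta, objective=float(res.fun),
                       residuals=resid, rank_scores=duals, tau=tau)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Project the columns of M off the column space of Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def qr_rank_score_test(y: np.ndarray, Z: np.ndarray, markers: np.ndarray,
                       tau: float, fit: QuantRegFit | None = None):
    """Rank-score p-values for H0: α_j = 0, one per marker column.

    ``Z`` is the reduced design (intercept + covariates); ``markers`` may
    be one column or an (n × M) matrix.  Returns (pvalues, statistics).
    """
    markers = np.asarray(markers, float)
    one_col = markers.ndim == 1
    Xm = markers[:, None] if one_col else markers
    if fit is None:
        fit = fit_quantile_model(y, Z, tau)
    b = fit.rank_scores
    Xt = _residualize(Xm, Z)
    ss = np.einsum("ij,ij->j", Xt, Xt)
    if np.any(ss <= 1e-10 * Xm.shape[0]):
        raise np.linalg.LinAlgError(
            "a marker is collinear with the covariates")
    T = (Xt.T @ b) / np.sqrt(tau * (1.0 - tau) * ss)
    p = 2.0 * stats.norm.sf(np.abs(T))
    return (float(p[0]), float(T[0])) if one_col else (p, T)


def fit_ols_model(y: np.ndarray, X: np.ndarray, marker_col: int = 1):
    """OLS fit with the usual t-test on the marker coefficient.

    Returns (params, marker p-value, full statsmodels results).  The
    marker is column ``marker_col`` of the design (default: right after
    the intercept).
    """
    import statsmodels.api as sm

    X = np.atleast_2d(np.asarray(X, float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(np.asarray(y, float), X).fit()
    return res.params, float(res.pvalues[marker_col]), res


def qvalues(pvalues, method: str = "bh", lam: float = 0.5) -> np.ndarray:
    """FDR-adjusted q-values (monotone, order-preserving, in [0, 1]).

    ``bh``: Benjamini–Hochberg step-up adjusted p-values (default).
    ``storey``: BH multiplied by the π₀ estimate min(1, #{p > λ}/((1−λ)m)).
    """
    p = np.asarray(pvalues, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        q = np.minimum(pi0 * q, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    return q


# ---------------------------------------------------------------------------
# scan configuration and results

@dataclass(frozen=True)
class ScanConfig:
    """How one scan is run: method, quantile, FDR level."""

    method: str = "GLM"            # "QR" or "GLM"
    tau: float | None = None       # required for QR
    alpha: float = DEFAULT_ALPHA
    qvalue_method: str = "bh"
    effects: str = "none"          # QR effect estimation: none|significant|all

    def __post_init__(self):
        if self.method not in ("QR", "GLM"):
            raise ValueError("method must be 'QR' or 'GLM'")
        if self.method == "QR":
            if self.tau is None or not 0.0 < self.tau < 1.0:
                raise ValueError("QR requires tau strictly inside (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.effects not in ("none", "significant", "all"):
            raise ValueError("effects must be none|significant|all")

    @property
    def label(self) -> str:
        return "GLM" if self.method == "GLM" else f"QR({self.tau:.2f})"


@dataclass
class GWASResults:
    """Per-marker results of one scan (one method / one quantile)."""

    table: pd.DataFrame            # marker, chrom, pos_cM, effect, statistic,
                                   # pvalue, qvalue, significant
    config: ScanConfig
    n_individuals: int
    n_covariates: int
    skipped: pd.DataFrame          # marker, reason

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy(bool)

    @property
    def significant_marker_idx(self) -> np.ndarray:
        """Genome-order indices of significant markers."""
        return self.table.loc[self.table["significant"], "marker_idx"].to_numpy()

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def summary(self) -> str:
        c = self.config
        lines = [
            f"{c.label} marker scan",
            "=" * 40,
            f"individuals:        {self.n_individuals}",
            f"structure PCs:      {self.n_covariates}",
            f"markers tested:     {len(self.table)}",
            f"markers skipped:    {len(self.skipped)} (monomorphic)",
            f"FDR level (q <=):   {c.alpha}",
            f"significant:        {self.n_significant}",
        ]
        top = self.table.nsmallest(min(10, len(self.table)), "qvalue")
        lines.append("-" * 40)
        lines.append(top[["marker", "chrom", "pos_cM", "statistic",
                          "pvalue", "qvalue"]].to_string(index=False))
        return "\n".join(lines)


class _MarkerScan:
    """Shared scaffolding of the two scan models (statsmodels-style)."""

    def __init__(self, y, genotypes, covariates=None, marker_ids=None,
                 marker_chrom=None, marker_pos=None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(genotypes, float)
        n, m = self.X.shape
        if self.y.size != n:
            raise ValueError("phenotype / genotype dimension mismatch")
        C = None if covariates is None else np.asarray(covariates, float)
        if C is not None and C.shape[0] != n:
            raise ValueError("covariate dimension mismatch")
        self.covariates = C
        self.Z = np.column_stack([np.ones(n)] + ([C] if C is not None else []))
        self.marker_ids = list(marker_ids) if marker_ids is not None \
            else [f"M{j + 1}" for j in range(m)]
        self.marker_chrom = np.asarray(marker_chrom) if marker_chrom is not None \
            else np.zeros(m, int)
        self.marker_pos = np.asarray(marker_pos, float) if marker_pos is not None \
            else np.arange(m, dtype=float)
        self.tested = self.X.std(axis=0) > 0
        if not self.tested.any():
            raise ValueError("no polymorphic markers to test")

    @classmethod
    def from_population(cls, pop, y, covariates=None, **kw):
        gmap = pop.gmap
        return cls(y, pop.marker_dosages, covariates=covariates,
                   marker_ids=gmap.marker_ids, marker_chrom=gmap.marker_chrom,
                   marker_pos=gmap.marker_pos, **kw)

    def _package(self, config, pvals, stats_, effects):
        idx = np.flatnonzero(self.tested)
        q = qvalues(pvals, method=config.qvalue_method)
        sig = q <= config.alpha
        table = pd.DataFrame({
            "marker": [self.marker_ids[j] for j in idx],
            "marker_idx": idx,
            "chrom": self.marker_chrom[idx],
            "pos_cM": self.marker_pos[idx],
            "effect": effects,
            "statistic": stats_,
            "pvalue": pvals,
            "qvalue": q,
            "significant": sig,
        })
        skipped = pd.DataFrame({
            "marker": [self.marker_ids[j]
                       for j in np.flatnonzero(~self.tested)],
            "reason": "monomorphic",
        })
        return GWASResults(table=table, config=config,
                           n_individuals=self.y.size,
                           n_covariates=self.Z.shape[1] - 1, skipped=skipped)


class LinearGWAS(_MarkerScan):
    """Single-marker OLS scan (the paper-style general linear model).

    Marker effects and t-tests are computed via Frisch–Waugh
    residualisation on the covariate design, which reproduces the full
    per-marker OLS fit exactly (same α̂_j, standard error and p-value).
    """

    def fit(self, alpha: float = DEFAULT_ALPHA, qvalue_method: str = "bh",
            config: ScanConfig | None = None) -> GWASResults:
        config = config or ScanConfig(method="GLM", alpha=alpha,
                                      qvalue_method=qvalue_method)
        Xt = _residualize(self.X[:, self.tested], self.Z)
        yt = _residualize(self.y, self.Z)
        ss = np.einsum("ij,ij->j", Xt, Xt)
        beta = (Xt.T @ yt) / ss
        df = self.y.size - self.Z.shape[1] - 1
        rss = yt @ yt - beta ** 2 * ss
        sigma2 = rss / df
        tstat = beta / np.sqrt(sigma2 / ss)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        return self._package(config, pvals, tstat, beta)


class QuantileGWAS(_MarkerScan):
    """Single-marker quantile-regression scan at one quantile τ.

    Significance comes from the regression rank-score test anchored on
    the covariate-only τ-fit; per-marker effect estimates require one LP
    each and are therefore opt-in (``effects='significant'`` refits only
    the markers that pass the FDR threshold).
    """

    def __init__(self, y, genotypes, tau, covariates=None, **kw):
        super().__init__(y, genotypes, covariates=covariates, **kw)
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must lie strictly inside (0, 1)")
        self.tau = float(tau)

    def fit(self, alpha: float = DEFAULT_ALPHA, qvalue_method: str = "bh",
            effects: str = "none", config: ScanConfig | None = None
            ) -> GWASResults:
        config = config or ScanConfig(method="QR", tau=self.tau, alpha=alpha,
                                      qvalue_method=qvalue_method,
                                      effects=effects)
        null_fit = fit_quantile_model(self.y, self.Z, self.tau)
        pvals, tstat = qr_rank_score_test(
            self.y, self.Z, self.X[:, self.tested], self.tau, fit=null_fit)
        eff = np.full(pvals.size, np.nan)
        res = self._package(config, pvals, tstat, eff)
        if config.effects != "none":
            which = np.flatnonzero(res.table["significant"]) \
                if config.effects == "significant" else np.arange(pvals.size)
            cols = res.table["marker_idx"].to_numpy()
            for r in which:
                Xj = np.column_stack(
                    [self.Z[:, :1], self.X[:, cols[r]], self.Z[:, 1:]])
                f = fit_quantile_model(self.y, Xj, self.tau)
                res.table.iloc[r, res.table.columns.get_loc("effect")] = \
                    f.params[1]
        return res


def scan(pop, Y, covariates, config: ScanConfig) -> GWASResults:
    """Run one configured scan on a population sample.

    ``covariates`` may be a :class:`~qrgwas.structure.StructureCovariates`
    or a plain (n × K) array; monomorphic markers are skipped and listed
    in the result.
    """
    C = getattr(covariates, "scores", covariates)
    if config.method == "GLM":
        model = LinearGWAS.from_population(pop, Y, covariates=C)
        return model.fit(config=config)
    model = QuantileGWAS.from_population(pop, Y, tau=config.tau, covariates=C)
    return model.fit(config=config)
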