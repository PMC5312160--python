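"""Negative binomial GLM over the two-factorial RIP-Seq design.

The model for gene g in library i is

    y_gi ~ NB(mu_gi, phi_g),   Var = mu + phi * mu^2
    log mu_gi = x_i' beta_g + o_i

with a cell-means (one-hot) design over the six (IP, treatment) cells
``Ago.miR, IgG.miR, TL.miR, Ago.control, IgG.control, TL.control`` and
offsets ``o_i = ln(effective library size_i)``.  Comparisons of interest
are linear contrasts c'beta tested with likelihood-ratio tests against the
constrained model c'beta = 0; p-values are Benjamini-Hochberg adjusted.

All fitting is batched across genes: one IRLS iteration updates every
gene simultaneously via einsum-built normal equations, which keeps
5000-gene fits in the seconds range on one core.

:class:`NegativeBinomialLRT` packages design building, Cox-Reid dispersion
estimation, fitting and contrast testing as a scikit-learn estimator whose
samples are libraries (``X`` of shape ``(n_libraries, n_genes)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CELL_ORDER",
    "NegativeBinomialLRT",
    "build_design_matrix",
    "validate_design",
    "estimate_dispersion",
    "fit_nbglm",
    "lrt_contrast",
    "bh_adjust",
    "GLMFit",
]

#: fixed column order of the cell-means design matrix
CELL_ORDER = (
    "Ago.miR",
    "IgG.miR",
    "TL.miR",
    "Ago.control",
    "IgG.control",
    "TL.control",
)

TREATMENT_LEVELS = ("miR", "control")
IP_LEVELS = ("Ago", "IgG", "TL")

_MIN_MU = 1e-10
_BETA_FLOOR = -30.0  # ln scale; cells with no signal are capped here


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet with columns library_id, treatment, ip, replicate."""
    required = {"library_id", "treatment", "ip", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"sample sheet is missing columns: {sorted(missing)}")
    if design["library_id"].duplicated().any():
        dup = design.loc[design["library_id"].duplicated(), "library_id"].iloc[0]
        raise ValueError(f"duplicate library_id {dup!r} in sample sheet")
    bad_t = set(design["treatment"]) - set(TREATMENT_LEVELS)
    if bad_t:
        raise ValueError(f"unknown treatment level(s) {sorted(bad_t)}; expected {TREATMENT_LEVELS}")
    bad_ip = set(design["ip"]) - set(IP_LEVELS)
    if bad_ip:
        raise ValueError(f"unknown ip level(s) {sorted(bad_ip)}; expected {IP_LEVELS}")
    cells = {f"{ip}.{tr}" for ip, tr in zip(design["ip"], design["treatment"])}
    empty = [c for c in CELL_ORDER if c not in cells]
    if empty:
        raise ValueError(f"design cell(s) with no library: {empty}")
    return design


def build_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """One-hot cell-means design matrix (libraries x 6), fixed column order.

    Each row selects the (IP, treatment) cell of one library, so the GLM
    coefficients are offset-adjusted natural-log cell means.
    """
    validate_design(design)
    cell = design["ip"].astype(str) + "." + design["treatment"].astype(str)
    dm = pd.DataFrame(
        0.0, index=pd.Index(design["library_id"], name="library_id"), columns=list(CELL_ORDER)
    )
    for lib, c in zip(design["library_id"], cell):
        dm.loc[lib, c] = 1.0
    return dm


# ---------------------------------------------------------------------------
# likelihoods


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over libraries.

    ``y``/``mu`` are (genes x libraries), ``phi`` a per-gene vector;
    phi = 0 degenerates to the Poisson log-likelihood.
    """
    mu = np.maximum(mu, _MIN_MU)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(y.shape[0])
    pois = phi <= 0
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = np.sum(yp * np.log(mp) - mp - special.gammaln(yp + 1), axis=1)
    if (~pois).any():
        yn, mn = y[~pois], mu[~pois]
        r = 1.0 / phi[~pois, None]
        out[~pois] = np.sum(
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn)),
            axis=1,
        )
    return out


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance (2 * (saturated ll - model ll))."""
    mu = np.maximum(mu, _MIN_MU)
    phi = np.asarray(phi, dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        nbpart = np.where(
            phi > 0,
            (y + 1.0 / np.where(phi > 0, phi, 1.0))
            * np.log((1.0 + phi * mu) / (1.0 + phi * y)),
            mu - y,
        )
    return 2.0 * np.sum(term1 + nbpart, axis=1)


# ---------------------------------------------------------------------------
# batched IRLS


@dataclass
class GLMFit:
    """Result of a batched NB GLM fit."""

    beta: np.ndarray  # (genes x p) natural-log scale
    mu: np.ndarray  # (genes x libraries) fitted means
    loglik: np.ndarray  # (genes,)
    deviance: np.ndarray  # (genes,)
    converged: np.ndarray  # (genes,) bool
    dispersion: np.ndarray  # (genes,)
    design: np.ndarray = field(repr=False, default=None)
    offsets: np.ndarray = field(repr=False, default=None)


def _as_offsets(offsets, n_genes: int, n_libs: int) -> np.ndarray:
    offsets = np.asarray(offsets, dtype=float)
    if offsets.ndim == 1:
        offsets = np.broadcast_to(offsets, (n_genes, n_libs))
    if offsets.shape != (n_genes, n_libs):
        raise ValueError("offsets must be length n_libraries or genes x libraries")
    return offsets


def fit_nbglm(
    counts,
    design_matrix,
    offsets,
    dispersion,
    *,
    tol: float = 1e-8,
    max_iter: int = 50,
    ridge: float = 1e-6,
) -> GLMFit:
    """Fit per-gene NB GLMs with log link and offsets by batched IRLS.

    Parameters
    ----------
    counts : array or DataFrame, genes x libraries
    design_matrix : array or DataFrame, libraries x p
    offsets : length-n_libraries vector (or genes x libraries matrix) of
        natural-log effective library sizes
    dispersion : scalar or per-gene vector of NB dispersions (0 = Poisson)

    Convergence is declared per gene when the relative deviance change
    drops below ``tol``; singular weighted crossproducts receive a ridge
    jitter.  Cells without any count are capped at a floor on the ln scale
    and the gene is still reported converged once the deviance stabilises.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n_genes, n_libs = y.shape
    if X.shape[0] != n_libs:
        raise ValueError("design matrix rows must match number of libraries")
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    offsets = _as_offsets(offsets, n_genes, n_libs)
    phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,)).copy()
    if (phi < 0).any():
        raise ValueError("dispersions must be non-negative")

    # starting values: weighted least squares on log-adjusted counts
    z0 = np.log(y + 0.5) - offsets
    beta = z0 @ np.linalg.pinv(X).T

    eye = np.eye(p)
    dev_old = np.full(n_genes, np.inf)
    converged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ X.T + offsets
        mu = np.exp(np.clip(eta, _BETA_FLOOR, 50.0))
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offsets) + (y - mu) / np.maximum(mu, _MIN_MU)
        xtwx = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
        xtwz = np.einsum("sp,gs,gs->gp", X, w, z, optimize=True)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.linalg.solve(xtwx + ridge * eye, xtwz[..., None])[..., 0]
        if not np.isfinite(new_beta).all():
            new_beta = np.linalg.solve(xtwx + ridge * eye, xtwz[..., None])[..., 0]
        new_beta = np.clip(new_beta, _BETA_FLOOR, 50.0)
        beta = np.where(converged[:, None], beta, new_beta)

        mu = np.exp(np.clip(beta @ X.T + offsets, _BETA_FLOOR, 50.0))
        dev = _nb_deviance(y, mu, phi)
        delta = np.abs(dev - dev_old) / (np.abs(dev) + 0.1)
        converged = converged | (delta < tol)
        dev_old = dev
        if converged.all():
            break

    eta = np.clip(beta @ X.T + offsets, _BETA_FLOOR, 50.0)
    mu = np.exp(eta)
    return GLMFit(
        beta=beta,
        mu=mu,
        loglik=_nb_loglik(y, mu, phi),
        deviance=_nb_deviance(y, mu, phi),
        converged=converged,
        dispersion=phi,
        design=X,
        offsets=offsets,
    )


# ---------------------------------------------------------------------------
# dispersion estimation (Cox-Reid adjusted profile likelihood)


def _cr_apl(y, X, offsets, phi) -> np.ndarray:
    """Per-gene Cox-Reid adjusted profile log-likelihood at dispersion phi."""
    fit = fit_nbglm(y, X, offsets, phi, tol=1e-6, max_iter=25)
    w = fit.mu / (1.0 + fit.dispersion[:, None] * fit.mu)
    xtwx = np.einsum("sp,gs,sq->gpq", X, w, X, optimize=True)
    sign, logdet = np.linalg.slogdet(xtwx + 1e-10 * np.eye(X.shape[1]))
    return fit.loglik - 0.5 * logdet


def _golden_max(fun, lo: float, hi: float, n_iter: int = 40):
    """Vectorised golden-section maximisation over log10(phi) brackets.

    ``fun`` maps a vector of phi values to a vector of objective values;
    ``lo``/``hi`` may be scalars (common) or per-gene arrays.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a = np.atleast_1d(np.asarray(lo, dtype=float)).copy()
    b = np.atleast_1d(np.asarray(hi, dtype=float)).copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = fun(10.0**c)
    fd = fun(10.0**d)
    for _ in range(n_iter):
        take_c = fc > fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = fun(10.0**c)
        fd = fun(10.0**d)
        if np.max(b - a) < 1e-4:
            break
    mid = (a + b) / 2.0
    return 10.0**mid


def estimate_dispersion(
    counts,
    design_matrix,
    offsets,
    mode: str = "shrunk",
    *,
    prior_weight: float = 10.0,
    log10_bounds: tuple[float, float] = (-6.0, 1.5),
) -> np.ndarray:
    """Estimate NB dispersions by maximising the Cox-Reid APL.

    Modes
    -----
    ``common``
        One dispersion maximising the APL summed over genes, returned
        broadcast per gene.
    ``genewise``
        Per-gene APL maximiser (golden-section per gene).
    ``shrunk`` (default)
        Per-gene maximiser of ``APL_g(phi) + prior_weight * APLbar(phi)``
        where ``APLbar`` is the across-gene mean profile: genewise values
        are shrunk toward the common value with a prior weight equivalent
        to ``prior_weight`` genes.
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    n_genes = y.shape[0]
    offs = _as_offsets(offsets, n_genes, y.shape[1])
    lo, hi = log10_bounds

    def common_profile(phi_vec):
        return _cr_apl(y, X, offs, np.broadcast_to(phi_vec, (n_genes,)))

    if mode == "common":
        phi = _golden_max(
            lambda f: np.array([np.sum(common_profile(f[0]))]), lo, hi
        )
        return np.full(n_genes, float(phi[0]))

    if mode == "genewise":
        phi = _golden_max(
            lambda f: _cr_apl(y, X, offs, f),
            np.full(n_genes, lo),
            np.full(n_genes, hi),
        )
        return phi

    if mode == "shrunk":
        # mean APL profile on a grid, spline-interpolated for arbitrary phi
        from scipy.interpolate import CubicSpline

        grid = np.linspace(lo, hi, 41)
        mean_apl = np.array([np.mean(common_profile(10.0**g)) for g in grid])
        spline = CubicSpline(grid, mean_apl)

        def objective(phi_vec):
            apl = _cr_apl(y, X, offs, phi_vec)
            return apl + prior_weight * spline(np.log10(phi_vec))

        return _golden_max(objective, np.full(n_genes, lo), np.full(n_genes, hi))

    raise ValueError(f"unknown dispersion mode {mode!r}")


# ---------------------------------------------------------------------------
# contrasts, LRT and multiplicity


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _null_space_design(X: np.ndarray, contrast: np.ndarray) -> np.ndarray:
    """Reduced design spanning the null hypothesis c'beta = 0."""
    basis = linalg.null_space(contrast[None, :])
    X0 = X @ basis
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("reduced design under the contrast is singular")
    return X0


def lrt_contrast(
    counts,
    design_matrix,
    offsets,
    dispersion,
    contrast,
    *,
    full_fit: GLMFit | None = None,
    gene_ids=None,
    contrast_name: str = "contrast",
    zero_cell_prior: float = 0.125,
) -> pd.DataFrame:
    """Likelihood-ratio test of one linear contrast for every gene.

    Refits each gene under the constraint ``c'beta = 0`` (design projected
    onto the contrast's null space); the statistic ``2 (ll_full - ll_null)``
    is referred to chi-square with 1 df.  ``log2fc = c'beta / ln 2`` — the
    regression coefficients are estimated fold changes on the log2 scale.

    When every library of a cell entering the contrast has a zero count the
    fold change is recomputed from prior-augmented cell means
    (``zero_cell_prior`` reads per library, scaled by library size) to
    avoid reporting infinities; the test statistic is unaffected.
    """
    contrast = np.asarray(contrast, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    if contrast.shape != (X.shape[1],):
        raise ValueError("contrast length must equal the number of design columns")
    if np.all(contrast == 0):
        raise ValueError("contrast must not be all zeros")
    y = np.asarray(counts, dtype=float)
    n_genes, n_libs = y.shape
    offs = _as_offsets(offsets, n_genes, n_libs)

    if full_fit is None:
        full_fit = fit_nbglm(y, X, offs, dispersion)
    X0 = _null_space_design(X, contrast)
    null_fit = fit_nbglm(y, X0, offs, full_fit.dispersion)

    lrt = 2.0 * (full_fit.loglik - null_fit.loglik)
    lrt = np.clip(lrt, 0.0, None)
    p = stats.chi2.sf(lrt, df=1)
    log2fc = full_fit.beta @ contrast / np.log(2.0)

    # guard against infinite fold changes from empty cells
    used = contrast != 0
    cell_zero = np.einsum("gs,sp->gp", (y > 0).astype(float), X) == 0
    bad = cell_zero[:, used].any(axis=1)
    if bad.any():
        lib_size = np.exp(offs)
        prior = zero_cell_prior * lib_size / lib_size.mean(axis=1, keepdims=True)
        adj = np.log2((y[bad] + prior[bad]) / lib_size[bad])
        cell_counts = X.sum(axis=0)
        cell_means = (adj @ X) / cell_counts
        log2fc[bad] = cell_means @ contrast

    return pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids) if gene_ids is not None else np.arange(n_genes),
            "contrast_name": contrast_name,
            "log2fc": log2fc,
            "lrt_stat": lrt,
            "p_value": p,
            "fdr": bh_adjust(p),
            "zero_cell": bad,
        }
    )


# ---------------------------------------------------------------------------
# estimator facade


class NegativeBinomialLRT(BaseEstimator):
    """Negative binomial GLM contrast testing over a factorial design.

    A mass-univariate estimator: each gene (feature) gets its own NB
    regression on the shared cell-means design, after which the configured
    linear contrasts are tested by likelihood-ratio tests with
    Benjamini-Hochberg adjustment per contrast.

    Parameters
    ----------
    contrasts : dict of name -> length-6 coefficient vector over
        :data:`CELL_ORDER`.  Defaults to the three background-correcting
        comparisons from :func:`agoripseq.targets.builtin_contrasts`.
    dispersion : {"shrunk", "common", "genewise"} or float
        Dispersion estimation mode, or a fixed known value.
    prior_weight : float
        Shrinkage prior weight (in genes) for mode "shrunk".

    Attributes
    ----------
    dispersion_ : ndarray, per-gene dispersions used.
    coef_ : ndarray (n_genes, 6), natural-log cell means (offset adjusted).
    results_ : dict of contrast name -> per-gene result DataFrame.
    """

    def __init__(
        self,
        contrasts: dict | None = None,
        dispersion="shrunk",
        prior_weight: float = 10.0,
        tol: float = 1e-8,
        max_iter: int = 50,
    ):
        self.contrasts = contrasts
        self.dispersion = dispersion
        self.prior_weight = prior_weight
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, design, offsets=None, gene_ids=None):
        """Fit the GLM and test all contrasts.

        Parameters
        ----------
        X : libraries x genes count matrix (array or DataFrame).
        design : sample sheet DataFrame (library_id, treatment, ip,
            replicate) aligned with the rows of ``X``.
        offsets : optional natural-log effective library sizes; defaults
            to ``ln`` of raw totals.
        """
        from .targets import builtin_contrasts  # local import to avoid cycle

        if isinstance(X, pd.DataFrame):
            if gene_ids is None:
                gene_ids = np.asarray(X.columns)
            X = X.to_numpy()
        y = np.asarray(X, dtype=float).T  # genes x libraries
        dm = build_design_matrix(design)
        if dm.shape[0] != y.shape[1]:
            raise ValueError("design does not match number of libraries")
        if offsets is None:
            offsets = np.log(y.sum(axis=0))

        contrasts = self.contrasts
        if contrasts is None:
            contrasts = {c.name: c.coefficients for c in builtin_contrasts()}

        if isinstance(self.dispersion, str):
            self.dispersion_ = estimate_dispersion(
                y, dm.to_numpy(), offsets, mode=self.dispersion,
                prior_weight=self.prior_weight,
            )
        else:
            self.dispersion_ = np.broadcast_to(
                np.asarray(self.dispersion, dtype=float), (y.shape[0],)
            ).copy()

        fit = fit_nbglm(
            y, dm.to_numpy(), offsets, self.dispersion_,
            tol=self.tol, max_iter=self.max_iter,
        )
        self.fit_ = fit
        self.coef_ = fit.beta
        self.design_matrix_ = dm
        self.offsets_ = np.asarray(offsets, dtype=float)
        self.results_ = {}
        for name, coefs in contrasts.items():
            self.results_[name] = lrt_contrast(
                y, dm.to_numpy(), offsets, self.dispersion_, np.asarray(coefs),
                full_fit=fit, gene_ids=gene_ids, contrast_name=name,
            )
        return self

    def log2_fold_changes(self) -> pd.DataFrame:
        """Wide per-gene table of estimated log2 fold changes per contrast."""
        if not hasattr(self, "results_"):
            raise ValueError("estimator is not fitted")
        cols = {n: r.set_index("gene_id")["log2fc"] for n, r in self.results_.items()}
        return pd.DataFrame(cols)
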