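"""Bayesian phylogenetic mixed model ("animal model") by Gibbs sampling.

Univariate model for a trait y over n species related by a phylogenetic
covariance matrix A::

    y = mu + a + e,   a ~ N(0, sigma2_a * A),   e ~ N(0, sigma2_e * I)

Phylogenetic signal is the heritability-like ratio
``rho = sigma2_a / (sigma2_a + sigma2_e)`` — the proportion of among-species
variance attributable to the phylogeny.

The bivariate model stacks two traits with a 2x2 phylogenetic covariance
``Sigma_P`` (Kronecker with A) and a 2x2 residual covariance ``Sigma_E``
(Kronecker with I); the correlations implied by ``Sigma_P``, ``Sigma_E`` and
their sum are reported per posterior draw. The "phylogeny-adjusted"
correlation is taken from the residual component, with the phylogenetic and
total-component correlations always reported alongside.

Sampling exploits the eigendecomposition A = U diag(d) U': rotating the data
by U' diagonalises the phylogenetic precision, so the latent-effect update
costs O(n) (univariate) or n independent 2x2 solves (bivariate) per sweep.
Variance components get conjugate inverse-gamma / inverse-Wishart updates
with the weakly-informative parameterisation (shape nu/2, scale nu*V/2;
bivariate scale nu*V, degrees of freedom nu).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PMMConfig",
    "UnivariatePMMResult",
    "BivariatePMMResult",
    "fit_univariate",
    "fit_bivariate",
    "rho_from_samples",
    "hpd_interval",
    "pmcmc",
    "effective_sample_size",
    "geweke_z",
    "convergence_report",
    "posterior_mode",
]

_EIG_FLOOR = 1e-8


@dataclass
class PMMConfig:
    """MCMC settings and priors for a phylogenetic mixed-model fit.

    ``prior_v`` is the prior scale (scalar for univariate, 2x2 for
    bivariate; ``None`` picks 1 or the identity) and ``prior_nu`` the prior
    degree of belief: inverse-gamma(shape nu/2, scale nu*V/2) on each
    variance, inverse-Wishart(scale nu*V, df nu) on each covariance matrix.
    """

    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10
    prior_v: float | np.ndarray | None = None
    prior_nu: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_nu is not None and self.prior_nu <= 0:
            raise ValueError("prior_nu must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @classmethod
    def from_dict(cls, d: dict) -> "PMMConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


def _decompose_relatedness(A: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigendecomposition of A with an eigenvalue floor ("bending")."""
    A = np.asarray(A, dtype=float)
    A = 0.5 * (A + A.T)
    d, U = np.linalg.eigh(A)
    bent = bool(d.min() < _EIG_FLOOR)
    if bent:
        logger.warning(
            "phylogenetic covariance is singular or near-singular "
            "(min eigenvalue %.3g); bending eigenvalues to %.0e",
            d.min(),
            _EIG_FLOOR,
        )
        d = np.maximum(d, _EIG_FLOOR)
    return d, U, bent


def posterior_mode(draws: np.ndarray) -> float:
    """Posterior mode via a Gaussian kernel density (Silverman bandwidth)."""
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties between equally short windows are broken by the lowest start.
    Requires at least 100 draws.
    """
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 100:
        raise ValueError(f"hpd_interval needs >= 100 draws, got {n}")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    k = math.ceil(mass * n)
    widths = draws[k - 1 :] - draws[: n - k + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k - 1])


def pmcmc(draws) -> float:
    """MCMC two-sided sign probability: twice the smaller tail fraction,
    floored at 1/n_draws and capped at 1."""
    draws = np.asarray(draws, dtype=float)
    n = draws.size
    if n < 100:
        raise ValueError(f"pmcmc needs >= 100 draws, got {n}")
    p = 2.0 * min(np.mean(draws > 0), np.mean(draws < 0))
    return float(min(max(p, 1.0 / n), 1.0))


def effective_sample_size(draws) -> float:
    """ESS from the integrated autocorrelation time (Geyer's initial
    monotone positive sequence estimator)."""
    x = np.asarray(draws, dtype=float)
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return float(n)
    x = x - x.mean()
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] <= 0:
        return float(n)
    rho = acov / acov[0]
    # pair sums Gamma_m = rho_{2m} + rho_{2m+1}; truncate at first negative,
    # then enforce monotone decrease
    tau = -1.0
    prev = math.inf
    for m in range(n // 2):
        g = rho[2 * m] + rho[2 * m + 1] if 2 * m + 1 < n else rho[2 * m]
        if g < 0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau = max(tau, 1.0 / n)
    return float(min(n, n / tau))


def geweke_z(draws, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain means,
    with ESS-adjusted variances."""
    x = np.asarray(draws, dtype=float)
    a = x[: max(int(first * x.size), 2)]
    b = x[-max(int(last * x.size), 2) :]
    va = np.var(a, ddof=1) / effective_sample_size(a)
    vb = np.var(b, ddof=1) / effective_sample_size(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def rho_from_samples(var_phylo_draws, var_resid_draws) -> dict:
    """Per-draw phylogenetic signal rho = s2a/(s2a+s2e) with summaries.

    Returns a dict with the draw vector, posterior mode (kernel-density
    argmax), posterior mean, and 95% HPD interval.
    """
    va = np.asarray(var_phylo_draws, dtype=float)
    ve = np.asarray(var_resid_draws, dtype=float)
    if va.shape != ve.shape:
        raise ValueError("draw vectors differ in length")
    if (va <= 0).any() or (ve <= 0).any():
        raise ValueError("variance draws must be strictly positive")
    rho = va / (va + ve)
    lo, hi = hpd_interval(rho, 0.95)
    return {
        "draws": rho,
        "mode": posterior_mode(rho),
        "mean": float(rho.mean()),
        "hpd": (lo, hi),
    }


def _sample_inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    return scale / rng.gamma(shape)


@dataclass
class UnivariatePMMResult:
    """Posterior draws and summaries from a univariate animal-model fit."""

    samples_var_phylo: np.ndarray = field(repr=False)
    samples_var_resid: np.ndarray = field(repr=False)
    samples_rho: np.ndarray = field(repr=False)
    rho_point: float
    rho_mean: float
    rho_hpd: tuple[float, float]
    ess: float
    seed: int
    n_species: int
    trait_scale: float
    warnings: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "rho": self.rho_point,
            "rho_mean": self.rho_mean,
            "rho_hpd": list(self.rho_hpd),
            "ess": self.ess,
            "seed": self.seed,
            "warnings": self.warnings,
        }


def fit_univariate(y, A, config: PMMConfig | None = None) -> UnivariatePMMResult:
    """Gibbs sampler for the univariate animal model.

    ``A`` may be a :class:`~telopace.treeio.PhyloCovariance` or a plain
    matrix. The trait is standardised internally (signal is scale-free; the
    reported variance draws are rescaled back to the input units). Each
    sweep updates the latent phylogenetic effects from their Gaussian full
    conditional (diagonal in the eigenbasis of A), the intercept from its
    normal full conditional (flat prior), and both variances from conjugate
    inverse-gamma full conditionals.
    """
    config = config or PMMConfig()
    matrix = getattr(A, "matrix", A)
    y = np.asarray(y, dtype=float)
    n = y.size
    if matrix.shape != (n, n):
        raise ValueError("trait length does not match covariance dimension")
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")

    scale = float(y.std(ddof=1))
    ys = (y - y.mean()) / scale

    v0 = 1.0 if config.prior_v is None else float(np.asarray(config.prior_v).item())
    nu = 0.002 if config.prior_nu is None else float(config.prior_nu)

    d, U, bent = _decompose_relatedness(matrix)
    warnings_out: list[str] = []
    if bent:
        warnings_out.append("singular A bent by 1e-8 eigenvalue floor")

    yt = U.T @ ys
    c = U.T @ np.ones(n)
    cc = float(c @ c)  # == n

    rng = np.random.default_rng(config.seed)
    s2a, s2e = 0.5, 0.5
    mu = 0.0
    a = np.zeros(n)

    keep = config.n_retained
    out_a = np.empty(keep)
    out_e = np.empty(keep)
    k = 0
    post_shape = (nu + n) / 2.0

    for it in range(config.n_iter):
        # latent effects (eigenbasis: independent scalars)
        prec = 1.0 / (s2a * d) + 1.0 / s2e
        var = 1.0 / prec
        mean = var * (yt - mu * c) / s2e
        a = mean + np.sqrt(var) * rng.standard_normal(n)

        # intercept, flat prior
        mu_hat = float(c @ (yt - a)) / cc
        mu = mu_hat + math.sqrt(s2e / cc) * rng.standard_normal()

        # variance components, conjugate inverse-gamma
        s2a = _sample_inv_gamma(rng, post_shape, (nu * v0 + float(a @ (a / d))) / 2.0)
        resid = yt - mu * c - a
        s2e = _sample_inv_gamma(rng, post_shape, (nu * v0 + float(resid @ resid)) / 2.0)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_a[k] = s2a
            out_e[k] = s2e
            k += 1

    rho = rho_from_samples(out_a, out_e)
    ess = effective_sample_size(rho["draws"])
    if ess < 100:
        warnings_out.append(f"low effective sample size for rho: {ess:.0f}")

    return UnivariatePMMResult(
        samples_var_phylo=out_a * scale**2,
        samples_var_resid=out_e * scale**2,
        samples_rho=rho["draws"],
        rho_point=rho["mode"],
        rho_mean=rho["mean"],
        rho_hpd=rho["hpd"],
        ess=ess,
        seed=config.seed,
        n_species=n,
        trait_scale=scale,
        warnings=warnings_out,
    )


@dataclass
class BivariatePMMResult:
    """Posterior draws and summaries from a bivariate animal-model fit."""

    samples_cov_phylo: np.ndarray = field(repr=False)  # (draws, 2, 2)
    samples_cov_resid: np.ndarray = field(repr=False)
    r_phylo: np.ndarray = field(repr=False)
    r_resid: np.ndarray = field(repr=False)
    r_total: np.ndarray = field(repr=False)
    adjusted_r_point: float
    adjusted_r_mean: float
    adjusted_r_hpd: tuple[float, float]
    pmcmc: float
    ess: float
    seed: int
    n_species: int
    n_jitter_redraws: int = 0
    warnings: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "adjusted_r": self.adjusted_r_point,
            "adjusted_r_mean": self.adjusted_r_mean,
            "adjusted_r_hpd": list(self.adjusted_r_hpd),
            "pmcmc": self.pmcmc,
            "r_phylo_mode": posterior_mode(self.r_phylo),
            "r_resid_mode": posterior_mode(self.r_resid),
            "r_total_mode": posterior_mode(self.r_total),
            "ess": self.ess,
            "seed": self.seed,
            "warnings": self.warnings,
        }


def _corr_from_cov(cov: np.ndarray) -> np.ndarray:
    """Correlations from a stack of 2x2 covariance draws."""
    return cov[:, 0, 1] / np.sqrt(cov[:, 0, 0] * cov[:, 1, 1])


def _sample_invwishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """One 2x2 inverse-Wishart draw via the Bartlett decomposition."""
    # W ~ Wishart(df, scale^{-1});  X = W^{-1} ~ InvWishart(df, scale)
    L = np.linalg.cholesky(np.linalg.inv(scale))
    T = np.zeros((2, 2))
    T[0, 0] = math.sqrt(rng.chisquare(df))
    T[1, 1] = math.sqrt(rng.chisquare(df - 1))
    T[1, 0] = rng.standard_normal()
    Wc = L @ T  # W = Wc Wc'
    Winv_c = np.linalg.inv(Wc)
    return Winv_c.T @ Winv_c


def fit_bivariate(y1, y2, A, config: PMMConfig | None = None) -> BivariatePMMResult:
    """Block-Gibbs sampler for the bivariate animal model.

    Both traits are standardised internally (correlations are
    scale-invariant). Per sweep: the 2n latent effects are drawn from their
    Gaussian full conditional (n independent 2x2 problems in the eigenbasis
    of A), the intercept pair from its bivariate-normal full conditional,
    and the 2x2 phylogenetic and residual covariance matrices from conjugate
    inverse-Wishart full conditionals. A numerically non-positive-definite
    draw is retried with jitter added to its scale matrix; retries are
    counted and logged.
    """
    config = config or PMMConfig()
    matrix = getattr(A, "matrix", A)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.size
    if y2.size != n or matrix.shape != (n, n):
        raise ValueError("trait lengths and covariance dimension must agree")
    if n < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(y1) == 0 or np.ptp(y2) == 0:
        raise ValueError("constant trait")

    Y = np.column_stack(
        [(y1 - y1.mean()) / y1.std(ddof=1), (y2 - y2.mean()) / y2.std(ddof=1)]
    )

    V0 = np.eye(2) if config.prior_v is None else np.asarray(config.prior_v, dtype=float)
    nu = 2.002 if config.prior_nu is None else float(config.prior_nu)

    d, U, bent = _decompose_relatedness(matrix)
    warnings_out: list[str] = []
    if bent:
        warnings_out.append("singular A bent by 1e-8 eigenvalue floor")

    Yt = U.T @ Y  # (n, 2)
    c = U.T @ np.ones(n)
    cc = float(c @ c)

    rng = np.random.default_rng(config.seed)
    Sp = np.eye(2) * 0.5
    Se = np.eye(2) * 0.5
    mu = np.zeros(2)

    keep = config.n_retained
    out_p = np.empty((keep, 2, 2))
    out_e = np.empty((keep, 2, 2))
    k = 0
    post_df = nu + n
    prior_scale = nu * V0
    n_jitter = 0

    for it in range(config.n_iter):
        Sp_inv = np.linalg.inv(Sp)
        Se_inv = np.linalg.inv(Se)

        # latent effects: n independent 2x2 Gaussian solves in the eigenbasis
        prec = Sp_inv[None, :, :] / d[:, None, None] + Se_inv[None, :, :]
        cov = np.linalg.inv(prec)
        rhs = (Yt - np.outer(c, mu)) @ Se_inv.T  # (n, 2)
        mean = np.einsum("nij,nj->ni", cov, rhs)
        Ls = np.linalg.cholesky(cov)
        Aq = mean + np.einsum("nij,nj->ni", Ls, rng.standard_normal((n, 2)))

        # intercepts
        mu_hat = c @ (Yt - Aq) / cc
        Lmu = np.linalg.cholesky(Se / cc)
        mu = mu_hat + Lmu @ rng.standard_normal(2)

        # covariance components, conjugate inverse-Wishart
        Sa = Aq.T @ (Aq / d[:, None])
        Resid = Yt - np.outer(c, mu) - Aq
        Sr = Resid.T @ Resid
        for target, S in (("p", Sa), ("e", Sr)):
            scale_mat = prior_scale + S
            for attempt in range(5):
                try:
                    draw = _sample_invwishart(rng, post_df, scale_mat)
                    np.linalg.cholesky(draw)
                    break
                except np.linalg.LinAlgError:
                    n_jitter += 1
                    scale_mat = scale_mat + np.eye(2) * 1e-8 * (10.0**attempt)
            if target == "p":
                Sp = draw
            else:
                Se = draw

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_p[k] = Sp
            out_e[k] = Se
            k += 1

    if n_jitter:
        logger.warning("%d covariance draws required jitter", n_jitter)
        warnings_out.append(f"{n_jitter} covariance draws required jitter")

    r_phylo = _corr_from_cov(out_p)
    r_resid = _corr_from_cov(out_e)
    r_total = _corr_from_cov(out_p + out_e)

    adj = r_resid
    lo, hi = hpd_interval(adj, 0.95)
    ess = effective_sample_size(adj)
    if ess < 100:
        warnings_out.append(f"low effective sample size for adjusted r: {ess:.0f}")

    return BivariatePMMResult(
        samples_cov_phylo=out_p,
        samples_cov_resid=out_e,
        r_phylo=r_phylo,
        r_resid=r_resid,
        r_total=r_total,
        adjusted_r_point=posterior_mode(adj),
        adjusted_r_mean=float(adj.mean()),
        adjusted_r_hpd=(lo, hi),
        pmcmc=pmcmc(adj),
        ess=ess,
        seed=config.seed,
        n_species=n,
        n_jitter_redraws=n_jitter,
        warnings=warnings_out,
    )


def convergence_report(result) -> dict:
    """ESS and Geweke z for each monitored posterior quantity.

    Flags quantities with |z| > 2 or ESS < 200. Accepts either fit result
    type.
    """
    if isinstance(result, UnivariatePMMResult):
        monitored = {
            "var_phylo": result.samples_var_phylo,
            "var_resid": result.samples_var_resid,
            "rho": result.samples_rho,
        }
    elif isinstance(result, BivariatePMMResult):
        monitored = {
            "r_phylo": result.r_phylo,
            "r_resid": result.r_resid,
            "r_total": result.r_total,
        }
    else:
        raise TypeError(f"unsupported result type: {type(result).__name__}")

    report: dict[str, dict] = {}
    for name, draws in monitored.items():
        ess = effective_sample_size(draws)
        z = geweke_z(draws)
        report[name] = {
            "ess": ess,
            "geweke_z": z,
            "flagged": bool(ess < 200 or abs(z) > 2),
        }
    return report
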