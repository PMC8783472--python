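"""Count distributions for single-gene scRNA-seq counts and their selection.

Four families are supported: Poisson, zero-inflated Poisson (ZIP), negative
binomial (NB), and zero-inflated NB (ZINB). They form a nested lattice with
ZINB at the top: ZIP reduces to Poisson when the zero-inflation weight p is 0,
NB reduces to Poisson when the dispersion psi is +inf, and ZINB covers both.

Parameterization
----------------
* Poisson(lambda): mean = variance = lambda.
* NB(mu, psi): mean mu, Var = mu + mu**2 / psi ("size" parameterization);
  psi -> +inf recovers Poisson.
* ZIP(lambda, p) and ZINB(mu, psi, p): a point mass p at zero mixed with the
  base count distribution with weight 1 - p.

Fitting is exact maximum likelihood: closed form for Poisson, a profiled 1-D
search on log(psi) for NB, and EM over the latent zero-origin indicator for
the zero-inflated families. Model selection walks the nesting lattice with
likelihood-ratio tests whose null parameter sits on the boundary of the
parameter space, so the null law is the 50:50 mixture of a point mass at 0 and
a chi-square with one degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "CountModelParams",
    "FittedGeneModel",
    "ModelSelectionResult",
    "log_pmf",
    "zero_proportion",
    "cdf",
    "ppf",
    "sample",
    "fit_model",
    "lrt_nested",
    "select_model",
]

#: psi at or above this cap is reported as +inf (Poisson-equivalent).
PSI_CAP = 1e6
#: psi search window (on the log scale) for NB/ZINB fitting.
PSI_MIN = 1e-4
#: upper bound on the zero-inflation weight during optimization.
P_MAX = 0.999

_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_EM_WARMUP_ITER = 30


class Family(str, Enum):
    POISSON = "poisson"
    ZIP = "zip"
    NB = "nb"
    ZINB = "zinb"


#: number of free parameters of each family
N_PARAMS = {Family.POISSON: 1, Family.ZIP: 2, Family.NB: 2, Family.ZINB: 3}

#: directly nested (null, alternative) pairs differing by one parameter
_NESTED_PAIRS = {
    (Family.POISSON, Family.ZIP),
    (Family.POISSON, Family.NB),
    (Family.NB, Family.ZINB),
    (Family.ZIP, Family.ZINB),
}


@dataclass(frozen=True)
class CountModelParams:
    """Parameters of one gene's count distribution.

    ``mean`` is lambda for Poisson/ZIP and mu for NB/ZINB (the mean of the
    non-inflated component). ``dispersion`` is the NB size psi (+inf means
    the Poisson limit; always +inf for Poisson/ZIP). ``zero_inflation`` is
    the extra point mass p at zero (always 0 for Poisson/NB).
    """

    family: Family
    mean: float
    dispersion: float = math.inf
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "dispersion", float(self.dispersion))
        object.__setattr__(self, "zero_inflation", float(self.zero_inflation))
        if self.mean < 0 or not np.isfinite(self.mean):
            raise ValueError("mean must be a finite non-negative real")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (or +inf)")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.family in (Family.POISSON, Family.NB) and self.zero_inflation != 0:
            raise ValueError(f"{self.family.value} cannot carry zero inflation")
        if self.family in (Family.POISSON, Family.ZIP) and not math.isinf(
            self.dispersion
        ):
            raise ValueError(f"{self.family.value} must have dispersion +inf")

    @property
    def variance(self) -> float:
        """Variance of the full (possibly zero-inflated) distribution."""
        p, m = self.zero_inflation, self.mean
        if math.isinf(self.dispersion):
            base_var = m
        else:
            base_var = m + m * m / self.dispersion
        # mixture of point mass at 0 (weight p) and the base component
        return (1 - p) * (base_var + p * m * m)


@dataclass(frozen=True)
class FittedGeneModel:
    """Maximum-likelihood fit of one family to one gene's counts."""

    params: CountModelParams
    loglik: float
    n_cells: int
    converged: bool = True


@dataclass(frozen=True)
class ModelSelectionResult:
    """Outcome of the two-stage likelihood-ratio selection chain."""

    chosen: Family
    pvalue_dispersion: float
    pvalue_zero_inflation: float
    alpha: float
    fits: dict[Family, FittedGeneModel] = field(default_factory=dict, repr=False)

    @property
    def chosen_fit(self) -> FittedGeneModel:
        return self.fits[self.chosen]


# ---------------------------------------------------------------------------
# probability functions
# ---------------------------------------------------------------------------


def _validate_k(k) -> np.ndarray:
    k = np.asarray(k)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.all(k == np.floor(k)):
            raise ValueError("k must be integer-valued")
        k = k.astype(np.int64)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    return k


def _poisson_logpmf(k: np.ndarray, lam: float) -> np.ndarray:
    # direct gammaln form; much faster than the frozen-distribution call
    return special.xlogy(k, lam) - lam - special.gammaln(np.asarray(k) + 1.0)


def _nb_logpmf(k: np.ndarray, mean: float, psi: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return (
        special.gammaln(k + psi)
        - special.gammaln(psi)
        - special.gammaln(k + 1.0)
        + psi * math.log(psi / (psi + mean))
        + special.xlogy(k, mean / (psi + mean))
    )


def _base_logpmf(mean: float, dispersion: float, k: np.ndarray) -> np.ndarray:
    if math.isinf(dispersion):
        return _poisson_logpmf(k, mean)
    return _nb_logpmf(k, mean, dispersion)


def log_pmf(params: CountModelParams, k) -> np.ndarray | float:
    """Log probability mass of ``params`` at count(s) ``k``."""
    k = _validate_k(k)
    base = _base_logpmf(params.mean, params.dispersion, k)
    p = params.zero_inflation
    if p == 0:
        return base
    out = np.log1p(-p) + base
    at_zero = k == 0
    if np.any(at_zero):
        out = np.where(at_zero, np.logaddexp(math.log(p), out), out)
    return out if out.ndim else float(out)


def zero_proportion(params: CountModelParams) -> float:
    """Probability that the distribution produces a zero count."""
    return float(np.exp(log_pmf(params, 0)))


def cdf(params: CountModelParams, k) -> np.ndarray | float:
    """CDF at integer count(s) k (k < 0 gives 0)."""
    k = np.asarray(k)
    if math.isinf(params.dispersion):
        base = stats.poisson.cdf(k, params.mean)
    else:
        psi = params.dispersion
        base = stats.nbinom.cdf(k, psi, psi / (psi + params.mean))
    p = params.zero_inflation
    out = np.where(k < 0, 0.0, p + (1 - p) * base)
    return out if out.ndim else float(out)


def ppf(params: CountModelParams, u) -> np.ndarray | float:
    """Quantile function on u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    p = params.zero_inflation
    # mass p at zero, remainder through the base quantile
    ub = np.clip((u - p) / (1 - p), 0.0, 1.0 - 1e-12)
    if math.isinf(params.dispersion):
        base = stats.poisson.ppf(ub, params.mean)
    else:
        psi = params.dispersion
        base = stats.nbinom.ppf(ub, psi, psi / (psi + params.mean))
    out = np.where(u <= p, 0.0, base)
    return out if out.ndim else float(out)


def sample(params: CountModelParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw counts from the distribution."""
    if math.isinf(params.dispersion):
        x = rng.poisson(params.mean, size)
    else:
        psi = params.dispersion
        x = rng.negative_binomial(psi, psi / (psi + params.mean), size)
    p = params.zero_inflation
    if p > 0:
        x = np.where(rng.random(size) < p, 0, x)
    return x.astype(np.int64)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _validate_counts(counts) -> np.ndarray:
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts vector is empty")
    if counts.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    return _validate_k(counts)


def _poisson_loglik(counts: np.ndarray, lam: float) -> float:
    return float(np.sum(_poisson_logpmf(counts, lam)))


def _fit_poisson(counts: np.ndarray) -> FittedGeneModel:
    lam = float(counts.mean())
    params = CountModelParams(Family.POISSON, lam)
    return FittedGeneModel(params, _poisson_loglik(counts, lam), counts.size)


def _nb_loglik(counts: np.ndarray, mu: float, psi: float, weights=None) -> float:
    ll = _base_logpmf(mu, psi, counts)
    return float(np.sum(ll) if weights is None else np.dot(weights, ll))


def _profile_nb_psi(
    counts: np.ndarray, mu: float, weights=None, xatol: float = 1e-6
) -> tuple[float, float]:
    """Maximize the (weighted) NB log-likelihood over psi at fixed mu.

    Returns (psi_hat, loglik); psi_hat may be +inf (Poisson limit).
    """
    if mu == 0:
        return math.inf, 0.0

    def neg(log_psi: float) -> float:
        return -_nb_loglik(counts, mu, math.exp(log_psi), weights)

    res = optimize.minimize_scalar(
        neg,
        bounds=(math.log(PSI_MIN), math.log(PSI_CAP)),
        method="bounded",
        options={"xatol": xatol},
    )
    psi = float(math.exp(res.x))
    ll = -float(res.fun)
    lp = _poisson_logpmf(counts, mu)
    ll_pois = float(np.sum(lp) if weights is None else np.dot(weights, lp))
    if psi >= PSI_CAP * 0.99 or ll <= ll_pois + 1e-10:
        return math.inf, ll_pois
    return psi, ll


def _fit_nb(counts: np.ndarray) -> FittedGeneModel:
    mu = float(counts.mean())
    psi, ll = _profile_nb_psi(counts, mu)
    if math.isinf(psi):
        ll = _poisson_loglik(counts, mu)
    params = CountModelParams(Family.NB, mu, dispersion=psi)
    return FittedGeneModel(params, ll, counts.size)


def _zip_loglik(counts: np.ndarray, lam: float, p: float) -> float:
    return float(np.sum(log_pmf(CountModelParams(Family.ZIP, lam, zero_inflation=p), counts)))


def _fit_zip(counts: np.ndarray) -> FittedGeneModel:
    n = counts.size
    total = float(counts.sum())
    n_zero = int(np.sum(counts == 0))
    pois = _fit_poisson(counts)
    lam = max(total / n, 1e-8)
    expected_zero = math.exp(-lam)
    # score test at the boundary: d(loglik)/dp at p=0 is n_zero/f(0) - n,
    # so without excess zeros the Poisson fit is the ZIP maximum.
    if n_zero == 0 or total == 0 or n_zero / n <= expected_zero:
        params = CountModelParams(Family.ZIP, pois.params.mean, zero_inflation=0.0)
        return FittedGeneModel(params, pois.loglik, n)

    # moment start: excess zeros relative to Poisson at the sample mean
    p = min(max((n_zero / n - expected_zero) / (1 - expected_zero), 1e-4), P_MAX)
    ll_old = -math.inf
    converged = False
    for _ in range(_EM_MAX_ITER):
        # E-step: posterior weight that a zero came from the inflation mass
        w0 = p / (p + (1 - p) * math.exp(-lam))
        sum_w = n_zero * w0
        # M-step (closed form)
        p = min(max(sum_w / n, 0.0), P_MAX)
        denom = n - sum_w
        lam = total / denom if denom > 0 else 0.0
        ll = _zip_loglik(counts, lam, p)
        if ll - ll_old < _EM_TOL:
            converged = True
            break
        ll_old = ll
    ll = _zip_loglik(counts, lam, p)
    if ll < pois.loglik:  # safeguard: the p=0 boundary is part of the family
        params = CountModelParams(Family.ZIP, pois.params.mean, zero_inflation=0.0)
        return FittedGeneModel(params, pois.loglik, n)
    return FittedGeneModel(
        CountModelParams(Family.ZIP, lam, zero_inflation=p), ll, n, converged
    )


def _zinb_loglik(counts: np.ndarray, mu: float, psi: float, p: float) -> float:
    params = CountModelParams(Family.ZINB, mu, dispersion=psi, zero_inflation=p)
    return float(np.sum(log_pmf(params, counts)))


def _fit_zinb(counts: np.ndarray) -> FittedGeneModel:
    n = counts.size
    total = float(counts.sum())
    n_zero = int(np.sum(counts == 0))
    nb = _fit_nb(counts)
    nb_zero = math.exp(
        _base_logpmf(nb.params.mean, nb.params.dispersion, np.array([0]))[0]
    )
    # boundary score condition (see _fit_zip): no excess zeros over the NB
    # maximum means p = 0 is the ZINB optimum
    if n_zero == 0 or total == 0 or n_zero / n <= nb_zero:
        params = CountModelParams(
            Family.ZINB, nb.params.mean, dispersion=nb.params.dispersion
        )
        return FittedGeneModel(params, nb.loglik, n)

    zip_fit = _fit_zip(counts)
    mu = max(nb.params.mean, 1e-8)
    psi = nb.params.dispersion if math.isfinite(nb.params.dispersion) else PSI_CAP / 10
    base_zero = math.exp(_base_logpmf(mu, psi, np.array([0]))[0])
    p = min(max((n_zero / n - base_zero) / (1 - base_zero + 1e-12), 1e-4), P_MAX)
    is_zero = counts == 0
    ll_old = -math.inf
    converged = False
    # short EM warm-up (robust ascent from the moment start) ...
    for _ in range(_EM_WARMUP_ITER):
        base_zero = math.exp(_base_logpmf(mu, psi, np.array([0]))[0])
        w0 = p / (p + (1 - p) * base_zero)
        weights = np.where(is_zero, 1.0 - w0, 1.0)  # membership in the count component
        sum_w = n_zero * w0
        p = min(max(sum_w / n, 1e-6), P_MAX)
        wsum = float(weights.sum())
        mu = total / wsum if wsum > 0 else 1e-8
        psi_new, _ = _profile_nb_psi(counts, mu, weights, xatol=1e-3)
        psi = min(psi_new, PSI_CAP) if math.isfinite(psi_new) else PSI_CAP
        ll = _zinb_loglik(counts, mu, psi, p)
        if ll - ll_old < _EM_TOL:
            converged = True
            break
        ll_old = ll

    # ... then quasi-Newton polish on (log mu, log psi, logit p); EM alone
    # crawls along the psi/p ridge when the two are weakly identified
    def neg(theta):
        m_, s_, t_ = theta
        return -_zinb_loglik(
            counts, math.exp(m_), math.exp(s_), 1.0 / (1.0 + math.exp(-t_))
        )

    x0 = [
        math.log(max(mu, 1e-8)),
        math.log(min(max(psi, PSI_MIN), PSI_CAP)),
        math.log(p / (1 - p)),
    ]
    res = optimize.minimize(
        neg,
        x0,
        method="L-BFGS-B",
        bounds=[
            (-25.0, 25.0),
            (math.log(PSI_MIN), math.log(PSI_CAP)),
            (math.log(1e-6 / (1 - 1e-6)), math.log(P_MAX / (1 - P_MAX))),
        ],
    )
    ll = _zinb_loglik(counts, mu, psi, p)
    if -res.fun > ll:
        mu = math.exp(res.x[0])
        psi = math.exp(res.x[1])
        p = 1.0 / (1.0 + math.exp(-res.x[2]))
        ll = -float(res.fun)
        converged = bool(res.success)
    if psi >= PSI_CAP * 0.99:
        psi = math.inf
        ll = _zinb_loglik(counts, mu, psi, p)
    best = FittedGeneModel(
        CountModelParams(Family.ZINB, mu, dispersion=psi, zero_inflation=p),
        ll,
        n,
        converged,
    )
    # boundary safeguards: ZINB contains NB (p=0) and ZIP (psi=inf)
    if nb.loglik > best.loglik:
        best = FittedGeneModel(
            CountModelParams(Family.ZINB, nb.params.mean, dispersion=nb.params.dispersion),
            nb.loglik,
            n,
        )
    if zip_fit.loglik > best.loglik:
        best = FittedGeneModel(
            CountModelParams(
                Family.ZINB,
                zip_fit.params.mean,
                zero_inflation=zip_fit.params.zero_inflation,
            ),
            zip_fit.loglik,
            n,
        )
    return best


_FITTERS = {
    Family.POISSON: _fit_poisson,
    Family.ZIP: _fit_zip,
    Family.NB: _fit_nb,
    Family.ZINB: _fit_zinb,
}


def fit_model(counts, family: Family | str) -> FittedGeneModel:
    """Maximum-likelihood fit of one count family to a gene's counts.

    All-zero vectors are degenerate for every family and return the point
    mass at zero (mean 0, no zero inflation, log-likelihood 0).
    """
    family = Family(family)
    counts = _validate_counts(counts)
    if counts.size < 2:
        raise ValueError("need at least 2 observations to fit")
    if not counts.any():
        params = {
            Family.POISSON: CountModelParams(Family.POISSON, 0.0),
            Family.ZIP: CountModelParams(Family.ZIP, 0.0),
            Family.NB: CountModelParams(Family.NB, 0.0, dispersion=math.inf),
            Family.ZINB: CountModelParams(Family.ZINB, 0.0, dispersion=math.inf),
        }[family]
        return FittedGeneModel(params, 0.0, counts.size)
    return _FITTERS[family](counts)


# ---------------------------------------------------------------------------
# likelihood-ratio tests and model selection
# ---------------------------------------------------------------------------


def lrt_nested(
    null_fit: FittedGeneModel, alt_fit: FittedGeneModel, boundary: bool
) -> float:
    """P-value of the likelihood-ratio test of a nested family pair.

    With ``boundary=True`` the null value of the extra parameter lies on the
    boundary of the parameter space (p = 0, or psi = +inf), and the statistic's
    null law is the mixture 0.5*chi2_0 + 0.5*chi2_1 rather than chi2_1.
    """
    pair = (null_fit.params.family, alt_fit.params.family)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"{pair[0].value} is not nested in {pair[1].value}")
    if alt_fit.loglik < null_fit.loglik - 1e-6:
        raise ValueError("alternative log-likelihood below the null: fits inconsistent")
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    if stat == 0.0:
        return 1.0
    tail = float(stats.chi2.sf(stat, df=1))
    return 0.5 * tail if boundary else tail


def select_model(counts, alpha: float = 0.05) -> ModelSelectionResult:
    """Choose the least complex family that fits a gene's counts well.

    Two-stage chain of boundary likelihood-ratio tests: (1) Poisson vs NB
    (dispersion); (2) the stage-1 winner vs its zero-inflated extension.
    The chosen family is Poisson iff neither test rejects.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    counts = _validate_counts(counts)
    fits: dict[Family, FittedGeneModel] = {}
    if not counts.any():
        fits[Family.POISSON] = fit_model(counts, Family.POISSON)
        return ModelSelectionResult(Family.POISSON, 1.0, 1.0, alpha, fits)

    fits[Family.POISSON] = fit_model(counts, Family.POISSON)
    single_valued = np.unique(counts).size == 1
    if single_valued:
        p_disp = 1.0
        winner = Family.POISSON
    else:
        fits[Family.NB] = fit_model(counts, Family.NB)
        p_disp = lrt_nested(fits[Family.POISSON], fits[Family.NB], boundary=True)
        winner = Family.NB if p_disp < alpha else Family.POISSON

    zi_family = Family.ZINB if winner == Family.NB else Family.ZIP
    fits[zi_family] = fit_model(counts, zi_family)
    p_zi = lrt_nested(fits[winner], fits[zi_family], boundary=True)
    chosen = zi_family if p_zi < alpha else winner
    return ModelSelectionResult(chosen, float(p_disp), float(p_zi), alpha, fits)
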