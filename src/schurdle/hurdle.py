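"""Two-part ("hurdle") model and combined likelihood-ratio test.

Single-cell expression of one gene is modelled as a mixture of a point mass
at zero (the gene is off in that cell) and, conditional on being on, a
log-normal expression level — equivalently a normal distribution on the et
scale:

    U ~ Bernoulli(pi)          gene detected or not
    et | U = 1 ~ N(mu, sigma^2)

Three parameters per gene: the expression frequency ``pi``, and the
conditional mean ``mu`` and variance ``sigma^2`` of the positive et values.

For a two-group comparison the likelihood factorizes into a Bernoulli part
over all wells and a normal part over expressed wells, so the log-LRT for
H0: (pi, mu) common  vs  H1: (pi_g, mu_g) group-specific, with sigma^2
shared by the groups and re-estimated under each hypothesis, decomposes
exactly into a Bernoulli LRT plus a normal-theory LRT.  The combined
statistic is asymptotically chi-square with 2 degrees of freedom; the
approximation is adequate when the expected number of expressed wells per
group exceeds ~8, below which a permutation null is recommended.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import chdtrc, xlogy

from .core_data import ConfigError, ValidationError

__all__ = [
    "HurdleParams",
    "LrtResult",
    "fit_hurdle",
    "two_group_loglik",
    "combined_lrt",
    "batch_combined_lrt",
    "permutation_pvalue",
    "SMALL_SAMPLE_CUTOFF",
]

logger = logging.getLogger(__name__)

#: below this expected number of expressed wells per group, the chi-square(2)
#: reference is unreliable and permutation p-values are recommended
SMALL_SAMPLE_CUTOFF = 8

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class HurdleParams:
    """Per-gene hurdle parameters (et scale).

    ``mu`` is NaN with no expressed well; ``sigma2`` is NaN with fewer than
    two expressed wells and exactly 0.0 (degenerate) when all positive
    values tie.
    """

    pi: float
    mu: float
    sigma2: float

    @property
    def degenerate(self) -> bool:
        return not (self.sigma2 > 0)


@dataclass(frozen=True)
class LrtResult:
    """Combined two-group LRT and its Bernoulli/normal decomposition."""

    lambda_combined: float
    lambda_binom: float
    lambda_normal: float
    df: int
    p_asymptotic: float
    n_pos: tuple  # (n0+, n1+)
    direction: int
    small_sample_flag: bool
    p_permutation: Optional[float] = None


def fit_hurdle(et_values: np.ndarray) -> HurdleParams:
    """Maximum-likelihood hurdle fit for one gene's wells.

    pi-hat = n+/n; mu-hat = mean of the positive et values; sigma2-hat the
    MLE variance (1/n+ denominator) of the positive values.
    """
    x = np.asarray(et_values, dtype=float)
    if x.size == 0:
        raise ValidationError("fit_hurdle needs at least one well")
    if np.any(x < 0):
        raise ValidationError("et values must be >= 0")
    pos = x[x > 0]
    pi = pos.size / x.size
    mu = float(pos.mean()) if pos.size >= 1 else float("nan")
    sigma2 = float(pos.var(ddof=0)) if pos.size >= 2 else float("nan")
    return HurdleParams(pi=pi, mu=mu, sigma2=sigma2)


def _bernoulli_ll(n_pos: float, n: float, pi: float) -> float:
    return float(xlogy(n_pos, pi) + xlogy(n - n_pos, 1.0 - pi))


def _normal_ll(pos: np.ndarray, mu: float, sigma2: float) -> float:
    if pos.size == 0:
        return 0.0
    if not sigma2 > 0:
        raise ValidationError("sigma2 must be positive with expressed wells present")
    return float(
        -0.5 * pos.size * math.log(2.0 * math.pi * sigma2)
        - 0.5 * np.sum((pos - mu) ** 2) / sigma2
    )


def two_group_loglik(
    group0: np.ndarray,
    group1: np.ndarray,
    params0: HurdleParams,
    params1: HurdleParams,
) -> float:
    """Log-likelihood of the two-part model across two groups.

    Bernoulli term over all wells plus normal term over expressed wells,
    with the convention 0*log 0 = 0 at the pi boundaries.  Pass the same
    params object twice to evaluate a null (shared-parameter) fit.  sigma2
    is taken from each params object; callers enforce the common-variance
    constraint.
    """
    total = 0.0
    for x, p in ((np.asarray(group0, float), params0), (np.asarray(group1, float), params1)):
        pos = x[x > 0]
        total += _bernoulli_ll(pos.size, x.size, p.pi)
        total += _normal_ll(pos, p.mu, p.sigma2)
    return total


def _normal_lambda(s0: int, s1: int, sum0: float, sum1: float,
                   ss0: float, ss1: float) -> float:
    """Closed-form normal-part LRT from per-group positive sufficient stats.

    Lambda_n = n+ * ln(sigma2_H0 / sigma2_H1) where sigma2_H1 pools the
    within-group SSE and sigma2_H0 the total SSE about the common mean.
    Degenerate layouts (fewer than two positives total, a group empty with
    the other below two, or zero within-group SSE) carry no usable
    continuous information and contribute 0.
    """
    tot = s0 + s1
    if tot < 2 or (min(s0, s1) == 0 and max(s0, s1) < 2):
        return 0.0
    sse_within = 0.0
    if s0 >= 1:
        sse_within += ss0 - sum0 * sum0 / s0
    if s1 >= 1:
        sse_within += ss1 - sum1 * sum1 / s1
    sst = (ss0 + ss1) - (sum0 + sum1) ** 2 / tot
    sse_within = max(sse_within, 0.0)
    sst = max(sst, 0.0)
    if sse_within <= 0.0 or sst <= 0.0:
        return 0.0
    return float(tot * math.log(sst / sse_within))


def _bernoulli_lambda(s0: int, n0: int, s1: int, n1: int) -> float:
    pi0, pi1 = s0 / n0, s1 / n1
    pip = (s0 + s1) / (n0 + n1)
    ll1 = _bernoulli_ll(s0, n0, pi0) + _bernoulli_ll(s1, n1, pi1)
    ll0 = _bernoulli_ll(s0, n0, pip) + _bernoulli_ll(s1, n1, pip)
    return float(max(2.0 * (ll1 - ll0), 0.0))


def combined_lrt(group0: np.ndarray, group1: np.ndarray) -> LrtResult:
    """Combined LRT for a difference in expression frequency and/or level.

    Both arguments are vectors of non-negative et values (zeros are
    unexpressed wells).  The statistic is the exact sum of the Bernoulli
    and normal log-LRT parts; the asymptotic p-value uses the upper tail
    of chi-square(2).
    """
    x0 = np.asarray(group0, dtype=float)
    x1 = np.asarray(group1, dtype=float)
    if x0.size == 0 or x1.size == 0:
        raise ValidationError("both groups must be non-empty")
    if np.any(x0 < 0) or np.any(x1 < 0):
        raise ValidationError("et values must be >= 0")
    pos0, pos1 = x0[x0 > 0], x1[x1 > 0]
    s0, s1 = pos0.size, pos1.size
    n0, n1 = x0.size, x1.size

    lam_b = _bernoulli_lambda(s0, n0, s1, n1)
    lam_n = _normal_lambda(
        s0, s1, float(pos0.sum()), float(pos1.sum()),
        float(np.sum(pos0 ** 2)), float(np.sum(pos1 ** 2)),
    )
    lam = lam_b + lam_n
    p_asym = float(max(chdtrc(2, lam), _TINY_P))

    mu0 = pos0.mean() if s0 else 0.0
    mu1 = pos1.mean() if s1 else 0.0
    direction = int(np.sign((s1 / n1) * mu1 - (s0 / n0) * mu0))
    small = min(s0, s1) < SMALL_SAMPLE_CUTOFF
    if small:
        logger.debug(
            "few expressed wells (%d, %d): chi-square(2) p-value may be "
            "unreliable; consider permutation_pvalue", s0, s1,
        )
    return LrtResult(
        lambda_combined=lam,
        lambda_binom=lam_b,
        lambda_normal=lam_n,
        df=2,
        p_asymptotic=p_asym,
        n_pos=(s0, s1),
        direction=direction,
        small_sample_flag=small,
    )


def batch_combined_lrt(et0: np.ndarray, et1: np.ndarray) -> dict:
    """Vectorized combined LRT over many replicate two-group datasets.

    ``et0`` and ``et1`` are (reps, n_g) arrays of non-negative et values
    (zeros = unexpressed).  Returns arrays ``lambda_combined``,
    ``lambda_binom``, ``lambda_normal`` and ``p_asymptotic`` of length reps.
    Used for permutation nulls and large calibration studies.
    """
    et0 = np.asarray(et0, dtype=float)
    et1 = np.asarray(et1, dtype=float)
    u0, u1 = et0 > 0, et1 > 0
    n0, n1 = et0.shape[1], et1.shape[1]
    s0 = u0.sum(axis=1)
    s1 = u1.sum(axis=1)

    # Bernoulli part
    def bll(s, n, pi):
        return xlogy(s, pi) + xlogy(n - s, 1.0 - pi)

    pi0, pi1 = s0 / n0, s1 / n1
    pip = (s0 + s1) / (n0 + n1)
    lam_b = 2.0 * (bll(s0, n0, pi0) + bll(s1, n1, pi1)
                   - bll(s0, n0, pip) - bll(s1, n1, pip))
    lam_b = np.maximum(lam_b, 0.0)

    # normal part from per-replicate sufficient statistics
    sum0 = np.where(u0, et0, 0.0).sum(axis=1)
    sum1 = np.where(u1, et1, 0.0).sum(axis=1)
    ss0 = np.where(u0, et0 * et0, 0.0).sum(axis=1)
    ss1 = np.where(u1, et1 * et1, 0.0).sum(axis=1)
    tot = s0 + s1
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        sse_w = (ss0 - np.where(s0 > 0, sum0 ** 2 / np.maximum(s0, 1), 0.0)
                 + ss1 - np.where(s1 > 0, sum1 ** 2 / np.maximum(s1, 1), 0.0))
        sst = ss0 + ss1 - (sum0 + sum1) ** 2 / np.maximum(tot, 1)
        sse_w = np.maximum(sse_w, 0.0)
        sst = np.maximum(sst, 0.0)
        lam_n = np.where(
            (tot >= 2)
            & ~((np.minimum(s0, s1) == 0) & (np.maximum(s0, s1) < 2))
            & (sse_w > 0)
            & (sst > 0),
            tot * np.log(np.maximum(sst, _TINY_P) / np.maximum(sse_w, _TINY_P)),
            0.0,
        )
    lam = lam_b + lam_n
    return {
        "lambda_combined": lam,
        "lambda_binom": lam_b,
        "lambda_normal": lam_n,
        "p_asymptotic": np.maximum(chdtrc(2, lam), _TINY_P),
    }


def permutation_pvalue(
    group0: np.ndarray,
    group1: np.ndarray,
    B: int,
    seed=None,
) -> float:
    """Permutation p-value for the combined LRT.

    Group labels are permuted ``B`` times and the add-one estimator
    ``p = (1 + #{Lambda_perm >= Lambda_obs}) / (B + 1)`` returned.  ``seed``
    may be an int or a ``numpy.random.Generator``.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    x0 = np.asarray(group0, dtype=float)
    x1 = np.asarray(group1, dtype=float)
    pooled = np.concatenate([x0, x1])
    if pooled.size < 2:
        raise ValidationError("need at least two wells overall")
    obs = combined_lrt(x0, x1).lambda_combined
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # one independent shuffle per permutation, vectorized via argsort of noise
    order = np.argsort(rng.random((B, pooled.size)), axis=1)
    perm = pooled[order]
    stats = batch_combined_lrt(perm[:, : x0.size], perm[:, x0.size:])["lambda_combined"]
    return float((1 + np.sum(stats >= obs - 1e-12)) / (B + 1))
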