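"""Emission models for segment read counts.

The expected total read count of a segment is a linear combination of its
(effective) length, per-clone copy number and per-clone haploid read depth,

    mu_n = l_n * sum_m h_m * c_nm ,

where ``h_m`` is expressed in reads per nucleotide for a single copy in
clone ``m`` and encodes both sequencing depth and mixture proportion.
Observed counts are modelled as Poisson, negative binomial, or a
two-component negative binomial mixture (the default: a low-variance bulk
component plus a small high-variance component), optionally mixed with a
flat outlier component.  Allele-specific counts are modelled with a
beta-binomial on the major-allele read count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "LikelihoodParams",
    "expected_read_count",
    "total_count_loglik",
    "allele_loglik",
    "emission_loglik",
    "total_count_matrix",
    "emission_matrix",
]


@dataclass
class LikelihoodParams:
    """Global likelihood parameters (the parameter block theta).

    ``inverse_dispersions`` are the negative binomial ``r`` parameters of the
    two mixture components (variance ``mu + mu^2 / r``; r -> inf recovers
    Poisson).  ``mixture_weight`` is the prior weight of the second,
    high-variance component.  ``allele_overdispersion`` is the beta-binomial
    overdispersion (0 recovers a binomial).  ``outlier_weight`` mixes in a
    flat log-density ``outlier_log_density`` per observation.
    """

    family: str = "negbin_mixture"
    inverse_dispersions: tuple = (1000.0, 100.0)
    mixture_weight: float = 0.02
    allele_overdispersion: float = 0.002
    outlier_weight: float = 0.01
    outlier_log_density: float = -20.0

    def __post_init__(self):
        if self.family not in ("poisson", "negbin", "negbin_mixture"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must be in [0, 1]")
        if any(r <= 0 for r in np.atleast_1d(self.inverse_dispersions)):
            raise ValueError("inverse dispersions must be positive")
        if self.allele_overdispersion < 0:
            raise ValueError("allele_overdispersion must be non-negative")
        if not 0.0 <= self.outlier_weight < 1.0:
            raise ValueError("outlier_weight must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inverse_dispersions"] = [
            float(v) for v in np.atleast_1d(self.inverse_dispersions)]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LikelihoodParams":
        d = dict(d)
        if "inverse_dispersions" in d:
            d["inverse_dispersions"] = tuple(d["inverse_dispersions"])
        return cls(**d)


def expected_read_count(l_n, c_n, h) -> np.ndarray:
    """mu_n = l_n * sum_m h_m c_nm, summed over all clones.

    ``c_n`` holds per-clone total copy numbers; trailing dimensions of
    ``c_n`` and ``h`` must align.
    """
    l_n = np.asarray(l_n, dtype=float)
    c_n = np.asarray(c_n, dtype=float)
    h = np.asarray(h, dtype=float)
    return l_n * (c_n * h).sum(axis=-1)


def _poisson_logpmf(x, mu):
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = x * np.log(mu) - mu - gammaln(x + 1.0)
    return np.where(mu > 0, ll, np.where(x > 0, -np.inf, 0.0))


def _nb_logpmf(x, mu, r):
    # mean-parameterised negative binomial (variance mu + mu^2 / r);
    # mu = 0 is the limit p -> 1, a point mass at zero.  Written with
    # gammaln directly: these pmfs sit in the innermost optimisation loop.
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
              + r * np.log(r / (r + mu)) + x * np.log(mu / (r + mu)))
    return np.where(mu > 0, ll, np.where(x > 0, -np.inf, 0.0))


def total_count_loglik(x, mu, params: LikelihoodParams) -> np.ndarray:
    """Log-probability of total read count ``x`` at expected count ``mu``."""
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("read counts must be non-negative")
    mu = np.asarray(mu, dtype=float)

    if params.family == "poisson":
        ll = _poisson_logpmf(x, mu)
    elif params.family == "negbin":
        ll = _nb_logpmf(x, mu, params.inverse_dispersions[0])
    else:
        r1, r2 = params.inverse_dispersions[:2]
        w = params.mixture_weight
        if w == 0.0:
            ll = _nb_logpmf(x, mu, r1)
        elif w == 1.0:
            ll = _nb_logpmf(x, mu, r2)
        else:
            ll = np.logaddexp(
                np.log1p(-w) + _nb_logpmf(x, mu, r1),
                np.log(w) + _nb_logpmf(x, mu, r2),
            )
    if params.outlier_weight > 0.0:
        ll = np.logaddexp(
            np.log1p(-params.outlier_weight) + ll,
            np.log(params.outlier_weight) + params.outlier_log_density,
        )
    return ll


def _betabinom_logpmf(k, n, p, overdispersion):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-9, 1.0 - 1e-9)
    log_choose = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    if overdispersion == 0.0:
        return log_choose + k * np.log(p) + (n - k) * np.log1p(-p)
    s = 1.0 / overdispersion
    a, b = p * s, (1.0 - p) * s
    return log_choose + betaln(k + a, n - k + b) - betaln(a, b)


def allele_loglik(x_a, x_b, c_allele, h, params: LikelihoodParams) -> np.ndarray:
    """Log-probability of the allele read-count split.

    ``c_allele`` has shape (n_clones, 2): per-clone copy numbers of allele A
    and allele B (normal clone included by the caller).  The expected
    allele-A fraction is ``sum_m h_m c^A_m / sum_m h_m (c^A_m + c^B_m)``,
    falling back to 0.5 when the denominator vanishes.
    """
    c_allele = np.asarray(c_allele, dtype=float)
    h = np.asarray(h, dtype=float)
    num = (h * c_allele[..., 0]).sum(axis=-1)
    den = (h * c_allele.sum(axis=-1)).sum(axis=-1)
    p = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
    return _betabinom_logpmf(x_a, np.asarray(x_a) + np.asarray(x_b), p,
                             params.allele_overdispersion)


def emission_loglik(segment, state, h, params: LikelihoodParams) -> float:
    """Emission log-probability for one segment and one copy-number state.

    ``segment`` is a mapping with ``effective_length``, ``readcount``,
    ``allele_a_readcount``, ``allele_b_readcount``; ``state`` has shape
    (n_clones, 2) giving per-clone allele copy numbers, normal included.
    The total-count term uses the bias-adjusted effective length.
    """
    state = np.asarray(state)
    mu = expected_read_count(
        segment["effective_length"], state.sum(axis=-1), np.asarray(h)
    )
    ll = total_count_loglik(segment["readcount"], mu, params)
    xa, xb = segment["allele_a_readcount"], segment["allele_b_readcount"]
    if xa + xb > 0:
        ll = ll + allele_loglik(xa, xb, state, h, params)
    return float(ll)


def total_count_dll_dmu(x, mu, params: LikelihoodParams) -> np.ndarray:
    """d/dmu of :func:`total_count_loglik` (component-posterior weighted for
    mixtures); used for analytic gradients in the depth update."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    safe_mu = np.maximum(mu, 1e-300)

    def nb_d(r):
        return x / safe_mu - (x + r) / (r + safe_mu)

    if params.family == "poisson":
        comps = [(None, x / safe_mu - 1.0)]
    elif params.family == "negbin":
        r = params.inverse_dispersions[0]
        comps = [(None, nb_d(r))]
    else:
        r1, r2 = params.inverse_dispersions[:2]
        w = params.mixture_weight
        if w == 0.0:
            comps = [(None, nb_d(r1))]
        elif w == 1.0:
            comps = [(None, nb_d(r2))]
        else:
            l1 = np.log1p(-w) + _nb_logpmf(x, mu, r1)
            l2 = np.log(w) + _nb_logpmf(x, mu, r2)
            tot = np.logaddexp(l1, l2)
            comps = [(np.exp(l1 - tot), nb_d(r1)),
                     (np.exp(l2 - tot), nb_d(r2))]
    d = sum(g if w_ is None else w_ * g for w_, g in comps)
    if params.outlier_weight > 0.0:
        # posterior weight of the non-outlier part scales the derivative
        base = total_count_loglik(
            x, mu, replace(params, outlier_weight=0.0))
        mixed = np.logaddexp(
            np.log1p(-params.outlier_weight) + base,
            np.log(params.outlier_weight) + params.outlier_log_density)
        d = d * np.exp(np.log1p(-params.outlier_weight) + base - mixed)
    return d


# -- vectorised emission matrices used by inference ------------------------


def total_count_matrix(x, eff_len, unique_totals, h, params: LikelihoodParams):
    """(N, U) log-likelihood of counts for each unique clone-total vector.

    ``unique_totals`` has shape (U, n_clones) with the normal clone's total
    included.  This is the cheap part of the emission, factored out so the
    haploid-depth update can iterate on it.
    """
    mu = np.asarray(eff_len, dtype=float)[:, None] * (
        np.asarray(unique_totals, dtype=float) @ np.asarray(h, dtype=float)
    )[None, :]
    return total_count_loglik(np.asarray(x)[:, None], mu, params)


def emission_matrix(x, x_major, x_minor, eff_len, state_space, h,
                    params: LikelihoodParams) -> np.ndarray:
    """(N, S) emission log-likelihood over the tumour-clone state space.

    ``h`` is (1 + n_tumour,) with the normal clone first; the normal clone
    is fixed at one copy of each allele.  Allele counts are folded onto the
    major allele (``x_major >= x_minor``) to match the major/minor state
    parameterisation.
    """
    h = np.asarray(h, dtype=float)
    totals_full = np.concatenate(
        [np.full((state_space.n_states, 1), 2), state_space.totals], axis=1
    )
    uniq, inverse = np.unique(totals_full, axis=0, return_inverse=True)
    ll_tot = total_count_matrix(x, eff_len, uniq, h, params)[:, inverse]

    num = h[0] * 1.0 + state_space.majors @ h[1:]
    den = h[0] * 2.0 + state_space.totals @ h[1:]
    p = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)  # (S,)
    n_allele = np.asarray(x_major) + np.asarray(x_minor)
    # the observed split is folded onto the major allele, so the density is
    # the two-sided (folded) beta-binomial: either haplotype may be major
    k = np.asarray(x_major)[:, None]
    n = n_allele[:, None]
    ll_allele = np.logaddexp(
        _betabinom_logpmf(k, n, p[None, :], params.allele_overdispersion),
        _betabinom_logpmf(k, n, 1.0 - p[None, :],
                          params.allele_overdispersion),
    )
    return ll_tot + ll_allele
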