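"""Two-part MML87 message lengths for fitted models.

The Wallace-Freeman (1987) approximation codes a model as an assertion
(discrete feature-subset choice, then continuous parameters to finite
precision) followed by the data under that model:

    I = -ln pi(theta) + (1/2) ln|F(theta)| + (D/2)(ln kappa_D + 1)
        - ln f(Y | theta)

where F is the expected Fisher information over the D continuous
parameters and kappa_D the normalized second moment of the optimal
D-dimensional quantizing lattice.  Priors: a uniform code over subset
sizes followed by a uniform code over subsets of that size for the
discrete part; independent N(0, 10^2) priors per coefficient; an
exponential prior for the extra positive parameter (NB dispersion or
hardcore radius) with a family-specific mean.  All lengths are in nats.

Two parameter counts coexist deliberately: ``D_selected`` is the number of
selectable features coded by the discrete prior, while ``D_continuous``
counts every continuous parameter (intercept included, plus the extra
parameter when present) entering the Fisher and lattice terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import InvalidArgumentError, SingularInformationError
from .families import FittedModel

__all__ = [
    "MMLConfig",
    "MessageLength",
    "discrete_prior_nats",
    "gaussian_prior_neglog",
    "exponential_prior_neglog",
    "lattice_dim_term",
    "message_length",
    "mix_message_lengths",
]

#: prior standard deviation for each trend coefficient
PRIOR_SD = 10.0

#: tabulated optimal-quantizing-lattice constants for small dimension
KAPPA_SMALL = {1: 1.0 / 12.0, 2: 0.080, 3: 0.079}


@dataclass(frozen=True)
class MMLConfig:
    """Knobs of the message-length assembly.

    lattice_mode: 'approx' uses the asymptotic lattice-constant formula for
    every dimension (the default, applied uniformly); 'exact_small' uses
    the tabulated kappa_1..kappa_3 below dimension 4.  family_cost_nats
    adds a flat model-family code (ln of the number of families in play)
    for strictly decodable multi-family messages; the default 0 reflects
    equal family priors whose cost is common to all candidates.
    """

    lattice_mode: str = "approx"
    family_cost_nats: float = 0.0
    min_fisher_eig: float = 1e-10


@dataclass(frozen=True)
class MessageLength:
    """Total message length with its itemized breakdown (all nats)."""

    total: float
    discrete_prior: float
    continuous_prior: float
    fisher_half_logdet: float
    lattice_dim_term: float
    neg_loglik: float
    family_cost: float
    D_continuous: int
    D_selected: int
    K: int

    def parts(self) -> dict:
        return {
            "discrete_prior": self.discrete_prior,
            "continuous_prior": self.continuous_prior,
            "fisher_half_logdet": self.fisher_half_logdet,
            "lattice_dim_term": self.lattice_dim_term,
            "neg_loglik": self.neg_loglik,
            "family_cost": self.family_cost,
        }

    def to_json(self) -> str:
        import json

        d = {"total": float(f"{self.total:.17g}")}
        d.update({k: float(f"{v:.17g}") for k, v in self.parts().items()})
        d.update(D_continuous=self.D_continuous, D_selected=self.D_selected,
                 K=self.K)
        return json.dumps(d)


def discrete_prior_nats(K: int, D_selected: int) -> float:
    """Cost of asserting the feature subset: ln(K+1) + ln C(K, D).

    First the subset size (uniform over 0..K), then which subset of that
    size (uniform over C(K, D) subsets); log-gamma keeps large K stable.
    """
    if K < 0 or D_selected < 0 or D_selected > K:
        raise InvalidArgumentError(
            f"need 0 <= D_selected <= K, got D={D_selected}, K={K}")
    log_binom = (gammaln(K + 1) - gammaln(D_selected + 1)
                 - gammaln(K - D_selected + 1))
    return float(np.log(K + 1) + log_binom)


def gaussian_prior_neglog(theta) -> float:
    """-ln of independent N(0, 10^2) priors over the coefficients."""
    theta = np.asarray(theta, dtype=float)
    if theta.size and not np.all(np.isfinite(theta)):
        raise InvalidArgumentError("coefficients must be finite")
    if theta.size == 0:
        return 0.0
    return float(np.sum(0.5 * np.log(2 * np.pi) + np.log(PRIOR_SD)
                        + theta ** 2 / (2 * PRIOR_SD ** 2)))


def exponential_prior_neglog(x: float, mu: float) -> float:
    """-ln of an exponential(mean mu) prior at x: ln(mu) + x/mu."""
    if mu <= 0:
        raise InvalidArgumentError("exponential prior mean must be positive")
    if x < 0:
        raise InvalidArgumentError("exponential prior support is x >= 0")
    return float(np.log(mu) + x / mu)


def lattice_dim_term(D: int, mode: str = "approx") -> float:
    """Quantization cost (D/2)(ln kappa_D + 1) of D continuous parameters.

    'approx' evaluates the asymptotic form
        -(D/2) ln(2 pi) + (1/2) ln(D pi) + gamma
    (gamma the Euler-Mascheroni constant); 'exact_small' substitutes the
    tabulated kappa_D for D <= 3 and falls back to the approximation
    above it.  D = 0 costs nothing.
    """
    if D < 0:
        raise InvalidArgumentError("dimension must be >= 0")
    if D == 0:
        return 0.0
    if mode == "exact_small" and D in KAPPA_SMALL:
        return float(D / 2.0 * (np.log(KAPPA_SMALL[D]) + 1.0))
    if mode not in ("approx", "exact_small"):
        raise InvalidArgumentError(f"unknown lattice mode {mode!r}")
    return float(-D / 2.0 * np.log(2 * np.pi) + 0.5 * np.log(D * np.pi)
                 + np.euler_gamma)


def message_length(model: FittedModel, K: int,
                   config: MMLConfig | None = None) -> MessageLength:
    """Assemble the MML87 message length of a fitted model.

    The extra positive parameter (NB dispersion or hardcore radius) enters
    the continuous prior through its exponential prior and raises the
    Fisher/lattice dimension by one, mirroring the coefficient treatment.
    """
    config = config or MMLConfig()
    d_sel = len(model.subset)
    extra = model.dispersion if model.dispersion is not None else model.radius
    d_cont = len(model.theta) + (extra is not None)

    discrete = discrete_prior_nats(K, d_sel)
    continuous = gaussian_prior_neglog(model.theta)
    if extra is not None:
        continuous += exponential_prior_neglog(extra, model.extra_prior_mean)

    F = np.asarray(model.fisher, dtype=float)
    if F.shape != (d_cont, d_cont):
        raise InvalidArgumentError(
            f"fisher must be {d_cont}x{d_cont}, got {F.shape}")
    eigs = np.linalg.eigvalsh((F + F.T) / 2.0)
    if eigs.min() <= config.min_fisher_eig:
        raise SingularInformationError(
            f"Fisher information singular (min eigenvalue {eigs.min():.3g})")
    half_logdet = float(0.5 * np.sum(np.log(eigs)))

    lattice = lattice_dim_term(d_cont, config.lattice_mode)
    neg_ll = -float(model.loglik)
    total = (discrete + continuous + half_logdet + lattice + neg_ll
             + config.family_cost_nats)
    return MessageLength(total, discrete, continuous, half_logdet, lattice,
                         neg_ll, config.family_cost_nats, d_cont, d_sel, K)


def mix_message_lengths(I1: float, I2: float) -> float:
    """Length of the half-half mixture of two codes for the same event.

    -ln((e^{-I1} + e^{-I2})/2), computed by log-sum-exp; always within
    [min(I1,I2), min(I1,I2) + ln 2).  One input may be +inf (that code is
    unusable), both may not.
    """
    if np.isnan(I1) or np.isnan(I2):
        raise InvalidArgumentError("message lengths must not be NaN")
    if np.isinf(I1) and np.isinf(I2):
        raise InvalidArgumentError("both codes unusable (infinite length)")
    lo = min(I1, I2)
    if np.isinf(max(I1, I2)):
        return lo + np.log(2.0)
    out = lo - np.log1p(np.exp(-(max(I1, I2) - lo))) + np.log(2.0)
    return float(max(out, lo))  # guard the bound against rounding at I1~I2
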