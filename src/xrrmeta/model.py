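"""Restricted Beta random-effects law and the conditional sampling model.

Study-level treatment contrasts ``pi_i`` are modelled as independent
draws from a Beta(alpha, beta) distribution with ``alpha, beta >= 1``.
The shape restriction keeps the law unimodal, so the mean ``mu`` is an
interpretable, identifiable centre; in mean/variance coordinates it is
equivalent to ``v <= v_sup(mu)``.

Conditioning each study's treated-arm count on the study's total events
eliminates the baseline event rate: under the two-Poisson model,

    Y1 | Y_total ~ Binomial(Y_total, expit(logit(pi) + S)),

where ``S = log(n1 / n2)`` is the design offset.  The Monte-Carlo
sampler draws whole synthetic meta-datasets from this conditional law,
holding each study's total events and sample sizes fixed at their
observed values, so no double-zero study can ever arise in a replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from xrrmeta.data import MetaDataset, StudyCounts

# Below this variance the Beta shapes overflow; treat the law as a point
# mass at mu (the v -> 0 limit).
DEGENERATE_V = 1e-10


class ConstraintError(ValueError):
    """(mu, v) outside the unimodal Beta parameter space."""


def v_sup(mu):
    """Largest contrast variance compatible with a unimodal Beta law.

    ``v_sup(mu) = mu (1 - mu) * min(mu / (1 + mu), (1 - mu) / (2 - mu))``.
    At this boundary ``min(alpha, beta) = 1``; the function is symmetric
    about ``mu = 0.5`` where it attains ``1/12``.  Accepts scalars or
    arrays.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any((mu <= 0.0) | (mu >= 1.0)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    bound = mu * (1.0 - mu) * np.minimum(mu / (1.0 + mu), (1.0 - mu) / (2.0 - mu))
    return float(bound) if bound.ndim == 0 else bound


def shape_from_moments(mu: float, v: float) -> tuple[float, float]:
    """Map (mean, variance) of the contrast law to Beta shapes.

    ``alpha = mu (mu(1-mu) - v) / v`` and ``beta = (1-mu)(mu(1-mu) - v) / v``.
    Requires ``0 < v <= v_sup(mu)`` so that both shapes are >= 1; shapes
    are clipped to exactly 1 at the boundary to absorb rounding.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must be in (0, 1), got {mu}")
    if v <= 0.0:
        raise ValueError(f"v must be positive, got {v}")
    if v >= mu * (1.0 - mu):
        raise ConstraintError(f"v={v} is not a feasible Beta variance for mu={mu}")
    bound = v_sup(mu)
    if v > bound * (1.0 + 1e-12):
        raise ConstraintError(f"v={v} exceeds the unimodality bound v_sup({mu})={bound}")
    common = (mu * (1.0 - mu) - v) / v
    alpha = max(mu * common, 1.0)
    beta = max((1.0 - mu) * common, 1.0)
    # at the boundary v = v_sup(mu) the smaller shape equals 1 exactly;
    # snap away the last-ulp noise of the algebra above
    if abs(alpha - 1.0) < 1e-12:
        alpha = 1.0
    if abs(beta - 1.0) < 1e-12:
        beta = 1.0
    return alpha, beta


def moments_from_shape(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and variance of a Beta(alpha, beta) contrast law."""
    if alpha <= 0.0 or beta <= 0.0:
        raise ValueError(f"shape parameters must be positive, got ({alpha}, {beta})")
    mu = alpha / (alpha + beta)
    v = mu * (1.0 - mu) / (alpha + beta + 1.0)
    return mu, v


@dataclass(frozen=True)
class BetaParams:
    """The contrast random-effects law in both coordinate systems.

    ``mu``/``v`` are the mean and variance of the study contrast,
    ``alpha``/``beta`` the Beta shapes; the unimodality constraint
    ``v <= v_sup(mu)`` (equivalently ``min(alpha, beta) >= 1``) is
    enforced at construction.
    """

    mu: float
    v: float
    alpha: float
    beta: float

    @classmethod
    def from_moments(cls, mu: float, v: float) -> "BetaParams":
        alpha, beta = shape_from_moments(mu, v)
        return cls(mu=mu, v=v, alpha=alpha, beta=beta)

    @classmethod
    def from_shape(cls, alpha: float, beta: float) -> "BetaParams":
        if min(alpha, beta) < 1.0:
            raise ConstraintError(f"shapes ({alpha}, {beta}) violate min(alpha, beta) >= 1")
        mu, v = moments_from_shape(alpha, beta)
        return cls(mu=mu, v=v, alpha=alpha, beta=beta)

    @property
    def tau(self) -> float:
        """Between-study variability scale ``1 / (alpha + beta + 1)``."""
        return 1.0 / (self.alpha + self.beta + 1.0)


@dataclass(frozen=True)
class StudyEffect:
    """One study's treatment contrast on both scales.

    ``pi`` is the contrast ``lambda1 / (lambda1 + lambda2)``; ``xi`` is
    the log relative risk ``logit(pi)``.  ``pi = 0.5`` iff ``xi = 0``.
    """

    pi: float

    @property
    def xi(self) -> float:
        return float(logit(self.pi))

    @classmethod
    def from_log_rr(cls, xi: float) -> "StudyEffect":
        return cls(pi=float(expit(xi)))


def conditional_success_prob(pi, s):
    """Success probability of Y1 | Y_total: ``expit(logit(pi) + s)``.

    ``pi`` is the study contrast, ``s = log(n1/n2)`` the design offset;
    a balanced design (``s = 0``) returns ``pi`` itself.  Evaluated in
    log space, so extreme contrasts do not overflow.  Vectorised.
    """
    pi = np.asarray(pi, dtype=float)
    out = expit(logit(pi) + np.asarray(s, dtype=float))
    return float(out) if out.ndim == 0 else out


def _canonical_order(template: MetaDataset) -> np.ndarray:
    """Column permutation making the MC draws invariant to study order.

    Draws are generated in a canonical (lexicographically sorted)
    arrangement of the studies and mapped back, so permuting the input
    rows leaves every study's random stream — and hence the p-value —
    unchanged.
    """
    labels = np.array([s.label for s in template.studies])
    keys = (labels, template.n2, template.n1, template.y2, template.y1)
    return np.lexsort(keys)


def sample_y1_matrix(
    mu: float,
    v: float,
    template: MetaDataset,
    rng: np.random.Generator,
    m: int,
) -> np.ndarray:
    """Draw ``m`` conditional replicates of the treated-arm counts.

    Returns an ``(m, k)`` integer array; column ``i`` holds replicate
    treated-arm counts for study ``i``, with totals fixed at the
    template's observed totals.  When ``v`` is below the degeneracy
    floor the contrast is the point mass at ``mu``.
    """
    order = _canonical_order(template)
    y_tot = template.y_total[order]
    offsets = template.offsets[order]
    k = template.k
    if v < DEGENERATE_V:
        prob = conditional_success_prob(np.full((m, k), mu), offsets[None, :])
    else:
        alpha, beta = shape_from_moments(mu, v)
        pi = rng.beta(alpha, beta, size=(m, k))
        # Beta draws can hit 0.0/1.0 in floating point; clamp inside (0,1).
        tiny = np.finfo(float).tiny
        np.clip(pi, tiny, 1.0 - 1e-16, out=pi)
        prob = conditional_success_prob(pi, offsets[None, :])
    y1_sorted = rng.binomial(np.broadcast_to(y_tot, (m, k)), prob)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(k)
    return y1_sorted[:, inverse]


def sample_conditional_dataset(
    params: BetaParams,
    template: MetaDataset,
    rng_seed: int | np.random.Generator,
) -> MetaDataset:
    """Draw one synthetic meta-dataset from the conditional model.

    Sample sizes and per-study total events are copied from the
    template; only the split of each total between the arms is random.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    y1 = sample_y1_matrix(params.mu, params.v, template, rng, m=1)[0]
    studies = tuple(
        StudyCounts(
            y1=int(y1[i]),
            n1=s.n1,
            y2=int(s.y_total - y1[i]),
            n2=s.n2,
            label=s.label,
        )
        for i, s in enumerate(template.studies)
    )
    return MetaDataset(studies=studies, k_tot=template.k_tot)
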