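"""Method-of-moments estimation of the contrast law and the Wald statistic.

Under a balanced design (equal arm sizes) the conditional law of each
study's treated-arm count is beta-binomial, and the mean ``mu`` and
variance ``v`` of the contrast law have closed-form moment estimators.
Unbalanced studies are reduced to a weighted mixture of balanced ones by
*hypergeometric resampling*: the larger arm is notionally down-sampled
to the smaller arm's size, the possible retained event counts are
enumerated with hypergeometric probabilities, and the balanced-design
moment sums are averaged over that support.  An outcome that would turn
a study into a double-zero study is excluded from the support and the
weights renormalised, mirroring the removal of double-zero studies from
the observed data.

The continuity correction (0.5 added to events, 1 to totals) enters only
the variance-related moment sums, never the point estimator of ``mu``;
it keeps studies with a single event contributing and keeps the
estimated variance positive.  Because the exact test applies the same
statistic to observed and simulated data, the correction does not affect
the validity of the resulting inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from xrrmeta.data import MetaDataset, StudyCounts

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


class InsufficientStudiesError(ValueError):
    """Fewer than two retained studies; the moment estimators need k >= 2."""


class DesignError(ValueError):
    """Balanced-design estimator applied to unbalanced data."""


class DegenerateVarianceError(ValueError):
    """Wald statistic requested with a non-positive variance estimate."""


@dataclass(frozen=True)
class MomentEstimates:
    """Moment estimates of the contrast law from one meta-dataset.

    ``mu_hat`` is the point estimate of the mean contrast (raw counts,
    no correction), ``v_hat`` the truncated-at-zero estimate of the
    between-study variance, ``var_mu_hat`` the estimated variance of
    ``mu_hat`` (continuity-corrected totals throughout).
    """

    mu_hat: float
    v_hat: float
    var_mu_hat: float
    design: str  # "balanced" | "weighted"
    k: int


@dataclass(frozen=True)
class ResampleSupport:
    """Balanced-design outcomes for one study after hypergeometric resampling.

    ``events`` holds the possible treated-arm event counts, ``totals``
    the corresponding study totals, ``weights`` their probabilities
    (summing to 1 after the double-zero correction).  Both resampled
    arm sizes equal the smaller arm's size ``size``.
    """

    events: np.ndarray
    totals: np.ndarray
    weights: np.ndarray
    size: int


def resample_support(study: StudyCounts) -> ResampleSupport:
    """Enumerate a study's balanced-design outcomes and their weights.

    The larger arm is down-sampled to the smaller arm's size; the number
    of events retained follows a hypergeometric law.  If the fixed
    (smaller) arm has zero events, the outcome retaining zero events —
    which would make the study double-zero — is dropped and the weights
    renormalised.  A balanced study yields its observed outcome with
    weight 1.
    """
    if study.is_double_zero:
        raise ValueError("double-zero studies have no resampling support")
    if study.is_balanced:
        return ResampleSupport(
            events=np.array([study.y1]),
            totals=np.array([study.y_total]),
            weights=np.array([1.0]),
            size=study.n1,
        )
    treated_larger = study.n1 > study.n2
    n_lg, y_lg = (study.n1, study.y1) if treated_larger else (study.n2, study.y2)
    n_sm, y_fix = (study.n2, study.y2) if treated_larger else (study.n1, study.y1)
    lo = max(0, n_sm - n_lg + y_lg)
    support = np.arange(lo, y_lg + 1)
    weights = hypergeom.pmf(support, n_lg, y_lg, n_sm)
    totals = support + y_fix
    if y_fix == 0:
        keep = support > 0
        support, weights, totals = support[keep], weights[keep], totals[keep]
    weights = weights / weights.sum()
    events = support if treated_larger else np.full_like(support, y_fix)
    return ResampleSupport(events=events, totals=totals, weights=weights, size=n_sm)


def mom_balanced(data: MetaDataset) -> MomentEstimates:
    """Closed-form moment estimates for an all-balanced meta-dataset.

    ``mu_hat = K^-1 sum y1_i / ytot_i`` on raw counts; the variance
    moments use corrected counts ``(y1 + 0.5) / (ytot + 1)``, and
    ``v_hat`` is truncated at zero.
    """
    _check_k(data)
    if data.any_unbalanced:
        raise DesignError("dataset contains unbalanced studies; use mom_weighted")
    y1 = data.y1.astype(float)
    ytot = data.y_total.astype(float)
    k = data.k
    mu_hat = float(np.mean(y1 / ytot))
    t1c = y1 + 0.5
    totc = ytot + 1.0
    mu_int = float(np.mean(t1c / totc))
    num = np.sum((t1c / totc) ** 2 - mu_int / totc)
    den = np.sum(1.0 - 1.0 / totc)
    v_hat = max(0.0, float(num / den - mu_int**2))
    var = float(np.sum(np.maximum(mu_hat * (1.0 - mu_hat), _EPS) / totc + (1.0 - 1.0 / totc) * v_hat) / k**2)
    _warn_degenerate(mu_hat, v_hat)
    return MomentEstimates(mu_hat=mu_hat, v_hat=v_hat, var_mu_hat=var, design="balanced", k=k)


def mom_weighted(data: MetaDataset) -> MomentEstimates:
    """Hypergeometric-resampling moment estimates for any design.

    Averages the balanced-design moment sums over each study's
    resampling support.  Reduces exactly to :func:`mom_balanced` when
    every study is balanced (singleton supports).
    """
    _check_k(data)
    engine = MomentEngine(data)
    mu, v, var = engine.moments(data.y1[None, :])
    _warn_degenerate(float(mu[0]), float(v[0]))
    return MomentEstimates(
        mu_hat=float(mu[0]),
        v_hat=float(v[0]),
        var_mu_hat=float(var[0]),
        design="weighted",
        k=data.k,
    )


def point_estimates(data: MetaDataset) -> MomentEstimates:
    """Moment estimates using the design-appropriate estimator."""
    return mom_weighted(data) if data.any_unbalanced else mom_balanced(data)


def wald_statistic(mu_null: float, est: MomentEstimates) -> float:
    """Wald statistic ``(point - mu_null)^2 / var`` for H0: mu = mu_null."""
    if not np.isfinite(est.var_mu_hat) or est.var_mu_hat <= 0.0:
        raise DegenerateVarianceError(f"invalid variance estimate {est.var_mu_hat}")
    return float((est.mu_hat - mu_null) ** 2 / est.var_mu_hat)


def _check_k(data: MetaDataset) -> None:
    if data.k < 2:
        raise InsufficientStudiesError(f"need at least 2 retained studies, got {data.k}")


def _warn_degenerate(mu_hat: float, v_hat: float) -> None:
    if v_hat == 0.0 and mu_hat in (0.0, 1.0):
        warnings.warn(
            "point estimate on the boundary with zero between-study variance; "
            "the Wald denominator is floored at machine epsilon",
            RuntimeWarning,
            stacklevel=3,
        )


class MomentEngine:
    """Vectorised weighted moment estimator over replicate datasets.

    Precomputes the per-study design facts from a template dataset;
    :meth:`moments` then evaluates the weighted estimator on an
    ``(m, k)`` matrix of treated-arm counts (totals, arm sizes and
    offsets fixed at the template's), returning ``(mu, v, var)`` arrays
    of length ``m``.  This is the inner loop of the Monte-Carlo test,
    so everything is batched per study across replicates.
    """

    def __init__(self, template: MetaDataset):
        self.template = template
        self.k = template.k
        self.y_tot = template.y_total
        self.n1 = template.n1
        self.n2 = template.n2
        self.balanced = self.n1 == self.n2
        # Per unbalanced study: hypergeometric population facts.
        self.treated_larger = self.n1 > self.n2
        self.n_lg = np.maximum(self.n1, self.n2)
        self.n_sm = np.minimum(self.n1, self.n2)

    def moments(self, y1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        y1 = np.asarray(y1)
        m, k = y1.shape
        if k != self.k:
            raise ValueError(f"expected {self.k} study columns, got {k}")
        # Accumulated moment sums across studies, per replicate:
        # A: raw ratio; B: corrected ratio; C1: corrected ratio squared;
        # C2: 1/corrected total; D: 1 - 1/corrected total.
        A = np.zeros(m)
        B = np.zeros(m)
        C1 = np.zeros(m)
        C2 = np.zeros(m)
        D = np.zeros(m)
        for i in range(k):
            col = y1[:, i].astype(np.int64)
            ytot = int(self.y_tot[i])
            if self.balanced[i]:
                ratio = col / ytot
                totc = ytot + 1.0
                rc = (col + 0.5) / totc
                A += ratio
                B += rc
                C1 += rc**2
                C2 += 1.0 / totc
                D += 1.0 - 1.0 / totc
                continue
            treated_larger = bool(self.treated_larger[i])
            y_lg = col if treated_larger else ytot - col
            y_fix = ytot - y_lg
            n_lg = int(self.n_lg[i])
            n_sm = int(self.n_sm[i])
            grid = np.arange(ytot + 1)  # y_lg <= ytot, so this covers every support
            w = hypergeom.pmf(grid[None, :], n_lg, y_lg[:, None], n_sm)
            # Double-zero correction: when the fixed arm has no events,
            # the all-zero resampled outcome is excluded.
            total = grid[None, :] + y_fix[:, None]
            w = np.where(total == 0, 0.0, w)
            w /= w.sum(axis=1, keepdims=True)
            treated = np.broadcast_to(grid[None, :], w.shape) if treated_larger else np.broadcast_to(
                y_fix[:, None], w.shape
            )
            safe_total = np.maximum(total, 1)
            totc = total + 1.0
            rc = (treated + 0.5) / totc
            A += np.sum(w * (treated / safe_total), axis=1)
            B += np.sum(w * rc, axis=1)
            C1 += np.sum(w * rc**2, axis=1)
            C2 += np.sum(w / totc, axis=1)
            D += np.sum(w * (1.0 - 1.0 / totc), axis=1)
        mu = A / k
        mu_int = B / k
        v = np.maximum(0.0, (C1 - mu_int * C2) / D - mu_int**2)
        var = (np.maximum(mu * (1.0 - mu), _EPS) * C2 + v * D) / k**2
        return mu, v, var

    def wald(self, mu_null: float, y1: np.ndarray) -> np.ndarray:
        """Wald statistics for H0: mu = mu_null over replicate datasets."""
        mu, _, var = self.moments(y1)
        return (mu - mu_null) ** 2 / var
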