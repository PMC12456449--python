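"""Poisson–Gamma data generation and operating-characteristic harness.

Each study's arm-level event rates are drawn as

    lambda_1 ~ Gamma(alpha0, rate = alpha0 / r0)
    lambda_2 ~ Gamma(beta0,  rate = alpha0 / r0)

with a shared rate parameter, so the contrast
``pi = lambda_1 / (lambda_1 + lambda_2)`` follows Beta(alpha0, beta0)
exactly, the treated arm has mean event rate ``r0`` and the control arm
``r0 * beta0 / alpha0``.  Counts are Poisson with mean ``n * lambda``,
truncated at the arm size (a vanishing-probability event at rare-event
rates, counted when it happens).

The harness measures type-I error / power (profile test at a
hypothesised contrast), coverage and CI length (full test inversion),
and the prevalence of double-zero studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from xrrmeta.data import MetaDataset, StudyCounts, filter_double_zero
from xrrmeta.inference import GridConfig, exact_ci, profile_pvalue
from xrrmeta.model import moments_from_shape, v_sup

logger = logging.getLogger(__name__)

#: Beta shape parameters of the three primary heterogeneity settings
#: (high, moderate, low between-study variability), each with a null
#: (mu0 = 0.5) and a protective (mu0 = 0.4, relative risk 0.67) variant.
SETTINGS: dict[str, tuple[float, float]] = {
    "setting1_null": (1.45, 1.45),
    "setting1_protective": (1.10, 1.65),
    "setting2_null": (5.50, 5.50),
    "setting2_protective": (4.20, 6.30),
    "setting3_null": (145.0, 145.0),
    "setting3_protective": (110.0, 165.0),
}

# Synthetic arm-size generator: per-study base size log-uniform on
# [60, 700], imbalance ratio drawn from {1, 1.6, 2}, larger arm assigned
# to treatment or control with equal probability.
_SIZE_RANGE = (60, 700)
_IMBALANCE_RATIOS = (1.0, 1.6, 2.0)


@dataclass(frozen=True)
class SimSetting:
    """One simulation scenario.

    ``alpha0``/``beta0`` are the Beta shapes of the contrast law,
    ``r0`` the mean treated-arm event rate, ``k_tot`` the number of
    studies generated (before double-zero filtering), ``size_source``
    an optional pool of ``(n1, n2)`` pairs sampled with replacement
    (defaults to the synthetic size generator above).
    """

    alpha0: float
    beta0: float
    r0: float = 0.01
    k_tot: int = 24
    size_source: Optional[Sequence[tuple[int, int]]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.alpha0, self.beta0) < 1.0:
            raise ValueError("shape parameters must be >= 1 (unimodal contrast law)")
        if not 0.0 < self.r0 < 1.0:
            raise ValueError(f"r0 must be in (0, 1), got {self.r0}")
        if self.k_tot < 1:
            raise ValueError("k_tot must be >= 1")
        mu0, v0 = self.moments
        assert v0 <= v_sup(mu0) * (1 + 1e-12)

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "SimSetting":
        a, b = SETTINGS[name]
        return cls(alpha0=a, beta0=b, label=name, **kwargs)

    @property
    def moments(self) -> tuple[float, float]:
        """True (mu0, v0) of the contrast law."""
        return moments_from_shape(self.alpha0, self.beta0)


def _draw_sizes(setting: SimSetting, rng: np.random.Generator) -> np.ndarray:
    k = setting.k_tot
    if setting.size_source is not None:
        pool = np.asarray(setting.size_source, dtype=np.int64)
        return pool[rng.integers(0, len(pool), size=k)]
    base = np.exp(rng.uniform(np.log(_SIZE_RANGE[0]), np.log(_SIZE_RANGE[1]), size=k))
    ratio = rng.choice(_IMBALANCE_RATIOS, size=k)
    small = np.maximum(1, np.round(base).astype(np.int64))
    large = np.maximum(1, np.round(base * ratio).astype(np.int64))
    treated_larger = rng.random(k) < 0.5
    n1 = np.where(treated_larger, large, small)
    n2 = np.where(treated_larger, small, large)
    return np.column_stack([n1, n2])


def draw_arm_rates(
    setting: SimSetting, rng: np.random.Generator, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-study arm event rates.

    Shared Gamma rate parameter ``alpha0 / r0`` in both arms, so the
    implied contrast ``lam1 / (lam1 + lam2)`` is Beta(alpha0, beta0),
    the treated arm has mean rate ``r0`` and the control arm
    ``r0 * beta0 / alpha0``.
    """
    rate = setting.alpha0 / setting.r0
    lam1 = rng.gamma(setting.alpha0, scale=1.0 / rate, size=k)
    lam2 = rng.gamma(setting.beta0, scale=1.0 / rate, size=k)
    return lam1, lam2


def generate_meta_dataset(
    setting: SimSetting,
    rng_seed: int | np.random.Generator,
) -> tuple[list[StudyCounts], Optional[MetaDataset]]:
    """Generate one meta-analysis dataset under the Poisson–Gamma model.

    Returns the full study list (including double-zero studies) and the
    filtered :class:`MetaDataset`, or ``None`` for the latter when every
    study is double-zero.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    k = setting.k_tot
    lam1, lam2 = draw_arm_rates(setting, rng, k)
    sizes = _draw_sizes(setting, rng)
    y1 = rng.poisson(sizes[:, 0] * lam1)
    y2 = rng.poisson(sizes[:, 1] * lam2)
    n_trunc = int(np.count_nonzero(y1 > sizes[:, 0]) + np.count_nonzero(y2 > sizes[:, 1]))
    if n_trunc:
        logger.debug("truncated %d Poisson counts at the arm size", n_trunc)
        y1 = np.minimum(y1, sizes[:, 0])
        y2 = np.minimum(y2, sizes[:, 1])
    studies = [
        StudyCounts(
            y1=int(y1[i]),
            n1=int(sizes[i, 0]),
            y2=int(y2[i]),
            n2=int(sizes[i, 1]),
            label=f"sim_{i + 1}",
        )
        for i in range(k)
    ]
    retained, _ = filter_double_zero(studies)
    dataset = MetaDataset(studies=tuple(retained), k_tot=k) if retained else None
    return studies, dataset


def dz_fraction(setting: SimSetting, n_studies: int, rng_seed: int) -> float:
    """Fraction of double-zero studies among ``n_studies`` generated ones."""
    rng = np.random.default_rng(rng_seed)
    total = 0
    dz = 0
    while total < n_studies:
        studies, _ = generate_meta_dataset(setting, rng)
        dz += sum(s.is_double_zero for s in studies)
        total += len(studies)
    return dz / total


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of the exact procedure."""

    rejection_rate: float
    rejection_se: float
    n_reps: int
    mu_null: float
    setting: SimSetting
    mode: str
    coverage: Optional[float] = None
    coverage_se: Optional[float] = None
    mean_ci_length: Optional[float] = None
    dz_fraction: float = 0.0
    n_redrawn: int = 0
    records: list = field(default_factory=list)


def run_operating_characteristics(
    setting: SimSetting,
    mu_null: float,
    n_reps: int,
    cfg: GridConfig,
    mode: str = "test_only",
    seed: int = 0,
    comparators: Optional[dict[str, Callable[[MetaDataset], bool]]] = None,
) -> OperatingCharacteristics:
    """Measure rejection rate (and, in ``full_ci`` mode, coverage/length).

    ``test_only`` computes the profile p-value at ``mu_null`` per
    replicate and rejects when it falls below ``cfg.alpha``; ``full_ci``
    inverts the whole test family per replicate and additionally scores
    coverage of the true mean contrast and CI length.  Replicates in
    which fewer than two studies survive double-zero filtering are
    counted and redrawn.  ``comparators`` maps names to callables
    returning a reject/accept decision, for benchmarking external
    methods on the same replicates.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mode not in ("test_only", "full_ci"):
        raise ValueError(f"unknown mode {mode!r}")
    mu0, _ = setting.moments
    rejections = 0
    coverage_hits = 0
    lengths = []
    records = []
    dz_total = 0
    study_total = 0
    n_redrawn = 0
    for rep in range(n_reps):
        attempt = 0
        while True:
            rep_seed = [seed % 2**31, rep, attempt]
            studies, dataset = generate_meta_dataset(setting, np.random.default_rng(rep_seed))
            dz_total += sum(s.is_double_zero for s in studies)
            study_total += len(studies)
            if dataset is not None and dataset.k >= 2:
                break
            n_redrawn += 1
            attempt += 1
            logger.info("replicate %d: %s; redrawing", rep, "all studies double-zero" if dataset is None else "fewer than 2 retained studies")
        rep_cfg = GridConfig(
            s=cfg.s,
            m=cfg.m,
            alpha=cfg.alpha,
            correction_span=cfg.correction_span,
            seed=(cfg.seed * 1000003 + rep) % 2**31,
        )
        record = {"rep": rep, "k": dataset.k, "k_tot": dataset.k_tot}
        if mode == "test_only":
            res = profile_pvalue(mu_null, dataset, rep_cfg)
            reject = res.p < cfg.alpha
            record.update(p=res.p, reject=reject)
        else:
            ci = exact_ci(dataset, rep_cfg)
            reject = not ci.contains(mu_null)
            covered = ci.contains(mu0)
            coverage_hits += covered
            lengths.append(ci.length)
            record.update(
                lower=ci.lower, upper=ci.upper, p=ci.p_at_null, reject=reject, covered=covered
            )
        if comparators:
            for name, fn in comparators.items():
                record[f"reject_{name}"] = bool(fn(dataset))
        rejections += reject
        records.append(record)
    rate = rejections / n_reps
    se = float(np.sqrt(rate * (1.0 - rate) / n_reps))
    oc = OperatingCharacteristics(
        rejection_rate=rate,
        rejection_se=se,
        n_reps=n_reps,
        mu_null=mu_null,
        setting=setting,
        mode=mode,
        dz_fraction=dz_total / study_total,
        n_redrawn=n_redrawn,
        records=records,
    )
    if mode == "full_ci":
        cov = coverage_hits / n_reps
        oc.coverage = cov
        oc.coverage_se = float(np.sqrt(cov * (1.0 - cov) / n_reps))
        oc.mean_ci_length = float(np.mean(lengths))
    return oc
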