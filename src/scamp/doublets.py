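"""Doublet-rate inference from a two-population genotype mixing experiment.

When nuclei from two patients with distinct private drivers are mixed and
run through the same droplet workflow, droplets containing nuclei from both
populations carry both genotypes and are unambiguous doublets. With overall
doublet rate ``d`` and population-A fraction ``p`` (constituents drawn
independently), the genotype categories occur with probabilities

    P(A-only) = (1-d)·p     + d·p²
    P(B-only) = (1-d)·(1-p) + d·(1-p)²
    P(AB)     = 2·d·p·(1-p)

Same-population doublets are genotypically indistinguishable from singlets
and are folded into the singlet categories, so ``d`` here is the full
doublet rate, not just the observable cross-population part. This mixture is
a reconstruction of the standard two-population multiplet model; allelic
dropout can misclassify true AB droplets as single-genotype and biases the
estimate downward (not corrected).

The multinomial likelihood over (d, p) is saturated (two free parameters,
two free frequencies), so the interior MLE is closed-form:
``p̂ = (1 + f_A − f_B)/2`` and ``d̂ = f_AB / (2·p̂·(1−p̂))``, clipped to
[0, 1]. A seeded nonparametric bootstrap supplies the 95% CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import Genotype, GenotypeMatrix, ValidationError, VariantId

__all__ = ["MixingCounts", "DoubletEstimate", "classify_mixing_cells", "estimate_doublet_rate"]


@dataclass(frozen=True)
class MixingCounts:
    n_A: int
    n_B: int
    n_AB: int
    n_neither: int = 0

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B, self.n_AB, self.n_neither) < 0:
            raise ValidationError("negative counts")
        if self.n_total == 0:
            raise ValidationError("no informative cells (all categories empty)")

    @property
    def n_total(self) -> int:
        return self.n_A + self.n_B + self.n_AB


@dataclass
class DoubletEstimate:
    d_hat: float
    p_hat: float
    log_likelihood: float
    ci_95: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_hat <= 1.0 and 0.0 <= self.p_hat <= 1.0):
            raise ValidationError("estimates outside [0,1]")
        lo, hi = self.ci_95
        if not (lo - 1e-12 <= self.d_hat <= hi + 1e-12):
            raise ValidationError("confidence interval does not contain the estimate")


def classify_mixing_cells(
    g: GenotypeMatrix,
    driver_A: VariantId,
    driver_B: VariantId,
) -> MixingCounts:
    """Count A-only / B-only / AB carriers among genotyped cells.

    A cell carries a driver if its call there is HET or HOM (MISSING counts
    as non-carrier). Cells carrying neither driver are reported separately
    and excluded from the mixture categories.
    """
    a = g.carrier_mask(driver_A)
    b = g.carrier_mask(driver_B)
    n_ab = int((a & b).sum())
    n_a = int((a & ~b).sum())
    n_b = int((b & ~a).sum())
    n_neither = int((~a & ~b).sum())
    return MixingCounts(n_A=n_a, n_B=n_b, n_AB=n_ab, n_neither=n_neither)


def _category_probs(d: float, p: float) -> np.ndarray:
    return np.array(
        [
            (1 - d) * p + d * p * p,
            (1 - d) * (1 - p) + d * (1 - p) * (1 - p),
            2 * d * p * (1 - p),
        ]
    )


def _log_likelihood(counts: np.ndarray, d: float, p: float) -> float:
    probs = _category_probs(d, p)
    with np.errstate(divide="ignore"):
        terms = np.where(counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(terms.sum())


def _mle(counts: np.ndarray) -> tuple[float, float]:
    n = counts.sum()
    f_a, f_b, f_ab = counts / n
    p_hat = float(np.clip((1.0 + f_a - f_b) / 2.0, 0.0, 1.0))
    if f_ab == 0:
        return 0.0, p_hat
    denom = 2.0 * p_hat * (1.0 - p_hat)
    if denom == 0:
        # one population absent yet AB observed: inconsistent, saturate d
        return 1.0, p_hat
    return float(np.clip(f_ab / denom, 0.0, 1.0)), p_hat


def estimate_doublet_rate(
    c: MixingCounts,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DoubletEstimate:
    """Maximum-likelihood doublet rate with a bootstrap 95% CI.

    The MLE is the closed-form multinomial solution; when the observed AB
    fraction exceeds its theoretical maximum ``2·p̂·(1−p̂)`` the estimate
    saturates at d̂ = 1 with a warning.
    """
    counts = np.array([c.n_A, c.n_B, c.n_AB], dtype=float)
    d_hat, p_hat = _mle(counts)
    if d_hat >= 1.0 and c.n_AB > 0:
        warnings.warn(
            "observed AB fraction exceeds the model maximum; reporting boundary d=1"
        )
    ll = _log_likelihood(counts, d_hat, p_hat)
    rng = np.random.default_rng(seed)
    n = int(counts.sum())
    boot = np.empty(n_bootstrap)
    resamples = rng.multinomial(n, counts / n, size=n_bootstrap)
    for i in range(n_bootstrap):
        boot[i], _ = _mle(resamples[i].astype(float))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo = min(float(lo), d_hat)
    hi = max(float(hi), d_hat)
    return DoubletEstimate(d_hat=d_hat, p_hat=p_hat, log_likelihood=ll, ci_95=(lo, hi))
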