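"""Poisson quantification of droplet digital PCR partitions.

A ddPCR reaction partitions template into ~20,000 droplets; each channel
(mutant probe, wild-type probe) reports how many droplets fluoresced.
Because template molecules distribute over droplets as Poisson, the mean
copies per droplet per channel is recovered from the positive fraction:

    λ = −ln(1 − n_pos / n_total)

Concentration follows from droplet volume, and the mutant fractional
abundance — the ddPCR analogue of VAF — is λ_mut / (λ_mut + λ_wt).
95% confidence intervals come from an exact (Clopper–Pearson) binomial CI
on the positive fraction, propagated through −ln(1 − ·), which is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

#: Droplet volume of the common QX-series systems, in nanolitres.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Minimum mutant-positive droplets for a "detected" call.
DEFAULT_MIN_POS_DROPLETS = 3


@dataclass(frozen=True)
class DropletCounts:
    """Per-channel positive droplet counts of one well."""

    n_total: int
    n_mut_pos: int
    n_wt_pos: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be > 0")
        for name in ("n_mut_pos", "n_wt_pos"):
            v = getattr(self, name)
            if not 0 <= v <= self.n_total:
                raise ValueError(f"{name} must be in [0, n_total], got {v}")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")


@dataclass
class PoissonQuant:
    """Derived quantities of one well."""

    lambda_mut: float
    lambda_wt: float
    conc_mut: float   # copies per microlitre
    conc_wt: float
    fractional_abundance: float | None  # None when both channels are empty
    ci95_mut: tuple[float, float]
    ci95_wt: tuple[float, float]
    detected: bool


def _lambda(n_pos: int, n_total: int, channel: str) -> float:
    if n_pos == n_total:
        raise ValueError(
            f"{channel} channel saturated ({n_pos}/{n_total} positive): "
            "lambda is undefined; dilute the sample"
        )
    return float(-np.log1p(-n_pos / n_total))


def _ci95_lambda(n_pos: int, n_total: int) -> tuple[float, float]:
    # Clopper-Pearson interval on the positive fraction, mapped through
    # the monotone -ln(1-p). Upper bound of p may be 1 only if n_pos==n_total,
    # which is rejected before we get here.
    alpha = 0.05
    lo = 0.0 if n_pos == 0 else float(beta_dist.ppf(alpha / 2, n_pos, n_total - n_pos + 1))
    hi = float(beta_dist.ppf(1 - alpha / 2, n_pos + 1, n_total - n_pos))
    return (float(-np.log1p(-lo)), float(-np.log1p(-hi)))


def quantify(d: DropletCounts, min_pos_droplets: int = DEFAULT_MIN_POS_DROPLETS) -> PoissonQuant:
    """Turn droplet counts into copies/droplet, concentration and abundance."""
    lam_mut = _lambda(d.n_mut_pos, d.n_total, "mutant")
    lam_wt = _lambda(d.n_wt_pos, d.n_total, "wild-type")
    vol_ul = d.droplet_volume_nl * 1e-3
    total = lam_mut + lam_wt
    return PoissonQuant(
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        conc_mut=lam_mut / vol_ul,
        conc_wt=lam_wt / vol_ul,
        fractional_abundance=(lam_mut / total) if total > 0 else None,
        ci95_mut=_ci95_lambda(d.n_mut_pos, d.n_total),
        ci95_wt=_ci95_lambda(d.n_wt_pos, d.n_total),
        detected=d.n_mut_pos >= min_pos_droplets,
    )
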