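"""Censored-normal outcome family.

The censored normal places the normal density on the open interval between
the scale bounds and accumulates the tail masses as point masses at the
bounds themselves — the standard outcome family for bounded or ordinal-like
scales in trajectory modeling.  With infinite bounds it reduces exactly to
the normal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CensoredNormalFamily:
    """Latent-normal distribution censored at ``censor_low``/``censor_high``.

    ``mu`` and ``sigma`` parametrise the latent normal; observations equal
    to a finite bound carry the corresponding tail mass.
    """

    mu: float
    sigma: float
    censor_low: float = -np.inf
    censor_high: float = np.inf

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not self.censor_low < self.censor_high:
            raise ValueError("censor_low must be < censor_high")


def cnorm_logdensity(y: float | np.ndarray, family: CensoredNormalFamily) -> float | np.ndarray:
    """Log-density/mass of the censored normal at ``y``.

    Interior points get the normal log-density; a point equal to the lower
    (upper) bound gets the log of the lower (upper) tail mass.  Values
    outside the bounds are errors: a censored observation cannot lie beyond
    its own censoring limit.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any(y_arr < family.censor_low) or np.any(y_arr > family.censor_high):
        raise ValueError("y outside censoring bounds")
    out = stats.norm.logpdf(y_arr, loc=family.mu, scale=family.sigma)
    if np.isfinite(family.censor_low):
        at_low = y_arr == family.censor_low
        if np.any(at_low):
            out = np.where(
                at_low,
                stats.norm.logcdf(family.censor_low, loc=family.mu, scale=family.sigma),
                out,
            )
    if np.isfinite(family.censor_high):
        at_high = y_arr == family.censor_high
        if np.any(at_high):
            out = np.where(
                at_high,
                stats.norm.logsf(family.censor_high, loc=family.mu, scale=family.sigma),
                out,
            )
    if np.isscalar(y) or y_arr.ndim == 0:
        return float(out)
    return out
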