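"""Five-feature variability summary of a behavioral spectrum.

The spectrum f = [f1..fm] is reduced to v = [mean, standard deviation,
variance, lag-k autocorrelation, entropy].  Moments use the population
denominator 1/m.  The autocorrelation is

    r_k = sum_{n=1}^{m-k} (f_n - mean)(f_{n+k} - mean) / sum_n (f_n - mean)^2

with delay k = 1 by default; by Cauchy-Schwarz |r_k| <= 1.  The entropy is
Shannon entropy with natural logarithm of the spectrum normalised to a
probability distribution (0*log 0 := 0), so a uniform spectrum scores
ln m and a one-hot spectrum scores 0; a raw mode that applies
-sum f_n ln f_n to the unnormalised values is available for comparison.

Degenerate inputs follow fixed conventions: a zero-variance spectrum has
r_k = 0 (the ratio is 0/0) and an all-zero spectrum has entropy 0; both emit
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectrum import BehavioralSpectrum

__all__ = ["VariabilityVector", "variability_features", "variability_table"]

FEATURE_NAMES = ["f_mean", "f_dev", "f_var", "r_k", "s"]


@dataclass(frozen=True)
class VariabilityVector:
    f_mean: float
    f_dev: float
    f_var: float
    r_k: float
    s: float
    delay_k: int = 1

    def __post_init__(self) -> None:
        if self.f_dev < 0 or self.f_var < 0 or self.s < 0:
            raise ValueError("f_dev, f_var and s must be non-negative")
        if abs(self.r_k) > 1 + 1e-12:
            raise ValueError(f"|r_k| must be <= 1, got {self.r_k}")
        if self.delay_k < 1:
            raise ValueError("delay_k must be a positive integer")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_mean, self.f_dev, self.f_var, self.r_k, self.s])


def variability_features(
    spectrum: BehavioralSpectrum | np.ndarray,
    delay_k: int = 1,
    entropy_mode: str = "normalized",
) -> VariabilityVector:
    """Compute the five variability features of one spectrum.

    Parameters
    ----------
    spectrum
        Behavioral spectrum (or bare non-negative vector) of length m >= 2.
    delay_k
        Autocorrelation delay, 1 <= delay_k < m.
    entropy_mode
        ``"normalized"`` (default): Shannon entropy, natural log, of the
        spectrum scaled to sum 1.  ``"raw"``: -sum f_n ln f_n on the
        unnormalised values (may be negative; clipped at 0 to respect the
        non-negativity contract, with a warning).
    """
    f = spectrum.values if isinstance(spectrum, BehavioralSpectrum) else np.asarray(spectrum, float)
    m = f.size
    if m < 2:
        raise ValueError("spectrum must have length >= 2")
    if not 1 <= delay_k < m:
        raise ValueError(f"delay_k must be in [1, {m - 1}], got {delay_k}")
    if entropy_mode not in ("normalized", "raw"):
        raise ValueError("entropy_mode must be 'normalized' or 'raw'")

    f_mean = float(np.mean(f))
    dev = f - f_mean
    f_var = float(np.mean(dev**2))
    f_dev = float(np.sqrt(f_var))

    denom = float(np.sum(dev**2))
    # relative threshold: a numerically-constant spectrum has only round-off
    # in dev, and the autocorrelation ratio would be 0/0 noise
    if f_dev <= 1e-12 * max(1.0, abs(f_mean)):
        warnings.warn("zero-variance spectrum: autocorrelation set to 0", stacklevel=2)
        r_k = 0.0
    else:
        r_k = float(np.sum(dev[: m - delay_k] * dev[delay_k:]) / denom)

    total = float(np.sum(f))
    if total == 0.0:
        warnings.warn("all-zero spectrum: entropy set to 0", stacklevel=2)
        s = 0.0
    elif entropy_mode == "normalized":
        p = f / total
        nz = p[p > 0]
        s = float(-np.sum(nz * np.log(nz)))
    else:
        nz = f[f > 0]
        s = float(-np.sum(nz * np.log(nz)))
        if s < 0:
            warnings.warn("raw entropy is negative; clipped to 0", stacklevel=2)
            s = 0.0
    # guard against tiny negative round-off in the entropy sum
    s = max(s, 0.0)
    return VariabilityVector(f_mean, f_dev, f_var, r_k, s, delay_k=delay_k)


def variability_table(
    spectra: Sequence[BehavioralSpectrum],
    delay_k: int = 1,
    entropy_mode: str = "normalized",
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-spectrum variability features as a table.

    Columns are Mean, SD, Variance, Correlation, Entropy, indexed by the
    given labels (default: each spectrum's source sequence key).
    """
    rows = []
    index = []
    for i, sp in enumerate(spectra):
        v = variability_features(sp, delay_k=delay_k, entropy_mode=entropy_mode)
        rows.append([v.f_mean, v.f_dev, v.f_var, v.r_k, v.s])
        if labels is not None:
            index.append(labels[i])
        elif sp.source is not None:
            index.append(sp.source.key)
        else:
            index.append(str(i))
    return pd.DataFrame(
        rows,
        index=pd.Index(index, name="observation"),
        columns=["Mean", "SD", "Variance", "Correlation", "Entropy"],
    )
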