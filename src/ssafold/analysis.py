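"""Folding-time distributions and the folding characteristic.

From a sample of first-passage times the two standard kinetic summaries
are computed: the distribution of folding times P(t) — the fraction of
trajectories folded by time t, read on a logarithmic time axis — and the
folding characteristic t * P'(t) / P(t).  Humps (local maxima) in the
characteristic indicate distinct folding pathways or timescales: a
sequence that folds down a single funnel shows a monotone characteristic
with no humps, while kinetic traps spread the folding times over decades
and raise one hump per timescale.

P'(t) is estimated by a Gaussian kernel density on log10(time) mapped back
to linear time (finite differences of an empirical step CDF are unusable),
with Silverman's rule as the default bandwidth.  Censored (not yet folded)
molecules count in the denominator of P(t) but never in the numerator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import DegenerateSampleError

LN10 = np.log(10.0)

#: a hump must rise above this fraction of the curve's range
DEFAULT_PROMINENCE_FRAC = 0.05


@dataclass
class FoldingTimeSample:
    """First-passage times plus the censored remainder of the ensemble.

    ``censored`` holds the base-pair distances still to go for molecules
    that had not folded when the run was stopped; ``n_total`` is the full
    ensemble size, so P(t) saturates at len(times)/n_total < 1 when the
    sample is censored.
    """

    times: np.ndarray
    censored: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and self.times.min() <= 0:
            raise ValueError("first-passage times must be positive")

    @property
    def n_total(self) -> int:
        return self.times.size + len(self.censored)

    @classmethod
    def from_records(cls, records) -> "FoldingTimeSample":
        """Build from kinetics.FoldRecord objects (folded or not)."""
        times = [r.fold_time for r in records if r.folded and r.fold_time > 0]
        censored = [r.bp_distance_remaining for r in records if not r.folded]
        n_zero = sum(1 for r in records if r.folded and r.fold_time == 0)
        if n_zero:
            warnings.warn(f"dropped {n_zero} zero-time records (start==target)")
        return cls(np.array(times), censored)


def log_time_grid(sample: FoldingTimeSample, n: int = 400) -> np.ndarray:
    """Log-spaced grid spanning [min/10, max*10] of the observed times."""
    if sample.times.size == 0:
        raise ValueError("cannot build a grid from an empty sample")
    lo, hi = sample.times.min() / 10.0, sample.times.max() * 10.0
    return np.logspace(np.log10(lo), np.log10(hi), n)


def folding_time_cdf(sample: FoldingTimeSample,
                     grid: np.ndarray) -> np.ndarray:
    """Empirical P(t): fraction of the WHOLE ensemble folded by t."""
    if sample.times.size == 0:
        raise ValueError("sample contains no uncensored folding times")
    sorted_times = np.sort(sample.times)
    counts = np.searchsorted(sorted_times, np.asarray(grid), side="right")
    return counts / sample.n_total


@dataclass
class FoldingCharacteristic:
    """The curve t * P'(t) / P(t) on a log-time grid, with its humps.

    ``characteristic`` is NaN where P = 0 (undefined).  ``humps`` holds
    (grid time, prominence) for each local maximum passing the default
    prominence rule.
    """

    grid: np.ndarray
    P: np.ndarray
    dPdt: np.ndarray
    characteristic: np.ndarray
    bandwidth: float
    humps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def log10_grid(self) -> np.ndarray:
        return np.log10(self.grid)

    @property
    def n_humps(self) -> int:
        return len(self.humps)


def folding_characteristic(sample: FoldingTimeSample,
                           grid: Optional[np.ndarray] = None,
                           bandwidth: Optional[float | str] = None,
                           prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
                           ) -> FoldingCharacteristic:
    """Estimate the folding characteristic from first-passage samples.

    The density of log10(t) is estimated by Gaussian KDE (Silverman's
    bandwidth unless overridden with a scalar factor), transformed back to
    linear time as P'(t) = f_log(log10 t) / (t ln 10) and scaled by the
    uncensored fraction; P(t) is the empirical CDF.  Fewer than 50
    uncensored times trigger an instability warning.
    """
    if sample.times.size < 2 or np.ptp(sample.times) == 0:
        raise DegenerateSampleError(
            "need >= 2 distinct folding times for a density estimate"
        )
    if sample.times.size < 50:
        warnings.warn("fewer than 50 folding times: derivative estimate "
                      "is unstable")
    if grid is None:
        grid = log_time_grid(sample)
    logt = np.log10(sample.times)
    kde = gaussian_kde(logt, bw_method=bandwidth
                       if bandwidth is not None else "silverman")
    frac_folded = sample.times.size / sample.n_total
    density_log = kde(np.log10(grid))
    dPdt = frac_folded * density_log / (grid * LN10)
    P = folding_time_cdf(sample, grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        char = np.where(P > 0, grid * dPdt / P, np.nan)
    fc = FoldingCharacteristic(grid=np.asarray(grid), P=P, dPdt=dPdt,
                               characteristic=char,
                               bandwidth=float(kde.factor))
    fc.humps = _find_humps(fc, prominence_frac)
    return fc


def _find_humps(fc: FoldingCharacteristic,
                prominence_frac: float) -> list[tuple[float, float]]:
    """Humps of the characteristic, located via the log-time density.

    Each mode of the folding-time density on the log axis produces one
    bump in t*P'(t)/P(t) when the distribution is multimodal; for a
    unimodal (single-pathway) sample the true characteristic declines
    monotonically and has no humps, so a single density mode counts as
    zero.  Modes are local maxima of the KDE density of log10(t) with
    prominence >= prominence_frac * the curve's range.
    """
    density_log = fc.dPdt * fc.grid * LN10
    if density_log.size < 3 or np.ptp(density_log) == 0:
        return []
    prominence = prominence_frac * np.ptp(density_log)
    idx, props = find_peaks(density_log, prominence=prominence)
    if len(idx) <= 1:
        return []
    times = fc.grid[idx]
    return list(zip(times.tolist(), props["prominences"].tolist()))


def count_humps(fc: FoldingCharacteristic,
                prominence_frac: float = DEFAULT_PROMINENCE_FRAC) -> int:
    """Number of humps in the folding characteristic.

    0 for a unimodal folding-time distribution (monotone characteristic,
    one folding pathway); otherwise one hump per prominence-passing mode
    of the log-time density (each corresponds to one bump of t*P'/P and
    one distinct folding timescale).
    """
    return len(_find_humps(fc, prominence_frac))


def characteristic_table(fc: FoldingCharacteristic):
    """The curves as a pandas DataFrame (log10_time, P, dPdt, characteristic)."""
    import pandas as pd

    return pd.DataFrame({
        "log10_time": fc.log10_grid,
        "P": fc.P,
        "dPdt": fc.dPdt,
        "characteristic": fc.characteristic,
    })


def plot_characteristic(fc: FoldingCharacteristic, path=None, ax=None):
    """Plot P(t) and the folding characteristic on a log-time axis.

    Needs matplotlib (the ``plot`` extra).  Returns the axes; saves to
    ``path`` if given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(fc.grid, fc.P, label="P(t)")
    ax.semilogx(fc.grid, fc.characteristic, label="t·P'(t)/P(t)")
    for t, _ in fc.humps:
        ax.axvline(t, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("time (arbitrary units)")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def exponential_characteristic(rate: float, grid: Sequence[float]) -> np.ndarray:
    """Closed-form characteristic of a single-exponential folding law.

    For P(t) = 1 - exp(-k t) the characteristic is
    k t e^{-k t} / (1 - e^{-k t}): monotone decreasing from 1 — no humps.
    Useful as an analytic reference curve.
    """
    t = np.asarray(grid, dtype=float)
    kt = rate * t
    with np.errstate(over="ignore"):
        return np.where(kt < 700, kt * np.exp(-kt) / (-np.expm1(-kt)), 0.0)


def mixture_characteristic(rates: Sequence[float],
                           weights: Sequence[float],
                           grid: Sequence[float]) -> np.ndarray:
    """Closed-form characteristic of a mixture of exponential folding laws."""
    t = np.asarray(grid, dtype=float)[:, None]
    k = np.asarray(rates, dtype=float)[None, :]
    w = np.asarray(weights, dtype=float)[None, :]
    with np.errstate(over="ignore"):
        ekt = np.exp(-np.minimum(k * t, 700.0))
    P = (w * (1 - ekt)).sum(axis=1)
    dP = (w * k * ekt).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(P > 0, t[:, 0] * dP / P, np.nan)
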