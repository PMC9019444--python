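"""Windowed feature extraction: Hjorth parameters plus moment statistics.

Eight features are computed on non-overlapping 30-s windows of every band
series: Hjorth activity, mobility, complexity; mean; standard deviation;
variance; skewness; excess kurtosis.  For a 120-s segment this yields the
study's 4 x 8 matrix per (channel, band).

Hjorth parameters (time-domain descriptors of an EEG window y):

    activity   = var(y)                       (signal power, uV^2)
    mobility   = sqrt(var(dy) / var(y))       (mean-frequency proxy)
    complexity = mobility(dy) / mobility(y)   (bandwidth / shape change)

with the derivative realized as the first difference (no fs scaling — the
scaling cancels in complexity and only rescales mobility by a constant).
For a sampled sinusoid of frequency f, mobility = 2 sin(pi f / fs) and
complexity = 1, which the tests use as a closed-form oracle.

Moment conventions: population variance (ddof 0); skewness is the third
standardized moment; kurtosis is Fisher excess kurtosis (Gaussian -> 0).
Constant (zero-variance) windows yield flagged zero features instead of
errors so pipelines survive silent channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signals import BandSet

__all__ = [
    "FEATURE_COLUMNS",
    "HjorthTriple",
    "hjorth",
    "statistical_features",
    "extract_features",
]

FEATURE_COLUMNS = (
    "activity", "mobility", "complexity",
    "mean", "std", "variance", "skew", "kurtosis",
)

KEY_COLUMNS = ("subject_id", "group", "condition", "channel", "band", "window")


@dataclass(frozen=True)
class HjorthTriple:
    activity: float
    mobility: float
    complexity: float
    degenerate: bool = False


def hjorth(y) -> HjorthTriple:
    """Hjorth activity, mobility and complexity of a time series."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("hjorth requires at least 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input")
    var0 = y.var()
    if var0 == 0:
        return HjorthTriple(0.0, 0.0, 0.0, degenerate=True)
    d1 = np.diff(y)
    d2 = np.diff(d1)
    var1 = d1.var()
    mobility = np.sqrt(var1 / var0)
    if var1 == 0:
        return HjorthTriple(float(var0), float(mobility), 0.0, degenerate=True)
    var2 = d2.var()
    complexity = np.sqrt(var2 / var1) / mobility
    return HjorthTriple(float(var0), float(mobility), float(complexity))


def statistical_features(y):
    """(mean, std, variance, skew, kurtosis, degenerate) of a series.

    Population moments; excess kurtosis.  A constant series reports zero
    spread/shape moments with the degenerate flag set.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    mean = float(y.mean())
    var = float(y.var())
    if var == 0:
        return mean, 0.0, 0.0, 0.0, 0.0, True
    return (
        mean,
        float(np.sqrt(var)),
        var,
        float(stats.skew(y)),
        float(stats.kurtosis(y)),  # Fisher: Gaussian -> 0
        False,
    )


def window_features(y) -> dict:
    """All eight features of one window, plus the degenerate flag."""
    h = hjorth(y)
    mean, std, var, skew, kurt, deg_s = statistical_features(y)
    return {
        "activity": h.activity,
        "mobility": h.mobility,
        "complexity": h.complexity,
        "mean": mean,
        "std": std,
        "variance": var,
        "skew": skew,
        "kurtosis": kurt,
        "degenerate": h.degenerate or deg_s,
    }


def extract_features(bands: BandSet, window_s: float = 30.0) -> pd.DataFrame:
    """Feature table over non-overlapping windows of every (channel, band).

    Rows are keyed by (subject_id, group, condition, channel, band, window);
    a trailing partial window is discarded.  A 120-s recording yields 4
    windows, i.e. the 4 x 8 feature matrix per band of each channel.
    """
    win = int(round(window_s * bands.fs))
    if win < 3:
        raise ValueError("window must span at least 3 samples")
    rows = []
    for ch in bands.channel_names:
        for band in bands.bands:
            y = bands.series[ch][band]
            n_win = len(y) // win
            if n_win < 1:
                raise ValueError(
                    f"window of {window_s}s exceeds series length "
                    f"({len(y) / bands.fs:.1f}s) for {ch}/{band}"
                )
            for w in range(n_win):
                feats = window_features(y[w * win:(w + 1) * win])
                rows.append({
                    "subject_id": bands.subject_id,
                    "group": bands.group,
                    "condition": bands.condition,
                    "channel": ch,
                    "band": band,
                    "window": w,
                    **feats,
                })
    return pd.DataFrame(rows)


def extract_cohort_features(band_sets, window_s: float = 30.0) -> pd.DataFrame:
    """Concatenate per-recording feature tables (iterable of BandSet)."""
    tables = [extract_features(bs, window_s) for bs in band_sets]
    return pd.concat(tables, ignore_index=True)
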