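"""Machine-learned quantification of circulation time series.

Seven feature families are extracted from each vital-sign channel
(SBP, DBP, HR, pulse and the derived MAP):

1. Fourier transform — magnitude and phase of low-order DFT
   coefficients, plus spectral centroid and variance.
2. Ricker (Mexican-hat) wavelet — CWT coefficients at a small grid of
   (width, position) pairs.
3. Lempel-Ziv compression — LZ76 phrase complexity of the symbolized
   series.
4. Approximate entropy (ApEn).
5. Permutation entropy.
6. Linear regression after block aggregation — OLS trend of
   block-aggregated values against block index.
7. Percentage of duplicate / non-duplicate values.

Each extractor is a pure function of one series; features that are
undefined on a too-short series return NaN sentinels (downstream the
pipeline maps them to 0 after normalization).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ALL_CHANNELS, CirculationSeries

__all__ = [
    "fft_features",
    "ricker_cwt_features",
    "lempel_ziv_complexity",
    "lz76_phrase_count",
    "approximate_entropy",
    "permutation_entropy",
    "agg_linear_trend",
    "duplicate_fractions",
    "channel_features",
    "series_feature_row",
    "extract_all",
    "feature_manifest",
]

FFT_COEFS = 10  # DFT coefficients k = 0..9
CWT_WIDTHS = (2, 5, 10, 20)
CWT_POSITIONS = (0.25, 0.5, 0.75)  # fractions of the series length
LZ_BINS = 2
APEN_M = 2
APEN_R_FACTOR = 0.2
PE_ORDER = 3
PE_DELAY = 1
TREND_CHUNKS = (5, 10)
TREND_AGGS = ("mean", "min", "max")


# ---------------------------------------------------------------- Fourier

def fft_features(x) -> dict[str, float]:
    """Magnitude/phase of DFT coefficients k=0..9 plus spectral moments.

    The centroid and variance are computed on the magnitude spectrum of
    the non-DC bins (the DC term reflects the channel's offset, not its
    oscillatory content). Coefficients beyond the available bins of a
    short series are NaN.
    """
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    if len(x) < 4:
        for k in range(FFT_COEFS):
            out[f"fft__abs_{k}"] = np.nan
            out[f"fft__angle_{k}"] = np.nan
        out["fft__centroid"] = np.nan
        out["fft__variance"] = np.nan
        return out
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    for k in range(FFT_COEFS):
        if k < len(spec):
            out[f"fft__abs_{k}"] = float(mag[k])
            out[f"fft__angle_{k}"] = float(np.angle(spec[k]))
        else:
            out[f"fft__abs_{k}"] = np.nan
            out[f"fft__angle_{k}"] = np.nan
    w = mag[1:]
    total = w.sum()
    if total > 0:
        k = np.arange(1, len(mag), dtype=float)
        centroid = float((k * w).sum() / total)
        variance = float(((k - centroid) ** 2 * w).sum() / total)
    else:  # constant series: no oscillatory energy
        centroid, variance = 0.0, 0.0
    out["fft__centroid"] = centroid
    out["fft__variance"] = variance
    return out


# ----------------------------------------------------------------- Ricker

def ricker_kernel(points: int, width: float) -> np.ndarray:
    """Discrete Ricker (Mexican-hat) wavelet, explicitly zero-meaned.

    psi(t) = A (1 - (t/a)^2) exp(-t^2 / (2 a^2)),
    A = 2 / (sqrt(3 a) pi^(1/4)).

    The discrete samples are re-centered to sum exactly to zero so that
    a constant input yields exactly-zero coefficients.
    """
    a = float(width)
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    t = np.arange(points) - (points - 1) / 2.0
    psi = amp * (1.0 - (t / a) ** 2) * np.exp(-(t**2) / (2.0 * a**2))
    return psi - psi.mean()


def ricker_cwt(x: np.ndarray, width: float) -> np.ndarray:
    """Same-length CWT response of ``x`` at one Ricker width."""
    x = np.asarray(x, dtype=float)
    kernel = ricker_kernel(min(10 * int(width), len(x)), width)
    return np.convolve(x, kernel, mode="same")


def ricker_cwt_features(x) -> dict[str, float]:
    """CWT coefficients at (width, position) pairs on a coarse grid.

    The series is demeaned first so boundary truncation of the kernel
    cannot leak the channel's offset into the coefficients (a constant
    series yields exactly-zero features).
    """
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    n = len(x)
    if n >= 8:
        x = x - x.mean()
    for w in CWT_WIDTHS:
        if n < 8:
            for p in CWT_POSITIONS:
                out[f"cwt__w{w}_p{p}"] = np.nan
            continue
        resp = ricker_cwt(x, w)
        for p in CWT_POSITIONS:
            out[f"cwt__w{w}_p{p}"] = float(resp[int(p * (n - 1))])
    return out


# ------------------------------------------------------------ Lempel-Ziv

def _symbolize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize to integer symbols: median split for 2 bins, else
    equal-width bins over [min, max]."""
    x = np.asarray(x, dtype=float)
    if n_bins == 2:
        return (x > np.median(x)).astype(np.int64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def lz76_phrase_count(symbols) -> int:
    """Number of phrases in the LZ76 exhaustive-history parse.

    Kaspar-Schuster formulation: scan the sequence, extending the
    current phrase while it reproduces (with overlap) a substring of
    the history; each failure starts a new phrase.
    """
    s = list(symbols)
    n = len(s)
    if n == 0:
        return 0
    c = 1  # first symbol is always a phrase
    i = 1  # start of current phrase
    while i < n:
        k = 1  # candidate phrase length
        kmax = 1
        j = 0  # start of the match attempt in the history
        while j < i:
            if s[j + k - 1] == s[i + k - 1]:
                k += 1
                if i + k - 1 >= n:
                    break
                kmax = max(kmax, k)
            else:
                kmax = max(kmax, k)
                j += 1
                k = 1
        c += 1
        i += kmax
    return c


def lempel_ziv_complexity(x, n_bins: int = LZ_BINS) -> float:
    """Normalized LZ76 complexity: phrases / (N / log2 N)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return np.nan
    c = lz76_phrase_count(_symbolize(x, n_bins))
    return float(c * np.log2(n) / n)


# -------------------------------------------------------------- entropies

def approximate_entropy(
    x, m: int = APEN_M, r: float | None = None
) -> float:
    """ApEn(m, r) with Chebyshev distance and self-matches included.

    Phi_m = mean_i ln(C_i^m) with C_i^m the fraction of templates
    within tolerance r of template i; ApEn = Phi_m - Phi_{m+1}.
    Default tolerance r = 0.2 * SD(x); a constant series returns 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return np.nan
    sd = x.std()
    if sd == 0:
        return 0.0
    if r is None:
        r = APEN_R_FACTOR * sd

    def phi(mm: int) -> float:
        k = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        counts = (d <= r).sum(axis=1) / k
        return float(np.log(counts).mean())

    return phi(m) - phi(m + 1)


def permutation_entropy(
    x, order: int = PE_ORDER, delay: int = PE_DELAY
) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy (natural log) of the ordinal-pattern distribution,
    divided by log(order!). Ties broken by order of appearance (stable
    argsort).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < order * delay + 1:
        return np.nan
    n_windows = n - (order - 1) * delay
    idx = np.arange(0, order * delay, delay)
    windows = x[np.arange(n_windows)[:, None] + idx[None, :]]
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log(p)).sum()
    return float(h / math.log(math.factorial(order)))


# ----------------------------------------------------- block linear trend

def agg_linear_trend(
    x,
    chunk_sizes: tuple[int, ...] = TREND_CHUNKS,
    aggs: tuple[str, ...] = TREND_AGGS,
) -> dict[str, float]:
    """OLS of block-aggregated values on block index.

    The series is cut into consecutive blocks of each chunk size (the
    trailing partial block is dropped), each block is reduced by the
    aggregate, and slope/intercept/standard error of the regression
    against the block index are reported per (chunk, agg) pair. Fewer
    than two complete blocks yields NaN sentinels.
    """
    x = np.asarray(x, dtype=float)
    out: dict[str, float] = {}
    for cs in chunk_sizes:
        n_blocks = len(x) // cs
        for agg in aggs:
            base = f"trend__chunk{cs}_{agg}"
            if n_blocks < 2:
                out[f"{base}_slope"] = np.nan
                out[f"{base}_intercept"] = np.nan
                out[f"{base}_stderr"] = np.nan
                continue
            blocks = x[: n_blocks * cs].reshape(n_blocks, cs)
            y = getattr(blocks, agg)(axis=1)
            if np.ptp(y) == 0.0:  # constant aggregate: flat exact fit
                out[f"{base}_slope"] = 0.0
                out[f"{base}_intercept"] = float(y[0])
                out[f"{base}_stderr"] = 0.0
            elif n_blocks == 2:  # two points: exact fit, zero residual
                out[f"{base}_slope"] = float(y[1] - y[0])
                out[f"{base}_intercept"] = float(y[0])
                out[f"{base}_stderr"] = 0.0
            else:
                res = stats.linregress(np.arange(n_blocks, dtype=float), y)
                out[f"{base}_slope"] = float(res.slope)
                out[f"{base}_intercept"] = float(res.intercept)
                out[f"{base}_stderr"] = float(res.stderr)
    return out


# ------------------------------------------------------------- duplicates

def duplicate_fractions(x) -> dict[str, float]:
    """Fraction of positions whose value recurs, and min/max duplication.

    Equality is assessed after rounding to 6 decimals (otherwise the
    concept is vacuous on continuous channels).
    """
    x = np.round(np.asarray(x, dtype=float), 6)
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    vals, counts = np.unique(x, return_counts=True)
    dup_mass = counts[counts > 1].sum() / n
    return {
        "dup__pct_duplicate": float(dup_mass),
        "dup__pct_non_duplicate": float(1.0 - dup_mass),
        "dup__has_duplicate_min": float(counts[0] > 1),
        "dup__has_duplicate_max": float(counts[-1] > 1),
    }


# -------------------------------------------------------------- assembly

def channel_features(x) -> dict[str, float]:
    """All seven families for one channel's values, unprefixed."""
    out: dict[str, float] = {}
    out.update(fft_features(x))
    out.update(ricker_cwt_features(x))
    out["lz__complexity"] = lempel_ziv_complexity(x)
    out["apen__m2"] = approximate_entropy(x)
    out["pe__o3_d1"] = permutation_entropy(x)
    out.update(agg_linear_trend(x))
    out.update(duplicate_fractions(x))
    return out


def series_feature_row(series: CirculationSeries) -> dict[str, float]:
    """One patient's quantified-feature row over the five channels."""
    row: dict[str, float] = {}
    for ch in ALL_CHANNELS:
        for name, val in channel_features(series.channel(ch)).items():
            row[f"{ch}__{name}"] = val
    return row


def extract_all(cohort: list[CirculationSeries]) -> pd.DataFrame:
    """Quantify every channel of every patient's series.

    Returns a patients x features DataFrame indexed by patient id.
    Extraction is pure per patient: a row depends only on that
    patient's series, never on cohort composition.
    """
    rows = {s.patient_id: series_feature_row(s) for s in cohort}
    return pd.DataFrame.from_dict(rows, orient="index")


def feature_manifest() -> pd.DataFrame:
    """Static manifest of the quantified-feature columns.

    One row per column with channel, family and parameter string;
    determined entirely by the extraction parameter grid.
    """
    probe = channel_features(np.linspace(0.0, 1.0, 64))
    records = []
    for ch in ALL_CHANNELS:
        for name in probe:
            family, _, params = name.partition("__")
            records.append(
                {"column": f"{ch}__{name}", "channel": ch,
                 "family": family, "params": params}
            )
    return pd.DataFrame.from_records(records)
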