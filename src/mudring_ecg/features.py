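"""The ten-feature description of an ECG lead.

Per lead the feature block is, in fixed order:

F1–F4
    Welch power-spectral-density integrals over four frequency sub-bands
    (signal units squared).
F5, F6
    Mean and standard deviation of the samples.
F7
    Zero-crossing rate: strict sign changes per sample pair, in [0, 1].
F8
    Higuchi fractal dimension.
F9
    Approximate entropy, ApEn(m, r) in nats (Chebyshev distance,
    self-matches included).
F10
    Grassberger–Procaccia correlation dimension of the delay embedding.

Blocks from multiple leads are concatenated, so a record with L leads maps
to a length-10·L vector.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy.spatial.distance import cdist, pdist

from .synthetic_ecg import Dataset, ECGRecord

#: Default sub-band edges (Hz): four bands below the 50 Hz Nyquist at 100 Hz.
DEFAULT_BAND_EDGES = (0.5, 4.0, 15.0, 30.0, 45.0)

FEATURE_NAMES = ("F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8", "F9", "F10")


def band_powers(
    signal: np.ndarray,
    fs: float,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    nperseg: int | None = None,
) -> np.ndarray:
    """Integrated Welch PSD over each of the bands defined by ``band_edges``.

    The integral uses the rectangle rule (PSD bin value times bin width)
    with bins assigned half-open to ``[lo, hi)``, so powers are exactly
    additive over disjoint bands.
    """
    signal = np.asarray(signal, dtype=float)
    edges = np.asarray(band_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least two band edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing")
    if edges[-1] > fs / 2 + 1e-12:
        raise ValueError("top band edge exceeds the Nyquist frequency")
    if nperseg is None:
        nperseg = min(256, signal.shape[-1])
    freqs, psd = _sig.welch(signal, fs=fs, nperseg=nperseg, detrend=False)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    powers = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if i == len(edges) - 2:
            mask = (freqs >= lo) & (freqs <= hi)  # close the top band
        else:
            mask = (freqs >= lo) & (freqs < hi)
        powers[i] = psd[mask].sum() * df
    return powers


def zero_crossing_rate(signal: np.ndarray) -> float:
    """Strict sign changes between consecutive samples, divided by n − 1.

    Zero samples inherit the sign of the most recent non-zero sample, so a
    touch of zero without a polarity change does not count as a crossing.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D signal with at least 2 samples")
    s = np.sign(x)
    nz = s != 0
    if nz.any():
        idx = np.where(nz, np.arange(len(s)), 0)
        np.maximum.accumulate(idx, out=idx)
        carried = s[idx]
        carried[: np.argmax(nz)] = 0  # leading zeros have no sign
        s = carried
    crossings = np.sum((s[1:] * s[:-1]) < 0)
    return float(crossings) / (len(x) - 1)


def fractal_dimension(signal: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension.

    For each lag k the normalised curve length L(k) is averaged over the k
    subsampled curves; the estimate is the slope of log L(k) versus
    log(1/k).  A straight line gives ~1, white noise ~2.  The estimate is
    invariant under positive amplitude scaling.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if n < 2 * kmax:
        raise ValueError("signal too short for the requested kmax")
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lk.append(dist * norm / k)
        lengths[k - 1] = np.mean(lk)
    k_arr = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lengths), 1)[0]
    return float(slope)


def _phi(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    d = cdist(emb, emb, metric="chebyshev")
    counts = (d <= r).sum(axis=1)  # self-match included
    return float(np.mean(np.log(counts / (n - m + 1))))


def approximate_entropy(signal: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Pincus approximate entropy ApEn(m, r) in nats.

    Template matches use the Chebyshev distance with tolerance ``r`` and
    include self-matches; ApEn = Φ_m − Φ_{m+1}.
    """
    x = np.asarray(signal, dtype=float)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if len(x) <= m + 1:
        raise ValueError("signal too short for the requested m")
    return _phi(x, m, r) - _phi(x, m + 1, r)


def correlation_sum(signal: np.ndarray, embed_dim: int, radii: np.ndarray) -> np.ndarray:
    """C(r): fraction of delay-embedded point pairs within distance r."""
    x = np.asarray(signal, dtype=float)
    emb = np.lib.stride_tricks.sliding_window_view(x, embed_dim)
    d = pdist(emb)
    radii = np.asarray(radii, dtype=float)
    return np.array([(d <= r).mean() for r in radii])


def correlation_dimension(
    signal: np.ndarray,
    embed_dim: int = 2,
    radii: np.ndarray | None = None,
) -> float:
    """Grassberger–Procaccia correlation dimension (delay-1 embedding).

    The estimate is the least-squares slope of log C(r) versus log r.  By
    default the radii are 10 log-spaced values between the 5th and 50th
    percentiles of the pairwise embedded distances, a range where the
    scaling region of low-dimensional signals is well resolved.
    """
    x = np.asarray(signal, dtype=float)
    n_points = len(x) - (embed_dim - 1)
    if n_points <= 10:
        raise ValueError("signal too short to embed")
    if np.all(x == x[0]):
        raise ValueError("degenerate (constant) signal has no correlation dimension")
    emb = np.lib.stride_tricks.sliding_window_view(x, embed_dim)
    d = pdist(emb)
    if radii is None:
        lo, hi = np.percentile(d[d > 0], [5, 50])
        radii = np.logspace(np.log10(lo), np.log10(hi), 10)
    radii = np.asarray(radii, dtype=float)
    c = np.array([(d <= r).mean() for r in radii])
    keep = c > 0
    if keep.sum() < 2:
        raise ValueError("correlation sums vanish on the supplied radii")
    slope = np.polyfit(np.log(radii[keep]), np.log(c[keep]), 1)[0]
    return float(slope)


def extract_features(
    record: ECGRecord,
    band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES,
    kmax: int = 10,
    m: int = 2,
    r_factor: float = 0.2,
    embed_dim: int = 2,
) -> np.ndarray:
    """Ten features per lead, concatenated in lead order.

    The ApEn tolerance is ``r_factor`` times the lead's standard deviation
    (the Pincus convention); for a normalised lead this is just ``r_factor``.
    """
    blocks = []
    for lead in record.signal:
        sd = float(lead.std())
        r = r_factor * sd if sd > 0 else r_factor
        blocks.append(np.array([
            *band_powers(lead, record.fs, band_edges),
            float(lead.mean()),
            sd,
            zero_crossing_rate(lead),
            fractal_dimension(lead, kmax=kmax),
            approximate_entropy(lead, m=m, r=r),
            correlation_dimension(lead, embed_dim=embed_dim),
        ]))
    return np.concatenate(blocks)


def feature_matrix(dataset: Dataset, **kwargs) -> pd.DataFrame:
    """One row per record: id, label, then F1..F(10·L)."""
    rows = []
    for rec in dataset:
        feats = extract_features(rec, **kwargs)
        row = {"id": rec.id, "label": rec.label}
        n_leads = rec.n_leads
        names = [f"{f}_lead{l}" for l in range(n_leads) for f in FEATURE_NAMES] \
            if n_leads > 1 else list(FEATURE_NAMES)
        row.update(dict(zip(names, feats)))
        rows.append(row)
    return pd.DataFrame(rows)


def save_features(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
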