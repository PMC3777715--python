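"""Synchronization likelihood (SL) between channel pairs.

SL is a generalized-synchronization measure built on state-space
recurrences (Stam & van Dijk, 2002). Each channel is time-delay embedded,

    X_i = (x_i, x_{i+l}, ..., x_{i+(m-1) l}),

and for every reference vector ``X_i`` a per-channel critical distance is
fixed implicitly so that a fraction ``p_ref`` of candidate vectors inside
the window ``w1 < |i - j| < w2`` count as recurrences (the Theiler window
``w1`` excludes trivially autocorrelated neighbors, the outer window
``w2`` bounds the search horizon). The instantaneous SL of a channel pair
is the fraction of one channel's recurrences that coincide with the
other's; averaged over references it is ~``p_ref`` for independent
signals and exactly 1 for identical (or affinely rescaled) signals.

Embedding parameters follow a frequency-prior scheme: for a band with
edges (LF, HF) at sampling rate fs,

    lag  l  = round(fs / (3 HF))            (~1/3 period of the fastest rhythm)
    dim  m  = round(3 HF / LF) + 1          (embedding spans the slowest rhythm)
    w1      = 2 l (m - 1)                   (autocorrelation guard)
    w2      = w1 + round(n_ref / p_ref)     (~n_ref recurrences per reference)

with half-up rounding. ``p_ref`` (default 0.01) and ``n_ref`` (default 10)
are conventions of this package, configurable per analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _sl_kernels
from .containers import EpochSet

__all__ = [
    "EmbeddingParams",
    "SLMatrix",
    "embed_parameters",
    "sl_pair",
    "sl_matrix",
    "mean_sl",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EmbeddingParams:
    """Time-delay embedding and recurrence-window parameters.

    The critical distance epsilon is never stored: it is defined
    implicitly, per reference vector, by the recurrence probability
    ``p_ref``.
    """

    lag: int
    dim: int
    w1: int
    w2: int
    p_ref: float
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be at least 2")
        if self.lag < 1:
            raise ValueError("embedding lag must be at least 1")
        if not (0 < self.p_ref < 0.5):
            raise ValueError("p_ref must be a small probability in (0, 0.5)")
        if self.w1 < 2 * self.lag * (self.dim - 1):
            raise ValueError("Theiler window w1 must be >= 2 * lag * (dim - 1)")
        if self.w2 <= self.w1:
            raise ValueError("outer window w2 must exceed w1")
        if self.metric not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def span(self) -> int:
        """Samples covered by one embedding vector."""
        return (self.dim - 1) * self.lag + 1

    @property
    def min_length(self) -> int:
        """Minimum analysis-segment length (samples) for any recurrence."""
        return self.w2 + (self.dim - 1) * self.lag


def embed_parameters(
    band_low: float,
    band_high: float,
    fs: float,
    p_ref: float = 0.01,
    n_ref: int = 10,
    metric: str = "euclidean",
) -> EmbeddingParams:
    """Band-specific embedding parameters from the frequency-prior formulas."""
    if not (0 < band_low < band_high <= fs / 2):
        raise ValueError(
            f"need 0 < band_low < band_high <= fs/2, got ({band_low}, {band_high}) at fs={fs}"
        )
    lag = max(1, _round_half_up(fs / (3.0 * band_high)))
    dim = max(2, _round_half_up(3.0 * band_high / band_low) + 1)
    w1 = 2 * lag * (dim - 1)
    w2 = w1 + max(1, _round_half_up(n_ref / p_ref))
    return EmbeddingParams(lag=lag, dim=dim, w1=w1, w2=w2, p_ref=p_ref, metric=metric)


@dataclass
class SLMatrix:
    """Symmetric channel-by-channel SL matrix for one subject and band.

    The diagonal is fixed at 1 by convention and excluded from every
    summary statistic, threshold, and graph computation downstream.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    subject_id: str | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.isfinite(self.values).all():
            raise ValueError("SL matrix contains non-finite entries")
        if (self.values < 0).any():
            raise ValueError("SL values must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("SL matrix must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def upper_values(self) -> np.ndarray:
        """The informative entries: strict upper triangle, row-major pair order."""
        iu = np.triu_indices(self.n_channels, k=1)
        return self.values[iu]


def _as_epoch_array(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError("time series must be 1-D or 2-D (epochs x samples)")
    return x


def _embed_channel(data: np.ndarray, params: EmbeddingParams) -> tuple[np.ndarray, np.ndarray]:
    """Embedding vectors and their global times for (epochs x samples) data.

    Vectors never span epoch boundaries; the global time of a vector is its
    starting sample on the concatenated epoch grid, so reference/candidate
    windows operate on the full analysis segment.
    """
    n_ep, n_samp = data.shape
    n_per = n_samp - (params.dim - 1) * params.lag
    if n_per < 1:
        raise ValueError(
            f"epoch length {n_samp} too short for embedding span {params.span}"
        )
    V = np.empty((n_ep * n_per, params.dim))
    times = np.empty(n_ep * n_per, dtype=np.int64)
    for e in range(n_ep):
        base = e * n_per
        for a in range(params.dim):
            V[base:base + n_per, a] = data[e, a * params.lag: a * params.lag + n_per]
        times[base:base + n_per] = e * n_samp + np.arange(n_per)
    return V, times


def _check_segment_length(total_T: int, params: EmbeddingParams) -> None:
    if total_T < params.min_length:
        raise ValueError(
            f"analysis segment of {total_T} samples is shorter than the "
            f"required minimum {params.min_length} (w2 + (dim-1)*lag)"
        )


def _channel_hits(data: np.ndarray, params: EmbeddingParams):
    if np.ptp(data) == 0:
        raise ValueError("constant signal: recurrence distances are degenerate")
    V, times = _embed_channel(data, params)
    total_T = data.shape[0] * data.shape[1]
    return _sl_kernels.channel_hits(
        V, times, total_T, params.w1, params.w2, params.p_ref,
        params.metric == "chebyshev",
    )


def sl_pair(x: np.ndarray, y: np.ndarray, params: EmbeddingParams) -> float:
    """SL between two equally shaped time series (1-D, or epochs x samples)."""
    xa, ya = _as_epoch_array(x), _as_epoch_array(y)
    if xa.shape != ya.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {ya.shape}")
    _check_segment_length(xa.shape[0] * xa.shape[1], params)
    hits_x, kvec = _channel_hits(xa, params)
    hits_y, _ = _channel_hits(ya, params)
    return float(_sl_kernels.pair_sl(hits_x, hits_y, kvec))


def sl_matrix(epochs: EpochSet, params: EmbeddingParams) -> SLMatrix:
    """All-pairs SL matrix from a band-filtered epoch set.

    Uses the retained (non-rejected) epochs; recurrence hit sets are built
    once per channel and combined per pair, which keeps the 406-pair
    computation linear in channels for the expensive part.
    """
    data = epochs.retained
    if data.shape[0] < 1:
        raise ValueError("no retained epochs to analyse")
    n_ch = data.shape[1]
    _check_segment_length(data.shape[0] * data.shape[2], params)

    hits = []
    kvec = None
    for c in range(n_ch):
        try:
            h, k = _channel_hits(data[:, c, :], params)
        except ValueError as err:
            raise ValueError(
                f"channel {epochs.channel_labels[c]}: {err}"
            ) from err
        hits.append(h)
        if kvec is None:
            kvec = k
    values = np.eye(n_ch)
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            v = float(_sl_kernels.pair_sl(hits[i], hits[j], kvec))
            if not np.isfinite(v):
                raise ValueError(
                    f"SL undefined for pair ({epochs.channel_labels[i]}, "
                    f"{epochs.channel_labels[j]}): no valid references"
                )
            values[i, j] = values[j, i] = v
    return SLMatrix(values=values, labels=epochs.channel_labels,
                    subject_id=epochs.subject_id, band=epochs.band)


def mean_sl(m: SLMatrix) -> float:
    """Arithmetic mean of the off-diagonal upper-triangle SL values."""
    return float(m.upper_values().mean())
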