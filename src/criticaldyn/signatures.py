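"""Evoked-response and passive critical-slowing signatures.

Line length quantifies the excursion of a signal window per millisecond and
serves both as the evoked-response magnitude (250 ms post-pulse) and as a
passive statistic on stimulation-free 4 s epochs.  The passive set further
comprises population variance, adjusted Fisher-Pearson skewness, the width
of the normalized autocorrelation function at half maximum, and the mean
pairwise Pearson correlation across channels.  Near a fold bifurcation all
of these increase (critical slowing): fluctuations recover more slowly, so
epochs are larger in amplitude, more asymmetric and more temporally
correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps
from scipy import stats

__all__ = [
    "Epoch",
    "PassiveSignatureSet",
    "line_length",
    "variance",
    "skewness",
    "autocorrelation",
    "autocorr_halfwidth",
    "spatial_correlation",
    "extract_passive_epochs",
    "passive_signature_set",
]

PASSIVE_EPOCH_S = 4.0
EVOKED_WINDOW_MS = 250.0
PASSIVE_BAND_HZ = (0.5, 100.0)


@dataclass(frozen=True)
class Epoch:
    """One single-channel analysis window."""

    signal: NDArray[np.float64]
    sampling_rate_hz: float
    role: Literal["evoked", "passive"] = "passive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))


@dataclass(frozen=True)
class PassiveSignatureSet:
    line_length: float
    variance: float
    skewness: float
    autocorr_halfwidth_ms: float
    spatial_correlation: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "line_length": self.line_length,
            "variance": self.variance,
            "skewness": self.skewness,
            "autocorr_halfwidth_ms": self.autocorr_halfwidth_ms,
        }
        if self.spatial_correlation is not None:
            d["spatial_correlation"] = self.spatial_correlation
        return d


def _as_array(epoch: Epoch | NDArray[np.float64]) -> tuple[NDArray[np.float64], float]:
    if isinstance(epoch, Epoch):
        return epoch.signal, epoch.sampling_rate_hz
    raise TypeError("expected an Epoch; wrap raw arrays with Epoch(signal, sf)")


def line_length(epoch: Epoch) -> float:
    """Mean absolute first difference scaled to per-millisecond units.

    ``LL = sum_i |x_i - x_{i-1}| / N * sf / 1000`` with N the number of
    samples in the window.
    """
    x, sf = _as_array(epoch)
    if x.size < 2:
        raise ValueError("line length needs at least 2 samples")
    return float(np.abs(np.diff(x)).sum() / x.size * sf / 1000.0)


def variance(epoch: Epoch) -> float:
    """Population variance (denominator N)."""
    x, _ = _as_array(epoch)
    return float(np.var(x))


def skewness(epoch: Epoch) -> float:
    """Adjusted Fisher-Pearson skewness, sqrt(N(N-1))/(N-2) * m3/m2^{3/2}."""
    x, _ = _as_array(epoch)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 samples")
    if np.var(x) == 0:
        raise ValueError("skewness undefined for a constant signal (SD = 0)")
    return float(stats.skew(x, bias=False))


def autocorrelation(epoch: Epoch, max_lag: int | None = None) -> NDArray[np.float64]:
    """Normalized autocorrelation function r(k) for k = 0..max_lag."""
    x, _ = _as_array(epoch)
    e = x - x.mean()
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("autocorrelation undefined for a constant signal")
    n = e.size
    if max_lag is None:
        max_lag = n - 1
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(e, nfft)
    ac = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return ac / denom


def autocorr_halfwidth(epoch: Epoch, max_lag_s: float = 1.0) -> float:
    """Lag (ms) at which the autocorrelation first drops to half maximum.

    The first downward crossing of r = 0.5 is located with linear
    interpolation between integer lags, which resolves sub-sample
    half-widths of weakly correlated signals.
    """
    x, sf = _as_array(epoch)
    max_lag = min(x.size - 1, int(round(max_lag_s * sf)))
    ac = autocorrelation(epoch, max_lag=max_lag)
    below = np.flatnonzero(ac < 0.5)
    if below.size == 0:
        raise ValueError("autocorrelation never drops below half maximum "
                         f"within {max_lag_s} s of lag")
    k = int(below[0])
    if k == 0:  # cannot happen for normalized acf, r(0)=1
        lag = 0.0
    else:
        lag = (k - 1) + (ac[k - 1] - 0.5) / (ac[k - 1] - ac[k])
    return float(lag / sf * 1000.0)


def spatial_correlation(
    signals: NDArray[np.float64], min_std: float = 0.0
) -> float:
    """Mean pairwise Pearson r over channels of one multi-channel epoch.

    ``signals`` is channels x samples.  Pairs involving a (near-)constant
    channel are skipped.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch = signals.shape[0]
    if n_ch < 2:
        raise ValueError("spatial correlation needs >= 2 channels")
    stds = signals.std(axis=1)
    keep = np.flatnonzero(stds > min_std)
    if keep.size < 2:
        raise ValueError("fewer than 2 non-constant channels")
    r = np.corrcoef(signals[keep])
    iu = np.triu_indices(keep.size, k=1)
    return float(r[iu].mean())


def passive_signature_set(
    epoch: Epoch,
    multichannel: NDArray[np.float64] | None = None,
) -> PassiveSignatureSet:
    """All univariate signatures of one epoch (plus spatial r if given)."""
    sc = None if multichannel is None else spatial_correlation(multichannel)
    return PassiveSignatureSet(
        line_length=line_length(epoch),
        variance=variance(epoch),
        skewness=skewness(epoch),
        autocorr_halfwidth_ms=autocorr_halfwidth(epoch),
        spatial_correlation=sc,
    )


def bandpass_for_signatures(
    x: NDArray[np.float64], sf: float, band: tuple[float, float] = PASSIVE_BAND_HZ
) -> NDArray[np.float64]:
    """Zero-phase band-pass for passive epochs.

    Band edges above Nyquist are dropped (the high edge is then an identity
    low-pass); applied along the last axis.
    """
    low, high = band
    nyq = sf / 2.0
    if high >= nyq:
        sos = sps.butter(4, low / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def extract_passive_epochs(
    signal: NDArray[np.float64],
    sf: float,
    event_onsets_s: Sequence[float],
    epoch_s: float = PASSIVE_EPOCH_S,
    min_gap_s: float = 4.0,
    apply_band: bool = True,
) -> list[Epoch]:
    """Non-overlapping stimulation-free windows of ``epoch_s`` seconds.

    A window qualifies when its distance to every event onset exceeds
    ``min_gap_s`` on both sides.  Band-limiting to 0.5-100 Hz is applied
    here so evoked analyses retain the wider preprocessing band.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    ns = int(round(epoch_s * sf))
    events = np.sort(np.asarray(list(event_onsets_s), dtype=float)) * sf
    gap = min_gap_s * sf
    epochs: list[Epoch] = []
    if apply_band:
        x = bandpass_for_signatures(x, sf)
    start = 0
    while start + ns <= n:
        lo, hi = start, start + ns
        if events.size:
            # distance from window to the nearest event
            d_left = events - hi  # events after the window
            d_right = lo - events  # events before the window
            inside = (events >= lo) & (events <= hi)
            too_close = (
                inside.any()
                or ((d_left > 0) & (d_left < gap)).any()
                or ((d_right > 0) & (d_right < gap)).any()
            )
            if too_close:
                # jump past the offending event's exclusion zone
                nxt = events[events >= lo - gap]
                start = int(nxt[0] + gap) + 1 if nxt.size else start + ns
                continue
        epochs.append(Epoch(x[lo:hi], sf, role="passive"))
        start += ns
    return epochs
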