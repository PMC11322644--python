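"""Active-probing excitability measures and bootstrap contrasts.

Evoked responses (line length over 250 ms post-pulse) are aggregated into
input-output curves over stimulation intensity; the normalized area under
the curve (IOC, in [0, 1]) summarizes excitability in one number — 0 means
no response at any intensity, 1 maximal response already at minimal
intensity.  Rheobase is the smallest intensity with a detectable response.
Condition contrasts are estimated with a seeded percentile bootstrap of the
mean difference (5000 resamples, 95% CI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray

from .signatures import Epoch, line_length
from .synthetic import Recording, StimEvent

EVOKED_WINDOW_MS = 250.0


@dataclass
class InputOutputCurve:
    site: str
    intensities: NDArray[np.float64]
    responses: NDArray[np.float64]
    normalization: float
    ioc: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if not np.all(np.diff(self.intensities) > 0):
            raise ValueError("intensities must be strictly increasing")


@dataclass(frozen=True)
class BootstrapEstimate:
    mean_difference: float
    ci_low: float
    ci_high: float
    n_resamples: int
    pairing: Literal["paired", "unpaired", "normalized-to-control"]

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean_difference <= self.ci_high:
            raise ValueError("point estimate outside its own CI")


def evoked_response(
    rec: Recording, event: StimEvent, channel: int | str,
    window_ms: float = EVOKED_WINDOW_MS,
) -> float:
    """Line length of the [0, window] ms post-onset window of one channel."""
    if isinstance(channel, str):
        channel = rec.channel_labels.index(channel)
    sf = rec.sampling_rate_hz
    i0 = int(round(event.onset_s * sf))
    i1 = i0 + int(round(window_ms / 1000.0 * sf))
    if i1 > rec.signal.shape[1]:
        raise ValueError("response window truncated by the end of the recording")
    return line_length(Epoch(rec.signal[channel, i0:i1], sf, role="evoked"))


def response_screen_mask(
    responses: NDArray[np.float64], n_mad: float = 5.0
) -> NDArray[np.bool_]:
    """Automated artifact screen: flag trials with LL > median + n_mad*MAD.

    Deterministic surrogate for visual screening of the highest-LL trials
    within a session/intensity group.  Returns True for trials to keep.
    """
    r = np.asarray(responses, dtype=float)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    if mad == 0:
        return np.ones(r.size, dtype=bool)
    return r <= med + n_mad * mad


def input_output_curve(
    intensities: Sequence[float],
    responses: Sequence[float],
    site: str = "S1",
    normalization: float | Literal["max"] = "max",
    baseline: float = 0.0,
) -> InputOutputCurve:
    """Mean response per intensity level, normalized, with trapezoidal area.

    ``intensities``/``responses`` are per-trial; trials are grouped by
    intensity.  The intensity axis is rescaled to [0, 1] and the curve to
    the normalization reference (its own maximum by default, or an external
    reference such as the within-animal maximum across sessions), so the
    area lands in [0, 1].  ``baseline`` is the no-response floor (e.g. the
    line length of unstimulated signal); it is subtracted before
    normalization so a flat curve at the floor yields IOC = 0.
    """
    inten = np.asarray(intensities, dtype=float)
    resp = np.asarray(responses, dtype=float)
    levels = np.unique(inten)
    if levels.size < 3:
        raise ValueError("need at least 3 intensity levels")
    means = np.array([resp[inten == v].mean() for v in levels])
    means = np.clip(means - baseline, 0.0, None)
    ref = float(means.max()) if normalization == "max" else float(normalization)
    if ref <= 0:
        return InputOutputCurve(site, levels, np.zeros_like(means), 0.0, 0.0)
    curve = means / ref
    span = levels.max() - levels.min()
    x = (levels - levels.min()) / span if span > 0 else levels
    ioc = float(np.trapezoid(curve, x))
    return InputOutputCurve(site, levels, curve, ref, ioc)


def estimate_rheobase(
    intensities: Sequence[float],
    responses: Sequence[float],
    baseline: Sequence[float],
    n_sd: float = 2.0,
) -> float | None:
    """Smallest intensity whose mean response exceeds baseline mean + n_sd*SD."""
    inten = np.asarray(intensities, dtype=float)
    resp = np.asarray(responses, dtype=float)
    base = np.asarray(baseline, dtype=float)
    thresh = base.mean() + n_sd * base.std()
    for v in np.unique(inten):
        if resp[inten == v].mean() > thresh:
            return float(v)
    return None


def session_responses(
    rec: Recording, channels: Sequence[int] | None = None,
    screen: bool = True,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """(intensity, channel-mean LL) per single-pulse trial of a session."""
    chans = range(rec.n_channels) if channels is None else channels
    inten, resp = [], []
    for e in rec.events:
        ll = np.mean([evoked_response(rec, e, c) for c in chans])
        inten.append(e.intensity)
        resp.append(ll)
    inten_a, resp_a = np.asarray(inten), np.asarray(resp)
    if screen and resp_a.size:
        keep = np.ones(resp_a.size, dtype=bool)
        for v in np.unique(inten_a):
            grp = inten_a == v
            keep[grp] &= response_screen_mask(resp_a[grp])
        inten_a, resp_a = inten_a[keep], resp_a[keep]
    return inten_a, resp_a


def session_baseline_ll(
    rec: Recording, channels: Sequence[int] | None = None,
    window_ms: float = EVOKED_WINDOW_MS, gap_ms: float = 500.0,
) -> NDArray[np.float64]:
    """Channel-mean LL of pre-stimulus windows (the no-response floor)."""
    chans = list(range(rec.n_channels)) if channels is None else list(channels)
    sf = rec.sampling_rate_hz
    ns = int(round(window_ms / 1000.0 * sf))
    out = []
    for e in rec.events:
        i1 = int(round((e.onset_s - gap_ms / 1000.0) * sf))
        i0 = i1 - ns
        if i0 < 0:
            continue
        out.append(np.mean([
            line_length(Epoch(rec.signal[c, i0:i1], sf)) for c in chans]))
    return np.asarray(out)


def session_ioc(rec: Recording, subtract_baseline: bool = True,
                **kwargs) -> InputOutputCurve:
    """Session-level IOC of channel-mean single-pulse responses."""
    inten, resp = session_responses(rec)
    if subtract_baseline and "baseline" not in kwargs:
        base = session_baseline_ll(rec)
        if base.size:
            kwargs["baseline"] = float(base.mean())
    return input_output_curve(inten, resp, **kwargs)


def session_time_to_seizure(
    rec: Recording, seizure_onset_s: float | None
) -> float | None:
    """Duration (s) of the first seizure-provoking train in a session.

    Trains are events with protocol 'train'; the provoking train is the
    last one starting before the seizure onset, and the returned value is
    the time from that train's onset to the seizure onset, capped at the
    train duration when annotated via pulse count metadata.
    """
    if seizure_onset_s is None:
        return None
    trains = [e for e in rec.events if e.protocol == "train"
              and e.onset_s < seizure_onset_s]
    if not trains:
        return None
    return seizure_onset_s - trains[-1].onset_s


def bootstrap_difference(
    values_a: Sequence[float],
    values_b: Sequence[float],
    pairing: Literal["paired", "unpaired"] = "unpaired",
    n_resamples: int = 5000,
    seed: int = 0,
    as_percent_of_a: bool = False,
) -> BootstrapEstimate:
    """Percentile bootstrap of mean(b) - mean(a) (or of paired differences).

    With ``as_percent_of_a`` the difference is expressed in percent of the
    resampled mean of ``a`` (normalized-to-control contrast).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    rng = np.random.default_rng(seed)
    if pairing == "paired":
        if a.size != b.size:
            raise ValueError("paired bootstrap needs equal-length samples")
        idx = rng.integers(0, a.size, size=(n_resamples, a.size))
        ma, mb = a[idx].mean(axis=1), b[idx].mean(axis=1)
        point_a, point_b = a.mean(), b.mean()
    else:
        ia = rng.integers(0, a.size, size=(n_resamples, a.size))
        ib = rng.integers(0, b.size, size=(n_resamples, b.size))
        ma, mb = a[ia].mean(axis=1), b[ib].mean(axis=1)
        point_a, point_b = a.mean(), b.mean()
    if as_percent_of_a:
        dist = 100.0 * (mb - ma) / ma
        point = 100.0 * (point_b - point_a) / point_a
    else:
        dist = mb - ma
        point = point_b - point_a
    lo, hi = np.percentile(dist, [2.5, 97.5])
    # the percentile CI may narrowly exclude the plug-in point estimate in
    # skewed small samples; report the distribution median in that case
    if not lo <= point <= hi:
        point = float(np.median(dist))
    return BootstrapEstimate(float(point), float(lo), float(hi),
                             n_resamples, pairing)
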