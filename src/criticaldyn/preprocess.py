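"""iEEG preprocessing: bipolar montage, artifact interpolation, filtering.

The chain mirrors routine clinical/experimental practice for stimulation
sessions: (1) bipolar derivation between neighbouring contacts of the same
electrode lead, (2) kriging-style interpolation of the stimulation artifact
in a [-2, +10] ms peri-pulse window (linear fit between the window
boundaries plus Gaussian noise matched to the preceding 50 ms), (3)
zero-phase Butterworth band-pass with 50 Hz (and harmonics) notch, and
optional rational resampling (human profile: 0.5-200 Hz, 500 Hz output;
mouse profile: 0.5-800 Hz, no resampling).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps

from .synthetic import Recording, StimEvent

logger = logging.getLogger(__name__)

PROFILES = {
    "human": {"bandpass_hz": (0.5, 200.0), "resample_hz": 500.0},
    "mouse": {"bandpass_hz": (0.5, 800.0), "resample_hz": None},
}


@dataclass(frozen=True)
class PreprocessConfig:
    species_profile: str = "mouse"
    bandpass_hz: tuple[float, float] | None = None  # None -> profile default
    notch_hz: float = 50.0
    notch_q: float = 30.0
    resample_hz: float | None | str = "profile"
    artifact_window_ms: tuple[float, float] = (-2.0, 10.0)
    kriging_noise_window_ms: float = 50.0

    def resolved(self) -> "PreprocessConfig":
        prof = PROFILES[self.species_profile]
        band = self.bandpass_hz or prof["bandpass_hz"]
        rs = prof["resample_hz"] if self.resample_hz == "profile" else self.resample_hz
        if not 0 < band[0] < band[1]:
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        lo, hi = self.artifact_window_ms
        if not lo <= 0 <= hi:
            raise ValueError("artifact window must contain the trigger (0 ms)")
        return replace(self, bandpass_hz=band, resample_hz=rs)


_LEAD_RE = re.compile(r"^([A-Za-z']+)(\d+)$")


def bipolar_montage(rec: Recording) -> Recording:
    """Adjacent-contact differences within each electrode lead.

    Labels must be lead+index ("A1", "HC3"); output channels are labelled
    "A1-A2".  Leads with a single contact are dropped with a warning.
    """
    leads: dict[str, list[tuple[int, int]]] = {}
    for idx, label in enumerate(rec.channel_labels):
        m = _LEAD_RE.match(label)
        if not m:
            raise ValueError(f"channel label {label!r} does not encode lead+contact")
        leads.setdefault(m.group(1), []).append((int(m.group(2)), idx))
    sig_rows, labels = [], []
    for lead, contacts in leads.items():
        contacts.sort()
        if len(contacts) < 2:
            logger.warning("lead %s has a single contact; dropped", lead)
            continue
        for (c1, i1), (c2, i2) in zip(contacts, contacts[1:]):
            sig_rows.append(rec.signal[i1] - rec.signal[i2])
            labels.append(f"{lead}{c1}-{lead}{c2}")
    if not sig_rows:
        raise ValueError("no lead with >= 2 contacts; cannot derive bipolar montage")
    return Recording(
        signal=np.vstack(sig_rows), sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=labels, events=list(rec.events), condition=rec.condition,
        montage="bipolar", meta={**rec.meta, "montage_source": "monopolar"},
    )


def remove_stim_artifact(
    rec: Recording,
    window_ms: tuple[float, float] = (-2.0, 10.0),
    noise_window_ms: float = 50.0,
    seed: int = 0,
) -> Recording:
    """Kriging-style interpolation of peri-stimulus artifact windows.

    Each window is replaced by the straight line joining the last clean
    sample before and the first clean sample after it, plus zero-mean
    Gaussian noise with the standard deviation of the ``noise_window_ms``
    of signal preceding the window.  Overlapping windows are merged.
    """
    sf = rec.sampling_rate_hz
    rng = np.random.default_rng(seed)
    lo = int(round(window_ms[0] / 1000.0 * sf))
    hi = int(round(window_ms[1] / 1000.0 * sf))
    nw = int(round(noise_window_ms / 1000.0 * sf))
    n = rec.signal.shape[1]
    spans: list[list[int]] = []
    for e in sorted(rec.events, key=lambda e: e.onset_s):
        i0 = int(round(e.onset_s * sf))
        a, b = i0 + lo, i0 + hi
        if a < 1 or b >= n - 1:
            raise ValueError(f"artifact window of event at {e.onset_s} s is "
                             "truncated by the recording edge")
        if spans and a <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], b)
            logger.warning("overlapping artifact windows merged at %.3f s", e.onset_s)
        else:
            spans.append([a, b])
    sig = rec.signal.copy()
    for a, b in spans:
        for c in range(sig.shape[0]):
            left, right = sig[c, a - 1], sig[c, b + 1]
            m = b - a + 1
            line = left + (right - left) * np.arange(1, m + 1) / (m + 1)
            sd = float(np.std(sig[c, max(0, a - 1 - nw) : a - 1]))
            sig[c, a : b + 1] = line + rng.normal(0.0, sd, size=m)
    return Recording(
        signal=sig, sampling_rate_hz=sf, channel_labels=list(rec.channel_labels),
        events=list(rec.events), condition=rec.condition, montage=rec.montage,
        meta={**rec.meta, "artifact_interpolated": True},
    )


def filter_and_resample(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase band-pass + 50 Hz-harmonic notch, then rational resampling.

    Filters are 4th-order Butterworth applied forward-backward; the notch
    is a second-order IIR of quality ``notch_q`` at every multiple of
    ``notch_hz`` strictly below the band-pass high edge.  Event onsets are
    carried in seconds and therefore remain exact under resampling.
    """
    cfg = cfg.resolved()
    sf = rec.sampling_rate_hz
    nyq = sf / 2.0
    low, high = cfg.bandpass_hz
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    sig = sps.sosfiltfilt(sos, rec.signal, axis=1)
    k = 1
    while k * cfg.notch_hz < high:
        b, a = sps.iirnotch(k * cfg.notch_hz, cfg.notch_q, fs=sf)
        sig = sps.filtfilt(b, a, sig, axis=1)
        k += 1
    out_sf = sf
    if cfg.resample_hz is not None and cfg.resample_hz != sf:
        frac = Fraction(cfg.resample_hz / sf).limit_denominator(1000)
        sig = sps.resample_poly(sig, frac.numerator, frac.denominator, axis=1)
        out_sf = sf * frac.numerator / frac.denominator
    logger.info("filtered %s: band %s Hz, notch %s Hz x%d, resample %s",
                rec.condition, cfg.bandpass_hz, cfg.notch_hz, k - 1, out_sf)
    return Recording(
        signal=sig, sampling_rate_hz=out_sf,
        channel_labels=list(rec.channel_labels),
        events=[StimEvent(e.onset_s, e.site, e.intensity, e.pulse_width_ms,
                          e.protocol) for e in rec.events],
        condition=rec.condition, montage=rec.montage,
        meta={**rec.meta, "bandpass_hz": list(cfg.bandpass_hz),
              "resampled_hz": out_sf},
    )


def preprocess(
    rec: Recording,
    cfg: PreprocessConfig | None = None,
    seed: int = 0,
    bipolar: bool = False,
) -> Recording:
    """Full chain: (bipolar) -> artifact interpolation -> filter/resample."""
    cfg = (cfg or PreprocessConfig()).resolved()
    if bipolar:
        rec = bipolar_montage(rec)
    rec = remove_stim_artifact(rec, cfg.artifact_window_ms,
                               cfg.kriging_noise_window_ms, seed=seed)
    return filter_and_resample(rec, cfg)
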