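"""Synthetic multi-channel iEEG sessions with known ground truth.

Emulates a 12-channel depth-electrode montage sampled at 2000 Hz during
stimulation experiments: AR(1) background activity whose lag-1 coefficient
and evoked-response gain depend on the excitability condition (low / normal
/ high), a damped biphasic evoked template with per-channel weights and
propagation delays, 50 Hz line noise, and a brief high-amplitude artifact
in the [-2, +10] ms peri-stimulus window (the segment later interpolated by
preprocessing).  Alternatively the stochastic Epileptor proxy can serve as
the common source signal, linearly mixed to channels.

These sessions are phenomenological: they carry the statistical structure
the analysis stack consumes (condition-ordered gains and autocorrelation,
intensity saturation, delays) but no biophysics of LFP generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import signal as sps

from . import epileptor as ep

Condition = Literal["low", "normal", "high"]

#: per-condition defaults: evoked gain, background AR(1) phi, background SD
#: multiplier — all ordered low < normal < high so downstream metrics have a
#: known ground-truth direction
CONDITION_EVOKED_GAIN = {"low": 0.7, "normal": 1.0, "high": 1.4}
CONDITION_AR_COEFF = {"low": 0.88, "normal": 0.90, "high": 0.93}
CONDITION_BG_SCALE = {"low": 0.8, "normal": 1.0, "high": 1.3}
#: x0 values of the Epileptor backend per condition
CONDITION_X0 = {"low": -2.30, "normal": -2.25, "high": -2.20}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition defaults for one synthetic session."""

    n_channels: int = 12
    sampling_rate_hz: float = 2000.0
    condition: Condition = "normal"
    backend: Literal["parametric", "epileptor"] = "parametric"
    evoked_gain: float | None = None  # None -> condition default
    ar_coefficient: float | None = None
    background_scale: float | None = None  # None -> condition default
    background_sigma_uv: float = 50.0
    evoked_amplitude_uv: float = 400.0
    propagation_delays_ms: tuple[float, ...] | None = None  # None -> 0..5.5 ms
    channel_weights: tuple[float, ...] | None = None
    line_noise_hz: float = 50.0
    line_noise_uv: float = 10.0
    artifact_amplitude_uv: float = 2000.0
    isi_range_s: tuple[float, float] = (8.0, 12.0)
    #: logistic intensity->amplitude map: 1/(1+exp(-slope*(i-midpoint)))
    intensity_midpoint: float = 0.45
    intensity_slope: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        phi = self.resolved_ar_coefficient
        if not 0 <= phi < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if any(d < 0 for d in self.resolved_delays_ms):
            raise ValueError("delays must be non-negative")
        if any(w < 0 for w in self.resolved_weights):
            raise ValueError("channel weights must be non-negative")

    @property
    def resolved_evoked_gain(self) -> float:
        return (CONDITION_EVOKED_GAIN[self.condition]
                if self.evoked_gain is None else self.evoked_gain)

    @property
    def resolved_ar_coefficient(self) -> float:
        return (CONDITION_AR_COEFF[self.condition]
                if self.ar_coefficient is None else self.ar_coefficient)

    @property
    def resolved_background_sigma(self) -> float:
        scale = (CONDITION_BG_SCALE[self.condition]
                 if self.background_scale is None else self.background_scale)
        return self.background_sigma_uv * scale

    @property
    def resolved_delays_ms(self) -> tuple[float, ...]:
        if self.propagation_delays_ms is not None:
            return self.propagation_delays_ms
        return tuple(0.5 * i for i in range(self.n_channels))

    @property
    def resolved_weights(self) -> tuple[float, ...]:
        if self.channel_weights is not None:
            return self.channel_weights
        # monotone taper mimicking distance to the stimulation site
        return tuple(1.0 - 0.5 * i / max(1, self.n_channels - 1)
                     for i in range(self.n_channels))

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class StimEvent:
    onset_s: float
    site: str
    intensity: float
    pulse_width_ms: float
    protocol: str


@dataclass
class Recording:
    """Multi-channel time series plus stimulation events and metadata."""

    signal: NDArray[np.float64]  # channels x samples, µV
    sampling_rate_hz: float
    channel_labels: list[str]
    events: list[StimEvent] = field(default_factory=list)
    condition: str | None = None
    montage: Literal["monopolar", "bipolar"] = "monopolar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("label count must match channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.signal.shape[1]
        for e in self.events:
            if not 0 <= e.onset_s * self.sampling_rate_hz < n:
                raise ValueError(f"event at {e.onset_s} s outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate_hz

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"onset_s": e.onset_s, "site": e.site, "intensity": e.intensity,
                 "pulse_width_ms": e.pulse_width_ms, "protocol": e.protocol}
                for e in self.events
            ]
        )

    # -- plain-text persistence (signal CSV + events CSV + JSON sidecar) --

    def save(self, basepath: str | Path) -> None:
        base = Path(basepath)
        base.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(self.signal.T, columns=self.channel_labels)
        df.to_csv(base.with_suffix(".signal.csv"), index=False)
        self.events_dataframe().to_csv(base.with_suffix(".events.csv"), index=False)
        sidecar = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "condition": self.condition,
            "montage": self.montage,
            "meta": self.meta,
        }
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, basepath: str | Path) -> "Recording":
        base = Path(basepath)
        df = pd.read_csv(base.with_suffix(".signal.csv"))
        evdf = pd.read_csv(base.with_suffix(".events.csv"))
        sidecar = json.loads(base.with_suffix(".json").read_text())
        events = [StimEvent(**row) for row in evdf.to_dict("records")]
        return cls(
            signal=df.to_numpy().T,
            sampling_rate_hz=sidecar["sampling_rate_hz"],
            channel_labels=list(df.columns),
            events=events,
            condition=sidecar.get("condition"),
            montage=sidecar.get("montage", "monopolar"),
            meta=sidecar.get("meta", {}),
        )

    @classmethod
    def from_edf(cls, path: str | Path, events: list[StimEvent] | None = None,
                 condition: str | None = None) -> "Recording":
        """Read a real session from EDF (via mne)."""
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return cls(
            signal=raw.get_data() * 1e6,  # V -> µV
            sampling_rate_hz=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            events=events or [],
            condition=condition,
        )


def evoked_template(sf: float, duration_ms: float = 250.0) -> NDArray[np.float64]:
    """Canonical evoked-response shape: two negative peaks over ~250 ms.

    Sum of two difference-of-exponentials deflections (fast ~15 ms and slow
    ~120 ms latency), normalized to unit peak amplitude, mirroring the
    biphasic morphology of cortico-cortical evoked potentials.
    """
    t = np.arange(int(duration_ms / 1000.0 * sf)) / sf * 1000.0  # ms
    def doe(tau_r, tau_d):
        w = np.exp(-t / tau_d) - np.exp(-t / tau_r)
        return w / np.abs(w).max()

    shape = -1.0 * doe(3.0, 15.0) - 0.6 * doe(25.0, 90.0)
    return shape / np.abs(shape).max()


def intensity_response(cfg: SyntheticConfig, intensity: float | NDArray) -> NDArray:
    """Saturating (logistic) map from normalized intensity to amplitude scale."""
    i = np.asarray(intensity, dtype=float)
    raw = 1.0 / (1.0 + np.exp(-cfg.intensity_slope * (i - cfg.intensity_midpoint)))
    base = 1.0 / (1.0 + np.exp(cfg.intensity_slope * cfg.intensity_midpoint))
    top = 1.0 / (1.0 + np.exp(-cfg.intensity_slope * (1.0 - cfg.intensity_midpoint)))
    return (raw - base) / (top - base)  # anchored to 0 at i=0, 1 at i=1


def _ar1_background(rng, phi: float, sigma: float, shape: tuple[int, int]) -> NDArray:
    innov = rng.standard_normal(shape) * sigma * np.sqrt(1 - phi**2)
    return sps.lfilter([1.0], [1.0, -phi], innov, axis=-1)


def default_intensity_grid(n_levels: int = 12) -> NDArray[np.float64]:
    """Normalized single-pulse intensity grid (12 linearly spaced levels)."""
    return np.linspace(1.0 / n_levels, 1.0, n_levels)


def generate_session(
    cfg: SyntheticConfig,
    protocol: Literal["single_pulse", "paired_pulse", "train"] = "single_pulse",
    n_stimulations: int = 60,
    intensities: Sequence[float] | None = None,
    site: str = "S1",
) -> Recording:
    """One synthetic stimulation session with ground-truth structure.

    Defaults mirror a standard session: 60 single pulses cycling through 12
    intensities at 8-12 s inter-stimulus intervals.
    """
    rng = np.random.default_rng(cfg.seed)
    sf = cfg.sampling_rate_hz
    if intensities is None:
        intensities = default_intensity_grid()
    intensities = np.asarray(intensities, dtype=float)
    if intensities.min() < 0 or intensities.max() > 1:
        raise ValueError("intensities must lie in [0, 1]")

    isi = rng.uniform(*cfg.isi_range_s, size=n_stimulations)
    onsets = 5.0 + np.cumsum(isi) - isi[0]
    template = evoked_template(sf)
    if np.min(np.diff(onsets, prepend=0.0)) * 1000.0 < 260.0:
        raise ValueError("stimulation events overlap the evoked template")
    total_s = onsets[-1] + 10.0
    n = int(total_s * sf)
    n_ch = cfg.n_channels

    sig = _ar1_background(rng, cfg.resolved_ar_coefficient,
                          cfg.resolved_background_sigma, (n_ch, n))
    t = np.arange(n) / sf
    sig += cfg.line_noise_uv * np.sin(2 * np.pi * cfg.line_noise_hz * t)

    weights = np.asarray(cfg.resolved_weights)
    delays = np.asarray(cfg.resolved_delays_ms)
    gain = cfg.resolved_evoked_gain
    events: list[StimEvent] = []
    trial_int = intensities[np.arange(n_stimulations) % len(intensities)]
    amp_scale = intensity_response(cfg, trial_int)
    art_lo, art_hi = int(-0.002 * sf), int(0.010 * sf)
    for onset, inten, amp in zip(onsets, trial_int, amp_scale):
        i0 = int(round(onset * sf))
        for c in range(n_ch):
            d = i0 + int(round(delays[c] / 1000.0 * sf))
            seg = sig[c, d : d + template.size]
            seg += (cfg.evoked_amplitude_uv * gain * weights[c] * amp
                    * template[: seg.size])
        # stimulation artifact in the kriging window [-2, +10] ms
        a0, a1 = max(0, i0 + art_lo), min(n, i0 + art_hi)
        sig[:, a0:a1] += cfg.artifact_amplitude_uv * rng.choice([-1, 1])
        events.append(StimEvent(onset, site, float(inten), 3.0, protocol))
        if protocol == "paired_pulse":
            # fixed 2/3-intensity second pulse 50 ms later
            onset2 = onset + 0.05
            i2 = int(round(onset2 * sf))
            for c in range(n_ch):
                d = i2 + int(round(delays[c] / 1000.0 * sf))
                seg = sig[c, d : d + template.size]
                seg += (cfg.evoked_amplitude_uv * gain * weights[c]
                        * float(intensity_response(cfg, 2.0 / 3.0))
                        * template[: seg.size])
            events.append(StimEvent(onset2, site, 2.0 / 3.0, 3.0, protocol))

    labels = [f"A{i + 1}" for i in range(n_ch)]
    return Recording(
        signal=sig, sampling_rate_hz=sf, channel_labels=labels, events=events,
        condition=cfg.condition,
        meta={"seed": cfg.seed, "backend": "parametric",
              "evoked_gain": gain, "ar_coefficient": cfg.resolved_ar_coefficient},
    )


def generate_epileptor_backend_session(
    cfg: SyntheticConfig,
    params: ep.EpileptorParams | None = None,
    n_stimulations: int = 24,
    intensities: Sequence[float] | None = None,
    noise_sigma_uv: float = 5.0,
    proxy_scale_uv: float = 1000.0,
    site: str = "S1",
) -> Recording:
    """Session whose source signal is the stochastic Epileptor proxy.

    Channel i = weight_i * proxy(t - delay_i) + independent AR(1) noise.
    Single pulses at the configured intensities drive the model through
    Istim; the condition label follows x0 (-2.30 low, -2.25 normal,
    -2.20 high).
    """
    if params is None:
        params = ep.EpileptorParams(x0=CONDITION_X0[cfg.condition])
    x0_to_cond = {v: k for k, v in CONDITION_X0.items()}
    condition = x0_to_cond.get(params.x0, cfg.condition)
    rng = np.random.default_rng(cfg.seed)
    if intensities is None:
        intensities = default_intensity_grid()
    intensities = np.asarray(intensities, dtype=float)
    trial_int = intensities[np.arange(n_stimulations) % len(intensities)]

    isi = rng.uniform(*cfg.isi_range_s, size=n_stimulations)
    onsets_s = 5.0 + np.cumsum(isi) - isi[0]
    total_s = onsets_s[-1] + 10.0
    # simulate at the model's native proxy rate (100 Hz on the 10 ms grid)
    fp = ep.find_fixed_point(params)
    n_steps = int(total_s * 1000.0 / (params.dt * ep.MS_PER_MODEL_UNIT))
    stim = ep.StimulusTrain(
        pulse_onsets_ms=onsets_s * 1000.0, pulse_width_ms=3.0,
        amplitude_scale=1.0, label="single-pulse",
        per_pulse_scales=trial_int,
    )
    sim = ep.integrate_stochastic(params, fp, stim, n_steps,
                                  seed=int(rng.integers(2**31)))
    proxy = (sim.ieeg_proxy - np.mean(sim.ieeg_proxy)) * proxy_scale_uv
    sf = sim.sampling_rate_hz
    n = proxy.size
    n_ch = cfg.n_channels
    weights = np.asarray(cfg.resolved_weights)
    delays = np.asarray(cfg.resolved_delays_ms)
    sig = _ar1_background(rng, cfg.resolved_ar_coefficient, noise_sigma_uv,
                          (n_ch, n))
    for c in range(n_ch):
        shift = int(round(delays[c] / 1000.0 * sf))
        sig[c, shift:] += weights[c] * proxy[: n - shift]
    events = [StimEvent(float(o), site, float(i), 3.0, "single_pulse")
              for o, i in zip(onsets_s, trial_int)]
    labels = [f"A{i + 1}" for i in range(n_ch)]
    return Recording(
        signal=sig, sampling_rate_hz=sf, channel_labels=labels, events=events,
        condition=condition,
        meta={"seed": cfg.seed, "backend": "epileptor", "x0": params.x0},
    )


def generate_labelled_dataset(
    n_sessions_per_condition: int,
    cfg_base: SyntheticConfig | None = None,
    seed: int = 0,
    **session_kwargs,
) -> list[Recording]:
    """Balanced low/normal/high dataset with per-session derived seeds."""
    if n_sessions_per_condition < 1:
        raise ValueError("need at least one session per condition")
    base = cfg_base or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(3 * n_sessions_per_condition)
    out: list[Recording] = []
    i = 0
    for cond in ("low", "normal", "high"):
        for _ in range(n_sessions_per_condition):
            cfg = base.with_(condition=cond,
                             seed=int(child[i].generate_state(1)[0] % (2**31)))
            out.append(generate_session(cfg, **session_kwargs))
            i += 1
    return out
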