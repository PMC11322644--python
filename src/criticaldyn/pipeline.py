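"""End-to-end in-silico experiments and their orchestration.

Three canonical runs:

* :func:`run_insilico_signatures` — stochastic simulations at the three
  excitability levels (x0 = -2.30 / -2.25 / -2.20), 790 stimulation-free
  4 s epochs each, the four univariate passive signatures per epoch, and
  bootstrapped percent contrasts of each condition against baseline.
* :func:`run_insilico_probing` — single-pulse input-output curves and
  time-to-seizure per excitability level, plus the ramp experiment in the
  epileptogenic regime (serial pulses during the slow approach to the
  critical point, growing responses until a provoked seizure).
* :func:`run_synthetic_decoding` — a balanced synthetic dataset and the
  three condition classifiers with permutation tests.

Every stage derives its RNG stream from one master seed through a fixed
spawn order, so full runs re-execute bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import decoding as dec
from . import epileptor as ep
from . import probing
from . import signatures as sig
from . import synthetic as syn

logger = logging.getLogger(__name__)

CONDITION_X0 = syn.CONDITION_X0  # low -2.30 / normal -2.25 / high -2.20
SIGNATURE_NAMES = ("line_length", "variance", "skewness", "autocorr_halfwidth")

#: internal step for stimulation-free signature runs (model time units);
#: finer than the stimulation default so the fine-grid line length is
#: computed on noise-resolved samples
PASSIVE_DT = 0.02
TRANSIENT_S = 100.0


@dataclass
class RunConfig:
    experiment: str = "insilico"
    master_seed: int = 0
    scale: float = 1.0  # shrinks epoch counts / permutations, never physics
    n_epochs: int = 790
    n_bootstrap: int = 5000
    n_perm: int = 30
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    def scaled(self, n: int, minimum: int = 1) -> int:
        return max(minimum, int(round(n * self.scale)))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        import zlib

        ss = np.random.SeedSequence(
            [self.master_seed, zlib.crc32(stage.encode()) % 2**31])
        return int(ss.generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# passive signatures (the in-silico critical-slowing experiment)


@dataclass
class PassiveEpochSet:
    """Signature values per stimulation-free epoch of one condition."""

    x0: float
    values: dict[str, NDArray[np.float64]]  # name -> per-epoch values


def simulate_passive_epochs(
    params: ep.EpileptorParams,
    n_epochs: int,
    seed: int,
    epoch_s: float = 4.0,
    dt: float = PASSIVE_DT,
    transient_s: float = TRANSIENT_S,
) -> PassiveEpochSet:
    """Stochastic run chopped into contiguous stimulation-free epochs.

    Signatures are computed on the full-resolution samples of the
    integration grid.  The distributional signatures (variance, skewness,
    autocorrelation half-width) are taken on 0.5-100 Hz band-passed
    epochs, the standard passive-signature band; line length on the raw
    samples, whose increments resolve the driving noise (the proxy is a
    diffusion, so low-passing first would fold slow-fluctuation amplitude
    into what is meant to be a per-sample excursion measure).
    """
    p = params.with_(dt=dt)
    fp = ep.find_fixed_point(p)
    step_ms = dt * ep.MS_PER_MODEL_UNIT
    n_steps = int(round((transient_s + n_epochs * epoch_s) * 1000.0 / step_ms))
    sim = ep.integrate_stochastic(p, fp, None, n_steps, seed=seed,
                                  keep_fine_proxy=True)
    sf = 1000.0 / sim.fine_step_ms
    ns = int(round(epoch_s * sf))
    start = int(round(transient_s * sf))
    epochs = sim.fine_proxy[start : start + n_epochs * ns].reshape(n_epochs, ns)
    banded = sig.bandpass_for_signatures(epochs, sf)

    values = {name: np.empty(n_epochs) for name in SIGNATURE_NAMES}
    for i in range(n_epochs):
        values["line_length"][i] = sig.line_length(sig.Epoch(epochs[i], sf))
        epoch_b = sig.Epoch(banded[i], sf)
        values["variance"][i] = sig.variance(epoch_b)
        values["skewness"][i] = sig.skewness(epoch_b)
        values["autocorr_halfwidth"][i] = sig.autocorr_halfwidth(epoch_b)
    return PassiveEpochSet(x0=p.x0, values=values)


def run_insilico_signatures(cfg: RunConfig | None = None) -> pd.DataFrame:
    """Bootstrap percent contrasts of passive signatures vs baseline.

    Returns one row per (condition, signature) with the mean percent
    change against the x0 = -2.25 baseline and its bootstrap 95% CI.
    """
    cfg = cfg or RunConfig()
    n_epochs = cfg.scaled(cfg.n_epochs, minimum=10)
    epoch_sets: dict[str, PassiveEpochSet] = {}
    for cond, x0 in CONDITION_X0.items():
        seed = cfg.stage_seed(f"signatures/{cond}")
        params = ep.EpileptorParams(x0=x0)
        epoch_sets[cond] = simulate_passive_epochs(params, n_epochs, seed)
        logger.info("simulated %d passive epochs at x0=%s", n_epochs, x0)
    rows = []
    base = epoch_sets["normal"]
    for cond in ("low", "high"):
        for name in SIGNATURE_NAMES:
            est = probing.bootstrap_difference(
                base.values[name], epoch_sets[cond].values[name],
                pairing="unpaired", n_resamples=cfg.n_bootstrap,
                seed=cfg.stage_seed(f"bootstrap/{cond}/{name}"),
                as_percent_of_a=True,
            )
            rows.append({
                "condition": cond, "x0": CONDITION_X0[cond],
                "signature": name,
                "percent_change": est.mean_difference,
                "ci_low": est.ci_low, "ci_high": est.ci_high,
                "n_epochs": n_epochs,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# active probing (IOC, time-to-seizure, ramp)


def single_pulse_response_ll(
    params: ep.EpileptorParams,
    intensity_scale: float,
    window_ms: float = 250.0,
    settle_s: float = 20.0,
    initial: ep.EpileptorState | None = None,
) -> float:
    """Line length of the proxy over the post-pulse window (deterministic)."""
    if initial is None:
        initial = ep.find_fixed_point(params)
    stim = ep.build_stimulus("single-pulse", onset_ms=settle_s * 1000.0,
                             intensity_scale=intensity_scale)
    step_ms = params.dt * ep.MS_PER_MODEL_UNIT
    n_steps = int(round((settle_s + 2.0) * 1000.0 / step_ms))
    sim = ep.integrate_deterministic(params, initial, stim, n_steps,
                                     keep_fine_proxy=True)
    sf_fine = 1000.0 / sim.fine_step_ms
    i0 = int(round(settle_s * 1000.0 / sim.fine_step_ms))
    i1 = i0 + int(round(window_ms / sim.fine_step_ms))
    return sig.line_length(sig.Epoch(sim.fine_proxy[i0:i1], sf_fine))


def insilico_ioc(
    params: ep.EpileptorParams,
    intensities: NDArray[np.float64] | None = None,
) -> probing.InputOutputCurve:
    """Deterministic single-pulse input-output curve for one x0."""
    if intensities is None:
        intensities = syn.default_intensity_grid()
    fp = ep.find_fixed_point(params)
    resp = [single_pulse_response_ll(params, float(i), initial=fp)
            for i in intensities]
    return probing.input_output_curve(intensities, resp, site="insilico")


@dataclass
class RampResult:
    pulse_times_s: NDArray[np.float64]
    pulse_ll: NDArray[np.float64]
    seizure_onset_s: float | None
    trend_slope: float  # LL per second, least squares over pre-ictal pulses


def run_ramp_experiment(
    x0: float = -2.0,
    z_start: float = 3.5,
    isi_range_s: tuple[float, float] = (8.0, 12.0),
    max_duration_s: float = 240.0,
    seed: int = 0,
) -> RampResult:
    """Pulse probing during the slow drift toward the critical point.

    The model is placed in the epileptogenic regime (x0 = -2.0) with the
    permittivity variable started well above its equilibrium, so z decays
    slowly toward the fold while single pulses probe the shrinking
    resilience; responses grow until one transition is detected.
    """
    params = ep.EpileptorParams(x0=x0)
    # resilient initial condition: interictal branch state with elevated z
    guess = ep.find_fixed_point(params.with_(x0=-2.25))
    initial = ep.EpileptorState(guess.x1, guess.y1, z_start, guess.x2,
                                guess.y2, guess.g)
    rng = np.random.default_rng(seed)
    n_pulses = int(max_duration_s / isi_range_s[0]) + 1
    gaps = rng.uniform(*isi_range_s, size=n_pulses)
    onsets_ms = (5.0 + np.cumsum(gaps) - gaps[0]) * 1000.0
    onsets_ms = onsets_ms[onsets_ms < max_duration_s * 1000.0]
    stim = ep.StimulusTrain(pulse_onsets_ms=onsets_ms, pulse_width_ms=3.0,
                            amplitude_scale=1.0, label="ramp")
    step_ms = params.dt * ep.MS_PER_MODEL_UNIT
    n_steps = int(round((max_duration_s + 15.0) * 1000.0 / step_ms))
    sim = ep.integrate_deterministic(params, initial, stim, n_steps,
                                     keep_fine_proxy=True)
    onset = ep.detect_seizure(sim)
    sf_fine = 1000.0 / sim.fine_step_ms
    win = int(round(250.0 / sim.fine_step_ms))
    times, lls = [], []
    for o in onsets_ms:
        if onset is not None and o >= onset:
            break
        i0 = int(round(o / sim.fine_step_ms))
        if i0 + win > sim.fine_proxy.size:
            break
        lls.append(sig.line_length(sig.Epoch(sim.fine_proxy[i0:i0 + win],
                                             sf_fine)))
        times.append(o / 1000.0)
    times_a, lls_a = np.asarray(times), np.asarray(lls)
    slope = (float(np.polyfit(times_a, lls_a, 1)[0])
             if times_a.size >= 2 else float("nan"))
    return RampResult(times_a, lls_a,
                      None if onset is None else onset / 1000.0, slope)


def run_insilico_probing(cfg: RunConfig | None = None) -> dict:
    """IOC and time-to-seizure per excitability level, plus the ramp run."""
    cfg = cfg or RunConfig()
    rows = []
    for cond, x0 in CONDITION_X0.items():
        params = ep.EpileptorParams(x0=x0)
        ioc = insilico_ioc(params)
        tts = ep.time_to_seizure(params, frequency_hz=20.0,
                                 max_duration_s=60.0)
        rows.append({"condition": cond, "x0": x0, "ioc": ioc.ioc,
                     "time_to_seizure_s": tts})
    ramp = run_ramp_experiment(seed=cfg.stage_seed("ramp"))
    return {"table": pd.DataFrame(rows), "ramp": ramp}


# ---------------------------------------------------------------------------
# synthetic decoding rehearsal


def run_synthetic_decoding(
    cfg: RunConfig | None = None,
    n_sessions_per_condition: int = 5,
    n_stimulations: int = 10,
    sampling_rate_hz: float = 500.0,
) -> dict[str, dec.ClassifierReport]:
    """Active / passive / combined classifiers on a balanced dataset."""
    cfg = cfg or RunConfig()
    base = syn.SyntheticConfig(sampling_rate_hz=sampling_rate_hz)
    recs = syn.generate_labelled_dataset(
        n_sessions_per_condition, base, seed=cfg.stage_seed("dataset"),
        n_stimulations=n_stimulations,
    )
    n_perm = cfg.scaled(cfg.n_perm, minimum=10)
    out = {}
    for kind, builder in [("active", dec.build_active_features),
                          ("passive", dec.build_passive_features),
                          ("combined", dec.build_combined_features)]:
        feats = builder(recs)
        out[kind] = dec.permutation_test(
            feats, n_perm=n_perm, seed=cfg.stage_seed(f"decode/{kind}"))
        logger.info("%s classifier: acc=%.3f p=%.4f", kind,
                    out[kind].mean_accuracy, out[kind].p_value)
    return out
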