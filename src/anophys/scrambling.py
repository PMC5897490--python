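"""Annexin-V scrambling time courses: synthesis and DF_norm quantification.

Phosphatidylserine exposure is read out as the ROI-integrated annexin-V
fluorescence of single cells during whole-cell recordings (1-min
time-lapse over 25 min).  Scrambling onset appears as a sigmoidal
fluorescence rise after a cell-specific lag; non-transfected controls
show only background, slow drift and photon noise.

``delta_f_norm`` implements the cohort normalisation: per cell the
baseline (first sample) is subtracted and the change is divided by the
cohort mean of the maximal change over transfected cells, so the
transfected-cohort mean of max(DF_norm) is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .recordings import FluorTrace
from .simulate import MAX_SEED, load_param_sets

__all__ = [
    "ScramblingParams",
    "OnsetSettings",
    "default_params",
    "default_onset_settings",
    "simulate_fluorescence",
    "simulate_cohort",
    "delta_f_norm",
    "detect_onset",
    "mean_true_latency",
]


@dataclass(frozen=True)
class ScramblingParams:
    """Generative parameters for single-cell scrambling fluorescence.

    The onset latency is drawn from a truncated Normal; ``latency_loc_min``
    is the location parameter (not the mean -- see ``mean_true_latency``).
    Amplitudes are in camera units (a.u.), times in minutes.
    """

    latency_loc_min: float = 5.0
    latency_sd_min: float = 2.214
    latency_lo_min: float = 1.0
    latency_hi_min: float = 22.0
    rise_tau_min: float = 6.0
    plateau_au: float = 1000.0
    plateau_cv: float = 0.25
    background_au: float = 100.0
    drift_au_per_min: float = 0.1
    noise_sd_au: float = 10.0
    sampling_min: float = 1.0
    duration_min: float = 25.0

    def __post_init__(self) -> None:
        if self.latency_loc_min <= 0 or self.sampling_min <= 0:
            raise ValueError("latency mean and sampling interval must be > 0")
        if self.plateau_au <= 0:
            raise ValueError("plateau amplitude must be > 0")
        if self.duration_min < self.latency_lo_min:
            raise ValueError("duration must cover the latency support")


@dataclass(frozen=True)
class OnsetSettings:
    """Detection rule for scrambling onset on normalised traces."""

    criterion_sd: float = 3.0
    sustain_samples: int = 2
    baseline_samples: int = 5
    floor_norm: float = 0.01
    correction_min: float = 0.0


def default_params(sets: dict | None = None) -> ScramblingParams:
    entry = (sets or load_param_sets())["scrambling"]
    fields = {k: v for k, v in entry.items()
              if k in ScramblingParams.__dataclass_fields__}
    return ScramblingParams(**fields)


def default_onset_settings(sets: dict | None = None) -> OnsetSettings:
    entry = (sets or load_param_sets())["scrambling"]
    return OnsetSettings(
        criterion_sd=entry.get("criterion_sd", 3.0),
        sustain_samples=int(entry.get("sustain_samples", 2)),
        baseline_samples=int(entry.get("baseline_samples", 5)),
        floor_norm=entry.get("floor_norm", 0.01),
        correction_min=entry.get("onset_correction_min", 0.0),
    )


def mean_true_latency(p: ScramblingParams) -> float:
    """Expected onset latency (min) of the truncated-Normal lag model."""
    a = (p.latency_lo_min - p.latency_loc_min) / p.latency_sd_min
    b = (p.latency_hi_min - p.latency_loc_min) / p.latency_sd_min
    return float(truncnorm.mean(a, b, loc=p.latency_loc_min,
                                scale=p.latency_sd_min))


def simulate_fluorescence(p: ScramblingParams, transfected: bool = True,
                          seed: int | None = 0,
                          cell_id: str = "cell0") -> FluorTrace:
    """One cell's raw annexin-V time course; deterministic per seed.

    Transfected: ``background + drift t + plateau (1 - e^{-(t-L)/rise})``
    for ``t > L`` with a truncated-Normal lag ``L``; control: background,
    drift and noise only.
    """
    rng = np.random.default_rng(None if seed is None else int(seed) % MAX_SEED)
    t = np.arange(0.0, p.duration_min + 0.5 * p.sampling_min, p.sampling_min)
    f = p.background_au + p.drift_au_per_min * t
    true_latency = None
    if transfected:
        a = (p.latency_lo_min - p.latency_loc_min) / p.latency_sd_min
        b = (p.latency_hi_min - p.latency_loc_min) / p.latency_sd_min
        lag = float(truncnorm.rvs(a, b, loc=p.latency_loc_min,
                                  scale=p.latency_sd_min, random_state=rng))
        sigma = math.sqrt(math.log(1.0 + p.plateau_cv**2)) if p.plateau_cv else 0.0
        plateau = p.plateau_au * math.exp(rng.normal(-0.5 * sigma**2, sigma)) \
            if sigma else p.plateau_au
        rise = np.where(t > lag, -np.expm1(-(t - lag) / p.rise_tau_min), 0.0)
        f = f + plateau * rise
        true_latency = lag
    if p.noise_sd_au > 0:
        f = f + rng.normal(0.0, p.noise_sd_au, size=t.shape)
    trace = FluorTrace(time_min=t, f_raw=f, f_background=p.background_au,
                       cell_id=cell_id, transfected=transfected)
    trace.true_latency_min = true_latency  # generative ground truth
    return trace


def simulate_cohort(p: ScramblingParams, n_transfected: int = 10,
                    n_control: int = 4, base_seed: int = 0) -> list[FluorTrace]:
    """Transfected + control cells; cell i uses seed base_seed + i."""
    out = []
    for i in range(n_transfected + n_control):
        transfected = i < n_transfected
        label = "t" if transfected else "c"
        out.append(simulate_fluorescence(
            p, transfected=transfected, seed=(base_seed + i) % MAX_SEED,
            cell_id=f"{label}{i:02d}"))
    return out


def delta_f_norm(traces: list[FluorTrace]) -> list[FluorTrace]:
    """Cohort normalisation producing DF_norm on every trace.

    Baseline (first sample) subtracted per cell; change divided by the
    mean maximal change over the cohort's transfected cells, which makes
    the transfected mean of max(DF_norm) equal 1 by construction.
    """
    if not any(tr.transfected for tr in traces):
        raise ValueError("cohort must contain at least one transfected cell")
    deltas = [tr.f_raw - tr.f_raw[0] for tr in traces]
    max_changes = [d.max() for tr, d in zip(traces, deltas) if tr.transfected]
    scale = float(np.mean(max_changes))
    if scale == 0:
        raise ValueError("transfected traces show no fluorescence change")
    out = []
    for tr, d in zip(traces, deltas):
        new = replace(tr, f_norm=d / scale)
        if hasattr(tr, "true_latency_min"):
            new.true_latency_min = tr.true_latency_min
        out.append(new)
    return out


def detect_onset(trace: FluorTrace,
                 settings: OnsetSettings | None = None) -> float | None:
    """Onset latency (min) of a normalised trace, or None if never detected.

    First time DF_norm exceeds baseline mean + criterion x baseline SD
    (with a floor on the SD so near-noiseless baselines do not produce a
    vanishing criterion) and stays above for ``sustain_samples``
    consecutive samples.  The crossing time is linearly interpolated and
    the calibrated detection delay ``correction_min`` subtracted.
    """
    settings = settings or default_onset_settings()
    if trace.f_norm is None:
        raise ValueError("trace is not normalised; run delta_f_norm first")
    f = np.asarray(trace.f_norm, dtype=float)
    t = np.asarray(trace.time_min, dtype=float)
    nb = settings.baseline_samples
    if f.size < nb:
        raise ValueError(f"trace too short: need >= {nb} baseline samples")
    base = f[:nb]
    sd = max(float(base.std(ddof=1)) if nb > 1 else 0.0, settings.floor_norm)
    thr = float(base.mean()) + settings.criterion_sd * sd

    above = f > thr
    k = settings.sustain_samples
    for i in range(1, f.size - k + 1):
        if above[i:i + k].all():
            # interpolate the crossing between samples i-1 and i
            if f[i] != f[i - 1]:
                frac = (thr - f[i - 1]) / (f[i] - f[i - 1])
                frac = min(max(frac, 0.0), 1.0)
            else:
                frac = 0.0
            t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
            return max(t_cross - settings.correction_min, 0.0)
    return None
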