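"""Synthetic data generators for sensillum recordings and forager visit logs.

Two generators provide inputs with the statistical structure the analysis
stages assume, so every stage is testable without real recordings:

* :func:`generate_grn_trace` — a 3 s voltage trace sampled at 30 kHz from a
  gustatory receptor neuron with phasic–tonic firing (an initial high rate
  decaying exponentially to a sustained tonic rate), Gaussian background
  noise, and optional injected artifacts (large-amplitude transients and
  over-wide non-spike events).  Ground-truth spike and artifact times are
  returned alongside the trace.

* :func:`generate_visit_log` — a free-flight foraging agent visiting an
  array of twelve artificial flowers.  Probing follows a Rescorla–Wagner
  delta rule on the learned value of each flower class; with cue salience
  zero the agent is cue-blind and probes at its base probability, giving a
  chance-level (0.5) success rate under the conditioning scoring rules.

Helpers :func:`generate_rate_table` and :func:`generate_bin_table` simulate
per-sensillum firing summaries directly, for exercising the statistical
models without running spike detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .spikes import STIMULI, Trace

__all__ = [
    "EphysSimConfig",
    "ForagerParams",
    "DesignSpec",
    "SimulatedTrace",
    "CONDITIONING_GROUPS",
    "generate_grn_trace",
    "generate_visit_log",
    "generate_cohort",
    "generate_rate_table",
    "generate_bin_table",
    "spike_template",
]

CONDITIONING_GROUPS: tuple[str, ...] = (
    "control",
    "sucrose_positive",
    "sucrose_negative",
    "nacl_positive",
    "nacl_negative",
    "quinine_positive",
    "quinine_negative",
    "caffeine_positive",
    "caffeine_negative",
)

#: refractory period enforced on simulated spike trains (s)
REFRACTORY_S = 0.002
#: amplitude factor for injected large-amplitude artifacts (>= 3x spike amplitude)
LARGE_ARTIFACT_FACTOR = 4.0
#: width of injected wide artifacts (ms); beyond the 1.5 ms rejection bound
WIDE_ARTIFACT_MS = 2.0


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass
class EphysSimConfig:
    """Parameters of a simulated tip-recording trace.

    The firing-rate profile is r(t) = tonic_rate + (peak_rate - tonic_rate)
    * exp(-t/decay_tau) after stimulus onset.  The default decay constant
    (0.13 s) brings the rate to within 5% of tonic by 0.4 s, matching the
    phasic decline seen in antennal GRN responses.
    """

    sample_rate: float = 30000.0
    duration: float = 3.0
    stimulus_onset: float = 0.0
    peak_rate: float = 100.0
    tonic_rate: float = 25.0
    decay_tau: float = 0.13
    spike_amplitude: float = 1.0
    spike_width: float = 0.8  # ms
    noise_sd: float = 0.25
    n_large_artifacts: int = 0
    n_wide_artifacts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.sample_rate > 0, "sample_rate", "must be positive")
        _require(self.duration > 0, "duration", "must be positive")
        _require(self.stimulus_onset >= 0, "stimulus_onset", "must be non-negative")
        _require(self.tonic_rate >= 0, "tonic_rate", "must be non-negative")
        _require(
            self.tonic_rate <= self.peak_rate,
            "peak_rate",
            "must be >= tonic_rate",
        )
        _require(self.decay_tau > 0, "decay_tau", "must be positive")
        _require(self.spike_amplitude >= 0, "spike_amplitude", "must be non-negative")
        _require(0 < self.spike_width < 1.5, "spike_width", "must be in (0, 1.5) ms")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        _require(self.n_large_artifacts >= 0, "n_large_artifacts", "must be >= 0")
        _require(self.n_wide_artifacts >= 0, "n_wide_artifacts", "must be >= 0")

    def rate(self, t: np.ndarray) -> np.ndarray:
        """Instantaneous firing rate (spikes/s) at time t."""
        t = np.asarray(t, dtype=float)
        dt = t - self.stimulus_onset
        r = self.tonic_rate + (self.peak_rate - self.tonic_rate) * np.exp(
            -np.clip(dt, 0, None) / self.decay_tau
        )
        return np.where(dt >= 0, r, 0.0)


class SimulatedTrace(NamedTuple):
    trace: Trace
    spike_times: np.ndarray
    artifacts: pd.DataFrame  # columns: time, kind {large|wide}


def spike_template(width_ms: float, sample_rate: float) -> np.ndarray:
    """Biphasic difference-of-Gaussians spike waveform, peak-normalized to 1.

    ``width_ms`` approximates the full span of the rectified waveform at half
    maximum.  The template is rolled so its positive extremum sits at the
    centre sample, aligning injected spike times with detected peak times.
    """
    w = width_ms * 1e-3
    # lobe scale keeps most spike energy inside a 100-1000 Hz passband,
    # as for real ~1 ms extracellular spikes
    s, c = w / 4.5, w / 3.0
    half = int(np.ceil((c + 4 * s) * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    y = np.exp(-((t + c) ** 2) / (2 * s**2)) - np.exp(-((t - c) ** 2) / (2 * s**2))
    y = np.roll(y, -int(np.argmax(y)) + half)
    return y / np.abs(y).max()


def _inhomogeneous_poisson_times(
    cfg: EphysSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Spike times by thinning a homogeneous Poisson process, then enforcing
    a 2 ms refractory period so injected spikes stay resolvable as peaks."""
    rmax = max(cfg.peak_rate, cfg.tonic_rate)
    if rmax <= 0:
        return np.array([])
    n_cand = rng.poisson(rmax * cfg.duration)
    cand = np.sort(rng.uniform(0, cfg.duration, n_cand))
    accept = rng.uniform(0, rmax, n_cand) < cfg.rate(cand)
    times = cand[accept]
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= REFRACTORY_S:
            kept.append(t)
    return np.array(kept)


def generate_grn_trace(
    cfg: EphysSimConfig,
    *,
    bee_id: str = "simbee",
    sensillum_id: str = "s1",
    location: str = "tip",
    stimulus: str = "water",
) -> SimulatedTrace:
    """Simulate one phasic–tonic GRN recording with noise and artifacts.

    Returns the raw trace plus ground truth: injected spike times (sample
    centred) and injected artifact events flagged by kind.  The same config
    and seed always produce bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = int(round(cfg.duration * cfg.sample_rate))
    samples = (
        rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else np.zeros(n)
    )

    template = spike_template(cfg.spike_width, cfg.sample_rate)
    half = len(template) // 2
    spike_times = _inhomogeneous_poisson_times(cfg, rng)
    spike_idx = np.round(spike_times * cfg.sample_rate).astype(int)
    in_range = (spike_idx >= half) & (spike_idx < n - half)
    spike_idx, spike_times = spike_idx[in_range], spike_idx[in_range] / cfg.sample_rate
    for idx in spike_idx:
        samples[idx - half : idx + half + 1] += cfg.spike_amplitude * template

    art_rows = []
    wide_template = spike_template(WIDE_ARTIFACT_MS, cfg.sample_rate)
    margin = 0.05 * cfg.duration
    placed = list(spike_times)
    for kind, count, tmpl, amp in (
        ("large", cfg.n_large_artifacts, template,
         LARGE_ARTIFACT_FACTOR * cfg.spike_amplitude),
        ("wide", cfg.n_wide_artifacts, wide_template, cfg.spike_amplitude),
    ):
        h = len(tmpl) // 2
        for _ in range(count):
            # artifacts are distinct events: keep them clear of spikes (and
            # each other) so the injected ground truth stays unambiguous
            for _ in range(1000):
                t = rng.uniform(margin, cfg.duration - margin)
                if not placed or np.min(np.abs(np.asarray(placed) - t)) >= 0.003:
                    break
            idx = int(round(t * cfg.sample_rate))
            idx = int(np.clip(idx, h, n - h - 1))
            samples[idx - h : idx + h + 1] += amp * tmpl
            placed.append(idx / cfg.sample_rate)
            art_rows.append({"time": idx / cfg.sample_rate, "kind": kind})

    trace = Trace(
        samples=samples,
        sample_rate=cfg.sample_rate,
        bee_id=bee_id,
        sensillum_id=sensillum_id,
        location=location,
        stimulus=stimulus,
    )
    artifacts = pd.DataFrame(art_rows, columns=["time", "kind"])
    return SimulatedTrace(trace, spike_times, artifacts)


@dataclass
class ForagerParams:
    """Behavioural parameters of the simulated forager.

    The agent probes a visited flower with probability
    clamp(p_probe_init + cue_salience * V(class)), where V is the learned
    value of the flower class.  In the conditioning design V is updated
    toward +1 (sucrose reward) or -1 (water) by ``learn_rate`` after each
    probe (a delta rule); leaving without probing yields no outcome and no
    update.  ``cue_salience = 0`` makes the agent cue-blind.  ``forget_rate``
    decays V toward zero at each bout boundary.  ``innate_bias`` adds a
    static value for treated flowers in the preference design (zero: no
    spontaneous preference, matching observed naive behaviour).
    ``scent_salience`` enables a per-flower mark cue left by previous probes
    (reset when flowers are cleaned between bouts), the within-colony
    confound that lets even cue-blind controls score above chance in
    training; off by default.
    """

    p_probe_init: float = 0.5
    learn_rate: float = 0.0
    cue_salience: float = 0.0
    forget_rate: float = 0.0
    innate_bias: float = 0.0
    scent_salience: float = 0.0
    p_mouthpart: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        _require(0 <= self.p_probe_init <= 1, "p_probe_init", "must be in [0, 1]")
        _require(0 <= self.learn_rate <= 1, "learn_rate", "must be in [0, 1]")
        _require(self.cue_salience >= 0, "cue_salience", "must be >= 0")
        _require(0 <= self.forget_rate <= 1, "forget_rate", "must be in [0, 1]")
        _require(self.scent_salience >= 0, "scent_salience", "must be >= 0")
        _require(0 <= self.p_mouthpart <= 1, "p_mouthpart", "must be in [0, 1]")


@dataclass
class DesignSpec:
    """Structure of one behavioural experiment.

    ``design='preference'``: 20 visits to an array of 6 tastant-treated and
    6 untreated flowers, all rewarding; ``group`` names the tastant.
    ``design='conditioning'``: 70 training visits (6 rewarding + 6
    non-rewarding flowers) then 20 unrewarded test visits on a fresh set
    that keeps the training-phase class labels; ``group`` is one of the nine
    conditioning groups (control, or tastant-positive/-negative per tastant).
    """

    design: Literal["preference", "conditioning"] = "conditioning"
    group: str = "control"
    n_flowers_per_class: int = 6
    n_visits: int = 20
    n_training_visits: int = 70
    n_test_visits: int = 20
    max_visits_per_bout: int = 20

    def __post_init__(self) -> None:
        _require(
            self.design in ("preference", "conditioning"),
            "design",
            "must be 'preference' or 'conditioning'",
        )
        if self.design == "conditioning":
            _require(
                self.group in CONDITIONING_GROUPS,
                "group",
                f"must be one of {CONDITIONING_GROUPS}",
            )
        _require(self.n_flowers_per_class > 0, "n_flowers_per_class", "must be > 0")
        _require(self.n_visits > 0, "n_visits", "must be > 0")
        _require(self.n_training_visits > 0, "n_training_visits", "must be > 0")
        _require(self.n_test_visits > 0, "n_test_visits", "must be > 0")
        _require(self.max_visits_per_bout > 0, "max_visits_per_bout", "must be > 0")


VISIT_COLUMNS = [
    "bee_id",
    "group",
    "phase",
    "bout",
    "visit_index",
    "flower_class",
    "probed",
    "mouthpart_contact",
]


def _clamp01(p: float) -> float:
    return min(1.0, max(0.0, p))


def generate_visit_log(
    params: ForagerParams,
    spec: DesignSpec,
    *,
    bee_id: str = "bee01",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one bee's visit log as a tidy DataFrame (one row per landing).

    Flower choice is uniform over the twelve-flower array; bout boundaries
    fall every ``max_visits_per_bout`` visits.  Test-phase visits keep
    training-phase class labels and trigger no learning update.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    rows: list[dict] = []
    n_total = 2 * spec.n_flowers_per_class

    if spec.design == "preference":
        classes = ("treated", "untreated")
        for i in range(spec.n_visits):
            flower = rng.integers(n_total)
            cls = classes[0] if flower < spec.n_flowers_per_class else classes[1]
            value = params.innate_bias if cls == "treated" else 0.0
            p = _clamp01(params.p_probe_init + params.cue_salience * value)
            rows.append(
                {
                    "bee_id": bee_id,
                    "group": spec.group,
                    "phase": "preference",
                    "bout": i // spec.max_visits_per_bout + 1,
                    "visit_index": i + 1,
                    "flower_class": cls,
                    "probed": int(rng.random() < p),
                    "mouthpart_contact": int(rng.random() < params.p_mouthpart),
                }
            )
        return pd.DataFrame(rows, columns=VISIT_COLUMNS)

    # conditioning: training then test
    value = {"rewarding": 0.0, "nonrewarding": 0.0}
    marks = np.zeros(n_total)  # scent-mark cue, signed by last outcome
    bout = 1
    for phase, n_visits in (("training", spec.n_training_visits),
                            ("test", spec.n_test_visits)):
        for i in range(n_visits):
            if i > 0 and i % spec.max_visits_per_bout == 0:
                bout += 1
                marks[:] = 0.0  # flowers cleaned between bouts
                for k in value:
                    value[k] *= 1.0 - params.forget_rate
            flower = int(rng.integers(n_total))
            cls = "rewarding" if flower < spec.n_flowers_per_class else "nonrewarding"
            p = _clamp01(
                params.p_probe_init
                + params.cue_salience * value[cls]
                + params.scent_salience * marks[flower]
            )
            probed = rng.random() < p
            if probed and phase == "training":
                outcome = 1.0 if cls == "rewarding" else -1.0
                value[cls] += params.learn_rate * (outcome - value[cls])
                if params.scent_salience > 0:
                    marks[flower] = outcome
            rows.append(
                {
                    "bee_id": bee_id,
                    "group": spec.group,
                    "phase": phase,
                    "bout": bout,
                    "visit_index": i + 1,
                    "flower_class": cls,
                    "probed": int(probed),
                    "mouthpart_contact": int(rng.random() < params.p_mouthpart),
                }
            )
        bout += 1  # test phase starts on the next foraging bout
        marks[:] = 0.0
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def generate_cohort(
    params: ForagerParams,
    spec: DesignSpec,
    n_bees: int = 10,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_bees`` independent bees; one child RNG stream per bee.

    Streams are spawned from (master seed, bee index), so each bee's log is
    reproducible independently of how many bees are generated.
    """
    seed = params.seed if master_seed is None else master_seed
    root = np.random.SeedSequence(seed)
    logs = []
    for i, child in enumerate(root.spawn(n_bees)):
        rng = np.random.default_rng(child)
        logs.append(
            generate_visit_log(
                params, spec, bee_id=f"{spec.group}_b{i + 1:02d}", rng=rng
            )
        )
    return pd.concat(logs, ignore_index=True)


def generate_rate_table(
    n_sensilla: int = 26,
    stimuli: tuple[str, ...] = STIMULI,
    stimulus_effects: dict[str, float] | None = None,
    location_effect: float = 0.0,
    interaction: dict[tuple[str, str], float] | None = None,
    base_log_rate: float = 3.0,
    shape: float = 5.0,
    seed: int = 0,
    family: str = "gamma",
) -> pd.DataFrame:
    """Simulate a per-sensillum 1 s firing-rate table.

    Rates are drawn from a Gamma GLM with log link: log mean =
    base_log_rate + stimulus effect + location effect + interaction, with
    sensilla split evenly between mid and tip locations and ~2.6 sensilla
    per bee (matching 26 sensilla across ten bees).  ``family='gaussian'``
    instead draws homoscedastic normal rates on the mean scale, for
    exercising family selection.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stimulus_effects = stimulus_effects or {}
    interaction = interaction or {}
    rows = []
    for s in range(n_sensilla):
        loc = "mid" if s < n_sensilla // 2 else "tip"
        bee = f"bee{(s % 10) + 1:02d}"
        for stim in stimuli:
            eta = (
                base_log_rate
                + stimulus_effects.get(stim, 0.0)
                + (location_effect if loc == "tip" else 0.0)
                + interaction.get((stim, loc), 0.0)
            )
            mu = np.exp(eta)
            if family == "gamma":
                rate = rng.gamma(shape, mu / shape)
            elif family == "gaussian":
                rate = max(rng.normal(mu, 2.0), 0.1)
            else:
                raise ValueError("family must be 'gamma' or 'gaussian'")
            rows.append(
                {
                    "bee_id": bee,
                    "sensillum_id": f"sens{s + 1:02d}",
                    "location": loc,
                    "stimulus": stim,
                    "rate_1s": rate,
                }
            )
    return pd.DataFrame(rows)


def generate_bin_table(
    n_bees: int = 8,
    stimuli: tuple[str, ...] = ("water", "sucrose"),
    tonic_rates: dict[str, float] | None = None,
    peak_rate: float = 100.0,
    decay_tau: float = 0.13,
    bee_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate 100 ms binned spike counts (20 bins) per bee and stimulus.

    Counts are Poisson draws from the phasic–tonic rate profile integrated
    over each bin, scaled by a log-normal per-bee factor (random intercept).
    The +1 zero offset is applied, yielding a ``count_plus_one`` column as
    the temporal mixed model expects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tonic_rates = tonic_rates or {s: 25.0 for s in stimuli}
    edges = np.linspace(0.1, 2.1, 21)
    rows = []
    for b in range(n_bees):
        bee_factor = np.exp(rng.normal(0.0, bee_sd))
        for stim in stimuli:
            tonic = tonic_rates.get(stim, 25.0)
            for j in range(20):
                t0, t1 = edges[j], edges[j + 1]
                # closed-form integral of tonic + (peak - tonic) exp(-t/tau)
                lam = tonic * (t1 - t0) + (peak_rate - tonic) * decay_tau * (
                    np.exp(-t0 / decay_tau) - np.exp(-t1 / decay_tau)
                )
                count = rng.poisson(bee_factor * lam)
                rows.append(
                    {
                        "bee_id": f"bee{b + 1:02d}",
                        "sensillum_id": f"sens{b + 1:02d}",
                        "stimulus": stim,
                        "time_bin": j + 1,
                        "count_plus_one": count + 1,
                    }
                )
    return pd.DataFrame(rows)
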