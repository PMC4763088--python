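"""Synthetic multichannel surface-EMG generator.

Surface EMG is modelled as amplitude-modulated, AR-coloured Gaussian noise
band-limited to 30-350 Hz (the acquisition band-pass), a standard surrogate
for interference-pattern EMG.  Structure in the generated data:

* **Class signature** — each motion class has (i) a per-channel RMS gain
  pattern (which muscles it activates) and (ii) an AR(6) spectral prototype
  (its characteristic spectrum).
* **Wrist confound** — wrist position multiplies channel gains, with a large
  modulation depth on the 8 extrinsic (forearm) channels and a small one on
  the 4 intrinsic (hand) channels.  This is the premise of the control
  problem: wrist motion obscures extrinsic finger-control EMG while largely
  sparing intrinsic EMG.
* **Onset transient** — movement classes ramp up linearly over ~200 ms with
  transiently broadened bandwidth, so testing on the first few hundred
  milliseconds genuinely probes transient EMG.
* **Trial-to-trial variability** — per-repetition lognormal channel-gain
  jitter, plus an additive band-limited noise floor.

The protocol builders reproduce the three training protocols: variable
wrist position (7 static positions x 4 repetitions x 4 s holds), dynamic
wrist motion (3 DOFs, 2 s per direction, 4 repetitions each direction) and
hybrid wrist motion (2 s hold / 2 s move / 2 s hold / 2 s move, 8 s), plus
the real-time training set (4 s neutral holds twice per posture and 8 s
hybrid trajectories).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .classes import ALL_POSTURES, GRASPS, HAND_OPEN, NO_MOVEMENT
from .recording import EmgRecording, default_roles

STATIC_POSITIONS = (
    "neutral", "flexion", "extension", "radial_deviation",
    "ulnar_deviation", "pronation", "supination",
)
DYNAMIC_DOFS = (
    ("flexion", "extension"),
    ("radial_deviation", "ulnar_deviation"),
    ("pronation", "supination"),
)
REALTIME_GRASPS = ("chuck", "fine_pinch", "key", "power")
REALTIME_POSTURES = (NO_MOVEMENT, HAND_OPEN) + REALTIME_GRASPS

_FILTER_PAD = 500  # samples discarded to flush filter transients


def valid_wrist_tags() -> list[str]:
    tags = [f"static:{p}" for p in STATIC_POSITIONS]
    for a, b in DYNAMIC_DOFS:
        for kind in ("dynamic", "hybrid"):
            tags += [f"{kind}:{a}-{b}:forward", f"{kind}:{a}-{b}:reverse"]
    return tags


def parse_wrist_tag(tag: str):
    """Split a wrist tag into (kind, start position, end position).

    ``forward`` trajectories start at the first-named position of the DOF,
    ``reverse`` ones at the second.
    """
    parts = tag.split(":")
    if parts[0] == "static" and len(parts) == 2 and parts[1] in STATIC_POSITIONS:
        return "static", parts[1], parts[1]
    if parts[0] in ("dynamic", "hybrid") and len(parts) == 3:
        ab = tuple(parts[1].split("-"))
        if ab in DYNAMIC_DOFS and parts[2] in ("forward", "reverse"):
            a, b = ab if parts[2] == "forward" else ab[::-1]
            return parts[0], a, b
    raise ValueError(
        f"unknown wrist_condition tag {tag!r}; valid tags: {valid_wrist_tags()}"
    )


# ---------------------------------------------------------------------------
# Generator configuration


def _class_gain_matrix(contrast: float, n_channels: int = 12) -> np.ndarray:
    """Per-(class, channel) RMS gain table.

    Each movement class activates a Gaussian bump of channels centred at a
    class-specific location, on top of a common baseline, with a small fixed
    perturbation so no two classes are exact translates.  ``contrast``
    scales the class-specific part: 0 makes all movement classes identical.
    """
    rng = np.random.default_rng(774_003)
    centers = {HAND_OPEN: 10.0, "chuck": 0.5, "fine_pinch": 2.2, "key": 4.0,
               "power": 5.8, "hook": 7.4, "tool": 9.0}
    ch = np.arange(n_channels)
    gains = np.zeros((len(ALL_POSTURES), n_channels))
    for i, cls in enumerate(ALL_POSTURES):
        if cls == NO_MOVEMENT:
            continue
        c0 = centers[cls]
        dist = np.minimum(np.abs(ch - c0), n_channels - np.abs(ch - c0))
        bump = np.exp(-(dist ** 2) / (2 * 2.0 ** 2))
        pert = rng.normal(0.0, 0.08, n_channels)
        gains[i] = 0.30 + contrast * (0.85 * bump + pert).clip(min=-0.25)
    return gains.clip(min=0.02)


def _wrist_factor_matrix(depth_extrinsic: float, depth_intrinsic: float,
                         n_extrinsic: int = 8, n_intrinsic: int = 4) -> dict:
    """Multiplicative per-channel factors for each static wrist position.

    Non-neutral positions raise forearm-channel activity (background
    activation of the wrist muscles under the extrinsic electrodes) with a
    position-specific channel emphasis; intrinsic channels are nearly
    untouched.  Neutral is the identity.
    """
    rng = np.random.default_rng(41_117)
    n = n_extrinsic + n_intrinsic
    depth = np.concatenate([
        np.full(n_extrinsic, depth_extrinsic), np.full(n_intrinsic, depth_intrinsic)
    ])
    factors = {"neutral": np.ones(n)}
    for pos in STATIC_POSITIONS[1:]:
        u = rng.uniform(0.3, 1.0, n)
        factors[pos] = np.exp(depth * u)
    return factors


def _spectral_prototypes(fs: float = 1000.0) -> dict:
    """Stable AR(6) denominators shaping each class's spectrum."""
    protos = {}
    for i, cls in enumerate(ALL_POSTURES):
        if cls == NO_MOVEMENT:
            f1, f2, f3, r1, r2, r3 = 90.0, 180.0, 280.0, 0.30, 0.25, 0.15
        else:
            k = i - 1  # 0..6 over movement classes
            f1, r1 = 60.0 + 14.0 * k, 0.82
            f2, r2 = 150.0 + 11.0 * k, 0.62
            f3, r3 = 250.0 + 8.0 * k, 0.35
        poles = []
        for f, r in ((f1, r1), (f2, r2), (f3, r3)):
            z = r * np.exp(2j * np.pi * f / fs)
            poles += [z, np.conj(z)]
        protos[cls] = np.real(np.poly(poles))
    return protos


@dataclass
class SynthConfig:
    """Parameters of the synthetic-EMG world.

    The defaults define the study conditions used throughout the evaluation
    suites; :meth:`well_separated` gives a low-noise, weak-confound variant
    for tests that need a nearly ideal subject.
    """

    n_extrinsic: int = 8
    n_intrinsic: int = 4
    band_hz: tuple[float, float] = (30.0, 350.0)
    sample_rate_hz: float = 1000.0
    noise_floor: float = 0.04        # additive band-limited white RMS
    class_contrast: float = 0.9      # scales inter-class gain differences
    wrist_depth_extrinsic: float = 0.35
    wrist_depth_intrinsic: float = 0.05
    rep_jitter_sigma: float = 0.22   # lognormal per-repetition channel jitter
    transient_ms: int = 200          # onset amplitude ramp
    transient_broadband: float = 0.6  # white-noise admixture at onset

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi < self.sample_rate_hz / 2:
            raise ValueError("band_hz must lie within (0, Nyquist)")
        if self.noise_floor < 0 or self.rep_jitter_sigma < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.n_extrinsic + self.n_intrinsic

    @classmethod
    def well_separated(cls) -> "SynthConfig":
        return cls(class_contrast=1.6, rep_jitter_sigma=0.05,
                   wrist_depth_extrinsic=0.12, wrist_depth_intrinsic=0.02,
                   noise_floor=0.02)

    # cached derived tables -------------------------------------------------
    def class_gains(self) -> np.ndarray:
        if not hasattr(self, "_gains"):
            self._gains = _class_gain_matrix(self.class_contrast, self.n_channels)
        return self._gains

    def wrist_factors(self) -> dict:
        if not hasattr(self, "_wrist"):
            self._wrist = _wrist_factor_matrix(
                self.wrist_depth_extrinsic, self.wrist_depth_intrinsic,
                self.n_extrinsic, self.n_intrinsic)
        return self._wrist

    def prototypes(self) -> dict:
        if not hasattr(self, "_protos"):
            self._protos = _spectral_prototypes(self.sample_rate_hz)
        return self._protos

    def bandpass_sos(self) -> np.ndarray:
        if not hasattr(self, "_sos"):
            self._sos = sps.butter(4, self.band_hz, btype="bandpass",
                                   fs=self.sample_rate_hz, output="sos")
        return self._sos

    def class_gain(self, cls: str) -> np.ndarray:
        return self.class_gains()[ALL_POSTURES.index(cls)]


# ---------------------------------------------------------------------------
# Trial synthesis


def _wrist_factor_series(tag: str, n_samples: int, config: SynthConfig) -> np.ndarray:
    """Per-sample (T, C) wrist gain factors along a wrist trajectory."""
    kind, a, b = parse_wrist_tag(tag)
    F = config.wrist_factors()
    fa, fb = F[a], F[b]
    t = np.arange(n_samples)
    if kind == "static":
        return np.tile(fa, (n_samples, 1))
    if kind == "dynamic":
        # a -> b over the first half, back over the second half
        half = n_samples / 2
        w = np.where(t < half, t / half, 2.0 - t / half)
    else:  # hybrid: hold 2 s, move 2 s, hold 2 s, move back 2 s
        q = n_samples / 4
        w = np.empty(n_samples)
        w[t < q] = 0.0
        seg2 = (t >= q) & (t < 2 * q)
        w[seg2] = (t[seg2] - q) / q
        w[(t >= 2 * q) & (t < 3 * q)] = 1.0
        seg4 = t >= 3 * q
        w[seg4] = 1.0 - (t[seg4] - 3 * q) / q
    logf = np.outer(1.0 - w, np.log(fa)) + np.outer(w, np.log(fb))
    return np.exp(logf)


def _colored_noise(rng, n_samples: int, n_channels: int, a_poly: np.ndarray,
                   config: SynthConfig) -> np.ndarray:
    """Unit-RMS band-limited AR-coloured Gaussian noise, (T, C)."""
    e = rng.standard_normal((n_samples + _FILTER_PAD, n_channels))
    x = sps.lfilter([1.0], a_poly, e, axis=0)
    x = sps.sosfilt(config.bandpass_sos(), x, axis=0)[_FILTER_PAD:]
    x /= x.std(axis=0) + 1e-12
    return x


def synth_trial(class_id: str, wrist_tag: str, duration_ms: int,
                config: SynthConfig, seed) -> EmgRecording:
    """One labelled recording of a posture held along a wrist trajectory.

    Deterministic given ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    if class_id not in ALL_POSTURES:
        raise ValueError(f"unknown class {class_id!r}; expected one of {list(ALL_POSTURES)}")
    kind, _, _ = parse_wrist_tag(wrist_tag)
    rng = np.random.default_rng(seed)
    T, C = int(duration_ms), config.n_channels
    protos = config.prototypes()

    x = _colored_noise(rng, T, C, protos[class_id], config)
    if class_id != NO_MOVEMENT and config.transient_broadband > 0:
        # transiently elevated bandwidth at grasp onset
        wb = _colored_noise(rng, T, C, np.array([1.0]), config)
        tw = np.zeros(T)
        nt = min(config.transient_ms, T)
        tw[:nt] = np.linspace(1.0, 0.0, nt, endpoint=False)
        mix = config.transient_broadband * tw[:, None]
        x = (1.0 - mix) * x + mix * wb

    amp = config.class_gain(class_id)[None, :] * _wrist_factor_series(wrist_tag, T, config)
    amp = amp * np.exp(rng.normal(0.0, config.rep_jitter_sigma, C))[None, :]
    if class_id != NO_MOVEMENT:
        nt = min(config.transient_ms, T)
        ramp = np.ones(T)
        ramp[:nt] = np.linspace(0.0, 1.0, nt, endpoint=False)
        amp = amp * ramp[:, None]

    floor = config.noise_floor * _colored_noise(rng, T, C, np.array([1.0]), config)
    samples = (amp * x + floor).astype(np.float32)
    labels = np.full(T, class_id, dtype=object)
    return EmgRecording(
        samples=samples,
        channel_roles=default_roles(config.n_extrinsic, config.n_intrinsic),
        labels=labels,
        wrist_condition=wrist_tag,
        meta={"class": class_id},
    )


# ---------------------------------------------------------------------------
# Protocols


@dataclass
class ProtocolSpec:
    """One of the training protocols (postures x conditions x repetitions)."""

    kind: str
    postures: tuple[str, ...] = ALL_POSTURES
    reps: int = 4
    duration_ms: int = 4000

    KINDS = ("neutral", "variable_wrist", "dynamic_wrist", "hybrid", "realtime_training")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}; expected one of {self.KINDS}")
        if self.kind == "hybrid" and self.duration_ms != 8000:
            raise ValueError("hybrid recordings last 8 s (2 s hold/2 s move/2 s hold/2 s move)")

    @classmethod
    def variable_wrist(cls, postures=ALL_POSTURES) -> "ProtocolSpec":
        """4 s holds in each of the 7 static wrist positions, 4 reps each."""
        return cls(kind="variable_wrist", postures=tuple(postures), reps=4, duration_ms=4000)

    @classmethod
    def dynamic_wrist(cls, postures=ALL_POSTURES) -> "ProtocolSpec":
        """2 s per direction (4 s total) along each of the 3 DOFs, 4 reps per direction."""
        return cls(kind="dynamic_wrist", postures=tuple(postures), reps=4, duration_ms=4000)

    @classmethod
    def neutral(cls, postures=ALL_POSTURES, reps: int = 4) -> "ProtocolSpec":
        return cls(kind="neutral", postures=tuple(postures), reps=reps, duration_ms=4000)

    @classmethod
    def hybrid(cls, postures=ALL_POSTURES, reps: int = 1) -> "ProtocolSpec":
        return cls(kind="hybrid", postures=tuple(postures), reps=reps, duration_ms=8000)

    @classmethod
    def realtime_training(cls) -> "ProtocolSpec":
        """Neutral 4 s holds twice per posture plus the six 8 s hybrid trajectories."""
        return cls(kind="realtime_training", postures=REALTIME_POSTURES, reps=2,
                   duration_ms=4000)

    def trial_plan(self) -> list[tuple[str, str, int, int]]:
        """Deterministic (posture, wrist_tag, duration_ms, rep) enumeration."""
        plan = []
        if self.kind == "neutral":
            for p in self.postures:
                for r in range(1, self.reps + 1):
                    plan.append((p, "static:neutral", self.duration_ms, r))
        elif self.kind == "variable_wrist":
            for p in self.postures:
                for pos in STATIC_POSITIONS:
                    for r in range(1, self.reps + 1):
                        plan.append((p, f"static:{pos}", self.duration_ms, r))
        elif self.kind == "dynamic_wrist":
            for p in self.postures:
                for a, b in DYNAMIC_DOFS:
                    for direction in ("forward", "reverse"):
                        for r in range(1, self.reps + 1):
                            plan.append((p, f"dynamic:{a}-{b}:{direction}", self.duration_ms, r))
        elif self.kind == "hybrid":
            for p in self.postures:
                for a, b in DYNAMIC_DOFS:
                    for direction in ("forward", "reverse"):
                        for r in range(1, self.reps + 1):
                            plan.append((p, f"hybrid:{a}-{b}:{direction}", 8000, r))
        else:  # realtime_training
            for p in self.postures:
                for r in range(1, self.reps + 1):
                    plan.append((p, "static:neutral", 4000, r))
            for p in self.postures:
                for a, b in DYNAMIC_DOFS:
                    for direction in ("forward", "reverse"):
                        plan.append((p, f"hybrid:{a}-{b}:{direction}", 8000, 1))
        return plan


def generate_protocol(spec: ProtocolSpec, config: SynthConfig, seed) -> list[EmgRecording]:
    """All labelled recordings of a protocol, deterministically seeded."""
    plan = spec.trial_plan()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(plan))
    recordings = []
    for (posture, tag, dur, rep), child in zip(plan, children):
        rec = synth_trial(posture, tag, dur, config, child)
        rec.meta.update({"rep": rep, "protocol": spec.kind})
        recordings.append(rec)
    return recordings


def make_offline_dataset(config: SynthConfig, seed,
                         postures=ALL_POSTURES) -> list[EmgRecording]:
    """Variable-wrist (224 recordings) plus dynamic-wrist (192) protocols."""
    ss = np.random.SeedSequence(seed)
    s_var, s_dyn = ss.spawn(2)
    return (generate_protocol(ProtocolSpec.variable_wrist(postures), config, s_var)
            + generate_protocol(ProtocolSpec.dynamic_wrist(postures), config, s_dyn))


# ---------------------------------------------------------------------------
# Simulated subject (causal stream)


@dataclass
class SubjectSkill:
    """Imperfection model of a simulated user.

    ``burst_rate_hz`` is the rate of brief accidental activations in which
    the emitted EMG pattern switches to a confusable class (another grasp or
    hand-open) for ``burst_ms`` milliseconds — the unintentional transients
    that trip up an unmodified classifier.
    """

    burst_rate_hz: float = 0.0
    burst_ms: int = 100
    amplitude_sigma: float = 0.08  # subject-level stationary channel gain jitter


class SubjectStream:
    """Causal 1000 Hz EMG stream following a time-varying intended class.

    The stream shares the class gain tables, spectral prototypes and wrist
    confound of :func:`synth_trial`, so classifiers trained on protocol
    recordings transfer to it.  Envelopes slew toward the intended class's
    amplitude pattern with a ~200 ms onset, giving realistic transients at
    every intent change.
    """

    def __init__(self, config: SynthConfig, skill: SubjectSkill | None = None,
                 seed=0):
        self.config = config
        self.skill = skill or SubjectSkill()
        self.rng = np.random.default_rng(seed)
        C = config.n_channels
        self._protos = config.prototypes()
        order = len(next(iter(self._protos.values()))) - 1
        self._zi_ar = np.zeros((order, C))
        sos = config.bandpass_sos()
        self._zi_bp = np.zeros((sos.shape[0], 2, C))
        self._zi_floor = np.zeros((sos.shape[0], 2, C))
        self._env = np.zeros(C)
        self._gain_jitter = np.exp(self.rng.normal(0.0, self.skill.amplitude_sigma, C))
        self._norms = self._filter_norms()
        self.intent = NO_MOVEMENT
        self.wrist_position = "neutral"
        self._burst_left_ms = 0.0
        self._burst_class = None

    def _filter_norms(self) -> dict:
        norms = {}
        probe_rng = np.random.default_rng(12_345)
        e = probe_rng.standard_normal(8000)
        for cls, a in self._protos.items():
            x = sps.lfilter([1.0], a, e)
            x = sps.sosfilt(self.config.bandpass_sos(), x)
            norms[cls] = x[1000:].std()
        return norms

    def set_intent(self, class_id: str) -> None:
        if class_id not in ALL_POSTURES:
            raise ValueError(f"unknown class {class_id!r}")
        self.intent = class_id

    def set_wrist(self, position: str) -> None:
        if position not in STATIC_POSITIONS:
            raise ValueError(
                f"unknown wrist position {position!r}; expected one of {STATIC_POSITIONS}"
            )
        self.wrist_position = position

    def _effective_class(self, dt_ms: float) -> str:
        if self._burst_left_ms > 0:
            self._burst_left_ms -= dt_ms
            return self._burst_class
        if (self.skill.burst_rate_hz > 0
                and self.rng.random() < self.skill.burst_rate_hz * dt_ms / 1000.0):
            pool = [c for c in (GRASPS + (HAND_OPEN,)) if c != self.intent]
            self._burst_class = pool[self.rng.integers(len(pool))]
            self._burst_left_ms = self.skill.burst_ms - dt_ms
            return self._burst_class
        return self.intent

    def emit(self, n_ms: int) -> np.ndarray:
        """The next ``n_ms`` milliseconds of EMG, shape ``(n_ms, C)``."""
        cfg = self.config
        C = cfg.n_channels
        cls = self._effective_class(n_ms)
        e = self.rng.standard_normal((n_ms, C))
        x, self._zi_ar = sps.lfilter([1.0], self._protos[cls], e, axis=0, zi=self._zi_ar)
        x, self._zi_bp = sps.sosfilt(cfg.bandpass_sos(), x, axis=0, zi=self._zi_bp)
        x = x / self._norms[cls]

        target = cfg.class_gain(cls) * cfg.wrist_factors()[self.wrist_position]
        target = target * self._gain_jitter
        # first-order slew toward the target pattern: ~200 ms onsets
        tau = max(cfg.transient_ms / 2.5, 1.0)
        alpha = 1.0 - np.exp(-n_ms / tau)
        env_end = self._env + (target - self._env) * alpha
        env = np.linspace(0, 1, n_ms, endpoint=False)[:, None] * (env_end - self._env) + self._env
        self._env = env_end

        ef = self.rng.standard_normal((n_ms, C))
        floor, self._zi_floor = sps.sosfilt(cfg.bandpass_sos(), ef, axis=0, zi=self._zi_floor)
        return env * x + cfg.noise_floor * floor


def stream_subject(intent_schedule, config: SynthConfig,
                   skill: SubjectSkill | None = None, seed=0,
                   chunk_ms: int = 25) -> np.ndarray:
    """Frame-by-frame EMG for a fixed intent schedule.

    ``intent_schedule`` is a sequence of ``(duration_ms, class_id, wrist_position)``
    segments; the result concatenates causal ``chunk_ms`` emissions.
    """
    stream = SubjectStream(config, skill=skill, seed=seed)
    chunks = []
    for duration_ms, class_id, wrist in intent_schedule:
        stream.set_intent(class_id)
        stream.set_wrist(wrist)
        remaining = int(duration_ms)
        while remaining > 0:
            step = min(chunk_ms, remaining)
            chunks.append(stream.emit(step))
            remaining -= step
    return np.concatenate(chunks, axis=0)
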