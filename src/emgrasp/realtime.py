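"""Closed-loop real-time experiment against a simulated subject.

A session tests every combination of 7 wrist positions and 4 grasps once
(28 trials).  Each trial: 2 s of wrist prepositioning (unscored), then the
virtual hand is revealed fully open and the subject has 15 s to fully close
it in the target grasp.  Four metrics summarise performance: timeout rate,
selection time, completion time and selection attempts, with timed-out
trials excluded from the three means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .classes import ClassSet, HAND_OPEN, NO_MOVEMENT, remap_maintenance
from .controller import Controller, ControllerConfig, Mode
from .features import FeatureConfig, extract_features, mav_columns, sliding_window_features
from .hand import HandState, is_fully_closed, is_fully_open, step_hand
from .lda import train_lda
from .synth import (REALTIME_GRASPS, STATIC_POSITIONS, ProtocolSpec, SubjectSkill,
                    SubjectStream, SynthConfig, generate_protocol)

FRAME_MS = 25
PREPOSITION_MS = 2000
TIMEOUT_MS = 15000


@dataclass(frozen=True)
class Trial:
    wrist_position: str
    target_grasp: str
    preposition_s: float = 2.0
    timeout_s: float = 15.0


@dataclass
class TrialResult:
    trial: Trial
    completed: bool
    selection_time_ms: float = math.nan
    completion_time_ms: float = math.nan
    selection_attempts: int = 0


def schedule_trials(seed, wrist_positions=STATIC_POSITIONS,
                    grasps=REALTIME_GRASPS) -> list[Trial]:
    """A seeded permutation of the wrist x grasp product (28 trials)."""
    pairs = list(product(wrist_positions, grasps))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [Trial(wrist_position=pairs[i][0], target_grasp=pairs[i][1]) for i in order]


# ---------------------------------------------------------------------------
# Controller training from the real-time protocol


def train_realtime_models(windowing: str, synth_config: SynthConfig, seed,
                          protocol: ProtocolSpec | None = None,
                          shrinkage: float = 1e-2) -> dict:
    """Selection/maintenance classifiers plus proportional-control
    calibration, trained from the real-time training protocol (neutral
    holds x2 plus 8 s hybrid trajectories).

    The result is shared by every classification technique of the same
    windowing method — only the post-processing differs between schemes.
    """
    spec = protocol or ProtocolSpec.realtime_training()
    recordings = generate_protocol(spec, synth_config, seed)
    cfg = ControllerConfig(windowing=windowing)
    sel_L = cfg.window_ms(Mode.SELECTION)
    mnt_L = cfg.window_ms(Mode.MAINTENANCE)
    classes = ClassSet(tuple(g for g in REALTIME_GRASPS if g in {r.meta["class"] for r in recordings}
                             ) or REALTIME_GRASPS)

    def table(window_ms):
        fc = FeatureConfig(window_ms=window_ms)
        Xs, labs = [], []
        for rec in recordings:
            X, _, l = sliding_window_features(rec, fc)
            Xs.append(X)
            labs.append(l)
        return np.concatenate(Xs), np.concatenate(labs)

    Xs, ys = table(sel_L)
    selection_model = train_lda(Xs, ys, shrinkage=shrinkage,
                                classes=classes.selection_classes)
    Xm, ym = table(mnt_L)
    maintenance_model = train_lda(Xm, np.asarray(remap_maintenance(ym), dtype=object),
                                  shrinkage=shrinkage,
                                  classes=classes.maintenance_classes)

    mav_cols = mav_columns(synth_config.n_channels)
    mav_mean = Xs[:, mav_cols].mean(axis=1)
    rest = float(np.median(mav_mean[ys == NO_MOVEMENT]))
    active = mav_mean[np.isin(ys, classes.grasps)]
    peak = float(np.percentile(active, 75))
    return {
        "selection_model": selection_model,
        "maintenance_model": maintenance_model,
        "prop_rest": rest,
        "prop_max": max(peak, rest * 2 + 1e-6),
    }


def build_controller(windowing: str, technique: str, models: dict) -> Controller:
    """Wrap trained models in a controller for one windowing/technique scheme."""
    return Controller(ControllerConfig(windowing=windowing, technique=technique),
                      **models)


def train_realtime_controller(windowing: str, technique: str,
                              synth_config: SynthConfig, seed,
                              protocol: ProtocolSpec | None = None,
                              shrinkage: float = 1e-2) -> Controller:
    models = train_realtime_models(windowing, synth_config, seed,
                                   protocol=protocol, shrinkage=shrinkage)
    return build_controller(windowing, technique, models)


# ---------------------------------------------------------------------------
# Trial execution


def default_intent_policy(hand: HandState, target: str, t_ms: float) -> str:
    """Reopen-and-retry behaviour: pursue the target grasp; if the wrong
    grasp latched, open fully and try again."""
    if hand.engaged_grasp is None or hand.engaged_grasp == target:
        return target
    return HAND_OPEN


def run_trial(controller: Controller, subject: SubjectStream, trial: Trial,
              hand: HandState | None = None, intent_policy=default_intent_policy,
              frame_ms: int = FRAME_MS) -> TrialResult:
    """Run one closed-loop trial at 25 ms control frames.

    Selection attempts count fully-open -> partially-closed transitions.
    The selection time is the time of the final such transition before
    successful completion (the attempt that actually completes); completion
    time is the remainder until full closure.
    """
    hand = hand or HandState()
    subject.set_wrist(trial.wrist_position)
    subject.set_intent(NO_MOVEMENT)
    n_ch = subject.config.n_channels
    prepos_ms = int(trial.preposition_s * 1000)
    timeout_ms = int(trial.timeout_s * 1000)
    total = prepos_ms + timeout_ms
    buf = np.empty((total, n_ch))
    # wrist prepositioning: simulated time passes, nothing is scored
    for t in range(0, prepos_ms, frame_ms):
        buf[t:t + frame_ms] = subject.emit(frame_ms)
    controller.reset(Mode.SELECTION)

    attempts = 0
    last_selection_ms = math.nan
    fc_cache: dict[int, FeatureConfig] = {}
    t = prepos_ms
    while t < total:
        subject.set_intent(intent_policy(hand, trial.target_grasp, t - prepos_ms))
        buf[t:t + frame_ms] = subject.emit(frame_ms)
        t += frame_ms
        L = controller.required_window_ms(hand.aperture)
        fc = fc_cache.setdefault(L, FeatureConfig(window_ms=L))
        fv = extract_features(buf[t - L:t], fc, window_end_ms=t)
        command = controller.step(fv, hand.aperture)
        was_open = is_fully_open(hand)
        hand = step_hand(hand, command, frame_ms)
        now_open = is_fully_open(hand)
        if was_open and not now_open:
            attempts += 1
            last_selection_ms = t - prepos_ms
        if is_fully_closed(hand) and hand.engaged_grasp == trial.target_grasp:
            done = t - prepos_ms
            return TrialResult(trial=trial, completed=True,
                               selection_time_ms=float(last_selection_ms),
                               completion_time_ms=float(done - last_selection_ms),
                               selection_attempts=attempts)
    return TrialResult(trial=trial, completed=False, selection_attempts=attempts)


def summarize(results) -> dict:
    """The four session metrics.

    Timeout rate is a percentage over all trials; the three means cover
    completed trials only and are NaN (undefined) when nothing completed.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one trial result")
    n = len(results)
    done = [r for r in results if r.completed]
    out = {
        "n_trials": n,
        "timeout_rate_percent": 100.0 * (n - len(done)) / n,
        "mean_selection_time_ms": math.nan,
        "mean_completion_time_ms": math.nan,
        "mean_selection_attempts": math.nan,
    }
    if done:
        out["mean_selection_time_ms"] = float(np.mean([r.selection_time_ms for r in done]))
        out["mean_completion_time_ms"] = float(np.mean([r.completion_time_ms for r in done]))
        out["mean_selection_attempts"] = float(np.mean([r.selection_attempts for r in done]))
    return out


ALL_SCHEMES = tuple((w, tq) for w in ("static", "dual")
                    for tq in ("unmodified", "delay", "voting"))


def run_session(windowing: str, technique: str, synth_config: SynthConfig,
                skill: SubjectSkill, seed, trials: list[Trial] | None = None,
                models: dict | None = None):
    """Run a trial block for one scheme against a freshly seeded simulated
    subject, training the classifiers first unless ``models`` is supplied.
    Returns the per-trial results."""
    ss = np.random.SeedSequence(seed)
    s_train, s_sched, s_subj = ss.spawn(3)
    if models is None:
        models = train_realtime_models(windowing, synth_config, s_train)
    controller = build_controller(windowing, technique, models)
    if trials is None:
        trials = schedule_trials(s_sched)
    subject = SubjectStream(synth_config, skill=skill, seed=s_subj)
    return [run_trial(controller, subject, tr) for tr in trials]


def run_session_matrix(synth_config: SynthConfig, skill: SubjectSkill, seed,
                       schemes=ALL_SCHEMES,
                       trials: list[Trial] | None = None) -> pd.DataFrame:
    """Session metrics for each windowing x technique scheme (6 rows).

    Classifier training is shared across the techniques of each windowing
    method, exactly as a subject's training data would be."""
    ss = np.random.SeedSequence(seed)
    s_train, _, _ = ss.spawn(3)
    model_cache: dict[str, dict] = {}
    rows = []
    for windowing, technique in schemes:
        if windowing not in model_cache:
            model_cache[windowing] = train_realtime_models(windowing, synth_config, s_train)
        results = run_session(windowing, technique, synth_config, skill, seed,
                              trials=trials, models=model_cache[windowing])
        row = {"windowing": windowing, "technique": technique}
        row.update(summarize(results))
        rows.append(row)
    return pd.DataFrame(rows)
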