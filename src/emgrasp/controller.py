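"""Real-time decision engine for the prosthesis controller.

Composes, once per 25 ms frame:

1. **Mode selection** — a fully-open hand means *grasp selection*
   (N+2-class classifier); a partially- or fully-closed hand means *grasp
   maintenance* (3-class classifier).
2. **Windowing method** — ``static`` uses a 250 ms analysis window in both
   modes; ``dual`` uses 500 ms during selection and 200 ms during
   maintenance.
3. **Classification technique** — ``unmodified`` (raw LDA decision),
   ``voting`` (majority vote over the trailing decisions spanning one
   window, requiring >= 50 % of possible votes, otherwise no-movement), or
   ``delay`` (motor control frozen on entry to fully-open until consecutive
   grasp decisions accumulate to half the current window length; any
   hand-open or no-movement decision resets the timer — a minimum freeze of
   125 ms with the static window and 250 ms with the dual window).
4. **Proportional speed** — mean-channel MAV rescaled between calibrated
   rest and maximum levels, multiplied by a linear 500 ms velocity ramp that
   resets whenever the decision class changes.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .classes import HAND_CLOSE, HAND_OPEN, NO_MOVEMENT, is_grasp
from .features import mav_columns
from .lda import LdaModel, predict


class Mode(Enum):
    SELECTION = "selection"
    MAINTENANCE = "maintenance"


TECHNIQUES = ("unmodified", "delay", "voting")
WINDOWINGS = ("static", "dual")


@dataclass
class ControllerConfig:
    windowing: str = "dual"
    technique: str = "unmodified"
    static_window_ms: int = 250
    selection_window_ms: int = 500
    maintenance_window_ms: int = 200
    increment_ms: int = 25
    vote_min_fraction: float = 0.5
    ramp_ms: int = 500
    open_threshold: float = 0.99
    #: whether raw decisions issued while frozen still enter the vote buffer
    votes_accrue_during_freeze: bool = True

    def __post_init__(self) -> None:
        if self.windowing not in WINDOWINGS:
            raise ValueError(f"windowing must be one of {WINDOWINGS}")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.windowing == "dual" and not self.selection_window_ms > self.maintenance_window_ms:
            raise ValueError("dual selection window must exceed the maintenance window")
        if not 0.0 < self.vote_min_fraction <= 1.0:
            raise ValueError("vote_min_fraction must be in (0, 1]")
        if self.ramp_ms <= 0:
            raise ValueError("ramp_ms must be positive")

    def window_ms(self, mode: Mode) -> int:
        """Analysis-window length dictated by the windowing method and mode."""
        if self.windowing == "static":
            return self.static_window_ms
        return self.selection_window_ms if mode is Mode.SELECTION else self.maintenance_window_ms


@dataclass
class ControlCommand:
    decision: str
    speed: float
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.frozen and self.speed != 0.0:
            raise ValueError("a frozen command must carry zero speed")
        if not 0.0 <= self.speed <= 1.0:
            raise ValueError("speed must lie in [0, 1]")


def select_mode(hand_aperture: float, open_threshold: float = 0.99) -> Mode:
    """SELECTION iff the aperture is at/above the fully-open threshold."""
    return Mode.SELECTION if hand_aperture >= open_threshold else Mode.MAINTENANCE


def majority_vote(buffer, n_possible: int, min_fraction: float = 0.5) -> str:
    """Plurality class of the decision buffer, gated by the 50 % vote rule.

    Returns ``no_movement`` when the buffer is empty, when the plurality
    count falls short of ``min_fraction * n_possible`` votes, or when the
    plurality is tied.
    """
    votes = list(buffer)
    if not votes:
        return NO_MOVEMENT
    counts = Counter(votes)
    best = max(counts.values())
    if best + 1e-9 < min_fraction * n_possible:
        return NO_MOVEMENT
    winners = [c for c, n in counts.items() if n == best]
    if len(winners) > 1:
        return NO_MOVEMENT
    return winners[0]


def velocity_ramp(ramp_ms_accrued: float, ramp_ms: int = 500) -> float:
    """Linear speed gain: 0 at a class change, 1 after ``ramp_ms`` of the same class."""
    if ramp_ms <= 0:
        raise ValueError("ramp_ms must be positive")
    return float(min(max(ramp_ms_accrued, 0.0) / ramp_ms, 1.0))


def proportional_speed(mav_mean: float, rest_level: float, max_level: float) -> float:
    """Mean-channel MAV rescaled from [rest, max] activation to [0, 1], clamped."""
    if not max_level > rest_level:
        raise ValueError("calibration max level must exceed the rest level")
    return float(np.clip((mav_mean - rest_level) / (max_level - rest_level), 0.0, 1.0))


class Controller:
    """Stateful per-frame controller.

    Classification models are optional: :meth:`step_decision` drives the
    post-processing pipeline directly from an externally supplied decision
    stream, which is how the freeze-timing behaviour is measured.
    """

    def __init__(self, config: ControllerConfig,
                 selection_model: LdaModel | None = None,
                 maintenance_model: LdaModel | None = None,
                 prop_rest: float | None = None,
                 prop_max: float | None = None):
        self.config = config
        self.selection_model = selection_model
        self.maintenance_model = maintenance_model
        self.prop_rest = prop_rest
        self.prop_max = prop_max
        self.reset()

    # -- state ------------------------------------------------------------
    def reset(self, mode: Mode = Mode.SELECTION) -> None:
        self.mode = mode
        self.vote_buffer: deque = deque(maxlen=self._capacity(mode))
        self.freeze_active = (
            self.config.technique == "delay" and mode is Mode.SELECTION
        )
        self.consecutive_grasp_ms = 0.0
        self.ramp_ms_accrued = 0.0
        self.last_decision = NO_MOVEMENT
        # reset() itself marks the mode-entry instant; frames stepped
        # afterwards accrue normally
        self._just_switched = False

    def _capacity(self, mode: Mode) -> int:
        return max(1, self.config.window_ms(mode) // self.config.increment_ms)

    def _update_mode(self, aperture: float) -> Mode:
        new = select_mode(aperture, self.config.open_threshold)
        if new is not self.mode:
            self.mode = new
            # stale votes belong to the other mode's class alphabet
            self.vote_buffer = deque(maxlen=self._capacity(new))
            self._just_switched = True
            if new is Mode.SELECTION and self.config.technique == "delay":
                self.freeze_active = True
                self.consecutive_grasp_ms = 0.0
            if new is Mode.MAINTENANCE:
                self.freeze_active = False
        return self.mode

    # -- per-frame API -----------------------------------------------------
    def step(self, feature_vector, hand_aperture: float) -> ControlCommand:
        """Classify one feature frame and post-process into a motor command.

        ``feature_vector`` must come from the analysis window dictated by the
        current mode (query :meth:`required_window_ms` before extraction).
        """
        mode = self._update_mode(hand_aperture)
        model = self.selection_model if mode is Mode.SELECTION else self.maintenance_model
        if model is None:
            raise ValueError(f"no classifier configured for {mode.value} mode")
        x = np.asarray(getattr(feature_vector, "values", feature_vector), dtype=float)
        if x.shape[-1] != model.n_features:
            raise ValueError(
                f"feature length {x.shape[-1]} inconsistent with the {mode.value}-mode "
                f"window ({model.n_features} expected)"
            )
        raw = predict(model, x)
        if model.n_features >= 10 and model.n_features % 10 == 0:
            mav_mean = float(np.mean(x[mav_columns(model.n_features // 10)]))
        else:  # features not in the per-channel 10-block layout
            mav_mean = None
        return self._advance(raw, mav_mean)

    def step_decision(self, raw_decision: str, hand_aperture: float,
                      mav_mean: float | None = None) -> ControlCommand:
        """Advance one frame from an externally supplied raw classification."""
        self._update_mode(hand_aperture)
        return self._advance(raw_decision, mav_mean)

    def required_window_ms(self, hand_aperture: float) -> int:
        return self.config.window_ms(select_mode(hand_aperture, self.config.open_threshold))

    # -- pipeline ----------------------------------------------------------
    def _advance(self, raw: str, mav_mean: float | None) -> ControlCommand:
        cfg = self.config
        decision = raw
        if cfg.technique == "voting":
            if self.votes_allowed():
                self.vote_buffer.append(raw)
            decision = majority_vote(
                self.vote_buffer, self._capacity(self.mode), cfg.vote_min_fraction
            )
        if cfg.technique == "delay" and self.mode is Mode.SELECTION:
            if self._just_switched:
                # the frame that detects full opening engages the freeze and
                # does not itself accrue grasp time: the minimum freeze is
                # then exactly half the window length
                self.consecutive_grasp_ms = 0.0
            elif is_grasp(raw):
                self.consecutive_grasp_ms += cfg.increment_ms
            else:
                self.consecutive_grasp_ms = 0.0
            if (self.freeze_active
                    and self.consecutive_grasp_ms + 1e-9 >= cfg.window_ms(self.mode) / 2):
                self.freeze_active = False
        self._just_switched = False

        frozen = bool(self.freeze_active and cfg.technique == "delay"
                      and self.mode is Mode.SELECTION)

        if decision == self.last_decision and decision != NO_MOVEMENT:
            self.ramp_ms_accrued += cfg.increment_ms
        else:
            self.ramp_ms_accrued = 0.0
        self.last_decision = decision

        if frozen or decision == NO_MOVEMENT:
            speed = 0.0
        else:
            if mav_mean is not None and self.prop_rest is not None and self.prop_max is not None:
                prop = proportional_speed(mav_mean, self.prop_rest, self.prop_max)
            else:
                prop = 1.0
            speed = prop * velocity_ramp(self.ramp_ms_accrued, cfg.ramp_ms)
        return ControlCommand(decision=decision, speed=speed, frozen=frozen)

    def votes_allowed(self) -> bool:
        if self.config.votes_accrue_during_freeze:
            return True
        return not self.freeze_active
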