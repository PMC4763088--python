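"""Discrete-time virtual prosthetic hand plant.

The hand is a single aperture degree of freedom in [0, 1] (1 = fully open)
with *grasp latching*: a grasp can only be engaged from the fully-open
position, and once engaged it cannot be exchanged for another grasp without
first fully opening the hand — the defining constraint of current
partial-hand prostheses.  Aperture integrates commanded speed linearly, with
``full_excursion_s`` the time to travel the whole range at unit speed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .classes import HAND_CLOSE, HAND_OPEN, NO_MOVEMENT, is_grasp

OPEN_TOL = 0.99
CLOSED_TOL = 0.01


@dataclass(frozen=True)
class HandState:
    aperture: float = 1.0
    engaged_grasp: str | None = None
    full_excursion_s: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.aperture <= 1.0:
            raise ValueError("aperture must lie in [0, 1]")
        if self.full_excursion_s <= 0:
            raise ValueError("full_excursion_s must be positive")


def is_fully_open(hand: HandState) -> bool:
    return hand.aperture >= OPEN_TOL


def is_fully_closed(hand: HandState) -> bool:
    return hand.aperture <= CLOSED_TOL


def step_hand(hand: HandState, command, dt_ms: float) -> HandState:
    """Advance the plant by one control frame.

    Rules:

    * a frozen command leaves the hand untouched;
    * a grasp decision while fully open and unengaged engages that grasp and
      starts closing; the same grasp keeps closing; a *different* grasp while
      partially closed is ignored (latched);
    * ``hand_close`` closes the engaged grasp; ``hand_open`` opens;
      ``no_movement`` holds position;
    * reaching the fully-open position clears the engaged grasp.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if command.frozen:
        return hand
    delta = command.speed * dt_ms / (hand.full_excursion_s * 1000.0)
    d = command.decision
    ap, eng = hand.aperture, hand.engaged_grasp

    if d == HAND_OPEN:
        ap = min(1.0, ap + delta)
        if ap >= OPEN_TOL:
            eng = None
    elif d == HAND_CLOSE:
        if eng is not None:
            ap = max(0.0, ap - delta)
    elif is_grasp(d):
        if eng is None and is_fully_open(hand):
            eng = d
            ap = max(0.0, ap - delta)
        elif eng == d:
            ap = max(0.0, ap - delta)
        # different grasp while latched: ignored
    elif d == NO_MOVEMENT:
        pass
    else:
        raise ValueError(f"unknown decision {d!r}")
    return replace(hand, aperture=ap, engaged_grasp=eng)
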