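"""Motion-class vocabulary and the selection/maintenance class sets.

A partial-hand pattern-recognition controller distinguishes two operating
modes.  With the hand fully open (*grasp selection*) the classifier decides
between the N enabled grasps plus ``hand_open`` and ``no_movement`` — N+2
classes in total.  Once a grasp is engaged (*grasp maintenance*) every grasp
collapses onto a single ``hand_close`` class and only three decisions remain:
close, open, or hold still.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NO_MOVEMENT = "no_movement"
HAND_OPEN = "hand_open"
HAND_CLOSE = "hand_close"

#: The six grasps, ordered from most to least used in activities of daily
#: living: chuck grip, fine pinch, key grip, power grip, hook grip, tool grip.
GRASPS = ("chuck", "fine_pinch", "key", "power", "hook", "tool")

#: All eight postures performed in the offline protocols.
ALL_POSTURES = (NO_MOVEMENT, HAND_OPEN) + GRASPS

#: The three-class alphabet available during grasp maintenance.
MAINTENANCE_CLASSES = (NO_MOVEMENT, HAND_OPEN, HAND_CLOSE)


def is_grasp(label: str) -> bool:
    return label in GRASPS


@dataclass(frozen=True)
class ClassSet:
    """The set of grasps enabled for grasp selection.

    Parameters
    ----------
    grasps
        Ordered grasp identifiers.  Subsets nest by ADL usage: the N most
        used grasps are always a prefix of :data:`GRASPS`.
    """

    grasps: tuple[str, ...] = field(default=GRASPS)

    def __post_init__(self) -> None:
        unknown = [g for g in self.grasps if g not in GRASPS]
        if unknown:
            raise ValueError(f"unknown grasp identifiers: {unknown}; valid: {list(GRASPS)}")
        if len(set(self.grasps)) != len(self.grasps):
            raise ValueError("duplicate grasp identifiers")

    @classmethod
    def most_used(cls, n: int) -> "ClassSet":
        """The ``n`` most ADL-used grasps (``n`` of 2, 4 or 6 in the studies)."""
        if not 1 <= n <= len(GRASPS):
            raise ValueError(f"n must be in 1..{len(GRASPS)}, got {n}")
        return cls(GRASPS[:n])

    @property
    def n_grasps(self) -> int:
        return len(self.grasps)

    @property
    def selection_classes(self) -> tuple[str, ...]:
        """The N+2 classes decided between while the hand is fully open."""
        return (NO_MOVEMENT, HAND_OPEN) + self.grasps

    @property
    def maintenance_classes(self) -> tuple[str, ...]:
        return MAINTENANCE_CLASSES


def remap_maintenance(labels) -> list[str]:
    """Map selection-mode labels onto the three maintenance classes.

    Every grasp label becomes ``hand_close``; ``no_movement`` and
    ``hand_open`` pass through unchanged.

    Raises
    ------
    ValueError
        If a label is not a known selection-mode class.
    """
    out = []
    for lab in labels:
        if lab in GRASPS or lab == HAND_CLOSE:
            out.append(HAND_CLOSE)
        elif lab in (NO_MOVEMENT, HAND_OPEN):
            out.append(lab)
        else:
            raise ValueError(
                f"unknown class label {lab!r}; expected one of {list(ALL_POSTURES)}"
            )
    return out
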