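"""Stimulus design: head-body orientation grids and trial timing.

The experiments manipulate the orientation of the head and the body of a
monkey avatar independently, in 45-degree steps around the vertical axis.
A *configuration* is identified by the orientation of its body (the avatar
orientation, by convention) and the signed angle between head and body
orientation.  Three stimulus sets are supported:

``E1``
    The full 8 x 8 head-body orientation grid (64 monkey images) plus 12
    isolated heads / headless bodies at matched locations, per pose and
    centering (monkey-centered ``MC`` or head-centered ``HC``).
``E2``
    The sum-versus-configuration set: 4 head-body angles x 4 avatar
    orientations (16 monkey images) plus 16 standalone heads and 4
    headless bodies, monkey-centered.
``E3``
    The upright-versus-inverted set: 4 angles x 8 orientations, each
    upright and inverted, plus isolated parts per inversion.

Isolated parts carry an ``anchor_orientation``: the orientation of the
matched configuration that fixes the part's location on the screen.  Two
isolated heads with the same head orientation but different anchors are
different images (they sit at different retinal locations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

ORIENTATIONS: Tuple[int, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
ANGLES: Tuple[int, ...] = (-135, -90, -45, 0, 45, 90, 135, 180)
#: the frontal, back and two lateral avatar orientations ("+" set)
PLUS_ORIENTATIONS: Tuple[int, ...] = (0, 90, 180, 270)
#: the oblique avatar orientations ("x" set)
CROSS_ORIENTATIONS: Tuple[int, ...] = (45, 135, 225, 315)

POSES = ("P1", "P2")
CENTERINGS = ("MC", "HC")
PARTS = ("monkey", "head", "body")
INVERSIONS = ("upright", "inverted")
EXPERIMENTS = ("E1", "E2", "E3")

#: trial window durations, seconds
BASELINE100_S = 0.1
BASELINE200_S = 0.2
RESPONSE_S = 0.25


def signed_angle(head_orientation: int, body_orientation: int) -> int:
    """Signed head-body angle, wrapped into (-180, 180].

    ``+90`` is the rightward right angle (head rotated 90 degrees clockwise
    from the body, seen from above), ``-90`` the leftward one; ``180`` is
    the anatomically impossible straight angle (never returned as -180).
    """
    for v in (head_orientation, body_orientation):
        if v % 45 != 0:
            raise ValueError(f"orientation {v} is not a multiple of 45 degrees")
    a = (head_orientation - body_orientation) % 360
    if a > 180:
        a -= 360
    return int(a)


def _check_orientation(value: Optional[int], name: str) -> None:
    if value is not None and value not in ORIENTATIONS:
        raise ValueError(f"{name}={value} not on the 45-degree grid {ORIENTATIONS}")


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus image: pose, visible part, orientations, centering, inversion.

    For ``part='monkey'`` both orientations are set and :attr:`angle` is the
    signed head-body angle.  For isolated parts only the visible part's
    orientation is set; ``anchor_orientation`` records the matched
    configuration's other-part orientation (location tag), or ``None`` when
    the part sits at its canonical location.
    """

    pose: str = "P1"
    part: str = "monkey"
    body_orientation: Optional[int] = None
    head_orientation: Optional[int] = None
    centering: str = "MC"
    inversion: str = "upright"
    anchor_orientation: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pose not in POSES:
            raise ValueError(f"unknown pose {self.pose!r}")
        if self.part not in PARTS:
            raise ValueError(f"unknown part {self.part!r}")
        if self.centering not in CENTERINGS:
            raise ValueError(f"unknown centering {self.centering!r}")
        if self.inversion not in INVERSIONS:
            raise ValueError(f"unknown inversion {self.inversion!r}")
        _check_orientation(self.body_orientation, "body_orientation")
        _check_orientation(self.head_orientation, "head_orientation")
        _check_orientation(self.anchor_orientation, "anchor_orientation")
        if self.part == "monkey":
            if self.body_orientation is None or self.head_orientation is None:
                raise ValueError("monkey conditions need both orientations")
            if self.anchor_orientation is not None:
                raise ValueError("monkey conditions carry no anchor")
        elif self.part == "head" and self.head_orientation is None:
            raise ValueError("head conditions need head_orientation")
        elif self.part == "body" and self.body_orientation is None:
            raise ValueError("body conditions need body_orientation")
        if self.part == "head" and self.body_orientation is not None:
            raise ValueError("isolated heads have no body orientation (use anchor)")
        if self.part == "body" and self.head_orientation is not None:
            raise ValueError("isolated bodies have no head orientation (use anchor)")

    @property
    def angle(self) -> Optional[int]:
        """Signed head-body angle in (-180, 180]; ``None`` unless part='monkey'."""
        if self.part != "monkey":
            return None
        return signed_angle(self.head_orientation, self.body_orientation)

    def sort_key(self) -> tuple:
        none = -1
        return (
            self.pose,
            PARTS.index(self.part),
            self.body_orientation if self.body_orientation is not None else none,
            self.head_orientation if self.head_orientation is not None else none,
            self.centering,
            self.inversion,
            self.anchor_orientation if self.anchor_orientation is not None else none,
        )


def monkey_condition(
    pose: str,
    body_orientation: int,
    angle: int,
    centering: str = "MC",
    inversion: str = "upright",
) -> StimulusCondition:
    """The whole-monkey image with the given avatar orientation and head-body angle."""
    return StimulusCondition(
        pose=pose,
        part="monkey",
        body_orientation=body_orientation,
        head_orientation=(body_orientation + angle) % 360,
        centering=centering,
        inversion=inversion,
    )


def monkey_conditions(
    pose: str = "P1",
    centering: str = "MC",
    angles: Sequence[int] = ANGLES,
    orientations: Sequence[int] = ORIENTATIONS,
    inversion: str = "upright",
) -> List[StimulusCondition]:
    """Whole-monkey conditions for the requested angles x avatar orientations."""
    return [
        monkey_condition(pose, b, a, centering, inversion)
        for a in angles
        for b in orientations
    ]


def _e1_isolated(pose: str, centering: str) -> List[StimulusCondition]:
    conds: List[StimulusCondition] = []
    if centering == "MC":
        # four headless bodies at their own location ...
        for b in PLUS_ORIENTATIONS:
            conds.append(StimulusCondition(pose=pose, part="body", body_orientation=b,
                                           centering=centering))
        # ... and eight heads: one zero-angle and one straight-angle head per body
        for b in PLUS_ORIENTATIONS:
            for ang in (0, 180):
                conds.append(StimulusCondition(
                    pose=pose, part="head", head_orientation=(b + ang) % 360,
                    centering=centering, anchor_orientation=b))
    else:
        # head-centered: four heads at fixation, eight bodies at matched locations
        for h in PLUS_ORIENTATIONS:
            conds.append(StimulusCondition(pose=pose, part="head", head_orientation=h,
                                           centering=centering))
        for h in PLUS_ORIENTATIONS:
            for ang in (0, 180):
                conds.append(StimulusCondition(
                    pose=pose, part="body", body_orientation=(h - ang) % 360,
                    centering=centering, anchor_orientation=h))
    return conds


def make_stimulus_grid(experiment: str, pose: str = "P1",
                       centering: str = "MC") -> List[StimulusCondition]:
    """The full stimulus set of one experiment for one pose and centering.

    Returns 76 conditions for ``E1`` (64 monkey + 12 isolated), 36 for
    ``E2`` (16 monkey + 16 heads + 4 bodies) and 88 for ``E3`` (32 monkey
    + 12 isolated, upright and inverted).  Ordering is deterministic.
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    conds: List[StimulusCondition] = []
    if experiment == "E1":
        conds += monkey_conditions(pose, centering)
        conds += _e1_isolated(pose, centering)
    elif experiment == "E2":
        e2_angles = (0, 90, -90, 180)
        conds += monkey_conditions(pose, centering, angles=e2_angles,
                                   orientations=PLUS_ORIENTATIONS)
        for b in PLUS_ORIENTATIONS:
            conds.append(StimulusCondition(pose=pose, part="body", body_orientation=b,
                                           centering=centering))
            for ang in e2_angles:
                conds.append(StimulusCondition(
                    pose=pose, part="head", head_orientation=(b + ang) % 360,
                    centering=centering, anchor_orientation=b))
    else:  # E3
        e3_angles = (0, 90, -90, 180)
        for inv in INVERSIONS:
            conds += monkey_conditions(pose, centering, angles=e3_angles,
                                       inversion=inv)
            for c in _e1_isolated(pose, centering):
                conds.append(StimulusCondition(
                    pose=c.pose, part=c.part, body_orientation=c.body_orientation,
                    head_orientation=c.head_orientation, centering=c.centering,
                    inversion=inv, anchor_orientation=c.anchor_orientation))
    return sorted(set(conds), key=StimulusCondition.sort_key)
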