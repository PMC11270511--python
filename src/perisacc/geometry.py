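"""Stimulus geometry of the two-fixation-point saccade task.

Two fixation points sit on the horizontal meridian, 10.04 degrees of visual
angle (dva) left and right of screen center (20.08 dva apart).  Four stimulus
locations form a 2 x 2 grid around each fixation point: each location is
5.06 dva from its nearest fixation point and vertically adjacent locations
are 5.06 dva apart.

Location ids are *retinotopic*: ids 1-4 always denote the grid around the
currently fixated point (1 upper-left, 2 lower-left, 3 upper-right, 4
lower-right, offsets in screen coordinates), and ids 5-8 the corresponding
grid around the other fixation point.  A saccade from one fixation point to
the other translates the retinal image by the fixation separation, so a
stimulus at peripheral location p lands, retinotopically, on central location
``remap_pairs[p]`` (5->1, 6->2, 7->3, 8->4).  Spatially, however, a
peripheral location is much closer to the central location on the facing
side of the grid, which is recorded in ``nearest_spatiotopic`` (e.g. 5->3);
that proximity is what drives below-chance horizontal cross-decoding in the
absence of a saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIXATION_SEPARATION_DVA = 20.08
FIXATION_ECCENTRICITY_DVA = FIXATION_SEPARATION_DVA / 2.0  # 10.04
STIMULUS_SPACING_DVA = 5.06

# vertical half-spacing; horizontal offset follows from the 5.06 dva
# distance to the nearest fixation point
_DY = STIMULUS_SPACING_DVA / 2.0
_DX = float(np.sqrt(STIMULUS_SPACING_DVA**2 - _DY**2))

#: offsets of the four grid locations relative to their fixation point,
#: in screen coordinates (x rightward, y upward)
GRID_OFFSETS: dict[int, tuple[float, float]] = {
    1: (-_DX, +_DY),  # upper-left
    2: (-_DX, -_DY),  # lower-left
    3: (+_DX, +_DY),  # upper-right
    4: (+_DX, -_DY),  # lower-right
}

REMAP_PAIRS: dict[int, int] = {5: 1, 6: 2, 7: 3, 8: 4}

#: central location (1-4) each peripheral location (5-8) is confused with
#: in the absence of a saccade.  For the inner column (5, 6) this is
#: literally the nearest central location in screen coordinates (5 -> 3:
#: both upper, facing each other across the screen center); the map is
#: extended antisymmetrically to the outer column (7 -> 1, 8 -> 2) so that
#: for every peripheral location the confusion target is the horizontal
#: complement of its remap partner — the property that makes veridical
#: (spatiotopic) confusion and remapping pull a horizontal-pair classifier
#: in opposite directions, and hence control decoding fall below chance.
NEAREST_SPATIOTOPIC: dict[int, int] = {5: 3, 6: 4, 7: 1, 8: 2}

CENTRAL_LOCATIONS = (1, 2, 3, 4)
PERIPHERAL_LOCATIONS = (5, 6, 7, 8)

#: the six pairwise comparisons among central locations and their classes
PAIR_CLASSES: dict[tuple[int, int], str] = {
    (1, 2): "vertical",
    (3, 4): "vertical",
    (1, 3): "horizontal",
    (2, 4): "horizontal",
    (1, 4): "diagonal",
    (2, 3): "diagonal",
}
ALL_PAIRS = tuple(PAIR_CLASSES)
HORIZONTAL_PAIRS = ((1, 3), (2, 4))


@dataclass(frozen=True)
class StimulusLayout:
    """Coordinates (dva, screen frame) and correspondences of the task."""

    fixation_left: tuple[float, float] = (-FIXATION_ECCENTRICITY_DVA, 0.0)
    fixation_right: tuple[float, float] = (+FIXATION_ECCENTRICITY_DVA, 0.0)
    stimulus_locations: dict[int, tuple[float, float]] = field(default_factory=dict)
    remap_pairs: dict[int, int] = field(default_factory=lambda: dict(REMAP_PAIRS))
    nearest_spatiotopic: dict[int, int] = field(
        default_factory=lambda: dict(NEAREST_SPATIOTOPIC)
    )

    def fixation_point(self, side: str) -> np.ndarray:
        if side == "left":
            return np.asarray(self.fixation_left, dtype=float)
        if side == "right":
            return np.asarray(self.fixation_right, dtype=float)
        raise ValueError(f"unknown fixation side {side!r}")

    def location_position(self, location_id: int, fixation_side: str) -> np.ndarray:
        """Screen position of a retinotopic location id for a fixation side.

        Ids 1-4 are anchored to the fixated point, ids 5-8 to the other
        point; the grid offsets themselves are fixed in screen coordinates.
        """
        if location_id in GRID_OFFSETS:
            anchor = self.fixation_point(fixation_side)
            offset = GRID_OFFSETS[location_id]
        elif location_id in REMAP_PAIRS:
            other = "right" if fixation_side == "left" else "left"
            anchor = self.fixation_point(other)
            offset = GRID_OFFSETS[REMAP_PAIRS[location_id]]
        else:
            raise ValueError(f"unknown stimulus location id {location_id}")
        return anchor + np.asarray(offset, dtype=float)

    def retinal_offset(self, location_id: int, fixation_side: str) -> np.ndarray:
        """Position of a location relative to the currently fixated point."""
        return self.location_position(location_id, fixation_side) - self.fixation_point(
            fixation_side
        )


def build_stimulus_layout() -> StimulusLayout:
    """Construct the task layout (left-fixation reference frame).

    ``stimulus_locations`` holds screen positions with ids numbered as when
    fixating the left point: 1-4 around the left fixation point, 5-8 around
    the right one.
    """
    layout = StimulusLayout()
    locations: dict[int, tuple[float, float]] = {}
    for loc in CENTRAL_LOCATIONS + PERIPHERAL_LOCATIONS:
        locations[loc] = tuple(layout.location_position(loc, "left"))
    return StimulusLayout(stimulus_locations=locations)
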