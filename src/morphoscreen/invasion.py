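"""3D invasion quantification: per-plane nucleus counts and invasion index.

Cells are pelleted at the bottom of a collagen gel and allowed to invade
upward; the gel is imaged at a few z-planes (20-um thick, depths label the
plane centres) and the invasion index is the percentage of all counted
cells found at the named invaded depths (by default 30, 60 and 90 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import imaging


@dataclass
class InvasionStack:
    """Nucleus counts per imaged z-plane (optionally with the images)."""

    plane_depths_um: List[float]
    counts: List[int]
    plane_thickness_um: float = 20.0
    plane_images: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        if len(self.plane_depths_um) != len(self.counts):
            raise ValueError("depths and counts must have equal length")
        if any(np.diff(self.plane_depths_um) <= 0):
            raise ValueError("plane depths must be strictly increasing")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.plane_thickness_um <= 0:
            raise ValueError("plane_thickness_um must be positive")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def count_per_plane(
    plane_images: Sequence[np.ndarray],
    plane_depths_um: Sequence[float],
    min_area_px: int = 30,
) -> InvasionStack:
    """Count nuclei on each plane image via the nucleus segmenter.

    A blank (constant) plane counts zero nuclei rather than failing.
    """
    counts = []
    for img in plane_images:
        try:
            labels = imaging.segment_nuclei(np.asarray(img), min_area_px=min_area_px)
            counts.append(labels.n_labels)
        except imaging.SegmentationError:
            counts.append(0)
    return InvasionStack(
        plane_depths_um=[float(d) for d in plane_depths_um],
        counts=counts,
        plane_images=[np.asarray(i) for i in plane_images],
    )


def invasion_index(
    stack: InvasionStack,
    invaded_depths_um: Sequence[float] = (30.0, 60.0, 90.0),
) -> Tuple[float, Dict[float, float]]:
    """Percentage of cells at the invaded depths, plus per-depth fractions.

    Returns ``(index_pct, {depth: pct})``.  The index is
    ``100 * sum(counts at invaded depths) / sum(all counts)``.
    """
    depths = list(stack.plane_depths_um)
    missing = [d for d in invaded_depths_um if d not in depths]
    if missing:
        raise ValueError(f"invaded depths {missing} not among imaged planes {depths}")
    total = stack.total
    if total == 0:
        raise ValueError("zero total count: invasion index undefined")
    by_depth = dict(zip(depths, stack.counts))
    per_depth = {float(d): 100.0 * by_depth[d] / total for d in invaded_depths_um}
    index = 100.0 * sum(by_depth[d] for d in invaded_depths_um) / total
    return index, per_depth


def fraction_at_or_beyond(stack: InvasionStack, depth_um: float) -> float:
    """Cumulative percentage of cells at planes >= ``depth_um``."""
    total = stack.total
    if total == 0:
        raise ValueError("zero total count")
    mass = sum(c for d, c in zip(stack.plane_depths_um, stack.counts) if d >= depth_um)
    return 100.0 * mass / total
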