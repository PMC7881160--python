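"""End-to-end convenience chains over the module-level operations."""

from __future__ import annotations

import numpy as np

from .geometry import ThetaSamples, assign_theta, detect_circle, fit_spline
from .images import PolarizationPair, correct_pair, dichroic_ratio_map

__all__ = ["analyze_ring_pair"]


def analyze_ring_pair(
    pair: PolarizationPair,
    geometry: str = "membrane",
    radius_range: tuple[float, float] = (8.0, 80.0),
    min_intensity: float = 0.0,
    n_anchors: int = 16,
    max_distance: float = 3.0,
    object_id: str = "object",
) -> ThetaSamples:
    """Correct a pair, locate the ring, fit its outline, extract θ-samples.

    The standard vesicle/round-cell chain: calibration correction →
    per-pixel dichroic ratio → Hough circle → periodic spline through
    anchors on the detected circle → nearest-outline tangent assignment.
    """
    corrected = correct_pair(pair)
    ldmap = dichroic_ratio_map(corrected, min_intensity=min_intensity)
    circ = detect_circle(ldmap.intensity, radius_range=radius_range)
    ang = np.linspace(0.0, 2 * np.pi, n_anchors, endpoint=False)
    anchors = np.stack(
        [circ.cx + circ.radius * np.cos(ang), circ.cy - circ.radius * np.sin(ang)],
        axis=1,
    )
    outline = fit_spline(anchors, closed=True)
    return assign_theta(
        ldmap,
        outline,
        geometry=geometry,
        max_distance=max_distance,
        modality=pair.modality,
        object_id=object_id,
    )
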