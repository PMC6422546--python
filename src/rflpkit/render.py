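"""Monospaced text rendering of gel lanes (illustrative only).

Band vertical position is interpolated on a log-size scale against the
ladder, mimicking electrophoretic migration; nothing quantitative should be
read off these diagrams.
"""

from __future__ import annotations

import math

from .assay import BandPattern

__all__ = ["render_text_gel", "DEFAULT_LADDER"]

# 50 bp ladder, as used for RFLP gels (descending).
DEFAULT_LADDER = [1000, 900, 800, 700, 600, 500, 400, 300, 250, 200, 150, 100, 50]

_LANE_WIDTH = 9
_BAND = "=" * 5


def render_text_gel(
    patterns: list[BandPattern],
    ladder: list[float] | None = None,
    height: int = 24,
) -> str:
    """Lane diagram: ladder first, then one lane per pattern (visible bands)."""
    ladder = list(ladder) if ladder else list(DEFAULT_LADDER)
    if ladder != sorted(ladder, reverse=True):
        raise ValueError("ladder must be sorted descending")
    top, bottom = math.log(ladder[0]), math.log(ladder[-1])
    span = top - bottom or 1.0

    def row_of(bp: float) -> int:
        r = round((top - math.log(bp)) / span * (height - 1))
        return min(max(r, 0), height - 1)

    lanes: list[dict[int, str]] = []
    labels = ["ladder"]
    lane0 = {row_of(bp): f"{bp:>4.0f} -" for bp in ladder}
    lanes.append(lane0)
    for pat in patterns:
        lanes.append({row_of(bp): _BAND for bp in pat.visible_bands})
        labels.append(pat.tube)

    lines = ["".join(lab[:_LANE_WIDTH].center(_LANE_WIDTH) for lab in labels)]
    for r in range(height):
        lines.append("".join(lane.get(r, "").center(_LANE_WIDTH) for lane in lanes).rstrip())
    return "\n".join(lines) + "\n"
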