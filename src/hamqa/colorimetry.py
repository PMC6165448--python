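"""CIELAB colorimetry: chroma, hue angle and CIE76 color difference.

The six color features used alongside the 22 texture features are
L*, a*, b* (instrument readings) plus the derived C* = sqrt(a*^2+b*^2),
hue angle h = atan2(b*, a*) in degrees wrapped to [0, 360), and
Delta-E* computed as the CIE76 Euclidean distance to a configurable
reference (default: the white calibration standard L* 97.83, a* -0.45,
b* +1.88).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ColorReading",
    "WHITE_STANDARD",
    "COLOR_NAMES",
    "chroma",
    "hue_degrees",
    "delta_e",
    "color_features",
    "augment_color_table",
]

COLOR_NAMES = ("L", "a", "b", "C", "h", "dE")


@dataclass(frozen=True)
class ColorReading:
    """A single CIELAB reading."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")


#: white calibration plate used as the default Delta-E reference
WHITE_STANDARD = ColorReading(L=97.83, a=-0.45, b=1.88)


def chroma(a: float, b: float) -> float:
    """C* = sqrt(a*^2 + b*^2)."""
    return math.hypot(a, b)


def hue_degrees(a: float, b: float) -> float:
    """Hue angle h = atan2(b*, a*) in degrees, wrapped to [0, 360)."""
    if a == 0.0 and b == 0.0:
        raise ValueError("hue angle undefined at a* = b* = 0")
    return math.degrees(math.atan2(b, a)) % 360.0


def delta_e(x: ColorReading, ref: ColorReading = WHITE_STANDARD) -> float:
    """CIE76 color difference sqrt(dL^2 + da^2 + db^2) to ``ref``."""
    return math.sqrt((x.L - ref.L) ** 2 + (x.a - ref.a) ** 2 + (x.b - ref.b) ** 2)


def color_features(x: ColorReading, ref: ColorReading = WHITE_STANDARD) -> dict[str, float]:
    """Assemble the 6-slot color feature set (L, a, b, C, h, dE)."""
    return {
        "L": x.L,
        "a": x.a,
        "b": x.b,
        "C": chroma(x.a, x.b),
        "h": hue_degrees(x.a, x.b),
        "dE": delta_e(x, ref),
    }


def augment_color_table(
    table: pd.DataFrame, ref: ColorReading = WHITE_STANDARD
) -> pd.DataFrame:
    """Append C, h, dE columns to a colorimeter table with L, a, b columns."""
    missing = {"L", "a", "b"} - set(table.columns)
    if missing:
        raise ValueError(f"color table lacks columns: {sorted(missing)}")
    out = table.copy()
    feats = [
        color_features(ColorReading(r.L, r.a, r.b), ref)
        for r in out[["L", "a", "b"]].itertuples(index=False)
    ]
    for name in ("C", "h", "dE"):
        out[name] = [f[name] for f in feats]
    return out
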