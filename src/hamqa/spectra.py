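"""FT-IR band-intensity extraction and diagnostics.

A spectrum is a (wavenumber, absorbance) series nominally spanning
4000-500 cm^-1 at ~4 cm^-1 resolution.  Band intensity is read as the
maximum absorbance inside a band window (Table-style intensities are
peak-scale, 0.01-0.15 AU), after optional linear baseline subtraction
anchored at 3800 and 520 cm^-1.

The default 15-band registry (plus the 717 cm^-1 unsaturation marker and
the 1083 cm^-1 P=O auxiliary) ships as ``data/bands.csv`` and can be
edited without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr

__all__ = [
    "Spectrum",
    "BandDefinition",
    "load_band_registry",
    "default_bands",
    "band_intensity",
    "band_table",
    "co_po_ratio",
    "band_presence",
    "color_band_correlation",
    "read_spectrum_csv",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber window with its chemical assignment."""

    name: str
    low: float
    high: float
    assignment: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


class Spectrum:
    """Wavenumber/absorbance series with strictly monotone wavenumbers."""

    def __init__(self, wavenumbers, absorbance):
        wn = np.asarray(wavenumbers, dtype=np.float64)
        ab = np.asarray(absorbance, dtype=np.float64)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        # store ascending internally; intensity reads are order-invariant
        if d[0] < 0:
            wn, ab = wn[::-1], ab[::-1]
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def baseline_corrected(self, anchors: tuple[float, float] = (3800.0, 520.0)) -> "Spectrum":
        """Subtract the straight line through the absorbance at the anchors."""
        lo, hi = sorted(anchors)
        i_lo = int(np.argmin(np.abs(self.wavenumbers - lo)))
        i_hi = int(np.argmin(np.abs(self.wavenumbers - hi)))
        x0, x1 = self.wavenumbers[i_lo], self.wavenumbers[i_hi]
        y0, y1 = self.absorbance[i_lo], self.absorbance[i_hi]
        slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
        base = y0 + slope * (self.wavenumbers - x0)
        return Spectrum(self.wavenumbers, self.absorbance - base)


def load_band_registry(path=None) -> list[BandDefinition]:
    """Load all bands (core + aux) from a registry CSV."""
    if path is None:
        with resources.files("hamqa.data").joinpath("bands.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return [
        BandDefinition(str(r.name_), float(r.low), float(r.high), str(r.assignment))
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def default_bands(include_aux: bool = False) -> list[BandDefinition]:
    """The 15 table bands, optionally with the 717/1083 auxiliaries."""
    with resources.files("hamqa.data").joinpath("bands.csv").open() as fh:
        df = pd.read_csv(fh)
    if not include_aux:
        df = df[df["role"] == "core"]
    return [
        BandDefinition(str(r[0]), float(r[1]), float(r[2]), str(r[4]))
        for r in df.itertuples(index=False)
    ]


def band_intensity(s: Spectrum, band: BandDefinition, baseline: bool = False) -> float:
    """Maximum absorbance inside the band window.

    With ``baseline=True`` the linear baseline (anchors 3800/520 cm^-1)
    is subtracted first.
    """
    if baseline:
        s = s.baseline_corrected()
    mask = (s.wavenumbers >= band.low) & (s.wavenumbers <= band.high)
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.low}, {band.high}] outside spectrum range")
    return float(s.absorbance[mask].max())


def band_table(
    s: Spectrum, bands: list[BandDefinition] | None = None, baseline: bool = False
) -> pd.Series:
    """Band intensities for every band in the registry; out-of-range bands NaN."""
    if bands is None:
        bands = default_bands()
    if baseline:
        s = s.baseline_corrected()
    out = {}
    for band in bands:
        try:
            out[band.name] = band_intensity(s, band, baseline=False)
        except ValueError:
            out[band.name] = float("nan")
    return pd.Series(out)


#: interval of the carbonyl/phosphate ratio attributed to phospholipids
PHOSPHOLIPID_RATIO = (1.9, 2.3)


def co_po_ratio(intensities: pd.Series | dict) -> tuple[float, str]:
    """Ratio I(1744)/I(1240) and its attribution.

    A ratio inside [1.9, 2.3] attributes the P=O absorption to
    phospholipids; outside, to nucleic acids.
    """
    i_co = float(intensities["1744"])
    i_po = float(intensities["1240"])
    if not (i_po > 0):
        raise ValueError("P=O (1240 cm^-1) intensity must be positive")
    ratio = i_co / i_po
    lo, hi = PHOSPHOLIPID_RATIO
    return ratio, ("phospholipid" if lo <= ratio <= hi else "nucleic_acid")


def band_presence(
    s: Spectrum, center: float, half_width: float = 8.0, k: float = 5.0
) -> bool:
    """True iff a local maximum with prominence > k x noise scale exists
    within ``center +/- half_width``.

    Noise scale is the median absolute successive difference of the whole
    spectrum.
    """
    wn, ab = s.wavenumbers, s.absorbance
    if not (wn[0] <= center <= wn[-1]):
        raise ValueError("center outside spectrum range")
    noise = float(np.median(np.abs(np.diff(ab))))
    threshold = k * max(noise, 1e-12)
    # search a margin around the window so edge peaks get real prominence
    margin = 6 * half_width
    region = (wn >= center - margin) & (wn <= center + margin)
    idx = np.flatnonzero(region)
    peaks, props = find_peaks(ab[idx], prominence=threshold)
    if peaks.size == 0:
        return False
    peak_wn = wn[idx][peaks]
    return bool(np.any(np.abs(peak_wn - center) <= half_width))


def color_band_correlation(
    colors: pd.DataFrame, bands: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Pearson r and two-sided p for each (color feature, band) pair.

    ``colors`` and ``bands`` must share their index (sample identifiers).
    Zero-variance variables yield NaN, flagged in the ``defined`` column.
    """
    joined = colors.join(bands, how="inner", lsuffix="_color")
    if len(joined) < 3:
        raise ValueError("need at least 3 matched samples")
    rows = []
    for color_var, band_var in pairs:
        x = joined[color_var].to_numpy(dtype=float)
        y = joined[band_var].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((color_var, band_var, math.nan, math.nan, False))
            continue
        r, p = pearsonr(x, y)
        rows.append((color_var, band_var, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["color", "band", "r", "p", "defined"])


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectrum CSV needs two columns: wavenumber, absorbance")
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())
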