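"""Stage orchestration: the three analyses behind the CLI and the
numbered analysis scripts.

1. type/processing discrimination -- 28-feature vectors (22 texture + 6
   color) per slice, PNN + exact LOO + exhaustive subset search;
2. spectra interpretation -- band tables, carbonyl/phosphate ratio,
   717 cm^-1 marker presence, color-band correlations;
3. shelf-life monitoring -- per-day group comparisons and quadratic
   storage-time trends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, colorimetry, spectra, synthetic, texture, trends

__all__ = [
    "FEATURE_NAMES",
    "RunConfig",
    "extract_features",
    "discriminate",
    "band_intensity_series",
    "shelflife_report",
]

#: the fixed 28-slot feature order: 22 texture then 6 color
FEATURE_NAMES = texture.TEXTURE_NAMES + colorimetry.COLOR_NAMES


@dataclass(frozen=True)
class RunConfig:
    """Serializable pipeline parameters (recorded in every report)."""

    seed: int = 0
    levels: int = 32
    distance: int = 1
    roi_fraction: float = 0.6
    max_subset_size: int = 3
    sigma_policy: str = "grid"
    norm_mode: str = "fold"
    trend_threshold: float = 0.2

    def texture_config(self) -> texture.TextureConfig:
        return texture.TextureConfig(
            levels=self.levels, distance=self.distance, roi_fraction=self.roi_fraction
        )


def extract_features(
    bundle: synthetic.StudyBundle, cfg: RunConfig = RunConfig()
) -> pd.DataFrame:
    """Per-slice 28-feature table from a synthetic study bundle.

    Texture features come from the replicate's image (central ROI crop);
    color features from its day-0 colorimeter reading.  Rows with any
    undefined feature are dropped with a note column.
    """
    tcfg = cfg.texture_config()
    day0 = bundle.colors[bundle.colors["day"] == bundle.colors["day"].min()]
    rows = []
    for (cname, rep), img in bundle.images.items():
        gray = texture.to_grayscale(img)
        roi = texture.crop_roi(gray, tcfg.roi_fraction)
        feats = texture.texture_vector(roi, tcfg, warn_undefined=False)
        cr = day0[(day0["class"] == cname) & (day0["replicate"] == rep)].iloc[0]
        reading = colorimetry.ColorReading(float(cr.L), float(cr.a), float(cr.b))
        feats.update(colorimetry.color_features(reading))
        rows.append({"class": cname, "replicate": rep, **feats})
    df = pd.DataFrame(rows)
    return df[["class", "replicate", *FEATURE_NAMES]]


def discriminate(
    features: pd.DataFrame,
    class_sets: dict,
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Subset search + LOO evaluation for each named class comparison.

    ``class_sets`` maps a comparison name to the tuple of class labels it
    involves.  Patterns with missing features are rejected (logged in the
    report), matching the documented degenerate-feature policy.
    """
    reports = {}
    for name, classes in class_sets.items():
        sub = features[features["class"].isin(classes)].reset_index(drop=True)
        X = sub[list(FEATURE_NAMES)].to_numpy(dtype=float)
        ok = ~np.isnan(X).any(axis=1)
        res = classification.subset_search(
            X[ok],
            sub.loc[ok, "class"].to_numpy(),
            max_size=cfg.max_subset_size,
            sigma=cfg.sigma_policy,
            norm=cfg.norm_mode,
            feature_names=list(FEATURE_NAMES),
        )
        reports[name] = {
            "classes": list(classes),
            "n_patterns": int(ok.sum()),
            "n_rejected_missing": int((~ok).sum()),
            "best_subset": [FEATURE_NAMES[i] for i in res.subset],
            "sigma": res.sigma,
            "accuracy": res.truth_table.accuracy,
            "per_class_recall": {str(k): v for k, v in res.truth_table.per_class_recall.items()},
            "truth_table": res.truth_table.to_frame().to_dict(),
            "config": asdict(cfg),
        }
    return reports


def band_amplitude_series(
    class_name: str,
    n_per_day: int = 30,
    days=synthetic.STORAGE_DAYS,
    seed: int = 0,
) -> pd.DataFrame:
    """Storage series of the generator's per-replicate band amplitudes
    (the synthetic study's measured intensities, no spectral rendering)."""
    spec = synthetic.CLASS_SPECS[class_name]
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        for rep in range(n_per_day):
            amps = synthetic.draw_band_amplitudes(spec, day, rng)
            rows.append({"class": class_name, "day": day, "replicate": rep, **amps})
    return pd.DataFrame(rows)


def band_intensity_series(
    class_name: str,
    n_per_day: int = 4,
    days=synthetic.STORAGE_DAYS,
    seed: int = 0,
    baseline: bool = False,
) -> pd.DataFrame:
    """Storage series of extracted band intensities for one class.

    Generates replicate spectra per sampling day and reads the 15-band
    table from each -- the spectra-module round trip, not the generator's
    internal amplitudes.
    """
    spec = synthetic.CLASS_SPECS[class_name]
    rng = np.random.default_rng(seed)
    bands = spectra.default_bands()
    rows = []
    for day in days:
        for rep in range(n_per_day):
            s = synthetic.gen_spectrum(spec, day=day, seed=rng)
            t = spectra.band_table(s, bands, baseline=baseline)
            rows.append({"class": class_name, "day": day, "replicate": rep, **t.to_dict()})
    return pd.DataFrame(rows)


def shelflife_report(
    series: pd.DataFrame,
    variables: list[str],
    cfg: RunConfig = RunConfig(),
) -> dict:
    """Day-effect scan plus quadratic trend fits for each variable."""
    scan = trends.day_effect_scan(series, variables)
    fits = {}
    for var in variables:
        fit = trends.fit_trend(
            series["day"].to_numpy(), series[var].to_numpy(), threshold=cfg.trend_threshold
        )
        fits[var] = {
            "c0": fit.c0,
            "c1": fit.c1,
            "c2": fit.c2,
            "spearman_r": fit.spearman_r,
            "accepted": fit.accepted,
        }
    return {
        "scan": scan.to_dict(orient="records"),
        "trends": fits,
        "config": asdict(cfg),
    }


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
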