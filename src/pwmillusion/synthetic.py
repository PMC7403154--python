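"""Procedural silhouettes and synthetic subject datasets.

Hand-drawn experiment images (animal silhouettes) and raw subject data
are not redistributable, so this module generates stand-ins with the same
structure: binary figure-on-background silhouettes for stimulus rendering,
and a subject table whose acuity values follow per-degradation-type linear
models of the limiting spatial frequency with subject-level random offsets
and residual noise — the generative structure the mixed model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .halftone import SourceImage

__all__ = ["SHAPES", "make_silhouette", "SimulationConfig", "simulate_subjects"]

SHAPES = ("disc", "ring", "cross", "heart", "smiley")

#: Default disc radius as a fraction of image size.
DISC_RADIUS_FRAC = 0.35


def make_silhouette(shape: str, size: int = 256) -> SourceImage:
    """Deterministic binary silhouette (figure = 1) of the given shape.

    Figure area lands between 10% and 60% of the image for every shape.
    """
    if size < 32:
        raise ValueError("size must be at least 32 px")
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; valid shapes: {SHAPES}")
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    x = (xx - cx) / size
    y = (yy - cy) / size
    r = np.hypot(x, y)
    if shape == "disc":
        fig = r <= DISC_RADIUS_FRAC
    elif shape == "ring":
        fig = (r <= 0.42) & (r >= 0.22)
    elif shape == "cross":
        arm = 0.12
        fig = ((np.abs(x) <= arm) | (np.abs(y) <= arm)) & (np.abs(x) <= 0.42) \
            & (np.abs(y) <= 0.42)
    elif shape == "heart":
        # classic implicit heart curve, y flipped so the point faces down
        xs, ys = x * 3.0, -y * 3.0 + 0.3
        fig = (xs ** 2 + ys ** 2 - 1.0) ** 3 - xs ** 2 * ys ** 3 <= 0
    else:  # smiley
        face = r <= 0.42
        eyes = (np.hypot(np.abs(x) - 0.15, y + 0.13) <= 0.06)
        mouth = (np.hypot(x, y - 0.08) <= 0.28) & (np.hypot(x, y - 0.08) >= 0.2) \
            & (y > 0.12)
        fig = face & ~eyes & ~mouth
    return SourceImage(fig.astype(float))


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for synthetic subject tables.

    Defaults emulate a typical acuity-degradation experiment: 21 subjects
    tested best-corrected and under two plus-lens and two occlusion-foil
    levels; per-condition mean limiting spatial frequencies follow
    published medians; acuity is generated from the published per-type
    regression lines plus a subject-level random intercept and residual
    noise.
    """

    n_subjects: int = 21
    #: (degradation_type, degradation_level, mean limiting SF in cpd)
    conditions: tuple = (
        ("none", "BCVA", 5.1),
        ("plus_lens", "+1D", 3.7),
        ("plus_lens", "+2D", 2.9),
        ("occlusion_foil", "0.6", 3.8),
        ("occlusion_foil", "0.2", 3.3),
    )
    sf_sd: float = 0.45
    sf_floor_cpd: float = 0.5
    #: generating acuity lines per type (intercept logMAR, slope logMAR/cpd);
    #: best-corrected rows use the mean of the two lines
    coefficients: dict = field(default_factory=lambda: {
        "occlusion_foil": (1.1519, -0.2365),
        "plus_lens": (1.4563, -0.2940),
    })
    subject_sd: float = 0.12
    residual_sd: float = 0.15
    outlier_rate: float = 0.0
    outlier_shift_logmar: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        for v in (self.sf_sd, self.subject_sd, self.residual_sd):
            if v < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")


def simulate_subjects(cfg: SimulationConfig = SimulationConfig()) -> pd.DataFrame:
    """Draw a synthetic subject table with the canonical measurement schema.

    For each subject and condition the limiting SF is normal around the
    condition mean (truncated at ``sf_floor_cpd``) and

        VA = intercept(type) + slope(type)·SF + subject offset + noise.

    With ``outlier_rate`` > 0 a matching fraction of rows gets an added
    acuity shift, for exercising the Mahalanobis screen.  Identical seeds
    give identical tables.
    """
    rng = np.random.default_rng(cfg.seed)
    offsets = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
    rows = []
    for i in range(cfg.n_subjects):
        for dtype, level, mu_sf in cfg.conditions:
            sf = rng.normal(mu_sf, cfg.sf_sd)
            sf = max(sf, cfg.sf_floor_cpd)
            if dtype == "none":
                lines = list(cfg.coefficients.values())
                icept = float(np.mean([c[0] for c in lines]))
                slope = float(np.mean([c[1] for c in lines]))
            else:
                icept, slope = cfg.coefficients[dtype]
            va = icept + slope * sf + offsets[i] + rng.normal(0.0, cfg.residual_sd)
            if cfg.outlier_rate > 0 and rng.random() < cfg.outlier_rate:
                va += cfg.outlier_shift_logmar * rng.choice((-1.0, 1.0))
            rows.append({
                "subject_id": f"S{i + 1:02d}",
                "degradation_type": dtype,
                "degradation_level": level,
                "limiting_sf_cpd": float(sf),
                "va_logmar": float(va),
            })
    return pd.DataFrame(rows)
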