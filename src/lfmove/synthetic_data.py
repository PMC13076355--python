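"""Synthetic landscapes and telemetry datasets with known ground truth.

The simulator mirrors the structure the analyses assume: sit-and-wait
movement (habitat-dependent move/stay Bernoulli), gamma step lengths with
sex-specific means, and discrete-choice step selection in which candidate
steps are weighted by ``exp(beta . x)`` against the landscape's feature
covariates.  Because the choice rule is exactly the likelihood the SSF
fitter maximizes, the estimator is consistent and the ground-truth
parameters are recoverable — the basis of the recovery test suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import geometry
from .errors import ValidationError
from .geometry import Landscape
from .ssf import SsfFit
from .movement_models import ContextFit, HurdleFit

__all__ = [
    "SimConfig",
    "SimOutput",
    "make_landscape",
    "simulate_population",
    "truth_report",
    "write_truth",
]

#: 45 ha square side length in meters.
_SIDE = float(np.sqrt(45.0 * 10_000))


def _default_animal_years():
    # 7 + 7 animals, 12 male and 11 female annual paths (23 total).
    return {"M": (2, 2, 2, 2, 2, 1, 1), "F": (2, 2, 2, 2, 1, 1, 1)}


@dataclass
class SimConfig:
    """Ground-truth parameters for a simulated population."""

    animal_years: dict = field(default_factory=_default_animal_years)
    n_relocations: int = 85
    gamma_mean: dict = field(default_factory=lambda: {"F": 21.8, "M": 35.1})
    gamma_shape: float = 1.5
    move_prob: dict = field(
        default_factory=lambda: {"buffer": 0.37, "powerline": 0.67, "elsewhere": 0.5}
    )
    beta: dict = field(
        default_factory=lambda: {
            "road_cross": -1.7,
            "trail_cross": 0.6,
            "end_in_powerline": 0.6,
            "end_in_buffer": 0.9,
        }
    )
    n_candidates: int = 50
    width: float = _SIDE
    height: float = _SIDE
    road_halfwidth: float = 3.0
    buffer_distance: float = 5.0
    confine: bool = True
    start_box: tuple | None = None  # (xmin, ymin, xmax, ymax) restricting start points
    duplicate_readings: bool = False
    start_year: int = 2018
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_relocations < 2:
            problems.append("n_relocations must be >= 2")
        if self.n_candidates < 2:
            problems.append("n_candidates must be >= 2")
        if self.gamma_shape <= 0:
            problems.append("gamma_shape must be positive")
        for sex, m in self.gamma_mean.items():
            if m <= 0:
                problems.append(f"gamma_mean[{sex!r}] must be positive")
        for hab, p in self.move_prob.items():
            if not (0.0 < p < 1.0):
                problems.append(f"move_prob[{hab!r}] must lie in (0, 1)")
        if self.width <= 0 or self.height <= 0:
            problems.append("landscape dimensions must be positive")
        if set(self.animal_years) != {"M", "F"}:
            problems.append("animal_years must have entries for 'M' and 'F'")
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass
class SimOutput:
    landscape: Landscape
    fixes: pd.DataFrame
    truth: SimConfig


def make_landscape(config: SimConfig) -> Landscape:
    """Stylized landscape: through-road with buffered footprint, winding trail,
    and one powerline clear-cut strip, inside a rectangular study area."""
    config.validate()
    w, h = config.width, config.height
    study = box(0.0, 0.0, w, h)

    road_x = 0.22 * w
    road = np.array([[road_x, 0.0], [road_x, h]])
    road_poly = box(road_x - config.road_halfwidth, 0.0, road_x + config.road_halfwidth, h)
    road_buffer = geometry.buffer_polygon(road_poly, config.buffer_distance)

    tx = np.linspace(0.0, w, 25)
    ty = 0.62 * h + 0.08 * h * np.sin(2 * np.pi * tx / w * 2.5)
    trail = np.column_stack([tx, ty])

    pl_x = 0.68 * w
    powerline = box(pl_x - 15.0, 0.0, pl_x + 15.0, h)

    return Landscape(
        roads=[road],
        trails=[trail],
        powerline=[powerline],
        road_buffer=road_buffer,
        study_area=study,
        road_polygon=road_poly,
    )


def _habitat_of(point, landscape: Landscape) -> str:
    pt = np.asarray(point, dtype=float)[None]
    if geometry.points_in_polygon_mask(pt, landscape.road_buffer)[0]:
        return "buffer"
    if geometry.points_in_polygon_mask(pt, landscape.powerline_union)[0]:
        return "powerline"
    return "elsewhere"


def _simulate_path(rng, config: SimConfig, landscape: Landscape, sex: str) -> np.ndarray:
    scale = config.gamma_mean[sex] / config.gamma_shape
    bvec = np.array(
        [config.beta[k] for k in ("road_cross", "trail_cross", "end_in_powerline", "end_in_buffer")]
    )
    minx, miny, maxx, maxy = landscape.study_area.bounds
    if config.start_box is not None:
        bminx, bminy, bmaxx, bmaxy = config.start_box
        minx, miny = max(minx, bminx), max(miny, bminy)
        maxx, maxy = min(maxx, bmaxx), min(maxy, bmaxy)
    while True:
        cur = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if geometry.points_in_polygon_mask(cur[None], landscape.study_area)[0]:
            break
    prev_heading = None
    pts = [cur.copy()]
    nc = config.n_candidates
    for _ in range(config.n_relocations - 1):
        hab = _habitat_of(cur, landscape)
        if rng.random() >= config.move_prob[hab]:
            pts.append(cur.copy())
            continue
        chosen = None
        for _attempt in range(50):
            lengths = rng.gamma(config.gamma_shape, scale, nc)
            if prev_heading is None:
                bearings = rng.uniform(0.0, 2 * np.pi, nc)
            else:
                bearings = prev_heading + rng.uniform(-np.pi, np.pi, nc)
            ends = cur + np.column_stack([lengths * np.cos(bearings), lengths * np.sin(bearings)])
            segs = np.stack([np.broadcast_to(cur, (nc, 2)), ends], axis=1)
            x = np.column_stack(
                [
                    geometry.count_crossings_segments(segs, landscape.road_segments) > 0,
                    geometry.count_crossings_segments(segs, landscape.trail_segments) > 0,
                    geometry.points_in_polygon_mask(ends, landscape.powerline_union),
                    geometry.points_in_polygon_mask(ends, landscape.road_buffer),
                ]
            ).astype(float)
            w = np.exp(x @ bvec)
            if config.confine:
                w = w * geometry.points_in_polygon_mask(ends, landscape.study_area)
            if w.sum() > 0:
                idx = rng.choice(nc, p=w / w.sum())
                chosen = (ends[idx], bearings[idx])
                break
        if chosen is None:  # boxed in; remain in place
            pts.append(cur.copy())
            continue
        cur, prev_heading = chosen[0].copy(), float(chosen[1])
        pts.append(cur.copy())
    return np.array(pts)


def _jitter(rng, radius=0.5):
    r = radius * np.sqrt(rng.random())
    a = rng.uniform(0.0, 2 * np.pi)
    return np.array([r * np.cos(a), r * np.sin(a)])


def simulate_population(config: SimConfig) -> SimOutput:
    """Simulate telemetry fixes for a full population on a fresh landscape."""
    config.validate()
    landscape = make_landscape(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed)]))
    rows = []
    for sex in ("F", "M"):
        for i, n_years in enumerate(config.animal_years[sex], start=1):
            aid = f"{sex}{i:02d}"
            for year in range(config.start_year, config.start_year + n_years):
                path = _simulate_path(rng, config, landscape, sex)
                t0 = pd.Timestamp(year=year, month=4, day=1)
                for t, pt in enumerate(path):
                    ts = t0 + pd.Timedelta(days=t)
                    moved = t > 0 and not np.array_equal(pt, path[t - 1])
                    # the field protocol needs a confirming second reading for
                    # any relocation more than 1 m from the previous one —
                    # including the first fix of a new year's path
                    n_read = 2 if (moved or t == 0) else 1
                    for r in range(n_read):
                        obs = pt + _jitter(rng) if config.duplicate_readings else pt
                        rows.append((aid, sex, ts, obs[0], obs[1], r))
    fixes = pd.DataFrame(
        rows, columns=["animal_id", "sex", "timestamp", "x", "y", "reading_index"]
    )
    return SimOutput(landscape=landscape, fixes=fixes, truth=config)


def write_truth(config: SimConfig, path) -> None:
    """Write the ground-truth parameters as structured text (JSON)."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)


def _logit(p):
    return float(np.log(p / (1 - p)))


def truth_report(
    output: SimOutput,
    ssf_fit: SsfFit | None = None,
    hurdle_fit: HurdleFit | None = None,
    context_fits: dict | None = None,
) -> pd.DataFrame:
    """True vs. estimated parameters with 95%-CI coverage indicators.

    ``context_fits`` maps habitat name ('buffer' / 'powerline') to a
    :class:`ContextFit`; the implied truth is the log-odds difference between
    the habitat's move probability and the 'elsewhere' probability.
    """
    cfg = output.truth
    rows = []
    if ssf_fit is not None:
        for cov in ssf_fit.covariates:
            rows.append(
                {
                    "parameter": f"ssf.{cov}",
                    "truth": cfg.beta[cov],
                    "estimate": ssf_fit.beta[cov],
                    "ci_lower": ssf_fit.ci_lower[cov],
                    "ci_upper": ssf_fit.ci_upper[cov],
                }
            )
    if hurdle_fit is not None:
        for sex in ("F", "M"):
            est, lo, hi = hurdle_fit.mean_step[sex]
            rows.append(
                {
                    "parameter": f"hurdle.mean_step_{sex}",
                    "truth": cfg.gamma_mean[sex],
                    "estimate": est,
                    "ci_lower": lo,
                    "ci_upper": hi,
                }
            )
    if context_fits:
        for habitat, fit in context_fits.items():
            truth_beta = _logit(cfg.move_prob[habitat]) - _logit(cfg.move_prob["elsewhere"])
            rows.append(
                {
                    "parameter": f"context.{habitat}",
                    "truth": truth_beta,
                    "estimate": fit.beta,
                    "ci_lower": fit.ci_lower,
                    "ci_upper": fit.ci_upper,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["covered"] = (df["truth"] >= df["ci_lower"]) & (df["truth"] <= df["ci_upper"])
    return df
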