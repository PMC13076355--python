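"""Trajectory-randomization null models and the percentile crossing statistic.

Each observed annual path is replicated many times (default 1000) either by
rigid rotation about its starting location, or by translation to a random
start inside the study area followed by rotation.  Feature-interaction
counts of the observed path are then placed within the null distribution of
the randomized paths via a mid-rank percentile statistic, pooled by sex,
with leave-one-individual-out cross-validation to gauge individual
influence.

Randomized paths preserve the observed step-length sequence exactly (rigid
transforms), including stationary repeats, so occupancy tallies remain
comparable between observed and null paths.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry
from .errors import InvalidGeometryError, ValidationError
from .geometry import Landscape
from .trajectory import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "LoiocvResult",
    "NullResult",
    "NullScheme",
    "build_study_area",
    "loiocv",
    "percentile_statistic",
    "pooled_null_analysis",
    "random_angle_paths",
    "random_start_paths",
    "tally_features",
    "tally_features_batch",
]

FEATURES = ("road_cross", "trail_cross", "powerline_occupancy", "buffer_occupancy")

RANDOM_ANGLE = "random_angle"
RANDOM_START = "random_start_random_angle"


@dataclass
class NullScheme:
    """How to randomize trajectories: scheme kind, replicate count, master seed."""

    kind: str = RANDOM_ANGLE
    n_paths: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in (RANDOM_ANGLE, RANDOM_START):
            raise ValidationError(f"unknown null scheme kind {self.kind!r}")
        if self.n_paths < 1:
            raise ValidationError("n_paths must be >= 1")


@dataclass
class NullResult:
    feature: str
    sex: str
    observed: int
    null_counts: np.ndarray
    p_i: float


@dataclass
class LoiocvResult:
    feature: str
    sex: str
    p_i_by_left_out: dict = field(default_factory=dict)


def _traj_rng(scheme: NullScheme, traj: Trajectory) -> np.random.Generator:
    # Per-trajectory substream keyed by identity, so removing one individual
    # (LOIOCV) never perturbs the random paths of the others.
    key = zlib.crc32(f"{traj.animal_id}|{traj.year}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(scheme.seed), key]))


def random_angle_paths(traj: Trajectory, scheme: NullScheme) -> np.ndarray:
    """Rotations of the observed path about its first relocation.

    Returns an ``(n_paths, n_vertices, 2)`` array.  Every replicate keeps the
    observed start and the observed step-length sequence (rigid rotation),
    with an independent uniform rotation angle on [0, 2pi).
    """
    if scheme.kind != RANDOM_ANGLE:
        raise ValidationError(f"scheme kind is {scheme.kind!r}, expected {RANDOM_ANGLE!r}")
    rng = _traj_rng(scheme, traj)
    pts = traj.points()
    angles = rng.uniform(0.0, 2 * np.pi, scheme.n_paths)
    return geometry.rotate_paths(pts, angles, pts[0])


def sample_points_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a polygon via rejection sampling from its bounding box."""
    if poly.area <= 0:
        raise InvalidGeometryError("study area has zero area")
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(16, int((n - filled) * (maxx - minx) * (maxy - miny) / poly.area * 1.2))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = cand[geometry.points_in_polygon_mask(cand, poly)]
        take = min(len(inside), n - filled)
        out[filled : filled + take] = inside[:take]
        filled += take
    return out


def random_start_paths(traj: Trajectory, study_area, scheme: NullScheme) -> np.ndarray:
    """Copies of the observed path translated to random starts, then rotated.

    Starts are uniform over the study area; only the starting point is
    constrained to lie inside (the rest of each path may leave it).
    """
    if scheme.kind != RANDOM_START:
        raise ValidationError(f"scheme kind is {scheme.kind!r}, expected {RANDOM_START!r}")
    rng = _traj_rng(scheme, traj)
    pts = traj.points()
    starts = sample_points_in_polygon(study_area, scheme.n_paths, rng)
    angles = rng.uniform(0.0, 2 * np.pi, scheme.n_paths)
    rotated = geometry.rotate_paths(pts, angles, pts[0])
    return rotated + (starts - pts[0])[:, None, :]


def null_paths(traj: Trajectory, landscape: Landscape, scheme: NullScheme) -> np.ndarray:
    """Dispatch to the requested randomization scheme."""
    if scheme.kind == RANDOM_ANGLE:
        return random_angle_paths(traj, scheme)
    return random_start_paths(traj, landscape.study_area, scheme)


def tally_features_batch(paths: np.ndarray, landscape: Landscape) -> pd.DataFrame:
    """Feature-interaction tallies for a batch of equal-length paths.

    Crossings count transversal intersections with the road and trail line
    layers; occupancy counts path vertices (all relocations, stationary
    repeats included) inside the powerline and road-buffer polygons.
    """
    paths = np.asarray(paths, dtype=float)
    if paths.ndim == 2:
        paths = paths[None]
    k, n, _ = paths.shape
    flat = paths.reshape(-1, 2)
    power = geometry.points_in_polygon_mask(flat, landscape.powerline_union).reshape(k, n)
    buff = geometry.points_in_polygon_mask(flat, landscape.road_buffer).reshape(k, n)
    return pd.DataFrame(
        {
            "road_cross": geometry.count_crossings_segments(paths, landscape.road_segments),
            "trail_cross": geometry.count_crossings_segments(paths, landscape.trail_segments),
            "powerline_occupancy": power.sum(axis=1).astype(int),
            "buffer_occupancy": buff.sum(axis=1).astype(int),
        }
    )


def tally_features(path, landscape: Landscape) -> dict:
    """Tallies for a single path, as a feature -> count mapping."""
    df = tally_features_batch(np.asarray(path, dtype=float)[None], landscape)
    return {f: int(df[f].iloc[0]) for f in FEATURES}


def percentile_statistic(observed: float, null_counts) -> float:
    """Mid-rank percentile of the observed count within the null distribution.

    P = (#{null < observed} + 0.5 * #{null == observed}) / n.  Values below
    0.05 indicate avoidance, above 0.95 preference.
    """
    nulls = np.asarray(null_counts)
    if nulls.size == 0:
        raise ValidationError("empty null distribution")
    less = np.count_nonzero(nulls < observed)
    ties = np.count_nonzero(nulls == observed)
    return (less + 0.5 * ties) / nulls.size


def per_trajectory_tallies(trajs, landscape: Landscape, scheme: NullScheme) -> dict:
    """Observed tally and per-replicate null tallies for every trajectory.

    Returns a mapping ``(animal_id, year) -> (observed: Series, nulls:
    DataFrame of shape (n_paths, 4))``.  This is the cacheable unit shared by
    the pooled analysis and LOIOCV.
    """
    out = {}
    for traj in trajs:
        obs = tally_features_batch(traj.points()[None], landscape).iloc[0]
        nulls = tally_features_batch(null_paths(traj, landscape, scheme), landscape)
        out[(traj.animal_id, traj.year)] = (obs, nulls)
    return out


def _pool(trajs, tallies):
    obs = pd.Series(0, index=list(FEATURES), dtype=int)
    nulls = None
    for traj in trajs:
        o, nd = tallies[(traj.animal_id, traj.year)]
        obs = obs + o
        nulls = nd.copy() if nulls is None else nulls + nd
    return obs, nulls


def pooled_null_analysis(trajs, landscape: Landscape, scheme: NullScheme, tallies=None):
    """Sex-pooled null analysis: one :class:`NullResult` per sex and feature.

    Observed counts are summed over each sex's trajectories; the j-th pooled
    null count is the paired sum of each trajectory's j-th random path.
    """
    if tallies is None:
        tallies = per_trajectory_tallies(trajs, landscape, scheme)
    results = []
    for sex in sorted({t.sex for t in trajs}):
        sex_trajs = [t for t in trajs if t.sex == sex]
        obs, nulls = _pool(sex_trajs, tallies)
        for feature in FEATURES:
            nc = nulls[feature].to_numpy()
            results.append(
                NullResult(
                    feature=feature,
                    sex=sex,
                    observed=int(obs[feature]),
                    null_counts=nc,
                    p_i=percentile_statistic(int(obs[feature]), nc),
                )
            )
    return results


def loiocv(trajs, landscape: Landscape, scheme: NullScheme, tallies=None):
    """Leave-one-individual-out percentile statistics.

    For each sex with at least two individuals, recompute the pooled P value
    with each individual's trajectories removed.  Cached per-trajectory
    tallies are reused, so no re-randomization occurs.
    """
    if tallies is None:
        tallies = per_trajectory_tallies(trajs, landscape, scheme)
    results = {(f, s): LoiocvResult(f, s) for f in FEATURES for s in sorted({t.sex for t in trajs})}
    for sex in sorted({t.sex for t in trajs}):
        sex_trajs = [t for t in trajs if t.sex == sex]
        individuals = sorted({t.animal_id for t in sex_trajs})
        if len(individuals) < 2:
            log.warning("sex %s has a single individual; LOIOCV skipped", sex)
            for feature in FEATURES:
                del results[(feature, sex)]
            continue
        for left_out in individuals:
            kept = [t for t in sex_trajs if t.animal_id != left_out]
            obs, nulls = _pool(kept, tallies)
            for feature in FEATURES:
                p = percentile_statistic(int(obs[feature]), nulls[feature].to_numpy())
                results[(feature, sex)].p_i_by_left_out[left_out] = p
    return list(results.values())


def build_study_area(trajs, boundary):
    """Study area: union of the relocation MCP and the property boundary."""
    pts = np.concatenate([t.points() for t in trajs], axis=0)
    mcp = geometry.minimum_convex_polygon(pts)
    return geometry.union_polygons(mcp, boundary)


def results_table(results) -> pd.DataFrame:
    """Summary table: observed count, P value, and null quantiles."""
    rows = []
    for r in results:
        q = np.quantile(r.null_counts, [0.025, 0.5, 0.975])
        rows.append(
            {
                "sex": r.sex,
                "feature": r.feature,
                "observed": r.observed,
                "p_i": r.p_i,
                "null_q025": q[0],
                "null_median": q[1],
                "null_q975": q[2],
            }
        )
    return pd.DataFrame(rows)
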