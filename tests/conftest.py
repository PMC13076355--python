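import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from lfmove.geometry import Landscape, buffer_polygon
from lfmove.synthetic_data import SimConfig, simulate_population
from lfmove.trajectory import Trajectory, build_trajectories


@pytest.fixture(scope="session")
def toy_landscape():
    """Hand-constructed 100x100 m landscape with one road, trail, powerline."""
    road = np.array([[10.0, 0.0], [10.0, 100.0]])
    road_poly = box(8.0, 0.0, 12.0, 100.0)
    return Landscape(
        roads=[road],
        trails=[np.array([[0.0, 50.0], [100.0, 50.0]])],
        powerline=[box(60.0, 0.0, 80.0, 100.0)],
        road_buffer=buffer_polygon(road_poly, 5.0),
        study_area=box(0.0, 0.0, 100.0, 100.0),
        road_polygon=road_poly,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated population shared across tests (4 animal-years)."""
    cfg = SimConfig(
        animal_years={"M": (1, 1), "F": (1, 1)},
        n_relocations=60,
        n_candidates=20,
        seed=42,
    )
    sim = simulate_population(cfg)
    trajs = build_trajectories(sim.fixes)
    return sim, trajs


def make_trajectory(points, animal_id="A1", sex="F", year=2020, moved=None):
    """Build a Trajectory directly from coordinates (test helper)."""
    pts = np.asarray(points, dtype=float)
    if moved is None:
        moved = [False] + [
            not np.array_equal(pts[i], pts[i - 1]) for i in range(1, len(pts))
        ]
    reloc = pd.DataFrame(
        {
            "timestamp": pd.date_range("2020-05-01", periods=len(pts), freq="D"),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "moved": moved,
        }
    )
    return Trajectory(animal_id, sex, year, reloc)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
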