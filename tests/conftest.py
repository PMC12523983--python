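import numpy as np
import pytest

import phenotrack as pt


def run_pipeline(seed: int):
    """Simulate the two-class motility movie and produce labelled profiles."""
    movie, tracks, truth = pt.two_class_motility_fixture(seed)
    trajectories = pt.link_tracks_to_masks(tracks, movie)
    frame_table = pt.extract_frame_table(movie, trajectories)
    profiles = pt.build_profiles(trajectories, frame_table, truth=truth)
    return pt.profiles_to_frame(profiles)


@pytest.fixture(scope="session")
def motility_train():
    return run_pipeline(seed=1)


@pytest.fixture(scope="session")
def motility_test():
    return run_pipeline(seed=2)


@pytest.fixture(scope="session")
def small_simulation():
    """A compact two-class movie for plumbing tests (fast to extract)."""
    spec = pt.PopulationSpec(
        classes=[
            pt.ClassSpec(name="a", n_cells=4, mean_area=200, step_sd=1.0),
            pt.ClassSpec(name="b", n_cells=4, mean_area=200, step_sd=3.0),
        ],
        n_frames=16,
        height=160,
        width=160,
        seed=7,
    )
    return pt.simulate_population(spec)


@pytest.fixture()
def square_instance():
    mask = np.ones((10, 10), dtype=bool)
    return pt.CellInstance(
        mask=mask,
        intensity=np.zeros((10, 10)),
        offset=(0, 0),
        centroid=(4.5, 4.5),
        frame_index=0,
    )
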