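import numpy as np
import pytest

import flimclass as fc


@pytest.fixture(scope="session")
def axis() -> fc.TimeAxis:
    return fc.TimeAxis()


@pytest.fixture(scope="session")
def irf(axis) -> np.ndarray:
    return fc.make_irf(fc.DEFAULT_IRF, axis)


@pytest.fixture(scope="session")
def presets():
    return fc.class_presets()


@pytest.fixture(scope="session")
def small_cells(axis, irf):
    """Six simulated cells per metabolic class (Poisson noise, default axis)."""
    return fc.simulate_cell_dataset(6, axis, irf, rng=7)


@pytest.fixture(scope="session")
def small_field(axis, irf):
    """A 128x128 field with 10 non-overlapping labeled cells."""
    return fc.simulate_field(
        10,
        {"glycolysis": 4, "oxphos": 3, "glutaminolysis": 3},
        axis,
        irf,
        field_size=(128, 128),
        rng=5,
    )


def make_toy_cells(
    n_per_class: int = 20,
    shape=(10, 10, 32),
    taus=(4.0, 10.0),
    rate: float = 100.0,
    seed: int = 0,
):
    """Tiny two-class cells with distinct decay speeds (fast training)."""
    rng = np.random.default_rng(seed)
    t = np.arange(shape[2])
    cells = []
    cid = 1
    for label, tau in zip(("glycolysis", "oxphos"), taus):
        curve = rate * np.exp(-t / tau)
        for _ in range(n_per_class):
            lam = np.broadcast_to(curve, shape)
            counts = rng.poisson(lam)
            cells.append(
                fc.CellRecord(
                    counts=counts,
                    mask_crop=np.ones(shape[:2], bool),
                    time_axis=fc.TimeAxis(shape[2], 12.5),
                    phenotype=label,
                    cell_id=cid,
                )
            )
            cid += 1
    return cells
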