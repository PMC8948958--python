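import numpy as np
import pytest

import trichospec as ts


@pytest.fixture
def coarse_design():
    """Small, fast design: 5 classes, 2 trichomes x 4 points, coarse grid."""
    return ts.GeneratorDesign(
        trichomes_per_class=2,
        points_per_trichome=4,
        grid_low=200.0,
        grid_high=1000.0,
        grid_step=4.0,
        noise_sd=0.005,
        shift_sd=0.0,
        seed=11,
    )


@pytest.fixture
def two_class_design():
    """Two well-separated classes on a coarse grid (noise-free artifacts
    off) for discriminant-recovery tests."""
    return ts.GeneratorDesign(
        classes={"A": "Sativa", "B": "Indica"},
        trichomes_per_class=2,
        points_per_trichome=8,
        grid_low=200.0,
        grid_high=600.0,
        grid_step=2.0,
        baseline_coeffs_range=(0.0, 0.0),
        noise_sd=0.002,
        trichome_effect_sd=0.0,
        shift_sd=0.0,
        seed=7,
    )


@pytest.fixture
def two_class_dataset(two_class_design):
    effects = {
        "A": ts.ClassEffect.identity("A"),
        "B": ts.ClassEffect("B", {350.0: 1.8, 360.0: 1.8}),
    }
    return ts.generate_dataset(two_class_design, class_effects=effects)


@pytest.fixture
def separable_xy():
    """Raw matrix + labels with a strong planted 2-class difference."""
    rng = np.random.default_rng(5)
    n, p = 40, 25
    labels = ["pos"] * 20 + ["neg"] * 20
    direction = rng.normal(size=p)
    direction /= np.linalg.norm(direction)
    y_sign = np.array([1.0] * 20 + [-1.0] * 20)
    X = np.outer(y_sign, direction) * 3.0 + rng.normal(scale=0.2, size=(n, p))
    return X, labels, direction
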