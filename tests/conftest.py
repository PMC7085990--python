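import numpy as np
import pytest

from petkin.core import FrameSchedule, KineticParameters
from petkin.quantify import StudyMeta
from petkin.synth import LesionSpec, PhantomSpec, make_input_function


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.abdominal_45min()


@pytest.fixture(scope="session")
def cp():
    """Default synthetic arterial input function."""
    return make_input_function()


@pytest.fixture(scope="session")
def liver_params():
    """Liver-like kinetics: high delivery, low trapping, small reversible leak."""
    return KineticParameters(K1=0.37, k2=0.25, k3=0.0105634, k4=0.01, vb=0.12)


@pytest.fixture(scope="session")
def lesion_params():
    """Median lesion kinetics (Ki = 0.025 mL/cm^3/min)."""
    return KineticParameters(K1=0.2, k2=0.2, k3=0.0285714, vb=0.05)


def small_phantom_spec(noise_scale=0.0, seed=0, n_lesions=3):
    """A reduced phantom (32x32x16) for fast image-level tests."""
    kin = [(0.30, 0.25, 0.060), (0.20, 0.20, 0.025), (0.08, 0.30, 0.009)][:n_lesions]
    centers = [(35.0, 40.0, 26.0), (80.0, 40.0, 26.0), (35.0, 85.0, 26.0)]
    lesions = []
    for (K1, k2, ki), c in zip(kin, centers):
        k3 = ki * k2 / (K1 - ki)
        lesions.append(
            LesionSpec(c, 22.0, KineticParameters(K1=K1, k2=k2, k3=k3, vb=0.05))
        )
    return PhantomSpec(
        shape=(32, 32, 16),
        liver_box_mm=((10, 105), (15, 110), (5, 48)),
        aorta_center_mm=(115.0, 60.0),
        aorta_radius_mm=8.0,
        lesions=tuple(lesions),
        noise_scale=noise_scale,
        seed=seed,
        meta=StudyMeta(241e6, 70000.0),
    )


@pytest.fixture(scope="session")
def small_phantom():
    from petkin.synth import make_phantom

    return make_phantom(small_phantom_spec())
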