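import numpy as np
import pytest

from evpscope.simulate import MarkerModel, SceneParams, generate_scene, intensity_for_peak_snr


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bright_scene(seed: int = 0, density: float = 0.01, size: int = 400,
                 peak_snr: float = 20.0, gsd: float = 1.3,
                 category_probs=None) -> SceneParams:
    """A small, well-separated, bright mixture scene for fast unit tests."""
    base = SceneParams(field_size_px=(size, size), particle_density_per_um2=density,
                       seed=seed)
    median = intensity_for_peak_snr(peak_snr, base)
    kwargs = {}
    if category_probs is not None:
        kwargs["category_probs"] = category_probs
    return SceneParams(
        field_size_px=(size, size),
        particle_density_per_um2=density,
        coe_model=MarkerModel(median, gsd),
        cfse_model=MarkerModel(median, gsd),
        seed=seed,
        **kwargs,
    )


@pytest.fixture
def bright_field():
    params = bright_scene(seed=42)
    return generate_scene(params)
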