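import pytest

from semsgd import (
    GenConfig,
    build_spec,
    generate_instance,
    split,
    standardize,
    substream,
)


@pytest.fixture
def worked_two_equation_spec():
    """The classic worked two-equation system: y1 depends on y2 and
    x1, x2, x4; y2 depends on y1 and all four exogenous variables.
    Equation 0 is exactly identified, equation 1 underidentified."""
    return build_spec(
        m=2,
        k=4,
        endo_mask=[[False, True], [True, False]],
        exo_mask=[[True, True, False, True], [True, True, True, True]],
    )


@pytest.fixture
def small_instance():
    """A seeded identified m=2, k=4 system with its simulated data."""
    cfg = GenConfig(m=2, k=4, n=1000, sigma=0.1, seed=42)
    spec, params, data = generate_instance(cfg)
    return cfg, spec, params, data


@pytest.fixture
def standardized_split(small_instance):
    """70/30 split of the small instance, z-scored with train statistics."""
    cfg, spec, params, data = small_instance
    train, val = split(data, 0.7, rng=substream(cfg.seed, "split"))
    train_s, (val_s,), scaler = standardize(train, [val])
    return spec, train_s, val_s, scaler


def random_params(spec, rng, scale=1.0):
    """Free coefficients ~ Normal(0, scale^2) respecting the masks."""
    from semsgd import StructuralParams

    theta = scale * rng.standard_normal(spec.n_free())
    return StructuralParams.from_free_vector(spec, theta)
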