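import pytest

from immunoarray.synthetic_data import SyntheticConfig, simulate_study, with_planted


def small_config(**kwargs) -> SyntheticConfig:
    """A fast, down-scaled study: 60 antigens, full 9 vs 3 design."""
    defaults = dict(n_antigens=60, seed=11)
    defaults.update(kwargs)
    return SyntheticConfig(**defaults)


@pytest.fixture()
def noisy_study():
    """60-antigen study at default noise with 3 planted biomarkers."""
    cfg = with_planted(
        small_config(seed=5), n_planted=3, fold=5.0, penetrance=1.0
    )
    layout, samples, truth = simulate_study(cfg)
    return cfg, layout, samples, truth


@pytest.fixture()
def noise_free_study():
    """Exact study: no spot noise, float serialization, pure scale drift."""
    cfg = with_planted(
        small_config(
            spot_noise_cv=0.0,
            background_sd_rfu=0.0,
            sample_scale_range=(0.5, 2.0),
            round_intensities=False,
            seed=3,
        ),
        n_planted=2,
        fold=5.0,
        penetrance=1.0,
    )
    layout, samples, truth = simulate_study(cfg)
    return cfg, layout, samples, truth


def group_ids(samples):
    cases = [s.sample_id for s in samples if s.group == "case"]
    controls = [s.sample_id for s in samples if s.group == "control"]
    return cases, controls
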