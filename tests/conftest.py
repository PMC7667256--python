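import dataclasses

import pytest

from imrcea.cohorts import ArmProfile, default_profiles, generate_cohort


@pytest.fixture(scope="session")
def profiles() -> tuple[ArmProfile, ArmProfile]:
    return default_profiles()


@pytest.fixture(scope="session")
def conv_profile(profiles):
    return profiles[0]


@pytest.fixture(scope="session")
def imr_profile(profiles):
    return profiles[1]


@pytest.fixture(scope="session")
def small_cohorts(conv_profile, imr_profile):
    """Study-sized cohorts (146 / 50), fixed seeds."""
    return (
        generate_cohort(conv_profile, seed=11),
        generate_cohort(imr_profile, seed=12),
    )


@pytest.fixture(scope="session")
def big_cohorts(conv_profile, imr_profile):
    """n = 10,000 per arm for moment-recovery checks; generated once."""
    big_c = dataclasses.replace(conv_profile, n=10_000)
    big_i = dataclasses.replace(imr_profile, n=10_000)
    return generate_cohort(big_c, seed=21), generate_cohort(big_i, seed=22)


def degenerate_profile(**overrides) -> ArmProfile:
    """All-zero-variance, all-certain profile: every patient identical."""
    base = dict(
        arm="conventional",
        n=8,
        or_minutes=(300.0, 0.0),
        prob_pack=1.0,
        prob_navigation=0.0,
        prob_prosthesis=1.0,
        prob_device=0.0,
        prob_icu=0.0,
        icu_days_given_admitted=0.0,
        image_rates_pre={},
        image_rates_post={"MR-C": (2.0, 0.0)},
        los=(10.0, 0.0),
        pre_kps=(80.0, 0.0),
        post_kps=(90.0, 0.0),
        prob_gtr=1.0,
        prob_str=0.0,
        prob_complication=0.0,
        pfs_mean=200.0,
        pfs_sd=0.0,
        prob_os1y=1.0,
        prob_os2y=1.0,
        residual_cost=0.0,
        age=(50.0, 0.0),
        prob_female=0.0,
        prob_hgg=1.0,
        prob_reintervention=0.0,
    )
    base.update(overrides)
    return ArmProfile(**base)
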