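import numpy as np
import pytest

from avattn.session import SessionConfig, generate_session


@pytest.fixture(scope="session")
def small_config():
    """Compact session: fewer trials/units, no receptive-field drive, so the
    full pipeline runs in seconds."""
    return SessionConfig(
        n_unimodal_trials=12,
        n_av_trials=80,
        unit_counts={
            ("superficial", "BS"): 4,
            ("middle", "BS"): 3,
            ("deep", "BS"): 5,
            ("deep", "NS"): 2,
        },
        tuned_fraction=0.0,
        include_rds_drive=False,
        iti_range_s=(2.0, 5.0),
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    data, units = generate_session(small_config, seed=11)
    return data, units
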