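import numpy as np
import pytest

from norkit.synth import NORSpec, REGION_ORDER

# 1/10-scale region lengths used across the suite to keep runs fast
SCALED_LENGTHS = {
    "5'ETS": 366, "18S": 187, "ITS1": 108, "5.8S": 16,
    "ITS2": 117, "28S": 507, "3'ETS": 36, "IGS": 2970,
}


def scaled_spec(seed=0, n_units=2, rate_transcribed=7.5, rate_igs=15.0, **kw):
    rates = {r: rate_transcribed for r in REGION_ORDER}
    rates["IGS"] = rate_igs
    rates["5.8S"] = 0.0
    defaults = dict(
        pj_length=4000,
        dj_length=4000,
        n_units=n_units,
        region_lengths=dict(SCALED_LENGTHS),
        variant_rate=rates,
        planted_sites={"EcoRV": [1200, -1500], "ApaLI": [800, -2000]},
        enzyme_motifs={"EcoRV": "GATATC", "ApaLI": "GTGCAC"},
        seed=seed,
    )
    defaults.update(kw)
    return NORSpec(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
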