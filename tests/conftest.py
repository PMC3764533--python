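import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_msa():
    from rrnalvr.io import Msa

    return Msa.from_pairs(
        [
            ("s1", "GGGAA--ACCC"),
            ("s2", "GGGAAUUACCC"),
            ("s3", "GGGA---ACCC"),
        ]
    )
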