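from __future__ import annotations

import pytest

from dna_monitor import RoutineSpec, simulate_days

TINY_LOG = """\
2016-12-23 19:35:00.000000 M003 ON Sleep begin
2016-12-23 19:35:02 D001 OPEN
2016-12-23 19:40:00.000000 D001 CLOSE
2016-12-24 03:35:00.000000 M003 OFF Sleep end
2016-12-24 08:00:00.000000 M005 ON Cook_Breakfast begin
2016-12-24 08:30:00.000000 M005 OFF Cook_Breakfast end
"""


@pytest.fixture
def tiny_log(tmp_path):
    path = tmp_path / "tiny.log"
    path.write_text(TINY_LOG)
    return path


@pytest.fixture(scope="session")
def zero_noise_spec() -> RoutineSpec:
    """A resident with a perfectly repeatable routine: no day-to-day noise."""
    return RoutineSpec(
        activity_cv=0.0,
        onset_sd_h=0.0,
        duration_sd_s=0.0,
        interruption_rate=0.0,
    )


@pytest.fixture(scope="session")
def zero_noise_home(zero_noise_spec):
    return simulate_days(zero_noise_spec, 30, seed=7)
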