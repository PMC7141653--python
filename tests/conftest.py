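import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def standins():
    """Synthetic species stand-in datasets, one fixed seed per species."""
    from rhythmkit import SPECIES_PROFILES, species_standin

    return {sp: species_standin(sp, seed=2026) for sp in SPECIES_PROFILES}


@pytest.fixture()
def label_file(tmp_path):
    def make(rows, name="seq01.txt", header=None):
        lines = [] if header is None else [header]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    return make
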