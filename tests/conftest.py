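import numpy as np
import pytest

from cbescan import synthetic
from cbescan.variant_profile import ContextWindow


def make_window(seq: str, label: str | None = None, center: int | None = None) -> ContextWindow:
    """Build a ContextWindow with the site at `center` (default middle)."""
    off = len(seq) // 2 if center is None else center
    return ContextWindow(
        sequence=seq,
        site_offset=off,
        upstream_len=off,
        downstream_len=len(seq) - off - 1,
        label=label,
    )


def int_to_seq(i: int, length: int = 9) -> str:
    """Deterministic unique DNA string for integer i (base-4 encoding)."""
    bases = "ACGT"
    out = []
    for _ in range(length):
        out.append(bases[i % 4])
        i //= 4
    return "".join(out)


@pytest.fixture(scope="session")
def study():
    """One synthetic study shared across tests (3 editor + 3 control samples)."""
    return synthetic.simulate_study(
        synthetic.SimulationConfig(seed=11), n_cbe_samples=3, n_control_samples=3
    )


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    synthetic.write_study(study, out)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
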