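import pytest
from hypothesis import settings

from genochron.simgen import SimConfig, simulate_te_history

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def te_annotation_file(tmp_path):
    """Write a simulated repeat-annotation file; returns (path, history)."""

    def _make(cfg: SimConfig):
        history = simulate_te_history(cfg)
        path = tmp_path / "repeats.out"
        path.write_text(history.annotation_text())
        return path, history

    return _make
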