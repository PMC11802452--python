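import warnings

import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "ci",
        derandomize=True,
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(autouse=True)
def _quiet_subvoxel_warnings():
    """Sub-voxel planted puncta warn by design; keep test output readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*below the voxel size.*", category=UserWarning
        )
        yield
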