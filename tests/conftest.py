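from pathlib import Path

import pytest

from mrmgen import FragmentTrace

DATA_DIR = Path(__file__).parent / "data"

CE_GRID = [0.0, 10.0, 20.0, 40.0]


def make_trace(mz: float, profile: dict[float, float]) -> FragmentTrace:
    """Trace with identical member m/z at every CE (no jitter)."""
    return FragmentTrace(
        representative_mz=mz,
        intensities=dict(profile),
        member_mzs={ce: mz for ce in profile},
    )


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def ce_grid() -> list[float]:
    return list(CE_GRID)
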