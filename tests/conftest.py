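import sys
from pathlib import Path

import pandas as pd
import pytest

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "scripts"))  # day-grid oracle lives there

from pdckit import ClassMap, StudyWindow, worked_fixture  # noqa: E402
from pdckit.records import load_dispensing, load_participants  # noqa: E402

DATA = Path(__file__).resolve().parent / "data"


@pytest.fixture(scope="session")
def class_map() -> ClassMap:
    return ClassMap()


@pytest.fixture(scope="session")
def window() -> StudyWindow:
    return StudyWindow()


@pytest.fixture(scope="session")
def fixture_tables(tmp_path_factory, class_map):
    """Worked fixture written to CSV and loaded back through the IO layer."""
    participants, dispensing = worked_fixture()
    d = tmp_path_factory.mktemp("fixture")
    participants.to_csv(d / "participants.csv", index=False)
    dispensing.to_csv(d / "dispensing.csv", index=False)
    parts = load_participants(d / "participants.csv")
    resolved, report = load_dispensing(d / "dispensing.csv", class_map)
    return parts, resolved, report


def write_csv(tmp_path: Path, name: str, df: pd.DataFrame) -> Path:
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path
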