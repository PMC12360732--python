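from datetime import date, datetime, timezone

import pytest

from phenorisk.io import KeystrokeEvent, LocationFix, MessageLine


def ts(day: int, hour: int = 12, minute: int = 0, second: int = 0) -> int:
    """Epoch ms for a UTC time on day N of January 2023."""
    return int(
        datetime(2023, 1, day, hour, minute, second, tzinfo=timezone.utc).timestamp() * 1000
    )


@pytest.fixture
def make_line():
    def _make(text: str, day: int = 1, pid: str = "P0", package: str = "com.whatsapp"):
        return MessageLine(pid, date(2023, 1, day), package, text)

    return _make


@pytest.fixture
def make_event():
    def _make(text: str, t: int, pid: str = "P0", package: str = "com.whatsapp", url=None):
        return KeystrokeEvent(pid, t, package, text, url)

    return _make


@pytest.fixture
def make_fix():
    def _make(t: int, lat: float, lon: float, pid: str = "P0"):
        return LocationFix(pid, t, lat, lon)

    return _make
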