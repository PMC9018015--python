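import numpy as np
import pytest

from lumipulse import AcquisitionConfig, PulseTrain, SensorSpec

TOY_LOG = (
    "# lumipulse-log v1\n"
    "# device_id: SIM\n"
    "# n_wells: 2\n"
    "# integration_window_ms: 300000\n"
    "# session_start: 0\n"
    "# wells: A,B\n"
    "0,0,6,0\n"
    "1,300000,7,1\n"
    "2,600000,6,0\n"
)


@pytest.fixture
def toy_log_text() -> str:
    """A hand-built 3-window, 2-well canonical serial log."""
    return TOY_LOG


@pytest.fixture
def dark_sensor() -> SensorSpec:
    """Sensor with the measured in-dish noise floor (0.02 Hz)."""
    return SensorSpec(dark_frequency=0.02)


def make_train(events, well_id="A", duration=10.0) -> PulseTrain:
    return PulseTrain(well_id=well_id, events=np.asarray(events, float), total_duration=duration)


def replay_counts(trains, config: AcquisitionConfig):
    """Independent brute-force event-by-event replay of the MCU counter.

    Deliberately written as a plain python loop over a merged, sorted list of
    (time, well) pairs so it shares no code with the vectorised path.
    """
    merged = sorted(
        ((float(t), w) for w, tr in enumerate(trains) for t in tr.events),
        key=lambda p: (p[0], p[1]),
    )
    n_win = config.n_windows
    out = [[0] * n_win for _ in trains]
    last = None
    for t, w in merged:
        if last is None or t - last >= config.interrupt_dead_time:
            last = t
            k = int(t // config.integration_window)
            if k < n_win:
                out[w][k] += 1
    return out
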