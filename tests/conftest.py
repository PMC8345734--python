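from datetime import datetime, timedelta

import pytest

from radonrisk.dose_model import DoseModelConfig, default_config
from radonrisk.exposure_timeseries import (
    OccupancySchedule,
    RadonReading,
    RadonSeries,
)


@pytest.fixture
def config() -> DoseModelConfig:
    return default_config()


@pytest.fixture
def monday() -> datetime:
    return datetime(2021, 1, 4)  # a Monday


def make_series(values, start, step=timedelta(hours=1), flags=None, cid="test"):
    """Regularly sampled series from a list of concentrations."""
    flags = flags or ["ok"] * len(values)
    return RadonSeries(
        tuple(
            RadonReading(start + i * step, v, f)
            for i, (v, f) in enumerate(zip(values, flags))
        ),
        cid,
    )


def office_schedule(days=("Mon", "Tue", "Wed", "Thu", "Fri"), start="09:00", end="17:00"):
    return OccupancySchedule.from_dict(
        {"weekly": [{"day": d, "start": start, "end": end} for d in days]}
    )


def brute_force_masked_mean(series, mask, t0, t1, step_s=60):
    """Independent oracle: discretize [t0, t1) into step_s buckets, evaluate
    the left-hold series and mask membership per bucket, average.

    Returns (mean, observed_steps/masked_steps) or (None, None) when no
    bucket is both masked and observed.
    """
    segments = series.segments()
    total = 0.0
    observed = 0
    masked = 0
    t = t0
    dt = timedelta(seconds=step_s)
    while t < t1:
        in_mask = any(s <= t < e for s, e in mask)
        if in_mask:
            masked += 1
            for seg_s, seg_e, val in segments:
                if seg_s <= t < seg_e:
                    total += val
                    observed += 1
                    break
        t += dt
    if observed == 0:
        return None, None
    return total / observed, observed / masked
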