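"""Shared fixtures: seeded RNGs and small synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

from dyadsync.rsa import EstimatorConfig
from dyadsync.types import CodedStream, IBISeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def estimator_config():
    return EstimatorConfig()


def make_sine_ibi(
    freq_hz: float = 0.25,
    amp_ms: float = 40.0,
    base_ms: float = 800.0,
    task_s: float = 300.0,
    person_id: str = "p",
) -> IBISeries:
    """Deterministic sinusoidally modulated IBI series emitted beat by beat.

    Beats are emitted implicitly (t_i = t_{i-1} + ibi(t_i)/1000, solved by
    fixed-point iteration) so that the interval recorded at beat time t
    equals the analytic modulation evaluated at t exactly.
    """
    t = 0.0
    times, intervals = [], []

    def ibi_at(x):
        return base_ms + amp_ms * np.sin(2 * np.pi * freq_hz * x)

    while t < task_s:
        t_next = t + ibi_at(t) / 1000.0
        for _ in range(8):
            t_next = t + ibi_at(t_next) / 1000.0
        intervals.append(ibi_at(t_next))
        times.append(t_next)
        t = t_next
    return IBISeries(person_id, np.array(times), np.array(intervals))


def affect_stream(codes, role="parent", person_id=None) -> CodedStream:
    return CodedStream(
        person_id=person_id or f"{role}_affect",
        role=role,
        stream_kind="affect",
        codes=np.array(codes, dtype=object),
    )


def ersb_stream(codes, person_id="parent_ersb") -> CodedStream:
    return CodedStream(
        person_id=person_id, role="parent", stream_kind="ersb",
        codes=np.array(codes, dtype=object),
    )


@pytest.fixture
def sine_ibi():
    return make_sine_ibi()
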