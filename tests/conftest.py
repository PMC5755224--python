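from __future__ import annotations

import numpy as np
import pytest

from recurtrial import (
    EventHistory,
    StudyConfig,
    SubjectDesign,
    get_scenario,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def dataset_1a():
    """One simulated replicate of the constant-hazard scenario (n=200)."""
    return simulate_dataset(get_scenario("1a"), StudyConfig(seed=42), replicate=0)


@pytest.fixture(scope="session")
def dataset_3a():
    """One replicate under rising total-time baselines (more repeat events)."""
    return simulate_dataset(get_scenario("3a"), StudyConfig(seed=43), replicate=0)


def make_pairs(spec):
    """Build (design, history) pairs from compact tuples.

    ``spec`` is a list of (subject_id, group, [event times], terminal,
    end_time) with event types all non-fatal unless terminal is "death",
    in which case the last event is the death.
    """
    pairs = []
    for sid, group, times, terminal, end in spec:
        types = ["MI"] * len(times)
        if terminal == "death" and times:
            types[-1] = "D"
        pairs.append(
            (
                SubjectDesign(subject_id=sid, group=group, entry_time=0.0,
                              censor_time=max(end, 1e-9)),
                EventHistory(subject_id=sid, event_times=list(times),
                             event_types=types, terminal=terminal,
                             end_time=end),
            )
        )
    return pairs


@pytest.fixture
def toy_pairs():
    """Six hand-written subjects covering deaths, repeats and censoring."""
    return make_pairs(
        [
            (0, 1, [1.0, 2.5], "death", 2.5),
            (1, 0, [0.5, 1.5, 2.2], "administrative", 2.8),
            (2, 1, [], "administrative", 2.0),
            (3, 0, [1.2], "administrative", 2.6),
            (4, 1, [0.8], "death", 0.8),
            (5, 0, [1.9], "death", 1.9),
        ]
    )


def random_small_pairs(rng: np.random.Generator, max_subjects: int = 8):
    """Random tiny datasets for oracle comparisons (both groups present)."""
    n = int(rng.integers(3, max_subjects + 1))
    spec = []
    groups = [0, 1] + [int(rng.integers(0, 2)) for _ in range(n - 2)]
    for sid in range(n):
        end = float(rng.uniform(0.5, 3.0))
        n_ev = int(rng.integers(0, 4))
        times = sorted(float(t) for t in rng.uniform(0.01, end, size=n_ev))
        died = bool(rng.random() < 0.3) and n_ev > 0
        if died:
            end = times[-1]
        spec.append((sid, groups[sid], times,
                     "death" if died else "administrative", end))
    return make_pairs(spec)
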