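"""Deterministic random-stream management.

Every stochastic component of the generator draws from a named substream of
the dataset seed.  A substream draws arrays in patient-major order, so the
first ``n`` patients of a dataset are byte-identical regardless of how many
further patients are generated with the same seed: appending patients only
appends draws to each stream.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: stream identity must never depend on dict ordering.
_STREAMS = (
    "diagnosis", "age", "violation", "confounders", "demographics",
    "pcp_visits", "initiation", "adt", "first_fill", "fill_delays",
    "diabetes_onset", "contra_onset", "contra_code", "discontinuation",
    "noninit_start", "death", "death_offset", "cause", "ltfu",
    "ltfu_offset", "baseline_event_days", "early_death",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    The child is keyed by ``(seed, index-of-name)`` so the mapping is stable
    across sessions and platforms.
    """
    try:
        idx = _STREAMS.index(name)
    except ValueError:
        raise KeyError(f"unknown stream name: {name!r}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), idx]))


def spawn_seed(seed: int, k: int) -> int:
    """Derive the k-th integer child seed of ``seed`` (always < 2**31)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10_000 + int(k)]))
    return int(rng.integers(0, 2**31 - 1))
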