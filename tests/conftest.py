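"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from germdiv import default_config, default_schema, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def cohort151():
    """Default-sized synthetic cohort (n=151, all 37 traits), fixed seed."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def cohort151_blocks():
    """Same size with the block-correlation preset, for structure-sensitive stages."""
    return generate_cohort(default_config(seed=42, correlation="blocks"))


def brute_force_ward(X: np.ndarray) -> list[tuple[frozenset, float]]:
    """Exhaustive Ward agglomeration recomputing every candidate dSS from raw
    points at every step.  Returns the merge schedule as (member set, dSS).

    Independent of the package: no Lance-Williams update, no scipy.
    """
    X = np.asarray(X, dtype=float)
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    next_id = len(X)
    schedule = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma, mb = clusters[a], clusters[b]
            ca, cb = X[ma].mean(axis=0), X[mb].mean(axis=0)
            dss = len(ma) * len(mb) / (len(ma) + len(mb)) * float(((ca - cb) ** 2).sum())
            if best is None or dss < best[0]:
                best = (dss, a, b)
        dss, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = merged
        schedule.append((frozenset(merged), dss))
        next_id += 1
    return schedule


def merge_member_sets(tree) -> list[tuple[frozenset, float]]:
    """MergeTree schedule as (member set, height) for comparison with the oracle."""
    members = {i: frozenset([i]) for i in range(tree.n_leaves)}
    out = []
    for i, m in enumerate(tree.merges):
        s = members[m.left] | members[m.right]
        members[tree.n_leaves + i] = s
        out.append((s, m.height))
    return out


@pytest.fixture(scope="session")
def ward_oracle():
    return brute_force_ward


@pytest.fixture(scope="session")
def tree_member_sets():
    return merge_member_sets
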