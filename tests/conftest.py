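"""Shared fixtures: one fully processed default synthetic sample per session.

The heavy objects (10k-cell sample, fitted phase model, solved ordering LP)
are session-scoped so the acceptance-style tests can share them instead of
re-fitting per test.
"""

import numpy as np
import pytest

import cytocycle as cc


@pytest.fixture(scope="session")
def default_sample():
    return cc.generate(cc.GeneratorConfig(n_cells=10_000, seed=1))


@pytest.fixture(scope="session")
def processed(default_sample):
    """Default sample carried through volume correction and classification."""
    s = default_sample
    transformed, report = cc.volume_pipeline(s.matrix, s.channel_map)
    standardized, stats = cc.standardize(transformed, s.channel_map)
    X = standardized.values[
        :, standardized.column_index(s.channel_map.cellcycle_in_order)
    ]
    model = cc.fit_phase_model(
        X, s.truth["phase"].to_numpy(), seed=0, standardization=stats
    )
    assignment = cc.assign_phases(model, X, standardized.cell_ids)
    return {
        "sample": s,
        "transformed": transformed,
        "standardized": standardized,
        "X": X,
        "model": model,
        "assignment": assignment,
        "volume_report": report,
    }


@pytest.fixture(scope="session")
def trajectory(processed):
    """Pseudotime from a 10% stratified LP subsample (seed fixed)."""
    weights = cc.solve_ordering_lp(
        processed["X"], processed["assignment"], subsample_fraction=0.1, seed=11
    )
    return cc.embed(weights, processed["X"], processed["standardized"].cell_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
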