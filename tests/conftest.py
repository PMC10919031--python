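from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest

from cbskit import (
    AWDAL_MARGINALS,
    TOGDHEER_MARGINALS,
    SimConfig,
    fixture_from_marginals,
    simulate_programme,
)
from cbskit.config import default_dialect

UTC = timezone.utc


@pytest.fixture(scope="session")
def awdal_ledger():
    return fixture_from_marginals(AWDAL_MARGINALS)


@pytest.fixture(scope="session")
def togdheer_ledger():
    return fixture_from_marginals(TOGDHEER_MARGINALS)


@pytest.fixture(scope="session")
def dialect():
    return default_dialect()


def small_sim_config(seed: int, **overrides) -> SimConfig:
    """A fast programme (10 villages, 13 weeks) for property tests."""
    base = dict(
        n_villages=10,
        volunteers_per_village=2,
        period_start=datetime(2021, 1, 4, tzinfo=UTC),
        period_end=datetime(2021, 4, 4, 23, 59, tzinfo=UTC),
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture()
def random_ledgers():
    """A factory yielding varied small synthetic ledgers."""
    def make(n: int, seed: int = 20210):
        out = []
        for i in range(n):
            cfg = small_sim_config(
                seed=seed + i,
                dismissal_prob=0.1 + 0.4 * ((i * 7) % 10) / 10,
                documented_prob=((i * 3) % 11) / 10,
            )
            out.append(simulate_programme(cfg))
        return out
    return make
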