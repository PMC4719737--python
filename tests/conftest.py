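import numpy as np
import pytest

import mapalign as ma


@pytest.fixture(scope="session")
def params():
    return ma.AlignParams()


@pytest.fixture(scope="session")
def sigma_model():
    return ma.SigmaModel()


@pytest.fixture(scope="session")
def small_reference(sigma_model):
    """Synthetic reference used across pipeline tests.

    Large enough (600 fragments) that each map's feasible-candidate
    population supports the population-based significance model.
    """
    return ma.synth_reference(600, 12000, seed=20240101, sigma_model=sigma_model)


@pytest.fixture(scope="session")
def small_index(small_reference):
    return ma.SeedIndex([small_reference])


def random_instance(rng, params, sigma_model, m_max=6, n_max=12):
    """A small random extension instance for oracle comparisons.

    The query is drawn from a sub-region of the reference with mild
    perturbations (sizing noise, occasional merges) so that a reasonable
    fraction of instances has feasible extensions; the anchor is a plain
    2-mer placed somewhere inside the query.
    """
    from mapalign.dp_align import anchor_matches
    from mapalign.seed_index import PLAIN, Q_PLAIN, SeedHit

    n = int(rng.integers(6, n_max + 1))
    frags = np.maximum(150.0, rng.exponential(9000.0, n))
    # sprinkle small fragments to exercise the skip rule
    for j in range(n):
        if rng.random() < 0.25:
            frags[j] = rng.uniform(200.0, 2500.0)
    ref = ma.ReferenceMap.from_fragments("toy", frags, sigma_model)

    m = int(rng.integers(3, min(m_max, n - 1) + 1))
    start = int(rng.integers(0, n - m))
    q = frags[start : start + m].copy()
    q *= 1.0 + rng.normal(0.0, 0.04, m)
    if rng.random() < 0.4 and m >= 4:  # merge two query fragments (missing cut)
        j = int(rng.integers(0, m - 1))
        q = np.concatenate([q[:j], [q[j] + q[j + 1]], q[j + 2 :]])
        m -= 1
    o = ma.ExperimentalMap("toyq", np.maximum(q, 50.0))

    i = int(rng.integers(1, m))  # anchor query position (needs i+1 <= m)
    j = min(start + i, ref.n - 1)
    hit = SeedHit(ref, "forward", j, i, PLAIN, Q_PLAIN)
    anchor = anchor_matches(o, hit)
    return o, ref, hit, anchor
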