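import numpy as np
import pandas as pd
import pytest

from mbtraj.core import OtuTable, to_fractional
from mbtraj.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 3 regimes each, 21 samples, moderate depth."""
    spec = CohortSpec(
        n_subjects=3,
        n_otus=80,
        regimes_per_subject=(3, 3, 3),
        day_grid=tuple(range(-10, 300, 15)),
        depth_range=(3000, 6000),
        dirichlet_concentration=500,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_fractional(small_cohort):
    return to_fractional(small_cohort.table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def rearrangement_profiles(seed, n_states=6, inject_final=None):
    """Two subjects on disjoint supports; each subject's state sequence is a
    chain of gentle abundance rearrangements (6 taxa scaled by lognormal
    factors per step). ``inject_final=f`` replaces subject X's last state by
    a (1-f)/f mixture with subject Y's baseline."""
    r = np.random.default_rng(seed)
    n = 120
    base_x = np.zeros(n)
    base_x[:60] = r.dirichlet(np.ones(60) * 0.5)
    base_y = np.zeros(n)
    base_y[60:] = r.dirichlet(np.ones(60) * 0.5)

    def rearrange(p):
        q = p.copy()
        idx = r.choice(np.flatnonzero(p > 0), size=6, replace=False)
        q[idx] = q[idx] * np.exp(r.normal(0, 0.5, size=6))
        return q / q.sum()

    profs = {}
    for name, base in (("X", base_x), ("Y", base_y)):
        rows = [base]
        for _ in range(n_states - 1):
            rows.append(rearrange(rows[-1]))
        profs[name] = pd.DataFrame(rows, index=range(1, n_states + 1))
    if inject_final is not None:
        f = inject_final
        profs["X"].loc[n_states] = ((1 - f) * profs["X"].loc[n_states]
                                    + f * base_y)
    return profs


def random_otu_table(rng, n_samples=4, n_otus=6, max_count=50) -> OtuTable:
    counts = rng.integers(0, max_count, size=(n_samples, n_otus))
    counts[:, 0] += 1  # ensure positive sample totals
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"OTU_{j}" for j in range(n_otus)],
    ))
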