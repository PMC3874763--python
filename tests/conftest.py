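import numpy as np
import pandas as pd
import pytest

from metcorrnet.metnet import MetabolicNetwork, Reaction, Species
from metcorrnet.profiles import ProfileMatrix


def make_profile(values, condition, cohort=None, is_qc=None, samples=None, mets=None):
    """Small helper to build a ProfileMatrix from plain lists."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    mets = mets or [f"m{j}" for j in range(m)]
    idx = pd.Index(samples)
    return ProfileMatrix(
        values=pd.DataFrame(values, index=idx, columns=mets),
        condition=pd.Series(condition, index=idx),
        cohort=pd.Series(cohort if cohort is not None else ["c"] * n, index=idx),
        is_qc=pd.Series(is_qc if is_qc is not None else [False] * n, index=idx),
    )


@pytest.fixture
def two_step_network():
    """A+B→C; C→D — the canonical hand toy for connectivity and paths."""
    return MetabolicNetwork(
        species=[Species("A"), Species("B"), Species("C"), Species("D")],
        reactions=[
            Reaction("r1", consumed=(("A", 1.0), ("B", 1.0)), produced=(("C", 1.0),)),
            Reaction("r2", consumed=(("C", 1.0),), produced=(("D", 2.0),)),
        ],
    )


def brute_force_pearson(x, y):
    """Direct evaluation of the product-moment formula, plain Python.

    Independent oracle: sums of cross-products over sums of squared
    deviations, no numpy/scipy correlation code shared with the package.
    """
    pairs = [(a, b) for a, b in zip(x, y) if not (a != a or b != b)]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    num = sum((a - mx) * (b - my) for a, b in pairs)
    den = (
        sum((a - mx) ** 2 for a, _ in pairs) * sum((b - my) ** 2 for _, b in pairs)
    ) ** 0.5
    return num / den
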