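import numpy as np
import pytest

from aacontext import GeneratorConfig, ProteinRecord


@pytest.fixture
def records_small():
    return [
        ProteinRecord("p1", "ACDEFGHIKL"),
        ProteinRecord("p2", "LMNPQRSTVW"),
    ]


@pytest.fixture
def uniform_background():
    return np.full(20, 0.05)


@pytest.fixture
def iid_config():
    return GeneratorConfig(n_sequences=50, length_min=60, length_max=120, rng_seed=7)


def kl_oracle(counts, background, dps=50):
    """Term-by-term Eq.-style oracle at ``dps`` decimal digits.

    Exact rational P(a), high-precision logs; independent of the
    vectorized implementation under test.
    """
    import mpmath

    with mpmath.workdps(dps):
        total_count = int(sum(counts))
        comps = []
        for c, q in zip(counts, background):
            if c == 0:
                comps.append(mpmath.mpf(0))
                continue
            p = mpmath.mpf(int(c)) / total_count
            q = mpmath.mpf(q)
            comps.append(p * mpmath.log(p / q) / mpmath.log(2))
        return float(mpmath.fsum(comps)), [float(c) for c in comps]
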