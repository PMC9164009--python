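import numpy as np
import pytest

from mrforge.summary_io import HarmonizedInstrument
from mrforge.synthetic import table1_fixture


@pytest.fixture(scope="session")
def table1():
    """Exposure/outcome records for the conservative 4-SNP CRP instrument set."""
    return table1_fixture()


@pytest.fixture(scope="session")
def conservative_instruments(table1):
    """The 4 conservative instruments, harmonized."""
    from mrforge.summary_io import harmonize

    exposure, outcome = table1
    return harmonize(exposure, outcome).instruments


def make_instruments(bx, by, sy, sx=None, prefix="snp"):
    """Build HarmonizedInstrument objects from plain effect arrays."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sx = np.full_like(bx, 0.01, dtype=float) if sx is None else np.asarray(sx)
    return [
        HarmonizedInstrument(
            variant_id=f"{prefix}{j}",
            beta_exp=float(bx[j]), se_exp=float(sx[j]),
            beta_out=float(by[j]), se_out=float(sy[j]),
        )
        for j in range(len(bx))
    ]


@pytest.fixture
def random_instruments():
    """Factory for random harmonized instrument sets with strong exposures."""

    def _make(n, seed, theta=0.3):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
        sx = rng.uniform(0.005, 0.02, n)
        sy = rng.uniform(0.01, 0.05, n)
        by = rng.normal(theta * bx, sy)
        return make_instruments(bx, by, sy, sx)

    return _make
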