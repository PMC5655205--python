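import numpy as np
import pytest

from dbncs.simulate import AR_COEFF


def ar1_series(rng: np.random.Generator, n: int, burn: int = 20) -> np.ndarray:
    """Stationary AR(1) root-style series of length n (after burn-in)."""
    total = n + burn
    x = np.zeros(total)
    innov = rng.standard_normal(total) * np.sqrt(1.0 - AR_COEFF**2)
    for t in range(total):
        x[t] = AR_COEFF * (x[t - 1] if t else 0.0) + innov[t]
    return x[burn:]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_grn_files(tmp_path):
    """A tiny on-disk expression table + gold standard for I/O and CLI tests."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "gene\tt0\tt1\tt2\tt3\tt4\tt5\n"
        "G1\t0.1\t0.5\t0.9\t0.4\t0.2\t0.8\n"
        "G2\t1.0\t0.2\t0.4\t0.9\t0.3\t0.5\n"
        "G3\t0.3\t0.8\t0.2\t0.6\t0.7\t0.1\n"
    )
    gold = tmp_path / "gold.tsv"
    gold.write_text("G1\tG2\t1\nG1\tG3\t1\nG2\tG3\t0\n")
    return expr, gold
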