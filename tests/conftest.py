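import numpy as np
import pandas as pd
import pytest

from ripenet.de import CountMatrix


@pytest.fixture
def small_counts() -> CountMatrix:
    """5 genes x 6 samples (WT/MT x three stages) with easy numbers."""
    rng = np.random.default_rng(7)
    samples = [f"{g}{s}" for g in ("WT", "MT") for s in (170, 190, 210)]
    genes = [f"g{i}" for i in range(5)]
    counts = pd.DataFrame(rng.integers(0, 500, (5, 6)), index=genes, columns=samples)
    return CountMatrix(
        counts=counts,
        library_sizes=pd.Series(1_000_000, index=samples),
        gene_lengths=pd.Series([1000, 2000, 500, 1500, 3000], index=genes),
    )


@pytest.fixture
def module_expression():
    """Two tight 30-gene blocks plus 12 noise genes, 12 samples."""
    rng = np.random.default_rng(11)
    n = 12
    f1, f2 = rng.standard_normal((2, n))
    rows, ids = [], []
    for b, f in (("A", f1), ("B", f2)):
        for g in range(30):
            ids.append(f"{b}{g:02d}")
            rows.append(0.97 * f + rng.normal(0, 0.15, n))
    for g in range(12):
        ids.append(f"noise{g:02d}")
        rows.append(rng.standard_normal(n))
    expr = pd.DataFrame(rows, index=ids, columns=[f"S{j}" for j in range(n)])
    truth = pd.Series(["A"] * 30 + ["B"] * 30 + ["noise"] * 12, index=ids)
    return expr, truth
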