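import zlib

import numpy as np
import pandas as pd
import pytest

from segmint import (
    CooccurrenceMatrix,
    GeneratorSpec,
    default_codebook,
    table1_marginals,
)


def make_matrix(n: np.ndarray) -> CooccurrenceMatrix:
    """Wrap a raw binary array as a co-occurrence matrix with dummy labels."""
    n = np.asarray(n, dtype=np.int8)
    I, V = n.shape
    return CooccurrenceMatrix(
        n=n,
        row_ids=[f"r{i}" for i in range(I)],
        column_labels=[f"v{j}:x" for j in range(V)],
        var_slices={f"v{j}": slice(j, j + 1) for j in range(V)},
    )


@pytest.fixture
def codebook():
    return default_codebook()


@pytest.fixture
def block_matrix():
    """3x3 two-block matrix whose empirical cell distribution a K=2 model can saturate."""
    return make_matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]])


@pytest.fixture
def ones_2x2():
    return make_matrix(np.ones((2, 2)))


def random_roster(n: int, seed: int, codebook=None) -> pd.DataFrame:
    """Roster with levels drawn independently from the published male marginals."""
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(seed)
    marg = table1_marginals("male")
    data = {
        "id": [f"p{i}" for i in range(n)],
        "sex": list(rng.choice(["male", "female"], size=n)),
    }
    for var in codebook.variables:
        codes = list(marg[var])
        p = np.array([marg[var][c] for c in codes])
        data[var] = list(rng.choice(codes, size=n, p=p / p.sum()))
    return pd.DataFrame(data)


def small_spec(k: int = 2, n: int = 120, seed: int = 0, sep: float = 0.9) -> GeneratorSpec:
    """Tiny well-separated generator spec for fast recovery tests."""
    cb = default_codebook()
    rng = np.random.default_rng(seed + 1234)
    mixing = np.full(k, 1.0 / k)
    level_probs = {}
    for sex in ("male", "female"):
        segs = []
        for s in range(k):
            theta = {}
            for var in cb.variables:
                L = len(cb.level_codes(var))
                row = np.full(L, (1.0 - sep) / max(L - 1, 1))
                row[(s + zlib.crc32(f"{var}|{sex}".encode())) % L] = sep
                if L == 1:
                    row = np.array([1.0])
                theta[var] = row / row.sum()
            segs.append(theta)
        level_probs[sex] = segs
    return GeneratorSpec(
        n_male=n,
        n_female=n,
        k_true=k,
        mixing={"male": mixing, "female": mixing.copy()},
        level_probs=level_probs,
        seed=seed,
        codebook=cb,
    )
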