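import numpy as np
import pytest

from cmprof.alphabet import ALPHABET
from cmprof.msa_io import Msa


@pytest.fixture
def rng():
    return np.random.default_rng(20231123)


@pytest.fixture
def random_msa(rng):
    """Unstructured 30-sequence x 25-column MSA with ~10% gaps."""
    n_seq, n = 30, 25
    codes = rng.integers(0, 20, size=(n_seq, n))
    gaps = rng.random((n_seq, n)) < 0.1
    gaps[0] = False  # seed stays gap-free so columns index the seed
    rows = []
    for s in range(n_seq):
        rows.append("".join("-" if gaps[s, j] else ALPHABET[codes[s, j]] for j in range(n)))
    return Msa(seed_id="seed", ids=[f"s{k}" for k in range(n_seq)], rows=rows)


def brute_force_pair_counts(msa):
    """Independent nested-loop tally of N(a_i, b_j) for oracle comparisons."""
    from cmprof.alphabet import AA_INDEX

    n = msa.n
    N = np.zeros((n, n, 20, 20))
    for row in msa.rows:
        for i in range(n):
            if row[i] == "-" or row[i] not in AA_INDEX:
                continue
            for j in range(n):
                if row[j] == "-" or row[j] not in AA_INDEX:
                    continue
                N[i, j, AA_INDEX[row[i]], AA_INDEX[row[j]]] += 1
    return N
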