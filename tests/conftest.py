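from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from wolfscr.genotypes import NO_CALL, ErrorRates, ReplicateSet

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_replicates(locus_calls, amel=None, sample_id="s1", locus_ids=None):
    """Build a ReplicateSet from a list of per-replicate call lists.

    ``locus_calls[r][l]`` is an (a1, a2) tuple or None for no amplification.
    """
    n_rep = len(locus_calls)
    n_loci = len(locus_calls[0])
    calls = np.full((n_rep, n_loci, 2), NO_CALL, dtype=int)
    for r, rep in enumerate(locus_calls):
        for l, call in enumerate(rep):
            if call is not None:
                calls[r, l] = sorted(call)
    amel = amel if amel is not None else [None] * n_rep
    locus_ids = locus_ids or [f"L{l + 1:02d}" for l in range(n_loci)]
    return ReplicateSet(sample_id=sample_id, calls=calls, amel=amel,
                        locus_ids=locus_ids)


@pytest.fixture
def rates_two_loci():
    return ErrorRates(dropout=np.array([0.073, 0.03]), false_allele=0.004,
                      pool_size=6)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
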