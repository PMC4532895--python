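"""Independent oracles used by the test suite (kept free of the code paths
they check)."""
from __future__ import annotations

import numpy as np

from contextpp.accessibility import (
    DEFAULT_PAIR_ENERGIES,
    FOLD_TEMPERATURE_K,
    GAS_CONSTANT_KCAL,
    MIN_HAIRPIN_LOOP,
)

RT = GAS_CONSTANT_KCAL * FOLD_TEMPERATURE_K


def legal_pairs(seq: str, max_span: int = 40):
    lut = {}
    for p, e in DEFAULT_PAIR_ENERGIES.items():
        lut[p] = e
        lut[p[::-1]] = e
    return [
        (i, j, lut[seq[i] + seq[j]])
        for i in range(len(seq))
        for j in range(i + MIN_HAIRPIN_LOOP + 1, min(len(seq), i + max_span))
        if seq[i] + seq[j] in lut
    ]


def enumeration_partition_function(seq: str, forbid=frozenset()) -> float:
    """Brute-force sum of Boltzmann weights over every non-crossing set of
    legal pairs (exponential; sequences must stay short)."""
    pairs = [(i, j, e) for (i, j, e) in legal_pairs(seq) if i not in forbid and j not in forbid]
    total = 0.0

    def rec(idx, chosen, weight):
        nonlocal total
        total += weight
        for k in range(idx, len(pairs)):
            i, j, e = pairs[k]
            ok = all(
                i not in (a, b) and j not in (a, b) and ((a < i < b) == (a < j < b))
                for a, b in chosen
            )
            if ok:
                rec(k + 1, chosen + [(i, j)], weight * np.exp(-e / RT))

    rec(0, [], 1.0)
    return total


def enumeration_unpaired_probability(seq: str, start: int, length: int) -> float:
    forbid = frozenset(range(start, start + length))
    return enumeration_partition_function(seq, forbid) / enumeration_partition_function(seq)


def isoform_expectation_cwcs(cs: np.ndarray, air: np.ndarray) -> float:
    """CWCS via explicit expectation over tandem isoforms.

    Sites are ordered distal -> proximal with nondecreasing AIR; isoform l
    (l = 0..n) contains the l most proximal sites and has abundance equal to
    the AIR increment.  The expected remaining mRNA fraction is the
    abundance-weighted product of 2**CS over contained sites.
    """
    cs = np.asarray(cs, dtype=float)
    air = np.asarray(air, dtype=float)
    n = len(cs)
    boundaries = np.concatenate([[0.0], air])  # air sorted nondecreasing
    expectation = (1.0 - air[-1]) if n else 1.0  # isoforms containing no site
    for l in range(1, n + 1):
        # an isoform containing site l also contains every more-proximal
        # site, so the class with abundance (AIR_l - AIR_{l-1}) carries
        # exactly sites l..n
        abundance = boundaries[l] - boundaries[l - 1]
        remaining = np.prod(2.0 ** cs[l - 1 :])
        expectation += abundance * remaining
    return float(np.log2(expectation))
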