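"""Structural-accessibility backends.

The site-accessibility feature needs the probability that a target window is
completely single-stranded under a local folding model (maximal base-pair
span 40 nt, ~80 nt folding window, mirroring RNAplfold -L 40 -W 80).

Two providers are available:

* :class:`PartitionFunctionProvider` — an in-package simplified McCaskill
  partition function.  The energy model assigns one stacking-free free-energy
  term per base pair (GC/AU/GU), a minimum hairpin loop of 3 nt, and a
  maximal pair span; the partition function sums Boltzmann weights over all
  non-crossing sets of legal pairs.  The unpaired probability of a window is
  the ratio of the constrained partition function (no pair touching the
  window) to the unconstrained one.  Exact within its model — it equals
  exhaustive structure enumeration on short sequences — but it is not a
  replication of the Turner-2004 nearest-neighbor model.
* :class:`LunpProvider` — reads RNAplfold ``_lunp`` output for
  bit-compatible reproduction of a published pipeline.

Both expose ``window_probability(seq, start, length) -> float`` in (0, 1].
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "PartitionFunctionProvider",
    "LunpProvider",
    "GAS_CONSTANT_KCAL",
    "FOLD_TEMPERATURE_K",
]

GAS_CONSTANT_KCAL = 0.0019872041  # kcal / (mol K)
FOLD_TEMPERATURE_K = 310.15  # 37 degrees C

#: per-pair free energies (kcal/mol); coarse single-pair surrogates for the
#: relative stabilities of the three RNA pair classes
DEFAULT_PAIR_ENERGIES = {"GC": -3.0, "AU": -2.0, "GU": -1.0}

MIN_HAIRPIN_LOOP = 3


def _pair_weight_matrix(seq: str, energies: dict[str, float], rt: float, max_span: int) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n))
    lut = {}
    for pair, e in energies.items():
        lut[pair] = np.exp(-e / rt)
        lut[pair[::-1]] = np.exp(-e / rt)
    for i in range(n):
        jmax = min(n, i + max_span)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, jmax):
            w[i, j] = lut.get(seq[i] + seq[j], 0.0)
    return w


def _partition_function(w: np.ndarray, max_span: int | None = None) -> float:
    """Partition function Q(0, n) of the whole sequence over all
    non-crossing sets of admitted pairs, via the standard recursion

        Q[i,j] = Q[i+1,j] + sum_k w[i,k] Q[i+1,k-1] Q[k+1,j].

    Subsequence values are held diagonal-major (``diag[s][i]`` = Q of the
    half-open stretch [i, i+s)) so the recurrence runs on contiguous slices.
    """
    n = w.shape[0]
    dmax = n if max_span is None else min(n, max_span)
    wdiag = [np.ascontiguousarray(np.diagonal(w, d)) for d in range(min(n, dmax + 1))]
    diag = [np.ones(n + 1 - s) for s in range(n + 1)]
    for span in range(MIN_HAIRPIN_LOOP + 2, n + 1):
        m = n - span + 1  # number of start positions
        total = diag[span - 1][1 : 1 + m].copy()  # position i unpaired
        for d in range(MIN_HAIRPIN_LOOP + 1, min(span, dmax)):  # pair (i, i+d)
            wd = wdiag[d][:m]
            if wd.any():
                total += wd * diag[d - 1][1 : 1 + m] * diag[span - d - 1][d + 1 : d + 1 + m]
        diag[span] = total
    return float(diag[n][0])


class PartitionFunctionProvider:
    """Built-in accessibility backend (simplified McCaskill model)."""

    def __init__(
        self,
        max_pair_span: int = 40,
        fold_window: int = 80,
        pair_energies: dict[str, float] | None = None,
        temperature_k: float = FOLD_TEMPERATURE_K,
    ):
        self.max_pair_span = max_pair_span
        self.fold_window = fold_window
        self.pair_energies = dict(pair_energies or DEFAULT_PAIR_ENERGIES)
        self.rt = GAS_CONSTANT_KCAL * temperature_k

    def _segment(self, seq: str, start: int, length: int) -> tuple[str, int]:
        """Local folding segment: the window plus flanks filling the fold
        window (the local analogue of RNAplfold's sliding -W window)."""
        flank = max(0, (self.fold_window - length) // 2)
        lo = max(0, start - flank)
        hi = min(len(seq), start + length + flank)
        return seq[lo:hi], start - lo

    def window_probability(self, seq: str, start: int, length: int) -> float:
        """Probability that all ``length`` nucleotides of the window starting
        at 0-based ``start`` are simultaneously unpaired."""
        if length < 1 or start < 0 or start + length > len(seq):
            raise ValueError(
                f"window [{start},{start + length}) outside sequence of length {len(seq)}"
            )
        seg, off = self._segment(seq, start, length)
        if any(c not in "ACGU" for c in seg):
            return float("nan")  # N in the fold window -> missing value
        w = _pair_weight_matrix(seg, self.pair_energies, self.rt, self.max_pair_span)
        Q = _partition_function(w, self.max_pair_span)
        w_c = w.copy()
        w_c[off : off + length, :] = 0.0
        w_c[:, off : off + length] = 0.0
        Qc = _partition_function(w_c, self.max_pair_span)
        return Qc / Q


class LunpProvider:
    """Accessibility read from an RNAplfold ``_lunp`` file.

    The file has one row per sequence position ``l`` (1-based) with the
    probability that the stretch of ``u`` nucleotides *ending* at ``l`` is
    unpaired, for ``u`` = 1..max; absent values are NA.
    """

    def __init__(self, path):
        self._probs: dict[tuple[int, int], float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            l = int(parts[0])
            for u, tok in enumerate(parts[1:], start=1):
                if tok not in ("NA", "nan"):
                    self._probs[(l, u)] = float(tok)

    def window_probability(self, seq: str, start: int, length: int) -> float:
        key = (start + length, length)  # 1-based end position
        if key not in self._probs:
            return float("nan")
        return self._probs[key]
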