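"""Independent brute-force oracles used to check the implementation.

Each function here deliberately uses a different algorithm from the package
(exhaustive enumeration, naive sliding windows, patience sorting, textbook
formulas) so agreement is meaningful.
"""

from __future__ import annotations

from bisect import bisect_left

import numpy as np
from scipy import stats

_COMP = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def orf_oracle(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Every (start, end, strand) ORF under the first-ATG-per-stop policy.

    Enumerates every ATG in all six frames, walks codons to the stop
    (invalid if an N-containing codon intervenes or the frame runs off the
    end), then keeps the earliest ATG per stop and applies the length cut.
    """
    n = len(seq)
    found: set[tuple[int, int, str]] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            earliest: dict[int, int] = {}  # stop end -> earliest ATG
            for pos in range(frame, n - 2, 3):
                if s[pos : pos + 3] != "ATG":
                    continue
                q = pos
                end = None
                while q <= n - 3:
                    codon = s[q : q + 3]
                    if "N" in codon:
                        break
                    if codon in _STOPS:
                        end = q + 3
                        break
                    q += 3
                if end is None:
                    continue
                if end not in earliest or pos < earliest[end]:
                    earliest[end] = pos
            for end, start in earliest.items():
                if (end - start) // 3 - 1 < min_aa:
                    continue
                if strand == "+":
                    found.add((start, end, "+"))
                else:
                    found.add((n - end, n - start, "-"))
    return found


def motif_oracle(window: str) -> list[int]:
    """Start indices of TGAAANNNNA in a window, naive sliding 10-mer."""
    hits = []
    for i in range(len(window) - 9):
        w = window[i : i + 10]
        if w[:5] == "TGAAA" and w[9] == "A":
            hits.append(i)
    return hits


def longest_monotone_length(values: list[float], decreasing: bool = False) -> int:
    """Longest strictly monotone subsequence length via patience sorting."""
    vals = [-v for v in values] if decreasing else list(values)
    tails: list[float] = []
    for v in vals:
        i = bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def bh_oracle(pvalues: list[float]) -> list[float]:
    """Step-up BH by the definition: q_i = min_{j>=i} p_(j) * n / j."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q_sorted = [0.0] * n
    running = float("inf")
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * n / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = [0.0] * n
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def welch_oracle(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and two-sided p via the t distribution."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(2 * stats.t.sf(abs(t), df))
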