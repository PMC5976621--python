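"""Independent reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct route available —
combinatorial sums, exhaustive scans, regex over translated frames —
deliberately sharing no code with the package modules it checks.
"""

from __future__ import annotations

import re
from math import comb

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeom(pop=d, successes=c, draws=b),
    via the explicit combinatorial sum."""
    denom = comb(d, b)
    total = 0
    for i in range(a, min(b, c) + 1):
        if b - i <= d - c:
            total += comb(c, i) * comb(d - c, b - i)
    return total / denom


def n50_brute(lengths) -> int:
    """Largest member length L with sum(x for x >= L) >= half the total."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths)):
        if 2 * sum(x for x in lengths if x >= L) >= total:
            best = L
    return best


def orfs_brute(seq: str, min_aa: int):
    """All qualifying ORFs via regex over the six translated frames.

    Yields (nt_len, strand_rank, frame, fwd_start, fwd_end, peptide) with
    1-based inclusive forward-strand coordinates spanning ATG..stop.
    """
    seq = seq.upper()
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    for strand_rank, s in enumerate((seq, rc)):
        for frame in range(3):
            usable = s[frame: frame + 3 * ((len(s) - frame) // 3)]
            prot = str(Seq(usable).translate())
            for m in re.finditer(r"M[^*]*(?=\*)", prot):
                # trim to the peptide starting at each M is handled by
                # finditer only at the first M of a stretch; cover nested
                # starts explicitly below
                pass
            # explicit nested-start enumeration: every M up to its stop
            stops = [i for i, aa in enumerate(prot) if aa == "*"]
            for i, aa in enumerate(prot):
                if aa != "M":
                    continue
                nxt = next((sp for sp in stops if sp > i), None)
                if nxt is None or nxt - i < min_aa:
                    continue
                a = frame + 3 * i            # 0-based on this strand
                b = frame + 3 * (nxt + 1)    # past the stop codon
                if strand_rank == 0:
                    start, end = a + 1, b
                else:
                    start, end = n - b + 1, n - a
                yield (b - a, strand_rank, frame, start, end, prot[i:nxt])


def longest_orf_brute(seq: str, min_aa: int):
    """Best ORF under the tie order (-nt_len, strand, frame, start)."""
    best = None
    for nt_len, strand_rank, frame, start, end, pep in orfs_brute(seq, min_aa):
        key = (-nt_len, strand_rank, frame, start)
        if best is None or key < best[0]:
            best = (key, (strand_rank, frame, start, end, pep))
    return None if best is None else best[1]


def lcs_brute(a: str, b: str) -> int:
    """Longest common subsequence by the textbook full DP table."""
    la, lb = len(a), len(b)
    T = np.zeros((la + 1, lb + 1), dtype=int)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            if a[i - 1] == b[j - 1]:
                T[i, j] = T[i - 1, j - 1] + 1
            else:
                T[i, j] = max(T[i - 1, j], T[i, j - 1])
    return int(T[la, lb])


def greedy_cluster_brute(items, threshold: float):
    """Greedy clustering with no word filter; returns list of member-id
    lists in cluster-foundation order."""
    order = sorted(range(len(items)), key=lambda i: (-len(items[i][1]), i))
    reps: list[tuple[str, str]] = []
    clusters: list[list[str]] = []
    for idx in order:
        pid, seq = items[idx]
        for ci, (_rid, rseq) in enumerate(reps):
            ident = lcs_brute(seq, rseq) / min(len(seq), len(rseq))
            if ident >= threshold:
                clusters[ci].append(pid)
                break
        else:
            reps.append((pid, seq))
            clusters.append([pid])
    return clusters


def trim_brute(seq: str, quals, headcrop: int, end_q: int, w: int,
               win_q: int, min_len: int):
    """Replay of the trimming rules with numpy primitives."""
    q = np.asarray(quals)[headcrop:]
    s = seq[headcrop:]
    keep = q >= end_q
    if keep.any():
        lo = int(np.argmax(keep))
        hi = len(q) - int(np.argmax(keep[::-1]))
    else:
        lo = hi = 0
    s, q = s[lo:hi], q[lo:hi]
    if len(q) >= w:
        sums = np.convolve(q, np.ones(w, dtype=int), mode="valid")
        failing = np.nonzero(sums < win_q * w)[0]
        if failing.size:
            cut = int(failing[0])
            s, q = s[:cut], q[:cut]
    if len(s) <= min_len:
        return None
    return s, list(int(x) for x in q)
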