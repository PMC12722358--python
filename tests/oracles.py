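"""Independent brute-force oracles used to validate the library algorithms.

Each oracle recomputes the target quantity by direct enumeration, sharing
no code path with the implementation it checks.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def brute_dyads(seq: str, min_arm: int, max_loop: int, max_mismatch: int):
    """All maximal dyads by exhaustive (inner-edge, loop, arm-length)
    enumeration plus explicit pair-set containment filtering.

    Returns a set of (arm1_start, arm2_start, arm_len, loop_len, mismatches).
    """
    seq = seq.upper()
    n = len(seq)
    cands = []  # (pairset frozenset, i, j, L, loop, mism)
    for e in range(1, n):            # arm1 inner end (exclusive)
        for loop in range(0, max_loop + 1):
            j0 = e + loop            # arm2 start
            if j0 >= n:
                break
            mism = 0
            L = 0
            while e - 1 - L >= 0 and j0 + L < n:
                x, y = seq[e - 1 - L], seq[j0 + L]
                if (x, y) not in _PAIRS:
                    mism += 1
                    if mism > max_mismatch:
                        break
                L += 1
                if L >= min_arm:
                    pairs = frozenset(
                        (e - 1 - t, j0 + t) for t in range(L)
                    )
                    cands.append((pairs, e - L, j0, L, loop, mism))
    out = set()
    for pairs, i, j, L, loop, mism in cands:
        contained = any(
            pairs < other[0] for other in cands
        )
        if not contained:
            out.add((i, j, L, loop, mism))
    return out


def brute_hairpin(seq: str, min_stem: int, min_loop: int, loop_penalty: float = 0.5):
    """Best fold by exhaustive enumeration of all perfect stems.

    Returns (score, stem_len, arm1_start) of the optimum or None.
    """
    seq = seq.upper()
    n = len(seq)
    best = None
    for i in range(n):
        for L in range(min_stem, n):
            for j0 in range(i + L + min_loop, n - L + 1):
                arm1 = seq[i:i + L]
                arm2 = seq[j0:j0 + L]
                if all((x, y) in _PAIRS for x, y in zip(arm1, arm2[::-1])):
                    gc = sum(1 for x in arm1 if x in "GC")
                    at = L - gc
                    loop = j0 - (i + L)
                    score = 3 * gc + 2 * at - loop_penalty * max(0, loop - min_loop)
                    key = (score, L, -i)
                    if best is None or key > best:
                        best = key
    if best is None:
        return None
    return best[0], best[1], -best[2]


def brute_lcs(a: str, b: str):
    """All longest common substrings by dynamic programming.

    Returns (length, frozenset of substrings).
    """
    na, nb = len(a), len(b)
    best = 0
    ends = []
    prev = [0] * (nb + 1)
    for i in range(1, na + 1):
        cur = [0] * (nb + 1)
        for j in range(1, nb + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
                    ends = [i]
                elif cur[j] == best:
                    ends.append(i)
        prev = cur
    if best == 0:
        return 0, frozenset()
    return best, frozenset(a[i - best:i] for i in ends)


def brute_single_copy(ab_edges, ba_edges, mode="reciprocal"):
    """Exhaustive single-copy classification on bipartite edge sets.

    ``ab_edges``/``ba_edges`` are iterables of (gene_a, gene_b) /
    (gene_b, gene_a). Returns a set of (gene_a, gene_b) pairs.
    """
    ab = {}
    for ga, gb in ab_edges:
        ab.setdefault(ga, set()).add(gb)
    ba = {}
    for gb, ga in ba_edges:
        ba.setdefault(gb, set()).add(ga)
    out = set()
    if mode == "one_way":
        for ga, targets in ab.items():
            if len(targets) == 1:
                out.add((ga, next(iter(targets))))
    else:
        for ga, targets in ab.items():
            if len(targets) != 1:
                continue
            gb = next(iter(targets))
            if ba.get(gb) == {ga}:
                out.add((ga, gb))
    return out


def brute_collapse(hits):
    """Group-by-max HSP collapapsing oracle.

    ``hits`` are (gene_a, gene_b, bitscore, pident, subject_id) tuples;
    returns {(gene_a, gene_b): best tuple}.
    """
    groups = {}
    for h in hits:
        groups.setdefault((h[0], h[1]), []).append(h)
    return {
        k: max(v, key=lambda h: (h[2], h[3], _NegStr(h[4])))
        for k, v in groups.items()
    }


class _NegStr(str):
    """Reverses string ordering so max() prefers the smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
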