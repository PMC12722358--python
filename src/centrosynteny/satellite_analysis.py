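"""Satellite monomer and array characterization.

Monomer level: exhaustive dyad-symmetry (inverted repeat) search, a
transparent stem-loop score as a proxy for hairpin-forming potential, and
longest shared motifs between two monomers (optionally circular and
reverse-complement aware). Array level: greedy decomposition of an array
into monomer copies with orientation and identity, and detection of a
higher-order repeat (HOR) period from lagged monomer-to-monomer identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .io_formats import GenomicInterval

__all__ = [
    "DyadSymmetry",
    "HairpinScore",
    "TilingSegment",
    "ArrayProfile",
    "revcomp",
    "find_dyads",
    "hairpin_score",
    "shared_motif",
    "SharedMotif",
    "decompose_array",
    "monomer_sequences",
    "detect_hor",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _pairs(x: str, y: str) -> bool:
    return (x, y) in _PAIRS  # N never pairs


@dataclass(frozen=True)
class DyadSymmetry:
    """An inverted repeat: arm2 is the reverse complement of arm1 (up to
    ``mismatches``), separated by ``loop_len`` unpaired bases."""

    arm1_start: int
    arm2_start: int
    arm_len: int
    loop_len: int
    mismatches: int


@dataclass(frozen=True)
class HairpinScore:
    """Best stem-loop fold under a simple additive score:
    3 per G:C pair, 2 per A:T pair, minus loop_penalty per loop base
    beyond min_loop."""

    stem_len: int
    paired_gc: int
    paired_at: int
    loop_len: int
    score: float
    arm1_start: int = 0


@dataclass(frozen=True)
class TilingSegment:
    start: int
    end: int
    orientation: str  # 'F' or 'R'
    identity: float


@dataclass
class ArrayProfile:
    """Monomer tiling of a satellite array."""

    interval: GenomicInterval
    monomer_count: int
    tiling: list[TilingSegment]
    orientation_runs: list[tuple[str, int]]
    hor_period: Optional[int] = None
    mean_adjacent_identity: float = float("nan")

    @property
    def coverage(self) -> float:
        covered = sum(seg.end - seg.start for seg in self.tiling)
        return covered / len(self.interval)

    @property
    def mean_identity(self) -> float:
        if not self.tiling:
            return float("nan")
        return sum(s.identity for s in self.tiling) / len(self.tiling)


# ---------------------------------------------------------------------------
# Dyad symmetries


def find_dyads(
    seq: str,
    min_arm: int = 4,
    max_loop: int = 12,
    max_mismatch: int = 0,
) -> list[DyadSymmetry]:
    """Enumerate all maximal dyad symmetries of ``seq``.

    A dyad is maximal when its set of paired positions is not a strict
    subset of another reported dyad's pairs (pairs of one dyad all lie on a
    single anti-diagonal i+j = const, so containment is checked per
    diagonal). Results are sorted by arm length (desc), then position.
    """
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    seq = seq.upper()
    n = len(seq)
    out: list[DyadSymmetry] = []
    # anti-diagonal c = arm1_pos + arm2_pos for every pair of the dyad
    for c in range(2 * min_arm - 1, 2 * n - 2 * min_arm + 2):
        p_lo = max(0, c - n + 1)
        # match[p]: seq[p] pairs with seq[c-p] (only p < c-p relevant)
        # inner arm end e = arm1_start + arm_len; loop = c - 2e + 1
        e_hi = (c + 1) // 2
        e_lo = max(min_arm, int(math.ceil((c + 1 - max_loop) / 2)))
        cands: list[tuple[int, int, int]] = []  # (i, e, mismatches)
        for e in range(e_lo, e_hi + 1):
            mism = 0
            best_i = None
            best_mism = 0
            i = e - 1
            while i >= p_lo:  # extend arm outward
                if not _pairs(seq[i], seq[c - i]):
                    mism += 1
                    if mism > max_mismatch:
                        break
                if e - i >= min_arm:
                    best_i = i
                    best_mism = mism
                i -= 1
            if best_i is not None:
                cands.append((best_i, e, best_mism))
        # suppress candidates contained in another candidate on this diagonal
        for i, e, m in cands:
            contained = any(
                (i2 <= i and e2 >= e and (i2, e2) != (i, e)) for i2, e2, _ in cands
            )
            if not contained:
                out.append(
                    DyadSymmetry(
                        arm1_start=i,
                        arm2_start=c - e + 1,
                        arm_len=e - i,
                        loop_len=c - 2 * e + 1,
                        mismatches=m,
                    )
                )
    out.sort(key=lambda d: (-d.arm_len, d.arm1_start, d.arm2_start))
    return out


# ---------------------------------------------------------------------------
# Hairpin scoring


def hairpin_score(
    seq: str,
    min_stem: int = 3,
    min_loop: int = 3,
    loop_penalty: float = 0.5,
) -> Optional[HairpinScore]:
    """Best-scoring perfect stem-loop fold, or None when no fold exists.

    All perfectly paired stems with loop >= ``min_loop`` are enumerated;
    ties go to the longest stem, then the leftmost.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return None
    best: Optional[HairpinScore] = None
    for e in range(1, n):  # arm1 inner end (exclusive)
        for loop in range(min_loop, n - e):
            j0 = e + loop  # arm2 start
            gc = at = 0
            L = 0
            while e - 1 - L >= 0 and j0 + L < n:
                x, y = seq[e - 1 - L], seq[j0 + L]
                if not _pairs(x, y):
                    break
                if x in "GC":
                    gc += 1
                else:
                    at += 1
                L += 1
                if L >= min_stem:
                    score = 3 * gc + 2 * at - loop_penalty * max(0, loop - min_loop)
                    cand = HairpinScore(
                        stem_len=L, paired_gc=gc, paired_at=at,
                        loop_len=loop, score=score, arm1_start=e - L,
                    )
                    if (
                        best is None
                        or cand.score > best.score
                        or (cand.score == best.score and cand.stem_len > best.stem_len)
                        or (
                            cand.score == best.score
                            and cand.stem_len == best.stem_len
                            and cand.arm1_start < best.arm1_start
                        )
                    ):
                        best = cand
    return best


# ---------------------------------------------------------------------------
# Shared motifs


@dataclass(frozen=True)
class SharedMotif:
    length: int
    motifs: tuple[str, ...]


def _common_substrings(a: str, b: str, length: int, max_start_a: int, max_start_b: int) -> set[str]:
    sa = {a[i:i + length] for i in range(min(max_start_a, len(a) - length + 1))}
    sb = {b[i:i + length] for i in range(min(max_start_b, len(b) - length + 1))}
    return sa & sb


def shared_motif(
    monomer_a: str,
    monomer_b: str,
    include_revcomp: bool = False,
    circular: bool = False,
) -> SharedMotif:
    """All longest substrings shared between two monomers.

    ``circular`` searches each monomer doubled (junction-spanning motifs),
    with match length capped at the shorter monomer length.
    ``include_revcomp`` additionally searches the reverse complement of
    ``monomer_b``; motifs are reported in ``monomer_a``'s frame.
    """
    if not monomer_a or not monomer_b:
        raise ValueError("both monomers must be non-empty")
    a, b = monomer_a.upper(), monomer_b.upper()
    variants = [b]
    if include_revcomp:
        variants.append(revcomp(b))

    if circular:
        sa, start_a = a + a, len(a)
        cap = min(len(a), len(b))
    else:
        sa, start_a = a, len(a)
        cap = min(len(a), len(b))

    def common_at(length: int) -> set[str]:
        found: set[str] = set()
        for v in variants:
            sv = v + v if circular else v
            start_v = len(v)
            found |= _common_substrings(sa, sv, length, start_a, start_v)
        return found

    # binary search the longest length with a common substring
    lo, hi, best_len = 0, cap, 0
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if common_at(mid):
            lo = mid
        else:
            hi = mid - 1
    best_len = lo
    if best_len == 0:
        return SharedMotif(0, ())
    return SharedMotif(best_len, tuple(sorted(common_at(best_len))))


# ---------------------------------------------------------------------------
# Array decomposition


def _edlib_identity(query: str, target: str, mode: str, k: int) -> tuple[int, int]:
    """(edit distance, end position in target) or (-1, -1) when above k."""
    res = edlib.align(query, target, mode=mode, task="locations", k=k)
    if res["editDistance"] < 0:
        return -1, -1
    return res["editDistance"], res["locations"][0][1]


def decompose_array(
    array_seq: str,
    consensus: str,
    min_identity: float = 80.0,
) -> ArrayProfile:
    """Greedy monomer tiling of a satellite array.

    At each position the consensus and its reverse complement are aligned
    to a prefix of the remaining sequence by banded edit distance (band =
    20% of the monomer length); the better orientation is accepted when its
    identity reaches ``min_identity``, else the scan advances one base.
    """
    if len(consensus) < 10:
        raise ValueError("consensus must be at least 10 bp")
    arr = array_seq.upper()
    cons = consensus.upper()
    rc = revcomp(cons)
    L = len(cons)
    band = int(math.ceil(0.2 * L))
    tiling: list[TilingSegment] = []
    pos = 0
    n = len(arr)
    while pos + L - band <= n and pos < n:
        window = arr[pos:pos + L + band]
        dist_f, end_f = _edlib_identity(cons, window, "SHW", band)
        dist_r, end_r = _edlib_identity(rc, window, "SHW", band)
        if dist_f >= 0 and (dist_r < 0 or dist_f <= dist_r):
            dist, end, orient = dist_f, end_f, "F"
        elif dist_r >= 0:
            dist, end, orient = dist_r, end_r, "R"
        else:
            pos += 1
            continue
        identity = 100.0 * (1.0 - dist / L)
        if identity >= min_identity:
            tiling.append(TilingSegment(pos, pos + end + 1, orient, identity))
            pos += end + 1
        else:
            pos += 1

    runs: list[tuple[str, int]] = []
    for seg in tiling:
        if runs and runs[-1][0] == seg.orientation:
            runs[-1] = (seg.orientation, runs[-1][1] + 1)
        else:
            runs.append((seg.orientation, 1))

    seqs = monomer_sequences(arr, tiling)
    adj = []
    for s1, s2 in zip(seqs, seqs[1:]):
        d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
        adj.append(100.0 * (1.0 - d / max(len(s1), len(s2))))
    mean_adj = sum(adj) / len(adj) if adj else float("nan")

    return ArrayProfile(
        interval=GenomicInterval("array", 0, max(n, 1), name="array"),
        monomer_count=len(tiling),
        tiling=tiling,
        orientation_runs=runs,
        mean_adjacent_identity=mean_adj,
    )


def monomer_sequences(
    array_seq: str, tiling: Sequence[TilingSegment], oriented: bool = True
) -> list[str]:
    """Extract each tiled monomer's sequence; R segments are
    reverse-complemented into the forward frame when ``oriented``."""
    out = []
    for seg in tiling:
        s = array_seq[seg.start:seg.end]
        if oriented and seg.orientation == "R":
            s = revcomp(s)
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Higher-order repeat detection


def detect_hor(
    monomer_seqs: Sequence[str],
    max_lag: int = 20,
    margin: float = 5.0,
    hor_min_identity: float = 85.0,
) -> Optional[int]:
    """Detect a higher-order repeat period from lagged monomer identity.

    The mean pairwise identity between monomers at lag L is computed for
    L = 1..min(max_lag, n/2). The HOR period is the smallest L >= 2 whose
    mean identity exceeds the lag-1 mean by at least ``margin`` percentage
    points and reaches ``hor_min_identity``. Period 1 (homogeneous tandem)
    is reported when lag-1 identity itself reaches the floor and no
    higher-order signal exists; otherwise None.
    """
    n = len(monomer_seqs)
    if n < 8:
        return None

    def mean_id(lag: int) -> float:
        tot = 0.0
        cnt = 0
        for i in range(n - lag):
            s1, s2 = monomer_seqs[i], monomer_seqs[i + lag]
            d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
            tot += 100.0 * (1.0 - d / max(len(s1), len(s2)))
            cnt += 1
        return tot / cnt

    lag1 = mean_id(1)
    for lag in range(2, min(max_lag, n // 2) + 1):
        m = mean_id(lag)
        if m >= lag1 + margin and m >= hor_min_identity:
            return lag
    if lag1 >= hor_min_identity:
        return 1
    return None
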