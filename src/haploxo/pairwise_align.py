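"""Anchor-based co-linear alignment of two near-identical long sequences.

Haplotype pairs in the conserved MHC blocks are >99% identical, so long
k-mers that occur exactly once in each sequence are dense and make reliable
anchors.  The aligner

1. finds all k-mers unique in both sequences and pairs their positions,
2. collapses diagonal runs of paired k-mers into maximal exact-match anchors,
3. chains anchors by the strictly co-linear chain of highest total anchor
   length (leftmost tie-break, so output is deterministic),
4. closes inter-anchor gaps up to ``max_gap_fill`` on both sides with an
   optimal edit-distance alignment (edlib), and
5. leaves larger gaps as unaligned segments — these are structural indels,
   not SNP sources.

The result is a single-coverage alignment: every position of each sequence
belongs to at most one aligned block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import GenomicInterval, HaplotypeSequence

# op codes: "=" match run, "X" mismatch run, "IA" gap in A (B-only bases),
# "IB" gap in B (A-only bases)
Op = tuple[str, int]

_A_CONSUMING = {"=", "X", "IB"}
_B_CONSUMING = {"=", "X", "IA"}


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedBlock:
    """One co-linear aligned block with a CIGAR-like op list."""

    a_interval: GenomicInterval
    b_interval: GenomicInterval
    ops: list[Op] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_len = sum(n for op, n in self.ops if op in _A_CONSUMING)
        b_len = sum(n for op, n in self.ops if op in _B_CONSUMING)
        if a_len != len(self.a_interval) or b_len != len(self.b_interval):
            raise AlignmentError(
                f"op lengths ({a_len}, {b_len}) do not match intervals "
                f"({len(self.a_interval)}, {len(self.b_interval)})"
            )


@dataclass
class PairwiseAlignment:
    """A single-coverage chain of aligned blocks between haplotypes A and B."""

    a_id: str
    b_id: str
    blocks: list[AlignedBlock] = field(default_factory=list)
    unaligned_a: list[GenomicInterval] = field(default_factory=list)
    unaligned_b: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_a = prev_b = -1
        for blk in self.blocks:
            if blk.a_interval.start < prev_a or blk.b_interval.start < prev_b:
                raise AlignmentError("blocks must be strictly increasing on both sides")
            prev_a, prev_b = blk.a_interval.end, blk.b_interval.end

    def mismatch_columns(self) -> list[tuple[int, int]]:
        """All (pos_a, pos_b) pairs of aligned columns with differing symbols."""
        cols: list[tuple[int, int]] = []
        for blk in self.blocks:
            a, b = blk.a_interval.start, blk.b_interval.start
            for op, n in blk.ops:
                if op == "X":
                    cols.extend((a + i, b + i) for i in range(n))
                if op in _A_CONSUMING:
                    a += n
                if op in _B_CONSUMING:
                    b += n
        return cols

    def gap_runs(self) -> list[tuple[int, int, str]]:
        """Alignment gaps as (a_start, length, side).

        side "A" means B has ``length`` extra bases at A-position ``a_start``;
        side "B" means A has ``length`` extra bases starting at ``a_start``.
        Unaligned inter-block segments are included: they are indel blocks.
        """
        runs: list[tuple[int, int, str]] = []
        for blk in self.blocks:
            a = blk.a_interval.start
            for op, n in blk.ops:
                if op == "IA":
                    runs.append((a, n, "A"))
                elif op == "IB":
                    runs.append((a, n, "B"))
                if op in _A_CONSUMING:
                    a += n
        for iv in self.unaligned_a:
            runs.append((iv.start, len(iv), "B"))
        for iv in self.unaligned_b:
            # B-only segment: anchor it at the A coordinate where it occurs
            a_pos = 0
            for blk in self.blocks:
                if blk.b_interval.end <= iv.start:
                    a_pos = blk.a_interval.end
            runs.append((a_pos, len(iv), "A"))
        runs.sort()
        return runs

    def cost(self) -> int:
        """Unit-cost alignment cost: mismatches + gap bases within blocks."""
        return sum(
            n for blk in self.blocks for op, n in blk.ops if op in ("X", "IA", "IB")
        )


def project(aln: PairwiseAlignment, pos_on_a: int) -> int | None:
    """Map an A coordinate to the aligned B coordinate, or None in gaps.

    The mapping is a strictly increasing partial function.
    """
    for blk in aln.blocks:
        if pos_on_a >= blk.a_interval.end:
            continue
        if pos_on_a < blk.a_interval.start:
            return None
        a, b = blk.a_interval.start, blk.b_interval.start
        for op, n in blk.ops:
            a_next = a + n if op in _A_CONSUMING else a
            b_next = b + n if op in _B_CONSUMING else b
            if op in ("=", "X") and a <= pos_on_a < a_next:
                return b + (pos_on_a - a)
            if op == "IB" and a <= pos_on_a < a_next:
                return None  # inside an A-only gap
            a, b = a_next, b_next
        return None
    return None


# ---------------------------------------------------------------------------
# anchor discovery
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, c in enumerate(b"ACGT"):
    _CODE[c] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack k-mers into uint64; windows containing N get the sentinel ~0."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    out = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    c64 = codes.astype(np.uint64)
    for i in range(k):
        out = (out << np.uint64(2)) | c64[i : i + n]
        ok &= valid[i : i + n]
    out[~ok] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return out


def _unique_kmer_positions(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    uniq, start, counts = np.unique(sorted_codes, return_index=True, return_counts=True)
    once = counts == 1
    sentinel = uniq != np.uint64(0xFFFFFFFFFFFFFFFF)
    keep = once & sentinel
    return uniq[keep], order[start[keep]]


def _find_anchor_runs(a: str, b: str, k: int) -> np.ndarray:
    """Maximal diagonal runs of k-mers unique in both sequences.

    Returns an array of (a_start, b_start, length) rows, sorted by a_start.
    """
    ka = _kmer_codes(_encode(a), k)
    kb = _kmer_codes(_encode(b), k)
    ua, pa = _unique_kmer_positions(ka)
    ub, pb = _unique_kmer_positions(kb)
    common, ia, ib = np.intersect1d(ua, ub, assume_unique=True, return_indices=True)
    if len(common) == 0:
        return np.empty((0, 3), dtype=np.int64)
    apos = pa[ia].astype(np.int64)
    bpos = pb[ib].astype(np.int64)
    # collapse runs along the same diagonal into maximal anchors
    diag = apos - bpos
    order = np.lexsort((apos, diag))
    apos, bpos, diag = apos[order], bpos[order], diag[order]
    new_run = np.ones(len(apos), dtype=bool)
    new_run[1:] = (np.diff(diag) != 0) | (np.diff(apos) != 1)
    run_id = np.cumsum(new_run) - 1
    n_runs = run_id[-1] + 1
    starts_a = np.zeros(n_runs, dtype=np.int64)
    starts_b = np.zeros(n_runs, dtype=np.int64)
    lengths = np.bincount(run_id)
    first = np.nonzero(new_run)[0]
    starts_a = apos[first]
    starts_b = bpos[first]
    anchor_len = lengths + k - 1  # run of m consecutive k-mers spans m+k-1 bases
    anchors = np.column_stack([starts_a, starts_b, anchor_len])
    return anchors[np.argsort(anchors[:, 0], kind="stable")]


def _chain_anchors(anchors: np.ndarray) -> np.ndarray:
    """Highest-total-length strictly co-linear chain (leftmost tie-break).

    Quadratic DP vectorized over predecessors; anchor counts for ~99%
    identical pairs are proportional to the number of variant sites, which
    keeps this fast in practice.
    """
    n = len(anchors)
    if n == 0:
        return anchors
    a_start, b_start, length = anchors.T
    a_end = a_start + length
    b_end = b_start + length
    score = length.astype(np.float64).copy()
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        compat = (a_end[:i] <= a_start[i]) & (b_end[:i] <= b_start[i])
        if compat.any():
            cand = np.where(compat, score[:i], -np.inf)
            j = int(np.argmax(cand))  # leftmost maximum
            score[i] = length[i] + cand[j]
            parent[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(best)
        best = parent[best]
    chain.reverse()
    return anchors[chain]


def _diagonal_ops(a_seg: str, b_seg: str) -> list[Op]:
    ops: list[Op] = []
    for ca, cb in zip(a_seg, b_seg):
        op = "=" if ca == cb else "X"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return ops


def _gap_ops(a_seg: str, b_seg: str) -> list[Op]:
    """Optimal unit-cost alignment ops for an inter-anchor gap.

    Cost ties between a substitution and a micro-indel representation are
    resolved in favour of substitutions (the reading a human applies to a
    percentage-identity alignment): when both sides have equal length and
    the Hamming distance already equals the edit distance, the diagonal
    alignment is returned.
    """
    if not a_seg and not b_seg:
        return []
    if not a_seg:
        return [("IA", len(b_seg))]
    if not b_seg:
        return [("IB", len(a_seg))]
    res = edlib.align(a_seg, b_seg, mode="NW", task="path")
    if len(a_seg) == len(b_seg):
        ham = sum(x != y for x, y in zip(a_seg, b_seg))
        if ham == res["editDistance"]:
            return _diagonal_ops(a_seg, b_seg)
    ops: list[Op] = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            # edlib: query = a_seg; I consumes query only, D target only
            op = {"=": "=", "X": "X", "I": "IB", "D": "IA"}[ch]
            ops.append((op, n))
    return ops


def _merge_ops(ops: list[Op]) -> list[Op]:
    merged: list[Op] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def anchor_align(
    a: HaplotypeSequence,
    b: HaplotypeSequence,
    k: int = 31,
    max_gap_fill: int = 5000,
    polish_limit: int = 200_000,
) -> PairwiseAlignment:
    """Align two near-identical sequences into co-linear blocks.

    Blocks that contain indels are re-aligned whole with an optimal
    edit-distance pass (up to ``polish_limit`` bp): filling each
    inter-anchor gap independently pins the gap boundaries at the anchors,
    which can cost one or two extra operations when the optimal path
    re-synchronizes through coincidental matches near an indel.

    Raises :class:`AlignmentError` when no unique anchors exist (sequences
    too divergent, too repetitive, or shorter than ``k``).
    """
    if len(a.seq) < k or len(b.seq) < k:
        raise AlignmentError(f"sequences must be at least k={k} bp")
    anchors = _find_anchor_runs(a.seq, b.seq, k)
    if len(anchors) == 0:
        raise AlignmentError("sequences too divergent for anchor alignment")
    chain = _chain_anchors(anchors)

    blocks: list[AlignedBlock] = []
    unaligned_a: list[GenomicInterval] = []
    unaligned_b: list[GenomicInterval] = []
    cur_ops: list[Op] = []
    cur_a0, cur_b0 = int(chain[0, 0]), int(chain[0, 1])
    prev_a_end, prev_b_end = cur_a0, cur_b0

    def close_block(a_end: int, b_end: int) -> None:
        nonlocal cur_ops
        ops = _merge_ops(cur_ops)
        if ops:
            blocks.append(
                AlignedBlock(
                    GenomicInterval(a.id, cur_a0, a_end),
                    GenomicInterval(b.id, cur_b0, b_end),
                    ops,
                )
            )
        cur_ops = []

    for a_start, b_start, length in chain:
        a_start, b_start, length = int(a_start), int(b_start), int(length)
        gap_a = a_start - prev_a_end
        gap_b = b_start - prev_b_end
        if gap_a > 0 or gap_b > 0:
            if gap_a <= max_gap_fill and gap_b <= max_gap_fill:
                cur_ops.extend(
                    _gap_ops(a.seq[prev_a_end:a_start], b.seq[prev_b_end:b_start])
                )
            else:
                close_block(prev_a_end, prev_b_end)
                if gap_a > 0:
                    unaligned_a.append(GenomicInterval(a.id, prev_a_end, a_start))
                if gap_b > 0:
                    unaligned_b.append(GenomicInterval(b.id, prev_b_end, b_start))
                cur_a0, cur_b0 = a_start, b_start
        cur_ops.append(("=", length))
        prev_a_end, prev_b_end = a_start + length, b_start + length

    # trailing tails
    tail_a = len(a.seq) - prev_a_end
    tail_b = len(b.seq) - prev_b_end
    if (tail_a > 0 or tail_b > 0) and tail_a <= max_gap_fill and tail_b <= max_gap_fill:
        cur_ops.extend(_gap_ops(a.seq[prev_a_end:], b.seq[prev_b_end:]))
        prev_a_end, prev_b_end = len(a.seq), len(b.seq)
    close_block(prev_a_end, prev_b_end)
    if prev_a_end < len(a.seq):
        unaligned_a.append(GenomicInterval(a.id, prev_a_end, len(a.seq)))
    if prev_b_end < len(b.seq):
        unaligned_b.append(GenomicInterval(b.id, prev_b_end, len(b.seq)))
    # leading tails
    lead_a, lead_b = int(chain[0, 0]), int(chain[0, 1])
    if lead_a or lead_b:
        if lead_a <= max_gap_fill and lead_b <= max_gap_fill:
            head = _gap_ops(a.seq[:lead_a], b.seq[:lead_b])
            first = blocks[0]
            blocks[0] = AlignedBlock(
                GenomicInterval(a.id, 0, first.a_interval.end),
                GenomicInterval(b.id, 0, first.b_interval.end),
                _merge_ops(head + first.ops),
            )
        else:
            if lead_a:
                unaligned_a.insert(0, GenomicInterval(a.id, 0, lead_a))
            if lead_b:
                unaligned_b.insert(0, GenomicInterval(b.id, 0, lead_b))

    # polish: re-align indel-bearing blocks optimally end to end
    for i, blk in enumerate(blocks):
        if len(blk.a_interval) > polish_limit and len(blk.b_interval) > polish_limit:
            continue
        if any(op in ("IA", "IB") for op, _ in blk.ops):
            new_ops = _merge_ops(
                _gap_ops(
                    a.seq[blk.a_interval.start : blk.a_interval.end],
                    b.seq[blk.b_interval.start : blk.b_interval.end],
                )
            )
            blocks[i] = AlignedBlock(blk.a_interval, blk.b_interval, new_ops)

    return PairwiseAlignment(a.id, b.id, blocks, unaligned_a, unaligned_b)


# ---------------------------------------------------------------------------
# block-table serialization
# ---------------------------------------------------------------------------

def _ops_to_str(ops: list[Op]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def _ops_from_str(s: str) -> list[Op]:
    ops: list[Op] = []
    num = ""
    i = 0
    while i < len(s):
        ch = s[i]
        if ch.isdigit():
            num += ch
            i += 1
        elif ch == "I" and i + 1 < len(s) and s[i + 1] in "AB":
            ops.append((s[i : i + 2], int(num)))
            num = ""
            i += 2
        else:
            ops.append((ch, int(num)))
            num = ""
            i += 1
    return ops


def write_block_table(aln: PairwiseAlignment, path) -> None:
    """Serialize an alignment as a TSV block table."""
    with open(path, "w") as fh:
        fh.write(f"#a_id={aln.a_id}\tb_id={aln.b_id}\n")
        fh.write("a_start\ta_end\tb_start\tb_end\tops\n")
        for blk in aln.blocks:
            fh.write(
                f"{blk.a_interval.start}\t{blk.a_interval.end}\t"
                f"{blk.b_interval.start}\t{blk.b_interval.end}\t"
                f"{_ops_to_str(blk.ops)}\n"
            )
        for iv in aln.unaligned_a:
            fh.write(f"{iv.start}\t{iv.end}\t.\t.\tunaligned_a\n")
        for iv in aln.unaligned_b:
            fh.write(f".\t.\t{iv.start}\t{iv.end}\tunaligned_b\n")


def read_block_table(path) -> PairwiseAlignment:
    """Load an alignment produced by :func:`write_block_table` (or any
    externally computed alignment in the same format)."""
    blocks: list[AlignedBlock] = []
    unaligned_a: list[GenomicInterval] = []
    unaligned_b: list[GenomicInterval] = []
    a_id = b_id = ""
    with open(path) as fh:
        header = fh.readline().strip()
        if header.startswith("#"):
            parts = dict(kv.split("=", 1) for kv in header[1:].split("\t"))
            a_id, b_id = parts["a_id"], parts["b_id"]
            fh.readline()  # column header
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if f[4] == "unaligned_a":
                unaligned_a.append(GenomicInterval(a_id, int(f[0]), int(f[1])))
            elif f[4] == "unaligned_b":
                unaligned_b.append(GenomicInterval(b_id, int(f[2]), int(f[3])))
            else:
                blocks.append(
                    AlignedBlock(
                        GenomicInterval(a_id, int(f[0]), int(f[1])),
                        GenomicInterval(b_id, int(f[2]), int(f[3])),
                        _ops_from_str(f[4]),
                    )
                )
    return PairwiseAlignment(a_id, b_id, blocks, unaligned_a, unaligned_b)
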