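"""Substitution calling from a pairwise alignment, and the exclusion filters
that separate trustworthy SNPs from assembly noise.

A raw substitution is any aligned column where both haplotypes carry a plain
base (A/C/G/T) and the bases differ.  A substitution is *counted* only when
none of these filters fire:

``DENSE_CLUSTER``
    lies in some 50-nt window (A coordinates) holding more than 5
    substitutions — dense mismatch runs are characteristic of local
    mis-assembly, not of point mutation;
``N_PROXIMAL``
    within 50 bp of a run of unspecified bases (N) on either haplotype;
``GAP_PROXIMAL``
    within 50 bp of a long alignment gap (>= 50 bp) — long inconsistent
    deletion strings flag unreliable local assembly;
``SIMPLE_REPEAT``
    inside a Simple_repeat / Low_complexity / Satellite annotation on either
    haplotype (with an internal tandem-run fallback when no track is given);
``HOMOPOLYMER``
    inside a single-base run of >= 8 nt on either haplotype (polynucleotide
    slippage, not substitution).

Every raw call is retained with its filter set, so raw = counted + filtered
always holds exactly.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotationTrack, GenomicInterval, HaplotypeSequence
from .pairwise_align import PairwiseAlignment

_SIMPLE_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite")


@dataclass
class SnpCall:
    pos_a: int
    pos_b: int
    allele_a: str
    allele_b: str
    filters: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("substitution alleles must differ")

    @property
    def counted(self) -> bool:
        return not self.filters


@dataclass
class FilterParams:
    """Thresholds for the exclusion filters (all configurable)."""

    cluster_max: int = 5        # counted as clean up to this many per window
    cluster_window: int = 50    # nt
    n_flank: int = 50           # bp exclusion zone around N-runs
    min_n_run: int = 3          # nt; shorter N stretches are ignored
    min_gap_run_for_flank: int = 50  # bp; alignment gaps this long taint flanks
    gap_flank: int = 50         # bp
    homopolymer_min: int = 8    # nt

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value <= 0:
                raise ValueError(f"FilterParams.{name} must be positive")


def call_raw_substitutions(
    aln: PairwiseAlignment,
    a: HaplotypeSequence,
    b: HaplotypeSequence,
) -> tuple[list[SnpCall], list[tuple[int, int]]]:
    """Extract substitution columns and N-site columns from an alignment.

    Returns ``(snps, n_sites)`` where ``n_sites`` are aligned columns with an
    N on either side (kept for the proximity filter, never substitutions).
    """
    if aln.a_id != a.id or aln.b_id != b.id:
        raise ValueError(
            f"alignment is for ({aln.a_id!r}, {aln.b_id!r}), "
            f"got sequences ({a.id!r}, {b.id!r})"
        )
    snps: list[SnpCall] = []
    n_sites: list[tuple[int, int]] = []
    for pos_a, pos_b in aln.mismatch_columns():
        base_a, base_b = a.seq[pos_a], b.seq[pos_b]
        if base_a == "N" or base_b == "N":
            n_sites.append((pos_a, pos_b))
        else:
            snps.append(SnpCall(pos_a, pos_b, base_a, base_b))
    return snps, n_sites


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _char_runs(seq: str, target: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of ``target`` of length >= min_len, as [start, end)."""
    runs: list[tuple[int, int]] = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(target)
    if not arr.any():
        return runs
    padded = np.concatenate([[False], arr, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            runs.append((int(s), int(e)))
    return runs


def _homopolymer_runs(seq: str, min_len: int) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for base in "ACGT":
        runs.extend(_char_runs(seq, base, min_len))
    runs.sort()
    return runs


def _tandem_runs(seq: str, max_unit: int = 6, min_len: int = 12) -> list[tuple[int, int]]:
    """Fallback simple-repeat detector: maximal perfect tandem runs with unit
    size 2..max_unit covering >= min_len nt.  Used only when no annotation
    track is supplied.

    A period-``u`` repetition shows up as a run of positions where
    ``seq[i] == seq[i+u]``; a maximal such run of m matches spans m+u bases.
    """
    runs: list[tuple[int, int]] = []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(codes)
    is_n = codes == ord("N")
    for unit in range(2, max_unit + 1):
        if n < 2 * unit:
            continue
        match = (codes[:-unit] == codes[unit:]) & ~is_n[:-unit] & ~is_n[unit:]
        padded = np.concatenate([[False], match, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            m = e - s
            if m >= unit and m + unit >= min_len:  # at least 2 full units
                runs.append((int(s), int(e + unit)))
    runs.sort()
    return runs


def _near_any(pos: int, runs: list[tuple[int, int]], flank: int) -> bool:
    """True when pos is within ``flank`` bp of any [start, end) run."""
    if not runs:
        return False
    starts = [s for s, _ in runs]
    i = bisect_right(starts, pos)
    for j in (i - 1, i):
        if 0 <= j < len(runs):
            s, e = runs[j]
            if s - flank <= pos <= e - 1 + flank:
                return True
    return False


def _inside_any(pos: int, runs: list[tuple[int, int]]) -> bool:
    return _near_any(pos, runs, 0)


def _simple_repeat_intervals(track: AnnotationTrack | None) -> list[tuple[int, int]]:
    if track is None:
        return []
    ivs = [
        (a.interval.start, a.interval.end)
        for a in track
        if any(a.repeat_class.startswith(c) for c in _SIMPLE_CLASSES)
    ]
    ivs.sort()
    return ivs


def apply_filters(
    snps: list[SnpCall],
    aln: PairwiseAlignment,
    a: HaplotypeSequence,
    b: HaplotypeSequence,
    track_a: AnnotationTrack | None = None,
    track_b: AnnotationTrack | None = None,
    params: FilterParams | None = None,
    n_sites: list[tuple[int, int]] | None = None,
) -> list[SnpCall]:
    """Populate the filter set of every raw call (filters are total; the
    list is returned sorted by A position).

    ``n_sites`` is accepted for interface completeness; the N-proximity
    zones are derived from N-runs of length >= ``min_n_run`` scanned on the
    raw sequences, which already cover every aligned N column.
    """
    params = params or FilterParams()
    snps = sorted(snps, key=lambda s: s.pos_a)
    for s in snps:
        s.filters.clear()

    # dense clusters: any cluster_window holding > cluster_max substitutions
    pos = [s.pos_a for s in snps]
    w, cmax = params.cluster_window, params.cluster_max
    flagged = [False] * len(snps)
    for i in range(len(snps) - cmax):
        if pos[i + cmax] - pos[i] <= w - 1:
            for j in range(i, i + cmax + 1):
                flagged[j] = True
    for s, f in zip(snps, flagged):
        if f:
            s.filters.add("DENSE_CLUSTER")

    # N-run proximity, on both haplotypes in their own coordinates
    n_runs_a = _char_runs(a.seq, "N", params.min_n_run)
    n_runs_b = _char_runs(b.seq, "N", params.min_n_run)
    for s in snps:
        if _near_any(s.pos_a, n_runs_a, params.n_flank) or _near_any(
            s.pos_b, n_runs_b, params.n_flank
        ):
            s.filters.add("N_PROXIMAL")

    # long alignment-gap proximity (A coordinates; gaps on either side)
    gap_runs = [
        (a_start, a_start + (length if side == "B" else 1))
        for a_start, length, side in aln.gap_runs()
        if length >= params.min_gap_run_for_flank
    ]
    gap_runs.sort()
    for s in snps:
        if _near_any(s.pos_a, gap_runs, params.gap_flank):
            s.filters.add("GAP_PROXIMAL")

    # simple repeats / microsatellites
    simple_a = _simple_repeat_intervals(track_a)
    simple_b = _simple_repeat_intervals(track_b)
    if track_a is None:
        simple_a = _tandem_runs(a.seq)
    if track_b is None:
        simple_b = _tandem_runs(b.seq)
    for s in snps:
        if _inside_any(s.pos_a, simple_a) or _inside_any(s.pos_b, simple_b):
            s.filters.add("SIMPLE_REPEAT")

    # homopolymers (polynucleotide runs)
    homo_a = _homopolymer_runs(a.seq, params.homopolymer_min)
    homo_b = _homopolymer_runs(b.seq, params.homopolymer_min)
    for s in snps:
        if _inside_any(s.pos_a, homo_a) or _inside_any(s.pos_b, homo_b):
            s.filters.add("HOMOPOLYMER")

    return snps


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def counted_positions(snps: list[SnpCall]) -> list[int]:
    """Sorted A positions of counted SNPs."""
    return sorted(s.pos_a for s in snps if s.counted)


def count_snps(snps: list[SnpCall], interval: GenomicInterval) -> int:
    """Number of counted SNPs with pos_a inside the interval."""
    pos = counted_positions(snps)
    return bisect_left(pos, interval.end) - bisect_left(pos, interval.start)


def segment_counts(
    snps: list[SnpCall],
    segments: list[tuple[str, GenomicInterval]],
) -> pd.DataFrame:
    """Per-segment counted-SNP counts and densities, plus a total row.

    Densities are per kb.  Segments must not overlap.
    """
    for i, (_, iv1) in enumerate(segments):
        for _, iv2 in segments[i + 1:]:
            if iv1.overlaps(iv2):
                raise ValueError("segments must not overlap")
    rows = []
    total_count = 0
    total_len = 0
    for name, iv in segments:
        c = count_snps(snps, iv)
        total_count += c
        total_len += len(iv)
        rows.append(
            {"segment": name, "length": len(iv), "count": c,
             "density_per_kb": c / (len(iv) / 1000)}
        )
    rows.append(
        {"segment": "total", "length": total_len, "count": total_count,
         "density_per_kb": total_count / (total_len / 1000) if total_len else 0.0}
    )
    return pd.DataFrame(rows)


def snp_table(snps: list[SnpCall]) -> pd.DataFrame:
    """SNP calls as a tidy table (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "pos_a": s.pos_a,
                "pos_b": s.pos_b,
                "allele_a": s.allele_a,
                "allele_b": s.allele_b,
                "filters": ",".join(sorted(s.filters)) or ".",
                "counted": s.counted,
            }
            for s in sorted(snps, key=lambda s: s.pos_a)
        ],
        columns=["pos_a", "pos_b", "allele_a", "allele_b", "filters", "counted"],
    )
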