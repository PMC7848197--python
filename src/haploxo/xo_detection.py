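"""SNP-poor / SNP-rich region classification and crossover localization.

A pairwise haplotype alignment is scanned with a sliding window (default
100 kb window, 10 kb step) over the counted-SNP positions.  Windows are
labelled

* ``SPR`` (SNP-poor region): fewer than 20 counted SNPs per 100 kb,
* ``SRR`` (SNP-rich region): more than 100 counted SNPs per 100 kb,
* ``INTERMEDIATE`` otherwise.

Maximal runs of same-label windows form region runs; the junction between an
adjacent SPR and SRR run is a putative ancestral crossover (XO).  Within the
candidate span around the junction the changepoint is refined to nucleotide
resolution by exhaustively maximizing the two-rate Poisson log-likelihood of
the counted-SNP positions, and the call is reported at the first counted SNP
on the dense side of the changepoint — the convention used when reading a
junction off an alignment by eye is "the first SNP of the dense block".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import GenomicInterval

SPR = "SPR"
SRR = "SRR"
INTERMEDIATE = "INTERMEDIATE"


@dataclass
class DensityThresholds:
    spr_max: float = 20.0   # SPR iff density (per 100 kb) strictly below
    srr_min: float = 100.0  # SRR iff density strictly above

    def label(self, density_per_100kb: float) -> str:
        if density_per_100kb < self.spr_max:
            return SPR
        if density_per_100kb > self.srr_min:
            return SRR
        return INTERMEDIATE


@dataclass
class DensityWindow:
    interval: GenomicInterval
    count: int
    density_per_100kb: float
    label: str


@dataclass
class DensityProfile:
    seq_id: str
    window: int
    step: int
    rows: list[DensityWindow] = field(default_factory=list)


@dataclass
class RegionRun:
    """A maximal stretch of equal-label windows."""

    interval: GenomicInterval
    label: str
    mean_density: float
    first_window: int
    last_window: int  # inclusive index into the profile rows

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


@dataclass
class CrossoverCall:
    position: int                       # on haplotype A
    boundary_snp: tuple[int, str]       # (pos_a, "X/Y" alleles)
    direction: str                      # "SPR->SRR" or "SRR->SPR"
    left_run: RegionRun
    right_run: RegionRun
    support: tuple[int, int]            # counted SNPs within 10 kb left/right
    context: object | None = None       # RepeatContext, filled downstream


def density_profile(
    counted_pos: Sequence[int],
    region: GenomicInterval,
    window: int = 100_000,
    step: int = 10_000,
    thresholds: DensityThresholds | None = None,
) -> DensityProfile:
    """Sliding-window counted-SNP density profile over a region.

    The final partial window is normalized to per-100-kb density.  A region
    shorter than the window yields a single-window profile.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    thresholds = thresholds or DensityThresholds()
    pos = sorted(p for p in counted_pos if region.contains(p))
    import bisect

    rows: list[DensityWindow] = []
    start = region.start
    while True:
        end = min(start + window, region.end)
        count = bisect.bisect_left(pos, end) - bisect.bisect_left(pos, start)
        density = count * 100_000 / (end - start)
        rows.append(
            DensityWindow(
                GenomicInterval(region.seq_id, start, end),
                count,
                density,
                thresholds.label(density),
            )
        )
        if end >= region.end:
            break
        start += step
    return DensityProfile(region.seq_id, window, step, rows)


def classify_runs(
    profile: DensityProfile,
    min_run_length: int | None = None,
) -> list[RegionRun]:
    """Merge equal-label windows into maximal runs; absorb short runs.

    An interior run of n windows at step s has stepped extent ``n * s`` (the
    stretch of genome it alone vouches for); runs shorter than
    ``min_run_length`` (default: one full window) are merged into whichever
    neighbour has more windows, so a single-window blip never becomes a
    block of its own.  Terminal runs are truncated by the region edge and
    are measured by their genomic union ``(n - 1) * s + window`` instead.
    """
    if min_run_length is None:
        min_run_length = profile.window
    rows = profile.rows
    if not rows:
        return []

    labels = [r.label for r in rows]
    # absorb short runs until stable
    while True:
        runs: list[tuple[int, int]] = []  # (first, last) inclusive
        first = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[first]:
                runs.append((first, i - 1))
                first = i
        if len(runs) == 1:
            break
        changed = False
        for idx, (f, l) in enumerate(runs):
            n = l - f + 1
            terminal = f == 0 or l == len(labels) - 1
            extent = (n - 1) * profile.step + profile.window if terminal else n * profile.step
            if extent < min_run_length:
                left_n = runs[idx - 1][1] - runs[idx - 1][0] + 1 if idx > 0 else -1
                right_n = runs[idx + 1][1] - runs[idx + 1][0] + 1 if idx + 1 < len(runs) else -1
                dominant = idx - 1 if left_n >= right_n else idx + 1
                new_label = labels[runs[dominant][0]]
                for j in range(f, l + 1):
                    labels[j] = new_label
                changed = True
                break
        if not changed:
            break

    out: list[RegionRun] = []
    first = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[first]:
            last = i - 1
            members = rows[first : last + 1]
            out.append(
                RegionRun(
                    interval=GenomicInterval(
                        profile.seq_id,
                        members[0].interval.start,
                        members[-1].interval.end,
                    ),
                    label=labels[first],
                    mean_density=sum(m.density_per_100kb for m in members)
                    / len(members),
                    first_window=first,
                    last_window=last,
                )
            )
            first = i
    return out


def _split_loglik(n_l: int, len_l: float, n_r: int, len_r: float) -> float:
    """Two-rate Poisson profile log-likelihood of a split (0*log0 := 0)."""
    ll = 0.0
    if n_l > 0 and len_l > 0:
        ll += n_l * math.log(n_l / len_l)
    if n_r > 0 and len_r > 0:
        ll += n_r * math.log(n_r / len_r)
    return ll


def best_changepoint(pos: Sequence[int], span_start: int, span_end: int) -> int:
    """Exhaustive two-rate Poisson changepoint over counted-SNP positions.

    The log-likelihood is convex in the boundary position between adjacent
    SNPs, so every optimum lies immediately at a SNP (the SNP joins the
    right part) or immediately after one (it joins the left part); both
    boundary families are scanned, and this candidate set is closed under
    mirror reflection of the input.  The leftmost maximum wins.
    """
    pos = sorted(pos)
    if not pos:
        raise ValueError("no counted SNPs in span")
    candidates = sorted({c for p in pos for c in (p, p + 1)})
    best_c, best_ll = candidates[0], -math.inf
    n = len(pos)
    i = 0
    for c in candidates:
        while i < n and pos[i] < c:
            i += 1
        ll = _split_loglik(i, c - span_start, n - i, span_end - c)
        if ll > best_ll:
            best_ll, best_c = ll, c
    return best_c


def locate_crossover(
    counted_pos: Sequence[int],
    profile: DensityProfile,
    left_run: RegionRun,
    right_run: RegionRun,
    alleles: dict[int, str] | None = None,
    support_radius: int = 10_000,
) -> CrossoverCall:
    """Refine the junction between two adjacent runs to a SNP position.

    The candidate span runs from the last window fully inside the left run
    to the first window fully inside the right run.  ``alleles`` maps counted
    positions to their "X/Y" allele strings for reporting.
    """
    if left_run.last_window + 1 != right_run.first_window:
        raise ValueError("runs must be adjacent")
    span_start = profile.rows[left_run.last_window].interval.start
    span_end = profile.rows[right_run.first_window].interval.end
    pos = sorted(p for p in counted_pos if span_start <= p < span_end)
    if not pos:
        raise ValueError("cannot refine; report run boundary")

    c = best_changepoint(pos, span_start, span_end)
    direction = f"{left_run.label}->{right_run.label}"
    dense_right = _density_rank(right_run.label) > _density_rank(left_run.label)
    if dense_right:
        # first counted SNP at/after the changepoint
        idx = next(i for i, p in enumerate(pos) if p >= c)
        report = pos[idx]
    else:
        # mirror convention: last counted SNP before the changepoint,
        # or the changepoint SNP itself when nothing precedes it
        before = [p for p in pos if p < c]
        report = before[-1] if before else c

    allele = (alleles or {}).get(report, "?/?")
    left_support = sum(1 for p in counted_pos if report - support_radius <= p < report)
    right_support = sum(1 for p in counted_pos if report < p <= report + support_radius)
    return CrossoverCall(
        position=report,
        boundary_snp=(report, allele),
        direction=direction,
        left_run=left_run,
        right_run=right_run,
        support=(left_support, right_support),
    )


def _density_rank(label: str) -> int:
    return {SPR: 0, INTERMEDIATE: 1, SRR: 2}[label]


def detect_crossovers(
    counted_pos: Sequence[int],
    region: GenomicInterval,
    alleles: dict[int, str] | None = None,
    window: int = 100_000,
    step: int = 10_000,
    thresholds: DensityThresholds | None = None,
    min_run_length: int | None = None,
    include_intermediate: bool = False,
) -> tuple[list[CrossoverCall], str]:
    """Profile -> runs -> per-junction refinement.

    Returns the crossover calls and a region summary label ("SPR across
    whole region" when uniform, etc.).  By default only SPR<->SRR junctions
    are refined; ``include_intermediate`` also emits junctions at
    transitions involving INTERMEDIATE runs.
    """
    profile = density_profile(counted_pos, region, window, step, thresholds)
    runs = classify_runs(profile, min_run_length)
    if len(runs) == 1:
        return [], f"{runs[0].label} across whole region"
    calls: list[CrossoverCall] = []
    for left, right in zip(runs, runs[1:]):
        boundary_labels = {left.label, right.label}
        if boundary_labels == {SPR, SRR} or (
            include_intermediate and left.label != right.label
        ):
            try:
                calls.append(
                    locate_crossover(counted_pos, profile, left, right, alleles)
                )
            except ValueError:
                continue  # no counted SNPs in the span: unrefinable junction
    return calls, "mosaic"
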