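"""Presence/absence genotyping of dimorphic retroelement indels and STR
length markers, and the partition of haplotypes into ancestral lineages.

A dimorphic retroelement (Alu, SVA, HERV/LTR) is recognized not by genomic
coordinates — which shift between haplotype assemblies — but by the ordered
signature of repeat elements flanking its insertion site in the
RepeatMasker annotation.  The insertion allele is coded 2, the empty (or
solitary-relic) allele 1, and an unresolvable site 0.

Two markers carry most of the deep lineage signal: the HERVK9 provirus in
the alpha block (present as MER9/HERVK9-int/MER9, absent as a solitary
recombined MER9) and the SVA-HB insertion in the beta block.  Their cross-
classification splits haplotypes into four ancestral lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .io_formats import AnnotationTrack, GenomicInterval, HaplotypeSequence
from .repeat_association import name_matches


@dataclass
class IndelMarkerDefinition:
    """Flank/content signature of one dimorphic retroelement indel."""

    name: str
    flank_tel: list[str]
    flank_cen: list[str]
    present_content: list[str]
    absent_content: list[str] = field(default_factory=list)
    size_range_present: tuple[int, int] = (100, 10_000)
    tsd_motif: str | None = None
    max_flank_gap: int = 5_000   # bp between consecutive flank elements
    max_site_span: int = 25_000  # bp between the two flank strings

    def __post_init__(self) -> None:
        if not self.flank_tel or not self.flank_cen:
            raise ValueError(f"marker {self.name!r}: flank lists must be non-empty")
        lo, hi = self.size_range_present
        if not (0 < lo <= hi):
            raise ValueError(f"marker {self.name!r}: bad size range")


@dataclass(frozen=True)
class MarkerGenotype:
    haplotype_id: str
    marker_name: str
    call: int                      # 2 present, 1 absent, 0 uncallable
    site_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.call not in (0, 1, 2):
            raise ValueError("call must be 0, 1 or 2")


@dataclass(frozen=True)
class StrCall:
    haplotype_id: str
    locus: str
    motif: str
    unit_count: int
    interval: GenomicInterval


@dataclass(frozen=True)
class LineageAssignment:
    haplotype_id: str
    lineage: str   # e.g. "HERVK9+/SVA-HB-" or "uncallable"


# ---------------------------------------------------------------------------
# signature matching
# ---------------------------------------------------------------------------

def _match_ordered(
    track: AnnotationTrack,
    patterns: list[str],
    start_index: int,
    max_gap: int,
) -> tuple[int, int] | None:
    """First ordered occurrence of the pattern list at/after start_index.

    Consecutive matched elements must begin within ``max_gap`` bp of the
    previous match's end.  Returns (first_index, last_index) into the track.
    """
    anns = track.annotations
    i = start_index
    while i < len(anns):
        if name_matches(anns[i].repeat_name, patterns[0]):
            first = i
            j = i
            ok = True
            for pat in patterns[1:]:
                nxt = None
                for k in range(j + 1, len(anns)):
                    if anns[k].interval.start - anns[j].interval.end > max_gap:
                        break
                    if name_matches(anns[k].repeat_name, pat):
                        nxt = k
                        break
                if nxt is None:
                    ok = False
                    break
                j = nxt
            if ok:
                return first, j
        i += 1
    return None


def find_signature(
    track: AnnotationTrack, mdef: IndelMarkerDefinition
) -> tuple[int, int] | None:
    """Locate the inter-flank site: (site_start, site_end) coordinates
    between the telomeric and centromeric flank strings, or None."""
    anns = track.annotations
    start = 0
    while True:
        tel = _match_ordered(track, mdef.flank_tel, start, mdef.max_flank_gap)
        if tel is None:
            return None
        tel_end_ann = anns[tel[1]]
        cen = _match_ordered(track, mdef.flank_cen, tel[1] + 1, mdef.max_flank_gap)
        if cen is not None:
            cen_start_ann = anns[cen[0]]
            span = cen_start_ann.interval.start - tel_end_ann.interval.end
            if 0 <= span <= mdef.max_site_span:
                return tel_end_ann.interval.end, cen_start_ann.interval.start
        start = tel[0] + 1


def genotype_marker(
    track: AnnotationTrack,
    seq: HaplotypeSequence | None,
    mdef: IndelMarkerDefinition,
) -> MarkerGenotype:
    """Call one dimorphic indel: 2 (present), 1 (absent), 0 (uncallable).

    Never raises on missing signal — an absent flank signature or content
    matching neither allele definition yields call 0.
    """
    hap_id = track.seq_id
    site = find_signature(track, mdef)
    if site is None:
        return MarkerGenotype(hap_id, mdef.name, 0)
    site_start, site_end = site
    between = [
        a for a in track
        if a.interval.start >= site_start and a.interval.end <= site_end
    ]
    names = [a.repeat_name for a in between]

    if _ordered_subsequence(names, mdef.present_content):
        lo, hi = mdef.size_range_present
        content = [a for a in between
                   if any(name_matches(a.repeat_name, p)
                          for p in mdef.present_content)]
        span = content[-1].interval.end - content[0].interval.start
        if lo <= span <= hi:
            iv = GenomicInterval(hap_id, content[0].interval.start,
                                 content[-1].interval.end)
            return MarkerGenotype(hap_id, mdef.name, 2, iv)

    if not between or _only_absent_content(names, mdef.absent_content):
        iv = (
            GenomicInterval(hap_id, site_start, max(site_end, site_start + 1))
            if site_end > site_start
            else None
        )
        return MarkerGenotype(hap_id, mdef.name, 1, iv)
    return MarkerGenotype(hap_id, mdef.name, 0)


def _ordered_subsequence(names: list[str], patterns: list[str]) -> bool:
    if not patterns:
        return False
    it = iter(names)
    for pat in patterns:
        for name in it:
            if name_matches(name, pat):
                break
        else:
            return False
    return True


def _only_absent_content(names: list[str], absent: list[str]) -> bool:
    if not absent:
        return False
    return all(any(name_matches(n, p) for p in absent) for n in names) and (
        _ordered_subsequence(names, absent)
    )


# ---------------------------------------------------------------------------
# STR counting
# ---------------------------------------------------------------------------

def genotype_str(
    hap: HaplotypeSequence,
    locus_interval: GenomicInterval,
    motif: str,
    locus_name: str | None = None,
) -> StrCall:
    """Exact unit count of the longest pure tandem run of ``motif`` starting
    within the locus interval (no mismatch tolerance)."""
    if len(motif) < 2:
        raise ValueError("motif must be at least 2 nt")
    if locus_interval.end > hap.length:
        raise ValueError("locus outside sequence")
    m = len(motif)
    best = 0
    for s in range(locus_interval.start, locus_interval.end):
        count = 0
        p = s
        while hap.seq[p : p + m] == motif:
            count += 1
            p += m
        best = max(best, count)
    return StrCall(
        haplotype_id=hap.id,
        locus=locus_name or f"{locus_interval.start}-{locus_interval.end}",
        motif=motif,
        unit_count=best,
        interval=locus_interval,
    )


# ---------------------------------------------------------------------------
# matrices and lineages
# ---------------------------------------------------------------------------

def marker_matrix(
    genotypes: list[MarkerGenotype],
    haplotype_order: list[str] | None = None,
    marker_order: list[str] | None = None,
) -> pd.DataFrame:
    """Haplotypes x markers matrix of calls {0,1,2}; absent cells are 0."""
    seen: set[tuple[str, str]] = set()
    for g in genotypes:
        key = (g.haplotype_id, g.marker_name)
        if key in seen:
            raise ValueError(f"duplicate genotype for {key}")
        seen.add(key)
    haps = haplotype_order or sorted({g.haplotype_id for g in genotypes})
    markers = marker_order or sorted({g.marker_name for g in genotypes})
    mat = pd.DataFrame(0, index=haps, columns=markers, dtype=int)
    for g in genotypes:
        if g.haplotype_id in mat.index and g.marker_name in mat.columns:
            mat.loc[g.haplotype_id, g.marker_name] = g.call
    mat.index.name = "haplotype_id"
    return mat


def group_haplotype_families(matrix: pd.DataFrame) -> pd.DataFrame:
    """Group haplotypes sharing an identical marker vector (one row per
    family, with a member count)."""
    key = matrix.apply(lambda row: tuple(row), axis=1)
    groups = matrix.groupby(key, sort=False)
    rows = []
    for vec, sub in groups:
        rows.append(
            dict(zip(matrix.columns, vec))
            | {"n_haplotypes": len(sub), "haplotypes": ",".join(sub.index)}
        )
    return pd.DataFrame(rows)


def partition_lineages(
    genotypes: list[MarkerGenotype],
    marker_a: str = "HERVK9",
    marker_b: str = "SVA-HB",
) -> list[LineageAssignment]:
    """Cross-classify haplotypes on two presence/absence markers into the
    four ancestral lineages (uncallable when either marker is 0)."""
    calls: dict[str, dict[str, int]] = {}
    for g in genotypes:
        if g.marker_name in (marker_a, marker_b):
            calls.setdefault(g.haplotype_id, {})[g.marker_name] = g.call
    out: list[LineageAssignment] = []
    for hap_id in sorted(calls):
        a = calls[hap_id].get(marker_a, 0)
        b = calls[hap_id].get(marker_b, 0)
        if a == 0 or b == 0:
            out.append(LineageAssignment(hap_id, "uncallable"))
        else:
            sign = {2: "+", 1: "-"}
            out.append(
                LineageAssignment(
                    hap_id, f"{marker_a}{sign[a]}/{marker_b}{sign[b]}"
                )
            )
    return out


# ---------------------------------------------------------------------------
# marker catalogue I/O
# ---------------------------------------------------------------------------

def load_marker_definitions(path: str | Path | None = None) -> list[IndelMarkerDefinition]:
    """Load marker definitions from YAML (the shipped catalogue by default)."""
    if path is None:
        text = (
            resources.files("haploxo").joinpath("data/markers.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    defs = []
    for entry in raw["markers"]:
        defs.append(
            IndelMarkerDefinition(
                name=entry["name"],
                flank_tel=entry["flank_tel"],
                flank_cen=entry["flank_cen"],
                present_content=entry["present_content"],
                absent_content=entry.get("absent_content", []),
                size_range_present=tuple(entry["size_range_present"]),
                tsd_motif=entry.get("tsd_motif"),
                max_flank_gap=entry.get("max_flank_gap", 5_000),
                max_site_span=entry.get("max_site_span", 25_000),
            )
        )
    return defs
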