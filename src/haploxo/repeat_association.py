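"""Annotation of crossover calls against repeat and gene-feature tracks.

Crossover junctions in the MHC cluster preferentially near particular
transposable-element families (LTR16B/ERV3-16A3, MLT1, Charlie, THE1), so
each call is annotated with its containing or flanking repeat elements, the
repeat names within a 10-kb radius, signed distances to named gene features,
and exact-motif scans (e.g. the PRDM9-bound THE1B motif ATCCATG/CATGGAT and
retroelement target-site-duplication motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AnnotationTrack, GenomicInterval, RepeatAnnotation
from .xo_detection import CrossoverCall

# paper-style family names -> RepeatMasker naming, used by prefix matching
FAMILY_ALIASES: dict[str, list[str]] = {
    "ERV3-16A3_I": ["ERV3-16A3", "HERV16"],
    "ERV3-16A3": ["ERV3-16A3", "HERV16"],
    "MER9": ["MER9", "sMER9"],
    "sMER9": ["MER9", "sMER9"],
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class RepeatContext:
    containing_element: str | None
    flank_left: tuple[str, int] | None   # (repeat_name, distance bp)
    flank_right: tuple[str, int] | None
    context_string: str
    within_10kb: list[str] = field(default_factory=list)


def _expand_patterns(patterns: list[str]) -> list[str]:
    out: list[str] = []
    for p in patterns:
        out.extend(FAMILY_ALIASES.get(p, [p]))
    return out


def name_matches(repeat_name: str, pattern: str) -> bool:
    """Prefix match with alias expansion ("THE1" matches THE1A..THE1D)."""
    return any(repeat_name.startswith(p) for p in _expand_patterns([pattern]))


def annotate_xo(
    xo: CrossoverCall,
    track: AnnotationTrack,
    radius: int = 10_000,
) -> RepeatContext:
    """Containing / flanking repeat context of one crossover call.

    When the position falls inside several (nested) annotations the dominant
    one wins: highest Smith-Waterman score, then longest, then leftmost.
    """
    pos = xo.position
    containing: list[RepeatAnnotation] = []
    left: RepeatAnnotation | None = None
    right: RepeatAnnotation | None = None
    nearby: list[str] = []
    for ann in track:
        iv = ann.interval
        if iv.contains(pos):
            containing.append(ann)
        elif iv.end <= pos:
            if left is None or iv.end > left.interval.end:
                left = ann
        elif iv.start > pos and right is None:
            right = ann
        if iv.start <= pos + radius and iv.end > pos - radius:
            if ann.repeat_name not in nearby:
                nearby.append(ann.repeat_name)

    if containing:
        best = max(
            containing,
            key=lambda a: (a.sw_score, len(a.interval), -a.interval.start),
        )
        ctx = RepeatContext(
            containing_element=best.repeat_name,
            flank_left=None,
            flank_right=None,
            context_string=best.repeat_name,
            within_10kb=nearby,
        )
    else:
        fl = (left.repeat_name, pos - left.interval.end + 1) if left else None
        fr = (right.repeat_name, right.interval.start - pos) if right else None
        ctx = RepeatContext(
            containing_element=None,
            flank_left=fl,
            flank_right=fr,
            context_string=f"{fl[0] if fl else 'none'}/{fr[0] if fr else 'none'}",
            within_10kb=nearby,
        )
    xo.context = ctx
    return ctx


def proximity_summary(
    xos: list[CrossoverCall],
    track: AnnotationTrack,
    radius: int = 10_000,
    families: list[str] | None = None,
) -> dict[str, float]:
    """Fraction of crossovers with a family member within ``radius``.

    Returns per-family fractions plus the fraction with at least one hit
    from any family ("any").  Family matching is prefix-based with alias
    expansion.
    """
    if not xos:
        raise ValueError("no crossover calls to summarize")
    families = families or ["LTR16B", "ERV3-16A3_I", "MLT1", "Charlie", "THE1"]
    hits = {fam: 0 for fam in families}
    any_hits = 0
    for xo in xos:
        pos = xo.position
        found_any = False
        for fam in families:
            for ann in track:
                iv = ann.interval
                if iv.start <= pos + radius and iv.end > pos - radius and name_matches(
                    ann.repeat_name, fam
                ):
                    hits[fam] += 1
                    found_any = True
                    break
        if found_any:
            any_hits += 1
    out = {fam: hits[fam] / len(xos) for fam in families}
    out["any"] = any_hits / len(xos)
    return out


def distance_to_feature(
    xo: CrossoverCall,
    feature: GenomicInterval,
    anchor: str = "end",
) -> int:
    """Signed distance from the crossover to a feature anchor.

    Positive when the crossover lies outside the feature beyond the anchor,
    negative when inside the feature (a call 186 bp before a gene's end is
    reported as -186).
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    pos = xo.position
    anchor_pos = feature.end - 1 if anchor == "end" else feature.start
    if feature.contains(pos):
        return -abs(anchor_pos - pos)
    if anchor == "end":
        return pos - anchor_pos if pos > anchor_pos else -(anchor_pos - pos)
    return anchor_pos - pos if pos < anchor_pos else -(pos - anchor_pos)


def scan_motif(
    seq: str,
    motif: str,
    both_strands: bool = True,
) -> list[tuple[int, str]]:
    """All (possibly overlapping) exact occurrences of a motif.

    With ``both_strands`` the reverse complement is also scanned; a hit of
    the reverse complement at position p is reported as (p, "-").
    """
    seq = seq.upper()
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    hits = [(p, "+") for p in _find_all(seq, motif)]
    if both_strands:
        rc = motif.translate(_COMPLEMENT)[::-1]
        if rc != motif:
            hits.extend((p, "-") for p in _find_all(seq, rc))
    hits.sort()
    return hits


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    start = 0
    while True:
        i = seq.find(motif, start)
        if i == -1:
            return out
        out.append(i)
        start = i + 1


def find_tsd_site(seq: str, tsd_motif: str) -> list[int]:
    """Exact positions of a target-site-duplication motif (plus strand only).

    Used to localize empty retroelement insertion sites; an occupied site
    shows the motif twice (once on each side of the insertion).
    """
    if len(tsd_motif) < 8:
        raise ValueError("TSD motif must be at least 8 nt to be specific")
    return _find_all(seq.upper(), tsd_motif.upper())
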