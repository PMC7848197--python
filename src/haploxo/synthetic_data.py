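"""Synthetic haplotype mosaics with known ground truth.

The generator emulates the statistical structure of megabase-scale MHC
haplotype assemblies: long blocks drawn from a small pool of ancestral
lineages, ~7 substitutions/kb between lineages but <2 per 100 kb within a
lineage, dimorphic retroelement indels recognizable by their flanking
element signatures, plus the assembly artifacts the SNP filters must reject
(N-runs, dense mismatch clusters, microsatellite length variants, spurious
deletions).  Every planted feature is recorded in a truth table so each
downstream stage can be scored against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AnnotationTrack,
    GenomicInterval,
    HaplotypeSequence,
    RepeatAnnotation,
)
from .marker_genotyping import IndelMarkerDefinition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated region.

    Rates are the *pairwise* divergence between two haplotypes: 7 SNPs/kb
    between lineages, 1 SNP/100 kb within a lineage (each haplotype receives
    private mutations at half the within-lineage rate).
    """

    region_length: int = 400_000
    n_lineages: int = 2
    between_lineage_rate: float = 7.0     # SNPs per kb
    within_lineage_rate: float = 1.0      # SNPs per 100 kb
    breakpoints: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_lineage_rate < 0 or self.within_lineage_rate < 0:
            raise ValueError("rates must be >= 0")
        bps = sorted(self.breakpoints)
        if bps != list(self.breakpoints):
            raise ValueError("breakpoints must be strictly increasing")
        for b in bps:
            if not (0 < b < self.region_length):
                raise ValueError("breakpoints must lie inside the region")


@dataclass
class TruthRecord:
    haplotype_id: str
    block_assignments: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    planted_snps: list[tuple[int, str, str]] = field(default_factory=list)
    marker_truth: dict[str, int] = field(default_factory=dict)
    marker_sites: dict[str, GenomicInterval] = field(default_factory=dict)
    artifact_intervals: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, per_site_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site independently with the given probability; the
    new base is uniform over the three alternatives."""
    out = codes.copy()
    hit = np.nonzero(rng.random(len(codes)) < per_site_rate)[0]
    for i in hit:
        alts = _BASES[_BASES != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return out, hit


def generate_ancestral_pool(config: SimulationConfig) -> dict[int, str]:
    """Ancestral lineage sequences: lineage 0 is uniform random; the others
    are lineage 0 mutated at the between-lineage rate."""
    if config.region_length < 1000:
        raise ValueError("region_length must be at least 1 kb")
    rng = np.random.default_rng(config.seed)
    base = _random_sequence(rng, config.region_length)
    pool = {0: base.tobytes().decode()}
    per_site = config.between_lineage_rate / 1000.0
    for lineage in range(1, config.n_lineages):
        mutated, _ = _mutate(rng, base, per_site)
        pool[lineage] = mutated.tobytes().decode()
    return pool


def build_mosaic_haplotype(
    pool: dict[int, str],
    block_assignments: list[tuple[GenomicInterval, int]],
    haplotype_id: str,
) -> tuple[HaplotypeSequence, TruthRecord]:
    """Concatenate lineage blocks into one haplotype; truth records the
    breakpoints.  Blocks must tile the region without gaps or overlaps."""
    region_length = len(next(iter(pool.values())))
    expected_start = 0
    parts: list[str] = []
    for iv, lineage in block_assignments:
        if iv.start != expected_start:
            raise ValueError(
                f"block assignments must tile the region: gap/overlap at {iv.start}"
            )
        if lineage not in pool:
            raise ValueError(f"unknown lineage {lineage}")
        parts.append(pool[lineage][iv.start : iv.end])
        expected_start = iv.end
    if expected_start != region_length:
        raise ValueError("block assignments must cover the full region")
    truth = TruthRecord(
        haplotype_id=haplotype_id,
        block_assignments=list(block_assignments),
        breakpoints=[iv.start for iv, _ in block_assignments[1:]],
    )
    return HaplotypeSequence(id=haplotype_id, seq="".join(parts)), truth


def add_private_mutations(
    hap: HaplotypeSequence,
    truth: TruthRecord,
    rate_per_100kb: float,
    rng: np.random.Generator,
) -> HaplotypeSequence:
    """Private within-lineage mutations at the given per-haplotype rate."""
    codes = np.frombuffer(hap.seq.encode(), dtype=np.uint8).copy()
    mutated, hit = _mutate(rng, codes, rate_per_100kb / 100_000.0)
    for i in hit:
        truth.planted_snps.append((int(i), hap.seq[i], chr(mutated[i])))
    return HaplotypeSequence(id=hap.id, seq=mutated.tobytes().decode(),
                             description=hap.description)


def simulate_haplotype_pair(
    config: SimulationConfig,
) -> tuple[HaplotypeSequence, HaplotypeSequence, TruthRecord, TruthRecord]:
    """Two haplotypes sharing lineage 0 outside the alternating blocks.

    Haplotype A is pure lineage 0; haplotype B switches lineage at each
    configured breakpoint, so each breakpoint is a planted SNP-density
    crossover in the A/B comparison.
    """
    pool = generate_ancestral_pool(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    L = config.region_length
    edges = [0] + list(config.breakpoints) + [L]
    blocks_a = [(GenomicInterval("hapA", 0, L), 0)]
    blocks_b = []
    for i, (s, e) in enumerate(zip(edges, edges[1:])):
        blocks_b.append((GenomicInterval("hapB", s, e), i % config.n_lineages))
    hap_a, truth_a = build_mosaic_haplotype(pool, blocks_a, "hapA")
    hap_b, truth_b = build_mosaic_haplotype(
        pool, [(iv, lin) for iv, lin in blocks_b], "hapB"
    )
    half_rate = config.within_lineage_rate / 2.0
    hap_a = add_private_mutations(hap_a, truth_a, half_rate, rng)
    hap_b = add_private_mutations(hap_b, truth_b, half_rate, rng)
    return hap_a, hap_b, truth_a, truth_b


# ---------------------------------------------------------------------------
# marker scaffolds and indel injection
# ---------------------------------------------------------------------------

_FLANK_ELEMENT_LEN = 300
_FLANK_GAP = 60
_RELIC_LEN = 450


def _cassette(
    rng: np.random.Generator,
    names: list[str],
    seq_id: str,
    lengths: list[int] | None = None,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Random sequence carrying one annotation per name, with small gaps.

    Returns (sequence, [(rel_start, rel_end, name), ...]).
    """
    parts: list[str] = []
    anns: list[tuple[int, int, str]] = []
    offset = 0
    for i, name in enumerate(names):
        gap = _random_sequence(rng, _FLANK_GAP).tobytes().decode()
        parts.append(gap)
        offset += len(gap)
        ln = lengths[i] if lengths else _FLANK_ELEMENT_LEN
        body = _random_sequence(rng, ln).tobytes().decode()
        anns.append((offset, offset + ln, name))
        parts.append(body)
        offset += ln
    return "".join(parts), anns


def _splice(
    seq: str,
    track: AnnotationTrack,
    pos: int,
    insert_seq: str,
    insert_anns: list[tuple[int, int, str]],
) -> tuple[str, AnnotationTrack]:
    """Insert sequence at pos; shift downstream annotations."""
    L = len(insert_seq)
    new_anns: list[RepeatAnnotation] = []
    for ann in track:
        iv = ann.interval
        if iv.start >= pos:
            iv = GenomicInterval(iv.seq_id, iv.start + L, iv.end + L, iv.strand)
        elif iv.end > pos:
            raise ValueError("cannot splice inside an existing annotation")
        new_anns.append(
            RepeatAnnotation(iv, ann.repeat_name, ann.repeat_class,
                             ann.pct_div, ann.sw_score, ann.rm_id)
        )
    for rel_s, rel_e, name in insert_anns:
        new_anns.append(
            RepeatAnnotation(
                GenomicInterval(track.seq_id, pos + rel_s, pos + rel_e, "+"),
                name,
                _guess_class(name),
                sw_score=1000,
            )
        )
    return seq[:pos] + insert_seq + seq[pos:], AnnotationTrack(track.seq_id, new_anns)


def _guess_class(name: str) -> str:
    if name.startswith(("Alu",)):
        return "SINE/Alu"
    if name.startswith(("L1", "L2", "L3", "HAL1")):
        return "LINE/L1"
    if name.startswith(("SVA",)):
        return "Retroposon/SVA"
    if name.startswith(("MER", "Charlie", "Tigger", "FordPrefect")):
        return "DNA/hAT-Charlie"
    return "LTR/ERV"


def plant_marker_scaffold(
    hap: HaplotypeSequence,
    track: AnnotationTrack,
    marker_defs: list[IndelMarkerDefinition],
    positions: list[int],
    rng: np.random.Generator,
) -> tuple[HaplotypeSequence, AnnotationTrack]:
    """Write each marker's flanking-element signature (and TSD site motif)
    into the sequence, leaving the insertion site itself empty.

    Positions are in the current coordinates of ``hap`` and must be given
    telomeric-to-centromeric; cassettes are spliced right-to-left so earlier
    positions stay valid.
    """
    if len(positions) != len(marker_defs):
        raise ValueError("need one position per marker definition")
    seq = hap.seq
    for mdef, pos in sorted(
        zip(marker_defs, positions), key=lambda t: -t[1]
    ):
        tel_seq, tel_anns = _cassette(rng, mdef.flank_tel, track.seq_id)
        cen_seq, cen_anns = _cassette(rng, mdef.flank_cen, track.seq_id)
        site = mdef.tsd_motif or ""
        pad = _random_sequence(rng, _FLANK_GAP).tobytes().decode()
        cassette_seq = tel_seq + pad + site + pad + cen_seq
        anns = list(tel_anns)
        cen_off = len(tel_seq) + 2 * len(pad) + len(site)
        anns.extend((s + cen_off, e + cen_off, n) for s, e, n in cen_anns)
        seq, track = _splice(seq, track, pos, cassette_seq, anns)
    return HaplotypeSequence(hap.id, seq, hap.description), track


def _locate_flanks(
    track: AnnotationTrack, mdef: IndelMarkerDefinition
) -> tuple[int, int]:
    """Find the empty site between the telomeric and centromeric flank
    signatures; returns (site_start, site_end) in current coordinates."""
    from .marker_genotyping import find_signature

    hit = find_signature(track, mdef)
    if hit is None:
        raise ValueError(f"flank signature not found for marker {mdef.name!r}")
    return hit


def inject_marker_indels(
    hap: HaplotypeSequence,
    track: AnnotationTrack,
    marker_defs: list[IndelMarkerDefinition],
    genotypes: dict[str, int],
    rng: np.random.Generator,
    truth: TruthRecord | None = None,
) -> tuple[HaplotypeSequence, AnnotationTrack, TruthRecord]:
    """Realize each marker genotype at its scaffolded site.

    Genotype 2 (present): the insertion content, with its annotations and —
    when the definition carries a TSD motif — a duplication of the site
    motif, is spliced between the flanks.  Genotype 1 (absent): the site is
    left empty, or receives the solitary relic named in ``absent_content``.
    """
    truth = truth or TruthRecord(haplotype_id=hap.id)
    seq = hap.seq
    for mdef in marker_defs:
        call = genotypes[mdef.name]
        site_start, site_end = _locate_flanks(track, mdef)
        if mdef.tsd_motif:
            tsd_pos = seq.find(mdef.tsd_motif, site_start, site_end)
            insert_at = (tsd_pos + len(mdef.tsd_motif)) if tsd_pos >= 0 else site_start
        else:
            insert_at = (site_start + site_end) // 2
        if call == 2:
            target = (mdef.size_range_present[0] + mdef.size_range_present[1]) // 2
            n = len(mdef.present_content)
            span = max(target // n, 50)
            content_seq, content_anns = _cassette(
                rng, mdef.present_content, track.seq_id, lengths=[span] * n
            )
            if mdef.tsd_motif:
                content_seq = content_seq + mdef.tsd_motif
            seq, track = _splice(seq, track, insert_at, content_seq, content_anns)
            truth.marker_sites[mdef.name] = GenomicInterval(
                hap.id, insert_at, insert_at + len(content_seq)
            )
        elif call == 1:
            if mdef.absent_content:
                relic_seq, relic_anns = _cassette(
                    rng, mdef.absent_content, track.seq_id,
                    lengths=[_RELIC_LEN] * len(mdef.absent_content),
                )
                seq, track = _splice(seq, track, insert_at, relic_seq, relic_anns)
                truth.marker_sites[mdef.name] = GenomicInterval(
                    hap.id, insert_at, insert_at + len(relic_seq)
                )
            else:
                truth.marker_sites[mdef.name] = GenomicInterval(
                    hap.id, insert_at, insert_at + 1
                )
        else:
            raise ValueError(f"genotype for {mdef.name!r} must be 1 or 2")
        truth.marker_truth[mdef.name] = call
    return HaplotypeSequence(hap.id, seq, hap.description), track, truth


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

ARTIFACT_KINDS = ("n_run", "dense_cluster", "microsat", "deletion")


@dataclass(frozen=True)
class ArtifactSpec:
    kind: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("artifact length must be positive")


def inject_artifacts(
    hap: HaplotypeSequence,
    plan: list[ArtifactSpec],
    rng: np.random.Generator,
    truth: TruthRecord | None = None,
) -> tuple[HaplotypeSequence, TruthRecord]:
    """Write assembly artifacts into a haplotype.

    ``n_run`` replaces the interval with N; ``dense_cluster`` substitutes 6
    bases inside the interval (so a partner comparison shows >5 mismatches in
    50 nt); ``microsat`` overwrites the interval with a perfect dinucleotide
    tandem; ``deletion`` removes the interval.  Intervals must not overlap;
    deletions are applied last, right to left.
    """
    truth = truth or TruthRecord(haplotype_id=hap.id)
    plan = sorted(plan, key=lambda a: a.start)
    for x, y in zip(plan, plan[1:]):
        if x.start + x.length > y.start:
            raise ValueError("overlapping artifact intervals")
    seq = list(hap.seq)
    L = len(seq)
    for art in plan:
        if art.start + art.length > L:
            raise ValueError("artifact interval outside the region")
    for art in plan:
        s, e = art.start, art.start + art.length
        if art.kind == "n_run":
            seq[s:e] = "N" * (e - s)
        elif art.kind == "dense_cluster":
            span = min(art.length, 50)
            picks = rng.choice(span, size=6, replace=False) + s
            for p in sorted(int(v) for v in picks):
                alts = [c for c in "ACGT" if c != seq[p]]
                seq[p] = alts[rng.integers(0, 3)]
        elif art.kind == "microsat":
            unit = "AC"
            fill = (unit * (art.length // 2 + 1))[: art.length]
            seq[s:e] = fill
        truth.artifact_intervals.append(
            (GenomicInterval(hap.id, s, e), art.kind)
        )
    for art in sorted(plan, key=lambda a: -a.start):
        if art.kind == "deletion":
            del seq[art.start : art.start + art.length]
    return HaplotypeSequence(hap.id, "".join(seq), hap.description), truth


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    """Flat truth table: haplotype_id, kind, start, end, payload."""
    with open(path, "w") as fh:
        fh.write("haplotype_id\tkind\tstart\tend\tpayload\n")
        for t in truths:
            for iv, lineage in t.block_assignments:
                fh.write(f"{t.haplotype_id}\tblock\t{iv.start}\t{iv.end}\t{lineage}\n")
            for pos, ref, alt in t.planted_snps:
                fh.write(f"{t.haplotype_id}\tsnp\t{pos}\t{pos + 1}\t{ref}/{alt}\n")
            for name, call in t.marker_truth.items():
                iv = t.marker_sites.get(name)
                s, e = (iv.start, iv.end) if iv else (0, 0)
                fh.write(f"{t.haplotype_id}\tmarker\t{s}\t{e}\t{name}={call}\n")
            for iv, kind in t.artifact_intervals:
                fh.write(f"{t.haplotype_id}\tartifact\t{iv.start}\t{iv.end}\t{kind}\n")
            for bp in t.breakpoints:
                fh.write(f"{t.haplotype_id}\tbreakpoint\t{bp}\t{bp}\t.\n")
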