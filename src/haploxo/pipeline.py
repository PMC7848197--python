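"""End-to-end pipeline: align -> call SNPs -> detect crossovers -> annotate
-> genotype markers, with deterministic report bundles and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    AnnotationTrack,
    GenomicInterval,
    read_fasta,
    read_repeatmasker_out,
    write_bed,
)
from .marker_genotyping import (
    genotype_marker,
    load_marker_definitions,
    marker_matrix,
    partition_lineages,
)
from .pairwise_align import anchor_align, read_block_table, write_block_table
from .repeat_association import annotate_xo
from .snp_calling import (
    FilterParams,
    apply_filters,
    call_raw_substitutions,
    counted_positions,
    snp_table,
)
from .xo_detection import (
    DensityThresholds,
    density_profile,
    detect_crossovers,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, validated on construction."""

    # filters
    cluster_max: int = 5
    cluster_window: int = 50
    n_flank: int = 50
    min_n_run: int = 3
    min_gap_run_for_flank: int = 50
    gap_flank: int = 50
    homopolymer_min: int = 8
    # density thresholds, per 100 kb
    spr_max: float = 20.0
    srr_min: float = 100.0
    # windows
    window: int = 100_000
    step: int = 10_000
    # aligner
    k: int = 31
    max_gap_fill: int = 5_000
    # annotation
    radius: int = 10_000
    # markers
    marker_file: str | None = None
    # misc
    seed: int = 0
    output_dir: str = "haploxo_out"

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if f.name != "seed" and v <= 0:
                    raise ValueError(f"PipelineConfig.{f.name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def filter_params(self) -> FilterParams:
        return FilterParams(
            cluster_max=self.cluster_max,
            cluster_window=self.cluster_window,
            n_flank=self.n_flank,
            min_n_run=self.min_n_run,
            min_gap_run_for_flank=self.min_gap_run_for_flank,
            gap_flank=self.gap_flank,
            homopolymer_min=self.homopolymer_min,
        )

    def thresholds(self) -> DensityThresholds:
        return DensityThresholds(spr_max=self.spr_max, srr_min=self.srr_min)


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    input_checksums: dict[str, str]
    record_counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload.pop("output_dir", None)  # where results land is not a parameter
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    fasta_a: str | Path,
    fasta_b: str | Path,
    rm_out_a: str | Path | None = None,
    rm_out_b: str | Path | None = None,
    config: PipelineConfig | None = None,
    alignment_table: str | Path | None = None,
) -> dict[str, object]:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory results; files are written under
    ``config.output_dir``.
    """
    config = config or PipelineConfig()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    a = _stage("read-fasta", read_fasta, fasta_a)[0]
    b = _stage("read-fasta", read_fasta, fasta_b)[0]
    track_a = track_b = None
    if rm_out_a:
        tracks = _stage("read-repeatmasker", read_repeatmasker_out, rm_out_a)
        track_a = tracks.get(a.id) or next(iter(tracks.values()))
    if rm_out_b:
        tracks = _stage("read-repeatmasker", read_repeatmasker_out, rm_out_b)
        track_b = tracks.get(b.id) or next(iter(tracks.values()))

    if alignment_table:
        aln = _stage("import-alignment", read_block_table, alignment_table)
    else:
        aln = _stage("align", anchor_align, a, b, config.k, config.max_gap_fill)
    write_block_table(aln, outdir / "alignment.tsv")

    snps, n_sites = _stage("call-snps", call_raw_substitutions, aln, a, b)
    snps = _stage(
        "apply-filters", apply_filters, snps, aln, a, b,
        track_a, track_b, config.filter_params(), n_sites,
    )
    table = snp_table(snps)
    table.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    write_bed(
        [(GenomicInterval(a.id, s.pos_a, s.pos_a + 1),
          f"{s.allele_a}/{s.allele_b}") for s in snps if s.counted],
        outdir / "snps_counted.bed",
    )

    region = GenomicInterval(a.id, 0, a.length)
    pos = counted_positions(snps)
    alleles = {
        s.pos_a: f"{s.allele_a}/{s.allele_b}" for s in snps if s.counted
    }
    profile = density_profile(
        pos, region, config.window, config.step, config.thresholds()
    )
    prof_df = pd.DataFrame(
        [
            {"start": w.interval.start, "end": w.interval.end,
             "count": w.count, "density_per_100kb": w.density_per_100kb,
             "label": w.label}
            for w in profile.rows
        ]
    )
    prof_df.to_csv(outdir / "density_profile.tsv", sep="\t", index=False)

    xos, summary = _stage(
        "detect-xo", detect_crossovers, pos, region, alleles,
        config.window, config.step, config.thresholds(),
    )
    if track_a is not None:
        for xo in xos:
            annotate_xo(xo, track_a, config.radius)
    xo_df = pd.DataFrame(
        [
            {
                "a_id": a.id,
                "b_id": b.id,
                "position_a": xo.position,
                "position_b": _project_or_na(aln, xo.position),
                "boundary_snp": xo.boundary_snp[1],
                "direction": xo.direction,
                "left_label": xo.left_run.label,
                "right_label": xo.right_run.label,
                "support_left": xo.support[0],
                "support_right": xo.support[1],
                "context": xo.context.context_string if xo.context else ".",
                "within_10kb": ";".join(xo.context.within_10kb) if xo.context else ".",
            }
            for xo in xos
        ],
        columns=[
            "a_id", "b_id", "position_a", "position_b", "boundary_snp",
            "direction", "left_label", "right_label", "support_left",
            "support_right", "context", "within_10kb",
        ],
    )
    xo_df.to_csv(outdir / "crossovers.tsv", sep="\t", index=False)
    write_bed(
        [
            (GenomicInterval(a.id, xo.position, xo.position + 1), xo.direction)
            for xo in xos
        ],
        outdir / "crossovers.bed",
    )

    genotypes = []
    if track_a is not None or track_b is not None:
        defs = load_marker_definitions(config.marker_file)
        for hap, track in ((a, track_a), (b, track_b)):
            if track is None:
                continue
            for mdef in defs:
                genotypes.append(genotype_marker(track, hap, mdef))
        if genotypes:
            mat = marker_matrix(genotypes)
            mat.to_csv(outdir / "marker_matrix.tsv", sep="\t")
            lineages = partition_lineages(genotypes)
            pd.DataFrame(
                [{"haplotype_id": l.haplotype_id, "lineage": l.lineage}
                 for l in lineages]
            ).to_csv(outdir / "lineages.tsv", sep="\t", index=False)

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=_config_hash(config),
        input_checksums={
            str(p): _sha256(p)
            for p in (fasta_a, fasta_b, rm_out_a, rm_out_b)
            if p
        },
        record_counts={
            "raw_snps": len(snps),
            "counted_snps": len(pos),
            "crossovers": len(xos),
            "marker_genotypes": len(genotypes),
        },
    )
    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %s (%s)", summary, manifest.record_counts)
    return {
        "alignment": aln,
        "snps": snps,
        "profile": profile,
        "crossovers": xos,
        "summary": summary,
        "genotypes": genotypes,
        "manifest": manifest,
    }


def _project_or_na(aln, pos: int):
    from .pairwise_align import project

    p = project(aln, pos)
    return p if p is not None else "."


def render_pip_summary(
    profile,
    xos,
    track: AnnotationTrack | None = None,
    plot_path: str | Path | None = None,
) -> str:
    """Per-window identity strip with crossover glyphs.

    Returns the pure-text rendering (one line per window); when
    ``plot_path`` is given, also writes a percentage-identity-style plot.
    """
    glyph = {"SPR": "=", "SRR": "#", "INTERMEDIATE": "~"}
    xo_positions = [xo.position for xo in xos]
    lines = []
    for w in profile.rows:
        marks = "".join(
            " X" for p in xo_positions if w.interval.start <= p < w.interval.end
        )
        lines.append(
            f"{w.interval.start:>10}-{w.interval.end:<10} "
            f"{glyph[w.label] * 20} {w.label:<12} "
            f"{w.density_per_100kb:8.1f}/100kb{marks}"
        )
    text = "\n".join(lines)
    if plot_path is not None:
        _plot_pip(profile, xos, track, plot_path)
    return text


def _plot_pip(profile, xos, track, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    color = {"SPR": "#2ca02c", "SRR": "#9467bd", "INTERMEDIATE": "#ff7f0e"}
    fig, ax = plt.subplots(figsize=(10, 3))
    for w in profile.rows:
        ax.bar(
            w.interval.start,
            w.density_per_100kb,
            width=len(w.interval),
            align="edge",
            color=color[w.label],
            alpha=0.6,
            linewidth=0,
        )
    for xo in xos:
        ax.axvline(xo.position, color="red", linestyle="--", linewidth=1)
    if track is not None:
        for ann in track:
            ax.axvspan(
                ann.interval.start, ann.interval.end, ymin=0.0, ymax=0.03,
                color="gray", alpha=0.5,
            )
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("counted SNPs / 100 kb")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
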