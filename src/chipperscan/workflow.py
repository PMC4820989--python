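"""Orchestration: simulation -> read processing -> enrichment -> scan -> QC.

Glue layer tying the pipeline stages into reproducible, seeded runs. A single
master seed deterministically derives one named stream per stage (library,
screen, reads, QC subsampling) via ``numpy``'s SeedSequence spawning, so any
run is byte-identical under the same configuration.

``run_pipeline`` is the in-memory entry point (what the examples and tests
use); ``run`` materialises a run directory with all artifacts and a manifest;
``report`` renders a Markdown summary from an existing run directory without
recomputation.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chipper_sim, enrichment, escscanner, libqc, readproc, screen_sim
from .chipper_sim import ChipperParams, LibraryPool
from .enrichment import LocusInterval
from .escscanner import ScanProfile
from .refmodel import ReferenceRegion, load_regions
from .screen_sim import ScreenConfig, ScreenResult, TruthElement

__all__ = ["PipelineResult", "RunConfig", "run_pipeline", "run", "report"]


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


@dataclass
class PipelineResult:
    """Everything one simulated screen run computes."""

    regions: list[ReferenceRegion]
    library: LibraryPool
    truth: list[TruthElement]
    screen: ScreenResult
    counts: pd.DataFrame
    annotations: pd.DataFrame
    records: pd.DataFrame
    hits: pd.DataFrame | None
    profiles: dict[tuple[int, str, str], ScanProfile]
    read_stats: readproc.ReadStats | None = None


def run_pipeline(
    regions: Sequence[ReferenceRegion],
    chipper_params: ChipperParams,
    screen_config: ScreenConfig,
    truth: Sequence[TruthElement] | None = None,
    master_seed: int = 0,
    window_size: int = 21,
    locus: LocusInterval | None = None,
    via_fastq: bool = False,
    fastq_path: str | Path | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Simulate a library and screen, then analyse it end to end.

    With ``via_fastq`` the screen is rendered to FASTQ and re-processed by the
    read-processing stage (the full round trip); otherwise the simulated count
    table is annotated by mapping its spacers directly, which is equivalent
    when the sequencing error rate is zero and considerably faster.
    """
    seeds = _derive_seeds(master_seed, 4)
    regions = list(regions)
    if truth is None:
        truth = screen_sim.default_truth_elements(regions[0])

    lib = chipper_sim.build_library(regions, chipper_params, seed=seeds[0], verbose=verbose)
    import dataclasses

    cfg_seeded = dataclasses.replace(screen_config, seed=seeds[1])
    barcodes = screen_sim.make_barcode_table(screen_config.replicates)
    screen = screen_sim.simulate_screen_counts(lib, truth, cfg_seeded, barcodes, verbose=verbose)

    read_stats = None
    if via_fastq:
        if fastq_path is None:
            raise ValueError("via_fastq requires fastq_path")
        rng = np.random.default_rng(seeds[2])
        screen_sim.emit_reads(screen, fastq_path, cfg_seeded, rng)
        table = readproc.BarcodeTable(barcodes.copy())
        counts, annotations, read_stats = readproc.process_fastq(
            fastq_path, table, regions
        )
    else:
        mapper = readproc.SpacerMapper(regions)
        counts = screen.counts
        ann_rows = []
        for sp in counts.index:
            ann = mapper.map_spacer(sp, 0)
            ann_rows.append(
                {
                    "spacer": sp,
                    "status": ann.status,
                    "region_id": ann.region_id,
                    "strand": ann.strand,
                    "spacer_start": ann.spacer_start,
                    "pam_class": ann.pam_class,
                    "last_base_pos": ann.last_base_pos,
                    "third_last_pos": ann.third_last_pos,
                }
            )
        annotations = pd.DataFrame(ann_rows).set_index("spacer")

    records = enrichment.compute_enrichment(counts, screen.samples, annotations)

    hits = None
    if locus is not None:
        hits = enrichment.call_hits(records, locus)

    region_lengths = {r.region_id: len(r) for r in regions}
    profiles = escscanner.scan_records(records, region_lengths, window_size=window_size)

    return PipelineResult(
        regions=regions,
        library=lib,
        truth=list(truth),
        screen=screen,
        counts=counts,
        annotations=annotations,
        records=records,
        hits=hits,
        profiles=profiles,
        read_stats=read_stats,
    )


@dataclass
class RunConfig:
    """File-level run configuration (YAML-serialisable)."""

    regions_fasta: str
    output_dir: str
    master_seed: int = 0
    truth: str = "default"  # 'default', 'none', or a BED path
    chipper: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    window_size: int = 21
    locus: dict | None = None  # {region_id, start, end}
    via_fastq: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        if not Path(cfg.regions_fasta).exists():
            raise FileNotFoundError(cfg.regions_fasta)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute a configured run, materialising artifacts + manifest on disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    regions = load_regions(config.regions_fasta)

    params = ChipperParams(**config.chipper)
    scfg = ScreenConfig(**config.screen)
    if config.truth == "default":
        truth: Sequence[TruthElement] | None = None
    elif config.truth == "none":
        truth = []
    else:
        truth = _truth_from_bed(config.truth)

    locus = None
    if config.locus is not None:
        locus = LocusInterval(**config.locus)

    fastq = out / "reads.fastq" if config.via_fastq else None
    result = run_pipeline(
        regions,
        params,
        scfg,
        truth=truth,
        master_seed=config.master_seed,
        window_size=config.window_size,
        locus=locus,
        via_fastq=config.via_fastq,
        fastq_path=fastq,
        verbose=True,
    )

    result.library.to_tsv(out / "library.tsv")
    result.library.to_fasta(out / "library.fasta")
    screen_sim.write_truth_bed(result.truth, out / "truth.bed")
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    result.annotations.to_csv(out / "annotations.tsv", sep="\t")
    result.screen.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    result.records.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.hits is not None:
        result.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    for (rep, b, rid), prof in result.profiles.items():
        prof.to_bedgraph(out / f"scan_rep{rep}_{b}_{rid}.bedgraph")
    if result.read_stats is not None:
        result.read_stats.to_json(out / "read_stats.json")

    # QC block
    spacer_counts = result.counts.sum(axis=1).to_dict()
    hist, _ = readproc.length_histogram(spacer_counts)
    with open(out / "length_histogram.json", "w") as fh:
        json.dump({str(k): v for k, v in hist.items()}, fh, indent=2)
    mapped = result.annotations[result.annotations["status"] == "mapped"]
    obs = libqc.neighbor_distances(
        {
            rid: grp["third_last_pos"].tolist()
            for rid, grp in mapped[mapped["pam_class"] == "NGG"].groupby("region_id")
        }
    )
    theo = libqc.theoretical_distances(regions)
    total_len = sum(len(r) for r in regions)
    cap = libqc.capacity_estimate(total_len, params.clone_count, max(result.counts.values.sum(), 1))
    libqc.qc_summary_json(out / "qc_summary.json", observed=obs, theoretical=theo, capacity=cap)

    manifest = {
        "master_seed": config.master_seed,
        "regions_fasta_sha256": _sha256(Path(config.regions_fasta)),
        "artifacts": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"[run] artifacts written to {out}", file=sys.stderr)
    return out


def _truth_from_bed(path: str | Path) -> list[TruthElement]:
    elements = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.split("\t")[:4]
            cls = name if name in screen_sim.ELEMENT_CLASSES else "five_prime_hit"
            elements.append(
                TruthElement(
                    chrom, int(start), int(end), cls,
                    screen_sim.DEFAULT_BIN_PROFILES[cls], name=name,
                )
            )
    return elements


def report(run_dir: str | Path) -> str:
    """Render a Markdown summary of an existing run directory (no recomputation)."""
    run_dir = Path(run_dir)
    lines = ["# Screen run summary", ""]
    missing = []

    qc_path = run_dir / "qc_summary.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        lines.append("## Library QC")
        for k, v in qc.items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    else:
        missing.append(qc_path.name)

    hist_path = run_dir / "length_histogram.json"
    if hist_path.exists():
        hist = json.loads(hist_path.read_text())
        lines.append("## Targeting-domain length distribution (normalised to length 20)")
        lines.append("| length | relative count |")
        lines.append("|---|---|")
        for k in sorted(hist, key=int):
            lines.append(f"| {k} | {hist[k]:.4g} |")
        lines.append("")
    else:
        missing.append(hist_path.name)

    hits_path = run_dir / "hits.tsv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path, sep="\t")
        called = hits[hits["is_hit"]]
        lines.append(f"## Hit calls: {len(called)} of {len(hits)} guides")
        for sp in called["spacer"].head(50):
            lines.append(f"- `{sp}`")
        lines.append("")

    truth_path = run_dir / "truth.bed"
    peaks = []
    for bg in sorted(run_dir.glob("scan_*.bedgraph")):
        best = (None, -1.0)
        for line in bg.read_text().splitlines():
            chrom, s, _, v = line.split("\t")
            if float(v) > best[1]:
                best = ((chrom, int(s)), float(v))
        if best[0] is not None:
            peaks.append((bg.name, *best[0], best[1]))
    if peaks:
        lines.append("## Scan peaks")
        lines.append("| track | region | position | -log10 p |")
        lines.append("|---|---|---|---|")
        truth_iv = []
        if truth_path.exists():
            for line in truth_path.read_text().splitlines():
                f = line.split("\t")
                truth_iv.append((f[0], int(f[1]), int(f[2]), f[3]))
        for name, rid, pos, val in peaks:
            inside = [
                t[3] for t in truth_iv if t[0] == rid and t[1] <= pos < t[2]
            ]
            note = f" (in {inside[0]})" if inside else ""
            lines.append(f"| {name} | {rid} | {pos}{note} | {val:.3g} |")
        lines.append("")

    if missing:
        lines.append("## Missing artifacts")
        for m in missing:
            lines.append(f"- {m}")

    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
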