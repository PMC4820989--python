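"""Synthetic FACS-sorted CRISPR tiling screen.

Converts a simulated sgRNA library plus planted "truth" cis-elements into
per-bin, per-replicate count tables and raw barcoded FASTQ reads, emulating a
reporter screen in which disrupting a miRNA's cis-regulatory elements shifts
cells from the GFP-negative bin into low/medium/high GFP bins.

The generative model, per infected cell (single viral integration):

1. the cell's guide is drawn from the library's clone frequencies;
2. Cas9 cuts with probability ``pam_activity[(variant, pam_class)]``;
3. if the cut site (the position between targeting-domain bases 17 and 18,
   i.e. the blunt cut 3 bp 5' of the PAM) falls inside a planted element, the
   cell's GFP bin is drawn from that element's ``bin_profile``; otherwise the
   cell stays GFP-negative. Junction-spanning guides are always negative.

Sequencing is a multinomial draw of ``read_depth`` reads per sorted sample
from the within-bin guide frequencies. Reads carry the amplicon structure the
real protocol sequences: spacer (targeting domain minus the leading G, which
sits in the sequencing primer), then the 20-nt scaffold prefix, then the 6-nt
sample barcode, then a constant adaptor tail, with i.i.d. substitution errors.

Default activity magnitudes and bin profiles are free modelling knobs, not
measured quantities; see the methods note.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chipper_sim import LibraryPool
from .refmodel import ReferenceRegion

__all__ = [
    "BINS",
    "SCAFFOLD_PREFIX",
    "READ_TAIL",
    "TruthElement",
    "ScreenConfig",
    "ScreenResult",
    "default_truth_elements",
    "make_barcode_table",
    "assign_effects",
    "simulate_screen_counts",
    "emit_reads",
    "write_truth_bed",
]

BINS = ("neg", "low", "med", "high")

# 20-nt scaffold immediately 3' of the spacer in every read; the first seven
# bases (G + 6 wildcards) are what the clipping pattern wildcards downstream.
SCAFFOLD_PREFIX = "GTTTTAGAGCTAGAAATAGC"
# Constant adaptor sequence following the barcode (reverse complement of the
# Illumina-side primer tail); only its presence matters to read processing.
READ_TAIL = "ATCTCGTATGCCGTCTTCTGCTTG"

ELEMENT_CLASSES = ("mature_or_pre", "five_prime_hit", "three_prime_hit")

# Default GFP-bin outcome profiles for cells cut inside an element, over
# (neg, low, med, high). Cutting the hairpin itself abolishes most miRNA
# production (med/high GFP); cutting a flanking biogenesis element gives
# partial loss (mostly low GFP).
DEFAULT_BIN_PROFILES: dict[str, tuple[float, float, float, float]] = {
    "mature_or_pre": (0.05, 0.15, 0.30, 0.50),
    "five_prime_hit": (0.15, 0.55, 0.25, 0.05),
    "three_prime_hit": (0.15, 0.55, 0.25, 0.05),
}


@dataclass(frozen=True)
class TruthElement:
    """A planted cis-element: guides cutting inside it shift the GFP bin."""

    region_id: str
    start: int  # 0-based, half-open
    end: int
    element_class: str
    bin_profile: tuple[float, float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element_class {self.element_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("element interval must be non-empty and non-negative")
        if abs(sum(self.bin_profile) - 1.0) > 1e-9:
            raise ValueError("bin_profile must sum to 1")

    def contains(self, region_id: str, pos: int) -> bool:
        return region_id == self.region_id and self.start <= pos < self.end


def default_truth_elements(region: ReferenceRegion) -> list[TruthElement]:
    """Plant a hairpin element flanked by 5' and 3' biogenesis elements.

    Geometry loosely mirrors a miRNA locus: an ~85-bp hairpin at the region
    centre, a 66-bp element ~200 bp upstream and a 60-bp element ~150 bp
    downstream (widths of the order of the deletions that validated the real
    hit regions).
    """
    L = len(region)
    if L < 1200:
        raise ValueError("region too short to plant the default element layout")
    mid = L // 2
    rid = region.region_id
    return [
        TruthElement(rid, mid - 250 - 66, mid - 250, "five_prime_hit",
                     DEFAULT_BIN_PROFILES["five_prime_hit"], name="5p_hit"),
        TruthElement(rid, mid - 43, mid + 42, "mature_or_pre",
                     DEFAULT_BIN_PROFILES["mature_or_pre"], name="hairpin"),
        TruthElement(rid, mid + 190, mid + 250, "three_prime_hit",
                     DEFAULT_BIN_PROFILES["three_prime_hit"], name="3p_hit"),
    ]


@dataclass
class ScreenConfig:
    """Screen-level parameters.

    ``pam_activity`` maps (Cas9 variant, PAM class) to per-cell cutting
    probability. The optional ``gtgg_activity`` models the handful of active
    guides whose PAM context reads GTGG (a non-NGG context wild-type Cas9 can
    use weakly); it applies when the 4-base context 3' of the protospacer is
    exactly GTGG and would otherwise score lower. Off (``None``) by default.
    """

    n_cells: int = 2_000_000
    infection_rate: float = 0.30
    replicates: int = 3
    cas9_variant: str = "WT"
    pam_activity: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("WT", "NGG"): 0.8,
            ("WT", "NGA"): 0.05,
            ("WT", "OTHER"): 0.0,
            ("VQR", "NGA"): 0.4,
            ("VQR", "NGG"): 0.05,
            ("VQR", "OTHER"): 0.0,
        }
    )
    gtgg_activity: float | None = None
    read_depth: int = 500_000
    sequencing_error_rate: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.infection_rate <= 1.0:
            raise ValueError("infection_rate must be in [0,1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for k, v in self.pam_activity.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pam_activity[{k}] outside [0,1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0,1)")

    def cut_probability(self, pam_class: str, pam_context4: str = "") -> float:
        p = self.pam_activity.get((self.cas9_variant, pam_class), 0.0)
        if (
            self.gtgg_activity is not None
            and self.cas9_variant == "WT"
            and pam_context4 == "GTGG"
        ):
            p = max(p, self.gtgg_activity)
        return p


def make_barcode_table(replicates: int = 3, seed: int = 7) -> pd.DataFrame:
    """Deterministic sample sheet: one 6-nt barcode per (replicate, bin).

    The first sample always receives the barcode CGTGAT (the one printed in
    the sequencing primer design); the rest are drawn to be mutually distinct.
    """
    rng = np.random.default_rng(seed)
    barcodes = ["CGTGAT"]
    bases = np.array(list("ACGT"))
    while len(barcodes) < replicates * len(BINS):
        cand = "".join(rng.choice(bases, size=6))
        if cand not in barcodes:
            barcodes.append(cand)
    rows = []
    i = 0
    for rep in range(1, replicates + 1):
        for b in BINS:
            rows.append(
                {"sample_id": f"rep{rep}_{b}", "replicate": rep, "bin": b,
                 "barcode": barcodes[i]}
            )
            i += 1
    return pd.DataFrame(rows)


def assign_effects(
    library: LibraryPool,
    truth: Sequence[TruthElement],
    config: ScreenConfig,
) -> np.ndarray:
    """Per-guide GFP-bin outcome distribution, shape (n_entries, 4).

    Row i is the probability over (neg, low, med, high) for a cell carrying
    library entry i: a mixture of the containing element's bin profile (weight
    = cutting probability) and the negative bin. Overlapping elements at a cut
    site raise an error — plant disjoint elements or resolve priority
    upstream.
    """
    config.validate()
    out = np.zeros((len(library.entries), len(BINS)))
    out[:, 0] = 1.0
    for i, entry in enumerate(library.entries):
        prov = entry.provenance
        if prov.junction or prov.region_id is None:
            continue
        p_cut = config.cut_probability(prov.pam_class, prov.pam_context4)
        if p_cut == 0.0:
            continue
        cut_pos = prov.third_last_pos  # base just 3' of the blunt cut
        hits = [e for e in truth if e.contains(prov.region_id, cut_pos)]
        if len(hits) > 1:
            raise ValueError(
                f"cut site {prov.region_id}:{cut_pos} lies in {len(hits)} "
                "overlapping truth elements; no priority order configured"
            )
        if not hits:
            continue
        profile = np.asarray(hits[0].bin_profile)
        out[i] = (1.0 - p_cut) * np.array([1.0, 0, 0, 0]) + p_cut * profile
    return out


@dataclass
class ScreenResult:
    """Counts plus ground truth for one simulated screen."""

    counts: pd.DataFrame  # rows = spacer sequences, columns = sample_ids
    samples: pd.DataFrame  # sample_id, replicate, bin, barcode, n_cells, empty flag
    truth: list[TruthElement]
    effect_spacers: dict[str, str]  # spacer -> element name (affected guides)


def simulate_screen_counts(
    library: LibraryPool,
    truth: Sequence[TruthElement],
    config: ScreenConfig,
    barcode_table: pd.DataFrame | None = None,
    verbose: bool = False,
) -> ScreenResult:
    """Simulate sorting and sequencing for all replicates.

    Infected cells (``n_cells * infection_rate``, single integration each) are
    multinomial over library clone frequencies; each cell's bin is drawn from
    its guide's outcome distribution; each sorted sample is sequenced as a
    multinomial of ``read_depth`` reads over within-bin guide frequencies.
    Replicates use independent child RNG streams. Samples from empty bins are
    flagged and yield all-zero counts.
    """
    config.validate()
    if barcode_table is None:
        barcode_table = make_barcode_table(config.replicates)
    bin_dist = assign_effects(library, truth, config)
    freqs = library.frequencies
    n_infected = int(round(config.n_cells * config.infection_rate))
    spacers = [e.spacer for e in library.entries]

    root = np.random.default_rng(config.seed)
    streams = root.spawn(config.replicates)

    counts = pd.DataFrame(0, index=pd.Index(spacers, name="spacer"),
                          columns=list(barcode_table["sample_id"]), dtype=np.int64)
    sample_rows = []
    for rep, rng in zip(range(1, config.replicates + 1), streams):
        cells = rng.multinomial(n_infected, freqs)
        # per-guide bin assignment of its cells
        bin_counts = np.zeros((len(spacers), len(BINS)), dtype=np.int64)
        nz = np.nonzero(cells)[0]
        for i in nz:
            bin_counts[i] = rng.multinomial(cells[i], bin_dist[i])
        for j, b in enumerate(BINS):
            sample_id = f"rep{rep}_{b}"
            total_cells = int(bin_counts[:, j].sum())
            empty = total_cells == 0
            if not empty:
                p = bin_counts[:, j] / total_cells
                reads = rng.multinomial(config.read_depth, p)
                counts[sample_id] = reads
            elif verbose:
                print(f"[screen] sample {sample_id}: empty bin", file=sys.stderr)
            sample_rows.append(
                {"sample_id": sample_id, "replicate": rep, "bin": b,
                 "n_cells": total_cells, "empty": empty}
            )
    samples = pd.DataFrame(sample_rows).merge(
        barcode_table[["sample_id", "barcode"]], on="sample_id"
    )

    effect_spacers: dict[str, str] = {}
    for entry, dist in zip(library.entries, bin_dist):
        if dist[0] < 1.0:
            prov = entry.provenance
            for e in truth:
                if e.contains(prov.region_id, prov.third_last_pos):
                    effect_spacers[entry.spacer] = e.name or e.element_class
                    break
    return ScreenResult(counts=counts, samples=samples, truth=list(truth),
                        effect_spacers=effect_spacers)


def emit_reads(
    result: ScreenResult,
    path: str | Path,
    config: ScreenConfig,
    rng: np.random.Generator | None = None,
) -> int:
    """Write the screen as FASTQ (4-line records, constant quality 'I').

    Each read is spacer + scaffold prefix + sample barcode + constant tail
    with i.i.d. substitution errors at ``sequencing_error_rate``. Returns the
    number of reads written. Raises if a sample lacks a barcode.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    err = config.sequencing_error_rate
    missing = result.samples["barcode"].isna()
    if missing.any():
        bad = result.samples.loc[missing, "sample_id"].tolist()
        raise ValueError(f"samples without barcode: {bad}")
    n_written = 0
    bases = "ACGT"
    with open(path, "w") as fh:
        for _, sample in result.samples.iterrows():
            sid, bc = sample["sample_id"], str(sample["barcode"]).upper()
            col = result.counts[sid]
            for spacer, n in col[col > 0].items():
                template = f"{spacer}{SCAFFOLD_PREFIX}{bc}{READ_TAIL}"
                for _ in range(int(n)):
                    read = template
                    if err > 0.0:
                        arr = list(read)
                        hits = np.nonzero(rng.random(len(arr)) < err)[0]
                        for h in hits:
                            arr[h] = bases[(bases.index(arr[h]) + rng.integers(1, 4)) % 4]
                        read = "".join(arr)
                    fh.write(f"@read_{n_written} {sid}\n{read}\n+\n{'I' * len(read)}\n")
                    n_written += 1
    return n_written


def write_truth_bed(truth: Sequence[TruthElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in truth:
            fh.write(
                f"{e.region_id}\t{e.start}\t{e.end}\t{e.name or e.element_class}"
                f"\t0\t+\n"
            )
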