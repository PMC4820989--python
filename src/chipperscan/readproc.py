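"""Raw screen reads -> per-sample sgRNA count tables.

Four steps, mirroring how the sequencing output of an end-derived sgRNA
library is processed:

1. **Clipping.** Every read carries the guide's targeting portion (without
   the leading G, which sits in the sequencing primer) followed by the sgRNA
   scaffold. The scaffold is located with the 20-nt wildcard pattern
   ``GNNNNNNAGCTAGAAATAGC`` (N matches any base); the spacer is everything
   before the match and the 6-nt sample barcode immediately follows it.
2. **Demultiplexing** against a barcode table (exact by default, optionally
   one mismatch when unambiguous).
3. **Mapping** each spacer to the input regions by exhaustive search over
   both strands, with 0 mismatches for all analyses or 1 mismatch for the
   neighbour-distance estimate. Unique hits get full site annotation (PAM
   class read from the reference); multi-locus spacers are kept in count
   tables but flagged so positional analyses can exclude them.
4. **Counting** by exact spacer string, which is how library complexity
   ("unique sgRNAs") is accounted.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .refmodel import ReferenceRegion, classify_pam, revcomp

__all__ = [
    "CLIP_PATTERN",
    "BarcodeTable",
    "MappingAnnotation",
    "SpacerMapper",
    "ReadStats",
    "clip_read",
    "demultiplex",
    "map_spacer",
    "build_count_table",
    "length_histogram",
    "process_fastq",
    "read_fastq_sequences",
]

# The scaffold-locating pattern: G, six wildcards, then 13 fixed scaffold
# bases. Reproduced literally from the processing protocol this emulates.
CLIP_PATTERN = "GNNNNNNAGCTAGAAATAGC"
_CLIP_RE = re.compile(CLIP_PATTERN.replace("N", "[ACGTN]"))

MIN_SPACER_LEN = 10  # shorter spacers are dropped before mapping


@dataclass
class BarcodeTable:
    """sample_id -> (replicate, bin, 6-nt barcode); barcodes must be unique."""

    samples: pd.DataFrame  # columns: sample_id, replicate, bin, barcode

    def __post_init__(self) -> None:
        df = self.samples
        required = {"sample_id", "replicate", "bin", "barcode"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"barcode table missing columns: {sorted(missing)}")
        df["barcode"] = df["barcode"].str.upper()
        if (df["barcode"].str.len() != 6).any():
            raise ValueError("all barcodes must be exactly 6 nt")
        if df["barcode"].duplicated().any():
            dup = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
            raise ValueError(f"duplicate barcodes: {dup}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in barcode table")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"barcode": str}))

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return dict(zip(self.samples["barcode"], self.samples["sample_id"]))

    def check_mismatch_radius(self, max_mismatch: int) -> None:
        """Error if two barcodes could claim the same read at this tolerance."""
        if max_mismatch == 0:
            return
        bcs = list(self.samples["barcode"])
        for i in range(len(bcs)):
            for j in range(i + 1, len(bcs)):
                d = sum(a != b for a, b in zip(bcs[i], bcs[j]))
                if d <= 2 * max_mismatch:
                    raise ValueError(
                        f"barcodes {bcs[i]} and {bcs[j]} are within the "
                        f"{max_mismatch}-mismatch radius (distance {d})"
                    )


def clip_read(read: str) -> tuple[str, str] | None:
    """Locate the scaffold pattern; return (spacer, barcode) or None.

    The spacer is the read prefix before the leftmost pattern match; the
    barcode is the 6 nt immediately after the 20-nt match. Returns ``None``
    when the pattern is absent or fewer than 6 nt remain for the barcode.
    """
    read = read.upper()
    m = _CLIP_RE.search(read)
    if m is None:
        return None
    barcode = read[m.end() : m.end() + 6]
    if len(barcode) < 6:
        return None
    return read[: m.start()], barcode


def demultiplex(
    clipped: Iterable[tuple[str, str]],
    table: BarcodeTable,
    max_barcode_mismatch: int = 0,
) -> tuple[dict[str, list[str]], int, int]:
    """Assign clipped (spacer, barcode) pairs to samples.

    Returns (per-sample spacer lists, n_unassigned, n_ambiguous). A read is
    ambiguous only in mismatch mode when >1 barcode ties at the minimum
    distance (configuration-time radius checking normally prevents this).
    """
    table.check_mismatch_radius(max_barcode_mismatch)
    lookup = table.barcode_to_sample
    out: dict[str, list[str]] = {sid: [] for sid in table.samples["sample_id"]}
    unassigned = ambiguous = 0
    for spacer, barcode in clipped:
        sid = lookup.get(barcode)
        if sid is None and max_barcode_mismatch > 0:
            hits = [
                s
                for bc, s in lookup.items()
                if sum(a != b for a, b in zip(bc, barcode)) <= max_barcode_mismatch
            ]
            if len(hits) == 1:
                sid = hits[0]
            elif len(hits) > 1:
                ambiguous += 1
                continue
        if sid is None:
            unassigned += 1
            continue
        out[sid].append(spacer)
    return out, unassigned, ambiguous


@dataclass(frozen=True, slots=True)
class MappingAnnotation:
    """Where (if anywhere) a spacer maps in the input regions."""

    status: str  # 'mapped', 'unmapped', or 'multi'
    region_id: str | None = None
    strand: str | None = None
    spacer_start: int | None = None
    spacer_len: int | None = None
    pam_seq: str | None = None
    pam_class: str | None = None
    last_base_pos: int | None = None
    third_last_pos: int | None = None
    mismatches: int | None = None


_UNMAPPED = MappingAnnotation(status="unmapped")


class SpacerMapper:
    """Exhaustive both-strand mapper over a small set of input regions.

    Builds, lazily per spacer length, a dictionary from every substring (and
    reverse-complemented substring) of the regions to its loci. A 1-mismatch
    query enumerates the spacer's 3L single-base variants against the same
    dictionary, which is exact and fast for the short, curated regions this
    pipeline targets (not a genome-scale aligner).
    """

    def __init__(self, regions: Sequence[ReferenceRegion]):
        self.regions = list(regions)
        self._by_id = {r.region_id: r for r in regions}
        self._index: dict[int, dict[str, list[tuple[str, str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, str, int]]]:
        idx = self._index.get(k)
        if idx is not None:
            return idx
        idx = {}
        for r in self.regions:
            seq = r.sequence
            for s in range(len(seq) - k + 1):
                sub = seq[s : s + k]
                idx.setdefault(sub, []).append((r.region_id, "+", s))
                idx.setdefault(revcomp(sub), []).append((r.region_id, "-", s))
        self._index[k] = idx
        return idx

    def _annotate(self, locus: tuple[str, str, int], k: int, mm: int) -> MappingAnnotation:
        region_id, strand, s = locus
        seq = self._by_id[region_id].sequence
        if strand == "+":
            pam = seq[s + k : s + k + 3]
            last, third = s + k - 1, s + k - 3
        else:
            pam = revcomp(seq[max(0, s - 3) : s]) if s >= 3 else ""
            last, third = s, s + 2
        return MappingAnnotation(
            status="mapped",
            region_id=region_id,
            strand=strand,
            spacer_start=s,
            spacer_len=k,
            pam_seq=pam if len(pam) == 3 else "",
            pam_class=classify_pam(pam),
            last_base_pos=last,
            third_last_pos=third,
            mismatches=mm,
        )

    def map_spacer(self, spacer: str, max_mismatch: int = 0) -> MappingAnnotation:
        """Map one spacer; see module docstring for the status semantics."""
        if max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        spacer = spacer.upper()
        k = len(spacer)
        if k < MIN_SPACER_LEN:
            return _UNMAPPED
        idx = self._index_for(k)
        loci = list(dict.fromkeys(idx.get(spacer, ())))
        mm_used = 0
        if not loci and max_mismatch == 1:
            seen: dict[tuple[str, str, int], None] = {}
            for i, base in enumerate(spacer):
                for alt in "ACGT":
                    if alt == base:
                        continue
                    variant = spacer[:i] + alt + spacer[i + 1 :]
                    for locus in idx.get(variant, ()):
                        seen.setdefault(locus)
            loci = list(seen)
            mm_used = 1
        if not loci:
            return _UNMAPPED
        if len(loci) > 1:
            return MappingAnnotation(status="multi", spacer_len=k, mismatches=mm_used)
        return self._annotate(loci[0], k, mm_used)


def map_spacer(
    spacer: str, regions: Sequence[ReferenceRegion], max_mismatch: int = 0
) -> MappingAnnotation:
    """One-shot convenience wrapper around :class:`SpacerMapper`."""
    return SpacerMapper(regions).map_spacer(spacer, max_mismatch)


def build_count_table(
    per_sample_spacers: Mapping[str, Sequence[str]],
    mapper: SpacerMapper | None = None,
    max_mismatch: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate identical spacers into a counts matrix + annotation frame.

    Returns ``(counts, annotations)``: counts indexed by spacer with one
    column per sample; annotations indexed identically with mapping columns
    (status '.'-filled when no mapper is given).
    """
    all_spacers = sorted({sp for lst in per_sample_spacers.values() for sp in lst})
    counts = pd.DataFrame(
        0, index=pd.Index(all_spacers, name="spacer"),
        columns=list(per_sample_spacers), dtype=np.int64
    )
    for sid, lst in per_sample_spacers.items():
        if lst:
            vc = pd.Series(lst).value_counts()
            counts.loc[vc.index, sid] = vc.values
    ann_rows = []
    for sp in all_spacers:
        if mapper is None:
            ann = _UNMAPPED
        else:
            ann = mapper.map_spacer(sp, max_mismatch)
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
    return counts, annotations


def length_histogram(spacer_counts: Mapping[str, int] | Sequence[str]) -> tuple[dict[int, float], bool]:
    """Targeting-domain length distribution normalised to the 20-base bin.

    Lengths are spacer length + 1 (the leading G counts). Returns
    ``(histogram, normalised)``; when the 20-base bin is empty the raw counts
    are returned with ``normalised=False``.
    """
    if not isinstance(spacer_counts, Mapping):
        spacer_counts = pd.Series(list(spacer_counts)).value_counts().to_dict()
    hist: dict[int, float] = {}
    for spacer, n in spacer_counts.items():
        hist[len(spacer) + 1] = hist.get(len(spacer) + 1, 0) + n
    ref = hist.get(20, 0)
    if ref == 0:
        return dict(sorted(hist.items())), False
    return {k: v / ref for k, v in sorted(hist.items())}, True


@dataclass
class ReadStats:
    """Conservation accounting: input = retained + rejected + unassigned(+ambiguous+short)."""

    n_input: int = 0
    n_clip_rejected: int = 0
    n_unassigned: int = 0
    n_ambiguous: int = 0
    n_short: int = 0
    n_retained: int = 0

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {**self.__dict__, **(extra or {})}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (optionally gzipped) 4-line FASTQ file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                yield line.strip()


def process_fastq(
    fastq_path: str | Path,
    barcode_table: BarcodeTable,
    regions: Sequence[ReferenceRegion] | None = None,
    max_mismatch: int = 0,
    max_barcode_mismatch: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, ReadStats]:
    """Full read-processing pipeline: clip, demultiplex, map, count.

    Returns (counts, annotations, stats). Spacers shorter than
    ``MIN_SPACER_LEN`` are dropped before counting (tallied in stats).
    """
    stats = ReadStats()
    clipped: list[tuple[str, str]] = []
    for seq in read_fastq_sequences(fastq_path):
        stats.n_input += 1
        res = clip_read(seq)
        if res is None:
            stats.n_clip_rejected += 1
            continue
        spacer, barcode = res
        if len(spacer) < MIN_SPACER_LEN:
            stats.n_short += 1
            continue
        clipped.append((spacer, barcode))
    per_sample, stats.n_unassigned, stats.n_ambiguous = demultiplex(
        clipped, barcode_table, max_barcode_mismatch
    )
    stats.n_retained = sum(len(v) for v in per_sample.values())
    mapper = SpacerMapper(regions) if regions is not None else None
    counts, annotations = build_count_table(per_sample, mapper, max_mismatch)
    return counts, annotations, stats
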