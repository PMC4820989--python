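"""Reference regions and exhaustive sgRNA target-site enumeration.

A tiling CRISPR screen built from random fragment ends can, in principle,
place a guide at every position of the input DNA where a protospacer plus a
3-nt PAM fits. This module holds the input regions, enumerates those sites on
both strands with PAM classification (NGG for wild-type spCas9, NGA for the
VQR variant, OTHER for everything else), and pins down the coordinate
conventions every downstream analysis uses:

* All coordinates are 0-based, half-open internally; exported files are
  1-based inclusive where the format demands it (BED stays half-open).
* ``spacer_start`` is always the leftmost plus-strand-frame coordinate of the
  protospacer, regardless of strand.
* ``last_base_pos`` / ``third_last_pos`` are the plus-frame coordinates of the
  last / third-last base of the targeting domain read 5'->3' on its own
  strand. These are the positions used for enrichment plotting and for
  neighbour-distance statistics respectively.

The full targeting domain of a guide is a leading non-genomic G plus the
genomic protospacer; the G is implicit here (sites store only genomic bases).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ReferenceRegion",
    "SgRNASite",
    "PAM_CLASSES",
    "classify_pam",
    "load_regions",
    "enumerate_sites",
    "site_density",
    "write_sites_bed",
    "write_sites_tsv",
    "revcomp",
    "random_region",
]

PAM_CLASSES = ("NGG", "NGA", "OTHER")

_VALID_RE = re.compile(r"^[ACGT]+$")
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReferenceRegion:
    """One piece of input DNA against which guides are enumerated and mapped.

    Sequences must be strictly A/C/G/T: ambiguity codes are rejected at load
    time because the input regions are short, curated sequences where an N
    would silently create phantom un-targetable positions.
    """

    region_id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.region_id:
            raise ValueError("region_id must be a non-empty string")
        if not self.sequence:
            raise ValueError(f"region {self.region_id!r}: empty sequence")
        if not _VALID_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ValueError(
                f"region {self.region_id!r}: sequence contains non-ACGT "
                f"characters {bad} (ambiguity codes are not accepted)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class SgRNASite:
    """A (region, strand, position) protospacer with its PAM classification."""

    region_id: str
    strand: str  # '+' or '-'
    spacer_start: int  # leftmost plus-frame coordinate of the protospacer
    spacer_len: int
    spacer_seq: str  # strand-oriented
    pam_seq: str  # 3 bases immediately 3' of the protospacer, strand-oriented
    pam_class: str
    last_base_pos: int
    third_last_pos: int


def classify_pam(pam_seq: str) -> str:
    """Classify a 3-nt PAM: the first base is free (N); bases 2-3 decide.

    GG -> NGG, GA -> NGA, anything else -> OTHER. Exclusive and exhaustive.
    """
    if len(pam_seq) != 3:
        return "OTHER"
    tail = pam_seq[1:]
    if tail == "GG":
        return "NGG"
    if tail == "GA":
        return "NGA"
    return "OTHER"


def random_region(
    length: int,
    seed: int | np.random.Generator | None = None,
    region_id: str = "synthetic",
) -> ReferenceRegion:
    """I.i.d. uniform-random A/C/G/T region (synthetic input DNA)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ReferenceRegion(region_id=region_id, sequence=seq)


def load_regions(fasta_path: str | Path) -> list[ReferenceRegion]:
    """Load reference regions from a (multi-record) FASTA file.

    Sequences are uppercased; record order is preserved. Raises ``ValueError``
    naming the offending record on duplicate IDs or non-ACGT characters, and
    on an empty file.
    """
    fasta_path = Path(fasta_path)
    regions: list[ReferenceRegion] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate region id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        regions.append(
            ReferenceRegion(
                region_id=rec.id,
                sequence=str(rec.seq).upper(),
                name=rec.description,
            )
        )
    if not regions:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return regions


def enumerate_sites(
    region: ReferenceRegion,
    spacer_len: int = 19,
    pam_filter: Iterable[str] | None = None,
) -> list[SgRNASite]:
    """Enumerate every possible sgRNA target site in a region, both strands.

    A site is any position where a ``spacer_len`` protospacer immediately
    followed (3' on its own strand) by a 3-nt PAM fits entirely within the
    region. ``pam_filter`` restricts to a subset of ``{"NGG","NGA","OTHER"}``
    (``None`` keeps all classes). Sites are sorted by (strand, spacer_start).
    Regions too short for protospacer+PAM yield an empty list.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    wanted = set(PAM_CLASSES) if pam_filter is None else set(pam_filter)
    bad = wanted - set(PAM_CLASSES)
    if bad:
        raise ValueError(f"unknown PAM classes in filter: {sorted(bad)}")

    seq = region.sequence
    L = len(seq)
    if L < spacer_len + 3:
        return []

    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    G, C, A, T = ord("G"), ord("C"), ord("A"), ord("T")

    sites: list[SgRNASite] = []
    rid = region.region_id

    # Plus strand: PAM triplet at [p, p+3), protospacer [p-spacer_len, p).
    p = np.arange(spacer_len, L - 2)
    if p.size:
        b2, b3 = codes[p + 1], codes[p + 2]
        cls = np.where((b2 == G) & (b3 == G), 0, np.where((b2 == G) & (b3 == A), 1, 2))
        keep = np.isin(cls, [i for i, c in enumerate(PAM_CLASSES) if c in wanted])
        for pos in p[keep]:
            s = int(pos) - spacer_len
            sites.append(
                SgRNASite(
                    region_id=rid,
                    strand="+",
                    spacer_start=s,
                    spacer_len=spacer_len,
                    spacer_seq=seq[s : s + spacer_len],
                    pam_seq=seq[pos : pos + 3],
                    pam_class=PAM_CLASSES[int(cls[pos - spacer_len])],
                    last_base_pos=s + spacer_len - 1,
                    third_last_pos=s + spacer_len - 3,
                )
            )

    # Minus strand: plus-frame PAM triplet [q, q+3) precedes protospacer
    # [q+3, q+3+spacer_len); strand-oriented PAM = revcomp(seq[q:q+3]), so its
    # bases 2-3 are the complements of seq[q+1], seq[q] reversed.
    q = np.arange(0, L - 2 - spacer_len)
    if q.size:
        # strand-oriented pam[1] == complement(seq[q+1]); pam[2] == complement(seq[q])
        m2, m3 = codes[q + 1], codes[q]
        cls = np.where((m2 == C) & (m3 == C), 0, np.where((m2 == C) & (m3 == T), 1, 2))
        keep = np.isin(cls, [i for i, c in enumerate(PAM_CLASSES) if c in wanted])
        for pos in q[keep]:
            s = int(pos) + 3
            sites.append(
                SgRNASite(
                    region_id=rid,
                    strand="-",
                    spacer_start=s,
                    spacer_len=spacer_len,
                    spacer_seq=revcomp(seq[s : s + spacer_len]),
                    pam_seq=revcomp(seq[pos : pos + 3]),
                    pam_class=PAM_CLASSES[int(cls[pos])],
                    last_base_pos=s,
                    third_last_pos=s + 2,
                )
            )

    sites.sort(key=lambda x: (x.strand, x.spacer_start))
    return sites


def site_density(
    sites: Sequence[SgRNASite], total_length_bp: int
) -> tuple[float, dict[str, float] | None]:
    """Sites per bp and per-PAM-class fractions over a region set.

    Returns ``(density, fractions)``; fractions is ``None`` (undefined) for an
    empty site list, where density is 0.
    """
    if total_length_bp <= 0:
        raise ValueError("total_length_bp must be positive")
    n = len(sites)
    if n == 0:
        return 0.0, None
    fractions = {c: 0 for c in PAM_CLASSES}
    for s in sites:
        fractions[s.pam_class] += 1
    return n / total_length_bp, {c: k / n for c, k in fractions.items()}


def write_sites_bed(sites: Iterable[SgRNASite], path: str | Path) -> None:
    """Export sites as BED6: chrom=region_id, half-open protospacer interval,
    name=spacer_seq, score=0."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.region_id}\t{s.spacer_start}\t{s.spacer_start + s.spacer_len}"
                f"\t{s.spacer_seq}\t0\t{s.strand}\n"
            )


def write_sites_tsv(sites: Iterable[SgRNASite], path: str | Path) -> None:
    """Export sites as TSV with PAM and coordinate columns (1-based positions)."""
    with open(path, "w") as fh:
        fh.write(
            "region_id\tstrand\tspacer_start\tspacer_seq\tpam_seq\tpam_class"
            "\tlast_base_pos\tthird_last_pos\n"
        )
        for s in sites:
            fh.write(
                f"{s.region_id}\t{s.strand}\t{s.spacer_start + 1}\t{s.spacer_seq}"
                f"\t{s.pam_seq}\t{s.pam_class}\t{s.last_base_pos + 1}"
                f"\t{s.third_last_pos + 1}\n"
            )
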