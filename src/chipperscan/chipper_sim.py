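"""In-silico Molecular Chipper: simulate a dense sgRNA library from DNA ends.

The wet-lab scheme being emulated: input regions are randomly ligated into
long concatemers, sonicated into 400-450 bp fragments, and ligated to an
adaptor carrying an EcoP15I recognition site followed by an 8-bp spacer and a
terminal G. EcoP15I, a type III restriction enzyme, cuts 25/27 nt downstream
of its site, so each fragment end releases 27-8 = 19 bases (top strand; 17 on
the bottom) of genomic sequence. Cloned behind the adaptor's G, every fragment
end therefore becomes a 20-base sgRNA targeting domain: G + 19 genomic bases.

This module reproduces that pipeline as a seedable sampling process with full
provenance: every released guide knows the region, strand and position it came
from (or is flagged as spanning a ligation junction), so downstream analyses
can be validated against ground truth.

Fragmentation is modeled as independent interval draws rather than a physical
partition of molecules: only fragment end positions matter downstream, and
independent draws keep the model simple and exactly seedable. Only the blunt
G-bearing adaptor end ligates to a fragment end, so each end yields exactly
one guide whose strand is determined by which end it is. The 17-base bottom
strand of the released duplex is not tracked separately; the long strand
defines the spacer, and residual length heterogeneity of the real digest is
captured by ``length_jitter``.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .refmodel import ReferenceRegion, classify_pam, revcomp

__all__ = [
    "ChipperParams",
    "Provenance",
    "EndRelease",
    "FragmentRecord",
    "Concatemer",
    "LibraryPool",
    "LibraryEntry",
    "simulate_concatemer",
    "fragment_dna",
    "release_end_sgRNAs",
    "build_library",
]


@dataclass
class ChipperParams:
    """Tunable knobs of the in-silico digest.

    ``ecop15i_cut_top``/``ecop15i_cut_bottom`` (25/27 nt) and the 8-bp adaptor
    spacer are properties of the enzyme and the printed adaptor and should not
    normally be changed; the released insert lengths are derived from them
    (27-8 = 19 long strand, 25-8 = 17 short strand). ``length_jitter`` is the
    distribution of realised insert lengths; its default mode of 19 makes the
    modal targeting domain (leading G + insert) 20 bases. The jitter weights
    are a free modelling parameter, not a measured quantity.
    """

    fragment_min: int = 400
    fragment_max: int = 450
    n_fragments: int = 200_000
    clone_count: int = 1_500_000
    ecop15i_cut_top: int = 25
    ecop15i_cut_bottom: int = 27
    adaptor_spacer_len: int = 8
    leading_base: str = "G"
    length_jitter: dict[int, float] = field(
        default_factory=lambda: {19: 0.90, 18: 0.05, 20: 0.04, 17: 0.01}
    )
    concatemer_length: int = 100_000
    seed: int | None = None

    @property
    def released_long(self) -> int:
        return self.ecop15i_cut_bottom - self.adaptor_spacer_len

    @property
    def released_short(self) -> int:
        return self.ecop15i_cut_top - self.adaptor_spacer_len

    def validate(self) -> None:
        if self.fragment_min > self.fragment_max:
            raise ValueError("fragment_min must be <= fragment_max")
        if self.fragment_min < 1:
            raise ValueError("fragment_min must be >= 1")
        total = sum(self.length_jitter.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_jitter probabilities sum to {total}, not 1")
        if any(k < 1 for k in self.length_jitter):
            raise ValueError("length_jitter lengths must be positive")
        if len(self.leading_base) != 1 or self.leading_base not in "ACGT":
            raise ValueError("leading_base must be a single DNA base")


@dataclass(frozen=True, slots=True)
class Provenance:
    """Origin of a released insert in input-region coordinates.

    ``spacer_start`` is the leftmost plus-frame coordinate of the insert;
    ``strand`` is the strand whose 5'->3' reading gives the insert sequence.
    ``junction`` marks inserts spanning a ligation junction, which have no
    single-region origin and are excluded from provenance-based analyses.
    """

    region_id: str | None
    strand: str | None
    spacer_start: int | None
    spacer_len: int
    pam_seq: str
    pam_class: str
    pam_context4: str
    last_base_pos: int | None
    third_last_pos: int | None
    junction: bool


@dataclass(frozen=True, slots=True)
class EndRelease:
    """One guide released from one fragment end by the EcoP15I digest."""

    end: str  # 'left' or 'right'
    insert_seq: str
    targeting_domain: str
    provenance: Provenance


@dataclass(slots=True)
class FragmentRecord:
    """A sonication fragment: an interval on the concatemer plus its releases."""

    concat_start: int
    length: int
    releases: tuple[EndRelease, ...] = ()

    @property
    def concat_end(self) -> int:
        return self.concat_start + self.length


@dataclass(frozen=True)
class ConcatSegment:
    region_id: str
    orientation: str  # '+' or '-'
    concat_start: int
    concat_end: int
    region_len: int


@dataclass
class Concatemer:
    """Random ligation product: concatenated regions in random orientations."""

    sequence: str
    segments: list[ConcatSegment]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def junctions(self) -> list[int]:
        """Internal ligation-junction coordinates (segment boundaries)."""
        return [s.concat_end for s in self.segments[:-1]]

    def map_interval(self, start: int, end: int, strand: str) -> tuple[str, str, int] | None:
        """Map a concatemer interval back to (region_id, strand, region_start).

        Returns ``None`` if the interval spans a ligation junction. ``strand``
        is the concatemer strand on which the insert was read; the returned
        strand composes it with the segment's ligation orientation.
        """
        import bisect

        starts = getattr(self, "_starts", None)
        if starts is None:
            starts = [s.concat_start for s in self.segments]
            object.__setattr__(self, "_starts", starts)
        i = bisect.bisect_right(starts, start) - 1
        if i < 0 or start >= self.segments[i].concat_end:
            raise ValueError(f"interval [{start},{end}) outside concatemer")
        seg = self.segments[i]
        if end > seg.concat_end:
            return None  # spans a junction
        if seg.orientation == "+":
            return seg.region_id, strand, start - seg.concat_start
        # segment holds revcomp(region): flip strand, mirror coords
        flipped = "-" if strand == "+" else "+"
        region_start = seg.region_len - (end - seg.concat_start)
        return seg.region_id, flipped, region_start


def simulate_concatemer(
    regions: Sequence[ReferenceRegion],
    target_length: int,
    rng: np.random.Generator,
) -> Concatemer:
    """Randomly ligate regions (sampled with replacement, random orientation)
    into a linear concatemer of length >= ``target_length``."""
    if not regions:
        raise ValueError("empty region set")
    max_len = max(len(r) for r in regions)
    if target_length < max_len:
        raise ValueError(
            f"target_length {target_length} shorter than longest region ({max_len})"
        )
    parts: list[str] = []
    segments: list[ConcatSegment] = []
    pos = 0
    while pos < target_length:
        region = regions[rng.integers(len(regions))]
        orient = "+" if rng.random() < 0.5 else "-"
        seq = region.sequence if orient == "+" else revcomp(region.sequence)
        parts.append(seq)
        segments.append(
            ConcatSegment(
                region_id=region.region_id,
                orientation=orient,
                concat_start=pos,
                concat_end=pos + len(seq),
                region_len=len(seq),
            )
        )
        pos += len(seq)
    return Concatemer(sequence="".join(parts), segments=segments)


def fragment_dna(
    concatemer: Concatemer,
    params: ChipperParams,
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    """Draw ``n_fragments`` sonication fragments from the concatemer.

    Starts are uniform over valid positions, lengths uniform over
    [fragment_min, fragment_max]; draws are independent (a sampling model of
    sonication breakpoints, not a partition).
    """
    params.validate()
    L = len(concatemer)
    if L < params.fragment_min:
        raise ValueError("concatemer shorter than fragment_min")
    if L <= params.fragment_max:
        raise ValueError("concatemer must be longer than fragment_max")
    n = params.n_fragments
    lengths = rng.integers(params.fragment_min, params.fragment_max + 1, size=n)
    starts = (rng.random(n) * (L - lengths + 1)).astype(np.int64)
    return [FragmentRecord(int(s), int(l)) for s, l in zip(starts, lengths)]


def _provenance_for(
    concatemer: Concatemer,
    regions_by_id: Mapping[str, ReferenceRegion],
    c_start: int,
    c_end: int,
    c_strand: str,
    k: int,
) -> Provenance:
    mapped = concatemer.map_interval(c_start, c_end, c_strand)
    if mapped is None:
        return Provenance(None, None, None, k, "", "OTHER", "", None, None, True)
    region_id, strand, s = mapped
    seq = regions_by_id[region_id].sequence
    if strand == "+":
        pam4 = seq[s + k : s + k + 4]
        last, third = s + k - 1, s + k - 3
    else:
        pam4 = revcomp(seq[max(0, s - 4) : s])
        last, third = s, s + 2
    pam = pam4[:3]
    return Provenance(
        region_id=region_id,
        strand=strand,
        spacer_start=s,
        spacer_len=k,
        pam_seq=pam if len(pam) == 3 else "",
        pam_class=classify_pam(pam),
        pam_context4=pam4 if len(pam4) == 4 else "",
        last_base_pos=last,
        third_last_pos=third,
        junction=False,
    )


def release_end_sgRNAs(
    fragment: FragmentRecord,
    concatemer: Concatemer,
    regions_by_id: Mapping[str, ReferenceRegion],
    params: ChipperParams,
    rng: np.random.Generator,
) -> tuple[EndRelease, ...]:
    """Release one guide from each end of a fragment.

    Left end: targeting domain = leading G + first k top-strand bases. Right
    end: leading G + first k bottom-strand bases (= revcomp of the last k
    top-strand bases). k is drawn per end from ``length_jitter``. Fragments
    shorter than the drawn k yield no release for that end.
    """
    lengths = np.array(sorted(params.length_jitter), dtype=int)
    probs = np.array([params.length_jitter[int(l)] for l in lengths])
    ks = lengths[rng.choice(len(lengths), size=2, p=probs)]
    releases: list[EndRelease] = []
    fs, fe = fragment.concat_start, fragment.concat_end
    seq = concatemer.sequence
    for end, k in zip(("left", "right"), ks):
        k = int(k)
        if fragment.length < k:
            continue
        if end == "left":
            insert = seq[fs : fs + k]
            prov = _provenance_for(concatemer, regions_by_id, fs, fs + k, "+", k)
        else:
            insert = revcomp(seq[fe - k : fe])
            prov = _provenance_for(concatemer, regions_by_id, fe - k, fe, "-", k)
        releases.append(
            EndRelease(
                end=end,
                insert_seq=insert,
                targeting_domain=params.leading_base + insert,
                provenance=prov,
            )
        )
    return tuple(releases)


@dataclass
class LibraryEntry:
    """One unique targeting domain in the clone pool."""

    targeting_domain: str
    count: int
    provenances: tuple[Provenance, ...]

    @property
    def spacer(self) -> str:
        return self.targeting_domain[1:]

    @property
    def provenance(self) -> Provenance:
        """Representative provenance (first non-junction one if any)."""
        for p in self.provenances:
            if not p.junction:
                return p
        return self.provenances[0]

    @property
    def ambiguous(self) -> bool:
        """True when the same domain was released from >1 distinct locus."""
        loci = {
            (p.region_id, p.strand, p.spacer_start)
            for p in self.provenances
            if not p.junction
        }
        return len(loci) > 1


@dataclass
class LibraryPool:
    """A multiset of sgRNA clones with full provenance (the simulated library)."""

    entries: list[LibraryEntry]
    clone_count: int
    n_fragments: int
    short_fragment_skips: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.array([e.count for e in self.entries], dtype=float)
        return counts / counts.sum()

    def unique_inventory(self, junction_free: bool = True) -> set[str]:
        """Set of unique targeting domains (optionally non-junction only)."""
        if not junction_free:
            return {e.targeting_domain for e in self.entries}
        return {
            e.targeting_domain
            for e in self.entries
            if any(not p.junction for p in e.provenances)
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "targeting_domain\tcount\tregion_id\tstrand\tspacer_start"
                "\tpam_class\tjunction_flag\tambiguous\n"
            )
            for e in self.entries:
                p = e.provenance
                fh.write(
                    f"{e.targeting_domain}\t{e.count}\t{p.region_id or '.'}"
                    f"\t{p.strand or '.'}"
                    f"\t{p.spacer_start if p.spacer_start is not None else '.'}"
                    f"\t{p.pam_class}\t{int(p.junction)}\t{int(e.ambiguous)}\n"
                )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, e in enumerate(self.entries):
                fh.write(f">sgRNA_{i}\n{e.targeting_domain}\n")


def build_library(
    regions: Sequence[ReferenceRegion],
    params: ChipperParams,
    seed: int | np.random.Generator | None = None,
    verbose: bool = False,
) -> LibraryPool:
    """Run the full in-silico Chipper: ligation, fragmentation, end release,
    and clone sampling.

    ``clone_count`` clones are drawn uniformly (with replacement) over all
    released ends, emulating the transformation bottleneck that fixes the
    library's composition.
    """
    params.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(params.seed if seed is None else seed)

    target = max(params.concatemer_length, max(len(r) for r in regions) + params.fragment_max + 1)
    concatemer = simulate_concatemer(regions, target, rng)
    if verbose:
        print(
            f"[chipper] concatemer {len(concatemer)} bp, "
            f"{len(concatemer.segments)} segments",
            file=sys.stderr,
        )
    fragments = fragment_dna(concatemer, params, rng)
    regions_by_id = {r.region_id: r for r in regions}

    releases: list[EndRelease] = []
    skipped = 0
    for frag in fragments:
        if frag.length < params.released_short:
            skipped += 1
            continue
        rel = release_end_sgRNAs(frag, concatemer, regions_by_id, params, rng)
        frag.releases = rel
        releases.extend(rel)
    if not releases:
        raise ValueError("no guides released; check fragment sizes")
    if verbose:
        print(
            f"[chipper] {len(releases)} released ends from {len(fragments)} fragments "
            f"({skipped} too short)",
            file=sys.stderr,
        )

    # Transformation bottleneck: sample clones uniformly over released ends.
    idx = rng.integers(0, len(releases), size=params.clone_count)
    counts = np.bincount(idx, minlength=len(releases))

    by_domain: dict[str, list] = {}
    for rel, c in zip(releases, counts):
        if c == 0:
            continue
        slot = by_domain.setdefault(rel.targeting_domain, [0, []])
        slot[0] += int(c)
        slot[1].append(rel.provenance)
    entries = [
        LibraryEntry(domain, cnt, tuple(dict.fromkeys(provs)))
        for domain, (cnt, provs) in sorted(by_domain.items())
    ]
    if verbose:
        print(f"[chipper] {len(entries)} unique targeting domains", file=sys.stderr)
    return LibraryPool(
        entries=entries,
        clone_count=params.clone_count,
        n_fragments=params.n_fragments,
        short_fragment_skips=skipped,
    )
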