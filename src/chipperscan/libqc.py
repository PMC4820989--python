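"""Library density and complexity QC.

Three questions about an end-derived tiling library:

* **Density** — how far apart are usable (NGG-PAM) target sites? Distances
  are measured between the third-last bases of the targeting domains of
  neighbouring guides, pooled across strands within each region, never across
  region boundaries. The theoretical distribution enumerates every possible
  site; the observed one uses guides actually detected (mapped with up to one
  mismatch, the one analysis where a mismatch is tolerated).
* **Saturation** — how does the number of unique guides grow with sequencing
  depth? Nested subsampling without replacement makes the curve exactly
  monotone; several independent draws give a mean and range.
* **Capacity** — given the clone count of the library and a reference read
  depth that already recovers most of its complexity, how much more input DNA
  could the same clone budget cover? fold = clones / reference reads; the
  conservative integer part of the fold times the current input length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .refmodel import ReferenceRegion, SgRNASite, enumerate_sites

__all__ = [
    "DistanceStats",
    "SaturationCurve",
    "neighbor_distances",
    "theoretical_distances",
    "saturation_curve",
    "capacity_estimate",
]


@dataclass
class DistanceStats:
    """Neighbour-distance statistics over third-last-base coordinates."""

    distances: np.ndarray
    n_coordinates: int
    empty: bool

    @property
    def median(self) -> float:
        if self.empty:
            return float("nan")
        return float(np.median(self.distances))

    @property
    def mean(self) -> float:
        if self.empty:
            return float("nan")
        return float(np.mean(self.distances))

    def histogram(self) -> dict[int, int]:
        if self.empty:
            return {}
        vals, cnts = np.unique(self.distances, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts)}

    def median_from_histogram(self) -> float:
        """Median recomputed from the histogram (independent of the array path)."""
        if self.empty:
            return float("nan")
        hist = self.histogram()
        n = sum(hist.values())
        mid_lo, mid_hi = (n - 1) // 2, n // 2
        acc = 0
        lo = hi = None
        for v in sorted(hist):
            acc += hist[v]
            if lo is None and acc > mid_lo:
                lo = v
            if hi is None and acc > mid_hi:
                hi = v
                break
        return (lo + hi) / 2

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("distance\tcount\n")
            for v, c in self.histogram().items():
                fh.write(f"{v}\t{c}\n")


def neighbor_distances(
    coordinates_by_region: Mapping[str, Sequence[int]] | Sequence[SgRNASite],
    pam_scope: Iterable[str] | None = ("NGG",),
) -> DistanceStats:
    """Successive differences of sorted third-last-base coordinates.

    Accepts either a mapping region_id -> coordinate list, or a sequence of
    sites (filtered by ``pam_scope`` first; ``None`` keeps all classes).
    Coordinates pool across strands within a region; duplicates yield
    distance-0 entries, which are retained. Fewer than 2 coordinates overall
    gives empty, flagged stats.
    """
    if not isinstance(coordinates_by_region, Mapping):
        scope = None if pam_scope is None else set(pam_scope)
        grouped: dict[str, list[int]] = {}
        for s in coordinates_by_region:
            if scope is None or s.pam_class in scope:
                grouped.setdefault(s.region_id, []).append(s.third_last_pos)
        coordinates_by_region = grouped
    diffs: list[np.ndarray] = []
    n_coords = 0
    for coords in coordinates_by_region.values():
        arr = np.sort(np.asarray(coords, dtype=int))
        n_coords += arr.size
        if arr.size >= 2:
            diffs.append(np.diff(arr))
    if not diffs:
        return DistanceStats(distances=np.empty(0, dtype=int), n_coordinates=n_coords, empty=True)
    all_diffs = np.concatenate(diffs)
    return DistanceStats(distances=all_diffs, n_coordinates=n_coords, empty=all_diffs.size == 0)


def theoretical_distances(
    regions: Sequence[ReferenceRegion],
    spacer_len: int = 19,
    pam_scope: Iterable[str] | None = ("NGG",),
) -> DistanceStats:
    """Distance stats assuming every possible site of the scope is present."""
    sites: list[SgRNASite] = []
    for r in regions:
        sites.extend(enumerate_sites(r, spacer_len=spacer_len, pam_filter=pam_scope))
    return neighbor_distances(sites, pam_scope=pam_scope)


@dataclass
class SaturationCurve:
    """Unique-guide recovery and NGG density versus subsampled read count."""

    sizes: list[int]
    unique_counts: pd.DataFrame  # rows = draws, columns = sizes
    median_ngg_distances: pd.DataFrame  # rows = draws, columns = sizes (NaN if <2 coords)
    seed: int | None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "unique_mean": self.unique_counts.mean(axis=0).values,
                "unique_min": self.unique_counts.min(axis=0).values,
                "unique_max": self.unique_counts.max(axis=0).values,
                "median_ngg_distance_mean": self.median_ngg_distances.mean(axis=0).values,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def saturation_curve(
    read_spacers: Sequence[str],
    sizes: Sequence[int],
    seed: int | None = None,
    n_draws: int = 5,
    spacer_info: Mapping[str, tuple[str, int, str]] | None = None,
) -> SaturationCurve:
    """Subsample mapped reads (without replacement, nested) and count uniques.

    ``read_spacers`` is the multiset of mapped reads (one spacer string per
    read). Within each draw a single permutation is prefix-sliced at each
    size, so every smaller subsample is contained in every larger one and
    unique counts are exactly nondecreasing. ``spacer_info`` optionally maps
    spacer -> (region_id, third_last_pos, pam_class) to also report the
    median NGG neighbour distance at each size. ``n_draws`` independent draws
    give a mean and range.
    """
    reads = np.asarray(read_spacers, dtype=object)
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[-1] > reads.size:
        raise ValueError(
            f"subsample size {sizes[-1]} exceeds total reads ({reads.size})"
        )
    rng = np.random.default_rng(seed)
    uniq = np.zeros((n_draws, len(sizes)), dtype=int)
    med = np.full((n_draws, len(sizes)), np.nan)
    for d in range(n_draws):
        perm = rng.permutation(reads.size)
        seen: set[str] = set()
        prev = 0
        for j, size in enumerate(sizes):
            seen.update(reads[perm[prev:size]])
            prev = size
            uniq[d, j] = len(seen)
            if spacer_info is not None:
                coords: dict[str, list[int]] = {}
                for sp in seen:
                    info = spacer_info.get(sp)
                    if info is not None and info[2] == "NGG":
                        coords.setdefault(info[0], []).append(info[1])
                stats = neighbor_distances(coords)
                if not stats.empty:
                    med[d, j] = stats.median
    return SaturationCurve(
        sizes=sizes,
        unique_counts=pd.DataFrame(uniq, columns=sizes),
        median_ngg_distances=pd.DataFrame(med, columns=sizes),
        seed=seed,
    )


def capacity_estimate(
    input_length_bp: int, clone_count: int, reference_reads: int
) -> tuple[float, int]:
    """How much input DNA the clone budget could cover at reference density.

    fold = clone_count / reference_reads; max_input uses the conservative
    integer part of the fold. Returns (fold, max_input_bp).
    """
    if reference_reads <= 0:
        raise ValueError("reference_reads must be positive")
    if input_length_bp <= 0 or clone_count <= 0:
        raise ValueError("input_length_bp and clone_count must be positive")
    fold = clone_count / reference_reads
    return fold, int(np.floor(fold)) * input_length_bp


def qc_summary_json(
    path: str | Path,
    observed: DistanceStats | None = None,
    theoretical: DistanceStats | None = None,
    saturation: SaturationCurve | None = None,
    capacity: tuple[float, int] | None = None,
) -> None:
    """Bundle the QC quantities into one JSON document."""
    payload: dict = {}
    if observed is not None:
        payload["observed_median_distance"] = None if observed.empty else observed.median
        payload["observed_n_coordinates"] = observed.n_coordinates
    if theoretical is not None:
        payload["theoretical_median_distance"] = (
            None if theoretical.empty else theoretical.median
        )
    if saturation is not None:
        payload["saturation"] = saturation.summary().to_dict(orient="records")
    if capacity is not None:
        payload["capacity_fold"] = capacity[0]
        payload["capacity_max_input_bp"] = capacity[1]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
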