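"""Window-product cluster statistic for enriched-sgRNA scanning (ESCScanner).

A true cis-element disrupted by Cas9 shows up as a *cluster* of enriched
guides, whereas an off-target artifact enriches an isolated guide. The scan
statistic captures this: fit a normal null N(mu, sigma) to the log2 enrichment
scores of all NGG-PAM guides in a sample, convert each guide's score to an
upper-tail probability p_i = 1 - Phi((score - mu)/sigma), and slide a 21-bp
window (10 bp each side of a centre position) along each region. The window
statistic is the product of the member guides' tail probabilities, reported
as -log10(product) = sum of -log10(p_i); an empty window has product 1 and
value 0. Several independently enriched guides in one window therefore
compound, while one strong guide alone cannot dominate.

Membership is by the last-targeting-base position of each unique guide; both
strands pool into the same window. Windows are truncated at region edges
(effectively a smaller window there). Values are raw -log10 probabilities
with no multiple-testing calibration, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "P_FLOOR",
    "NullModel",
    "ScanProfile",
    "fit_null",
    "tail_probability",
    "scan_region",
    "scan_records",
]

P_FLOOR = 1e-300  # keeps -log10 finite for extreme scores


@dataclass(frozen=True)
class NullModel:
    """Normal null for enrichment scores: mu, sigma (sample SD, n-1), n_fit."""

    mu: float
    sigma: float
    n_fit: int
    scope: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0 (degenerate null)")
        if self.n_fit < 3:
            raise ValueError("null model requires >= 3 scores")


@dataclass
class ScanProfile:
    """-log10 window-product probabilities along one region.

    ``values[c]`` is the statistic for the window centred at position ``c``;
    ``member_counts[c]`` the number of unique guides in that window.
    """

    region_id: str
    window_size: int
    values: np.ndarray
    member_counts: np.ndarray

    @property
    def peak_position(self) -> int:
        return int(np.argmax(self.values))

    @property
    def peak_value(self) -> float:
        return float(self.values.max())

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for pos, v in enumerate(self.values):
                if v != 0.0:
                    fh.write(f"{self.region_id}\t{pos}\t{pos + 1}\t{v:.6g}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("region_id\tposition\tneg_log10_p\tn_members\n")
            for pos, (v, m) in enumerate(zip(self.values, self.member_counts)):
                fh.write(f"{self.region_id}\t{pos + 1}\t{v:.6g}\t{int(m)}\n")


def fit_null(scores: Sequence[float], scope: str = "") -> NullModel:
    """Fit the normal null: sample mean and SD (n-1 denominator).

    Raises on fewer than 3 finite scores or zero variance.
    """
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError(f"need >= 3 finite scores to fit a null, got {arr.size}")
    sigma = float(arr.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("all scores identical: degenerate null")
    return NullModel(mu=float(arr.mean()), sigma=sigma, n_fit=int(arr.size), scope=scope)


def tail_probability(score: float | np.ndarray, null: NullModel) -> float | np.ndarray:
    """Upper-tail probability of the null at ``score``, floored at 1e-300."""
    p = sps.norm.sf(score, loc=null.mu, scale=null.sigma)
    p = np.maximum(p, P_FLOOR)
    return float(p) if np.isscalar(score) else p


def scan_region(
    region_length: int,
    positions: Sequence[int],
    scores: Sequence[float],
    null: NullModel,
    region_id: str = "",
    window_size: int = 21,
) -> ScanProfile:
    """Scan one region: window product of member tail probabilities.

    ``positions`` are last-targeting-base coordinates (0-based) of unique
    guides; ``scores`` their log2 enrichment values. All guides at a position
    contribute (best-per-position collapsing is a plotting rule, not a scan
    rule). Windows are ``[c - h, c + h]`` with ``h = (window_size - 1) // 2``,
    intersected with the region. ``window_size`` must be odd.
    """
    if window_size % 2 == 0 or window_size < 1:
        raise ValueError("window_size must be a positive odd integer")
    positions = np.asarray(positions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if positions.shape != scores.shape:
        raise ValueError("positions and scores must have equal length")
    if np.any((positions < 0) | (positions >= region_length)):
        raise ValueError("guide position outside region")

    half = (window_size - 1) // 2
    contrib = np.zeros(region_length)
    counts = np.zeros(region_length, dtype=int)
    if positions.size:
        p = tail_probability(scores, null)
        neg_log = -np.log10(p)
        np.add.at(contrib, positions, neg_log)
        np.add.at(counts, positions, 1)

    # Sliding-window sums via padded cumulative sums; truncation at edges
    # falls out of clipping the window bounds.
    csum = np.concatenate([[0.0], np.cumsum(contrib)])
    ccnt = np.concatenate([[0], np.cumsum(counts)])
    centers = np.arange(region_length)
    lo = np.clip(centers - half, 0, region_length)
    hi = np.clip(centers + half + 1, 0, region_length)
    values = csum[hi] - csum[lo]
    member_counts = ccnt[hi] - ccnt[lo]
    values[member_counts == 0] = 0.0
    return ScanProfile(
        region_id=region_id,
        window_size=window_size,
        values=values,
        member_counts=member_counts,
    )


def scan_records(
    records: pd.DataFrame,
    region_lengths: dict[str, int],
    window_size: int = 21,
    pam_filter: Iterable[str] = ("NGG",),
    trim_fraction: float = 0.0,
) -> dict[tuple[int, str, str], ScanProfile]:
    """Scan all (replicate, bin, region) combinations in an enrichment frame.

    The null is fitted per (replicate, bin) on the scores of every uniquely
    mapped guide whose PAM class is in ``pam_filter`` — including negative and
    floored scores. ``trim_fraction`` optionally drops that fraction from each
    tail before fitting (central-quantile fit; off by default). Returns
    ``{(replicate, bin, region_id): ScanProfile}``.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    pam_filter = set(pam_filter)
    ok = records[
        (records["status"] == "mapped") & (records["pam_class"].isin(pam_filter))
    ]
    profiles: dict[tuple[int, str, str], ScanProfile] = {}
    for (rep, b), grp in ok.groupby(["replicate", "bin"]):
        fit_scores = grp["log2_enrichment"].to_numpy()
        if trim_fraction > 0.0:
            lo, hi = np.quantile(fit_scores, [trim_fraction, 1.0 - trim_fraction])
            fit_scores = fit_scores[(fit_scores >= lo) & (fit_scores <= hi)]
        null = fit_null(fit_scores, scope=f"rep{rep}/{b}")
        for rid, rgrp in grp.groupby("region_id"):
            profiles[(rep, b, rid)] = scan_region(
                region_length=region_lengths[rid],
                positions=rgrp["last_base_pos"].to_numpy(dtype=int),
                scores=rgrp["log2_enrichment"].to_numpy(),
                null=null,
                region_id=rid,
                window_size=window_size,
            )
    return profiles
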