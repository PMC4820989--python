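"""Floored log2 enrichment scoring, positional tracks, and hit calling.

Read counts are normalised to frequencies by the total mapped reads of each
sample. The enrichment of a guide in a GFP-positive bin is

    log2( freq_positive / freq_negative )

computed within a biological replicate, after flooring: the negative-bin
frequency is floored at 6.25e-7 and the positive-bin frequency at 1e-8, which
removes division-by-zero and log-of-zero degeneracies and caps the score a
never-detected guide can receive (a guide absent from the positive bin always
scores below zero). Floors apply to frequencies, never to counts.

Hit calling uses four criteria: a guide is a hit when (its log2 enrichment
exceeds 2 in the high- or med-GFP bin in at least two replicates, OR exceeds
2 in the low-GFP bin in at least two replicates) AND it targets an NGG-PAM
site AND it lies within the target locus. "High or med" is evaluated per
replicate (a replicate qualifies when either bin exceeds the threshold), then
qualifying replicates are counted — the weakest reading consistent with the
criteria, and configurable.

Positional tracks follow the plotting convention of the source screen design:
one value per last-targeting-base position, keeping the best-scoring guide at
each position, restricted to NGG-PAM guides and positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NEG_FLOOR",
    "POS_FLOOR",
    "HIT_THRESHOLD",
    "MIN_QUALIFYING_REPLICATES",
    "POSITIVE_BINS",
    "sample_frequencies",
    "enrichment_score",
    "compute_enrichment",
    "positional_track",
    "call_hits",
    "write_bedgraph",
]

NEG_FLOOR = 6.25e-7  # minimal frequency in neg-GFP samples
POS_FLOOR = 1e-8  # minimal frequency in GFP-positive samples
HIT_THRESHOLD = 2.0  # log2 enrichment must strictly exceed this
MIN_QUALIFYING_REPLICATES = 2
POSITIVE_BINS = ("low", "med", "high")


def sample_frequencies(
    counts: pd.DataFrame, annotations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample read frequencies (count / total mapped reads of the sample).

    When annotations are given, the denominator is the total over rows whose
    status is not 'unmapped' (multi-mappers count as mapped, as an aligner
    would report them); unmapped rows receive frequency 0. Empty samples
    (total 0) yield all-zero frequency columns.
    """
    if annotations is not None:
        mapped_mask = (annotations["status"] != "unmapped").reindex(counts.index, fill_value=False)
    else:
        mapped_mask = pd.Series(True, index=counts.index)
    eff = counts.where(mapped_mask, 0)
    totals = eff.sum(axis=0)
    freqs = eff.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    return freqs


def enrichment_score(
    freq_pos: float | np.ndarray, freq_neg: float | np.ndarray
) -> float | np.ndarray:
    """Floored log2 enrichment of a positive-bin frequency over the negative."""
    fp = np.maximum(freq_pos, POS_FLOOR)
    fn = np.maximum(freq_neg, NEG_FLOOR)
    out = np.log2(fp / fn)
    return float(out) if np.isscalar(freq_pos) and np.isscalar(freq_neg) else out


def compute_enrichment(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long-form enrichment records: one row per (spacer, replicate, bin).

    ``samples`` must carry sample_id, replicate and bin columns with one
    'neg' sample per replicate. Site annotation columns are joined in when
    available.
    """
    freqs = sample_frequencies(counts, annotations)
    recs = []
    for rep, grp in samples.groupby("replicate"):
        by_bin = dict(zip(grp["bin"], grp["sample_id"]))
        if "neg" not in by_bin:
            raise ValueError(f"replicate {rep} has no neg-GFP sample")
        f_neg = freqs[by_bin["neg"]]
        for b in POSITIVE_BINS:
            if b not in by_bin:
                continue
            f_pos = freqs[by_bin[b]]
            score = enrichment_score(f_pos.values, f_neg.values)
            recs.append(
                pd.DataFrame(
                    {
                        "spacer": counts.index,
                        "replicate": rep,
                        "bin": b,
                        "freq_pos": f_pos.values,
                        "freq_neg": f_neg.values,
                        "log2_enrichment": score,
                    }
                )
            )
    records = pd.concat(recs, ignore_index=True)
    if annotations is not None:
        records = records.merge(
            annotations.reset_index()[
                ["spacer", "status", "region_id", "strand", "pam_class",
                 "last_base_pos", "third_last_pos"]
            ],
            on="spacer",
            how="left",
        )
    return records


def positional_track(
    records: pd.DataFrame,
    pam_filter: Iterable[str] = ("NGG",),
    positive_only: bool = True,
) -> pd.DataFrame:
    """Best score per last-base position (one track per region in the frame).

    Keeps uniquely mapped guides with a PAM class in ``pam_filter``; at each
    (region, position), the guide with the best enrichment score wins; scores
    <= 0 are dropped when ``positive_only``. The winning guide's strand is
    retained (plotting colours sense/antisense differently). Returns a frame
    with region_id, position (last_base_pos), score, strand, spacer.
    """
    pam_filter = set(pam_filter)
    ok = records[
        (records["status"] == "mapped") & (records["pam_class"].isin(pam_filter))
    ].copy()
    if positive_only:
        ok = ok[ok["log2_enrichment"] > 0]
    if ok.empty:
        return pd.DataFrame(
            columns=["region_id", "position", "score", "strand", "spacer"]
        )
    idx = ok.groupby(["region_id", "last_base_pos"])["log2_enrichment"].idxmax()
    best = ok.loc[idx]
    return (
        best.rename(
            columns={"last_base_pos": "position", "log2_enrichment": "score"}
        )[["region_id", "position", "score", "strand", "spacer"]]
        .sort_values(["region_id", "position"])
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class LocusInterval:
    """Target-locus filter: guides must map within this interval to be hits."""

    region_id: str
    start: int  # 0-based, half-open
    end: int

    def contains(self, region_id: str | None, pos: int | None) -> bool:
        return (
            region_id == self.region_id
            and pos is not None
            and self.start <= pos < self.end
        )


def call_hits(
    records: pd.DataFrame,
    locus: LocusInterval,
    threshold: float = HIT_THRESHOLD,
    min_replicates: int = MIN_QUALIFYING_REPLICATES,
) -> pd.DataFrame:
    """Apply the four hit criteria across replicates.

    Requires records from >= 2 replicates (the replicate-count criteria are
    undefined otherwise). Returns one row per spacer with the four boolean
    flags and the derived ``is_hit``; the threshold is a strict inequality.
    """
    n_reps = records["replicate"].nunique()
    if n_reps < 2:
        raise ValueError(
            f"hit criteria require >= 2 replicates, got {n_reps}"
        )
    wide = records.pivot_table(
        index="spacer", columns=["replicate", "bin"], values="log2_enrichment",
        aggfunc="max",
    )
    reps = sorted(records["replicate"].unique())

    def _bin_col(rep: int, b: str) -> pd.Series:
        if (rep, b) in wide.columns:
            return wide[(rep, b)].fillna(-np.inf)
        return pd.Series(-np.inf, index=wide.index)

    highmed_n = sum(
        (
            np.maximum(_bin_col(rep, "high"), _bin_col(rep, "med")) > threshold
        ).astype(int)
        for rep in reps
    )
    low_n = sum((_bin_col(rep, "low") > threshold).astype(int) for rep in reps)

    first = records.drop_duplicates("spacer").set_index("spacer").reindex(wide.index)
    is_ngg = (first["pam_class"] == "NGG") & (first["status"] == "mapped")
    in_locus = (
        (first["status"] == "mapped")
        & (first["region_id"] == locus.region_id)
        & (first["last_base_pos"] >= locus.start)
        & (first["last_base_pos"] < locus.end)
    )
    highmed_ok = highmed_n >= min_replicates
    low_ok = low_n >= min_replicates
    return pd.DataFrame(
        {
            "spacer": wide.index,
            "highmed_2reps": highmed_ok.values,
            "low_2reps": low_ok.values,
            "is_NGG": is_ngg.fillna(False).values,
            "in_target_locus": in_locus.fillna(False).values,
            "is_hit": ((highmed_ok | low_ok) & is_ngg.fillna(False) & in_locus.fillna(False)).values,
        }
    ).reset_index(drop=True)


def write_bedgraph(
    track: pd.DataFrame, path: str | Path, value_col: str = "score"
) -> None:
    """Write a positional track as bedGraph (half-open single-base intervals)."""
    with open(path, "w") as fh:
        for _, r in track.iterrows():
            pos = int(r["position"])
            fh.write(f"{r['region_id']}\t{pos}\t{pos + 1}\t{r[value_col]:.6g}\n")
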