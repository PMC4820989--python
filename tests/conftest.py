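"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from chipperscan import chipper_sim, enrichment, refmodel, screen_sim, workflow

BASES = "ACGT"


def revcomp_oracle(seq: str) -> str:
    """Independent reverse complement (Biopython, not the package's own)."""
    return str(Seq(seq).reverse_complement())


def brute_force_sites(seq: str, spacer_len: int, classes: set[str] | None = None):
    """Window-scan oracle for site enumeration, independent of the package.

    Scans every window of each oriented strand and maps coordinates back to
    the plus frame by hand. Returns a set of
    (strand, spacer_start, spacer_seq, pam_seq, pam_class) tuples.
    """

    def classify(pam: str) -> str:
        if pam[1] == "G" and pam[2] == "G":
            return "NGG"
        if pam[1] == "G" and pam[2] == "A":
            return "NGA"
        return "OTHER"

    out = set()
    L = len(seq)
    for strand, oriented in (("+", seq), ("-", revcomp_oracle(seq))):
        for i in range(L - spacer_len - 3 + 1):
            spacer = oriented[i : i + spacer_len]
            pam = oriented[i + spacer_len : i + spacer_len + 3]
            cls = classify(pam)
            if classes is not None and cls not in classes:
                continue
            start = i if strand == "+" else L - (i + spacer_len)
            out.add((strand, start, spacer, pam, cls))
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def screen_region():
    """A 10-kb synthetic locus used by end-to-end screen fixtures."""
    return refmodel.random_region(10_000, seed=11, region_id="mir_locus")


@pytest.fixture(scope="session")
def small_chipper_params():
    return chipper_sim.ChipperParams(
        n_fragments=20_000, clone_count=100_000, concatemer_length=60_000
    )


@pytest.fixture(scope="session")
def screen_pipeline(screen_region, small_chipper_params):
    """One fully analysed simulated screen, shared across tests."""
    truth = screen_sim.default_truth_elements(screen_region)
    cfg = screen_sim.ScreenConfig(n_cells=500_000, read_depth=200_000)
    locus = enrichment.LocusInterval(screen_region.region_id, 0, len(screen_region))
    return workflow.run_pipeline(
        [screen_region],
        small_chipper_params,
        cfg,
        truth=truth,
        master_seed=5,
        locus=locus,
    )
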