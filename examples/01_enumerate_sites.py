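"""Enumerate sgRNA target sites in a region and measure their density.

Builds a random 50-kb piece of DNA, enumerates every position where a
19-base protospacer plus a 3-nt PAM fits (both strands), and reports how
densely NGG-PAM sites — the ones wild-type spCas9 can use — tile the
sequence. On random DNA the chance of GG at the two fixed PAM positions is
1/16 per strand, so pooling strands gives about one NGG site every 8 bp.
"""

from chipperscan.libqc import neighbor_distances
from chipperscan.refmodel import enumerate_sites, random_region, site_density

region = random_region(50_000, seed=1, region_id="demo")

all_sites = enumerate_sites(region, spacer_len=19)
ngg = enumerate_sites(region, spacer_len=19, pam_filter={"NGG"})

density, fractions = site_density(all_sites, len(region))
print(f"total sites (all PAM classes): {len(all_sites)}  ({density:.2f}/bp)")
print("PAM class fractions:", {k: round(v, 3) for k, v in fractions.items()})

stats = neighbor_distances(ngg)
print(f"NGG sites: {len(ngg)}")
print(f"NGG neighbour distances: mean {stats.mean:.2f} bp, median {stats.median:.0f} bp")
print("-> one usable wild-type Cas9 site roughly every 8 bp of input DNA")
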