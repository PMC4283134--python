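"""Published descriptors of ten Nup98-family FG domains.

Reference values for the ten experimentally characterised Nup98 FG
domains spanning the major eukaryotic clades: molecular weight, domain
length, FG motif count, estimated critical (saturation) concentration
for phase separation, estimated intra-particle concentration, NQ content,
and the overall FG dipeptide density.  Values follow the published
rounding (molecular weights to 2 significant figures, concentrations to
1-2 significant figures).

These constants let the consistency of the derived columns be checked
(density = 100 * motifs / length; mass = molar x molar mass; motif
concentration = molar x motifs per molecule) without any sequence
download.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DomainDescriptor:
    name: str
    organism: str
    mw_kda: float
    length: int
    n_fg_motifs: int
    critical_nM: float
    critical_ug_ml: float
    critical_motif_uM: float
    intra_particle_mg_ml: float
    nq_content_pct: float
    fg_density_per_100aa: float  # published overall FG dipeptide density


REFERENCE_DOMAINS: tuple[DomainDescriptor, ...] = (
    DomainDescriptor("HsNup98", "Homo sapiens",
                     49, 500, 39, 25, 1, 1, 175, 11, 7.8),
    DomainDescriptor("BfNup98", "Branchiostoma floridae",
                     46, 479, 40, 20, 1, 1, 200, 8, 8.4),
    DomainDescriptor("DmNup98", "Drosophila melanogaster",
                     56, 581, 46, 200, 10, 9, 300, 10, 7.9),
    DomainDescriptor("CeNup98", "Caenorhabditis elegans",
                     48, 494, 36, 700, 40, 25, 300, 18, 7.3),
    DomainDescriptor("ScNup100", "Saccharomyces cerevisiae",
                     58, 578, 43, 175, 10, 7.5, 275, 28, 7.4),
    DomainDescriptor("ScNup116", "Saccharomyces cerevisiae",
                     65, 737, 47, 700, 50, 33, 350, 26, 6.4),
    DomainDescriptor("DdNup220", "Dictyostelium discoideum",
                     68, 719, 56, 125, 10, 7, 300, 12, 7.8),
    DomainDescriptor("AtNup98B", "Arabidopsis thaliana",
                     66, 668, 52, 25, 1, 1.5, 200, 13, 7.8),
    DomainDescriptor("TtMacNup98A", "Tetrahymena thermophila",
                     61, 666, 42, 25, 1, 1, 175, 18, 6.3),
    DomainDescriptor("TbNup158", "Trypanosoma brucei",
                     50, 565, 58, 300, 15, 17.5, 250, 12, 10.3),
)

#: Rows whose printed critical-concentration triples are mutually
#: consistent at the published 1-2 significant-figure rounding.  The
#: CeNup98 and AtNup98B mass columns deviate further from the product of
#: the printed molar value and molar mass and are only checked loosely.
CONSISTENT_ROWS = ("HsNup98", "BfNup98", "DmNup98", "ScNup100", "ScNup116",
                   "DdNup220", "TbNup158")
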