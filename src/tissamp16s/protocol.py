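"""Two-step PCR library layout: primer sequences and product-length arithmetic.

The library is built with two PCRs. PCR-1 amplifies the V3-V4 region of the
16S rDNA gene with fusion primers (partial sequencing-adapter tail + 16S
primer). PCR-2 extends the partial adapters to full P5/P7, adding the 6-base
sample index and a 6-base spacer on the P7 side.
"""

from __future__ import annotations

from ._seq import reverse_complement

# 16S-specific parts of the PCR-1 fusion primers (V3-V4 region)
FORWARD_16S_PRIMER = "TCCTACGGGAGGCAGCAGT"
REVERSE_16S_PRIMER = "GGACTACCAGGGTATCTAATCCTGTT"

# partial adapter tails carried by the PCR-1 fusion primers
PCR1_FORWARD_TAIL = "CTTTCCCTACACGACGCTCTTCCGATCT"
PCR1_REVERSE_TAIL = "GGAGTTCAGACGTGTGCTCTTCCGATCT"

# PCR-2 forward primer: P5 extension + sequence targeting the forward tail
PCR2_FORWARD_ADDED = "AATGATACGGCGACCACCGAGATCTACACT"
# PCR-2 reverse primer layout: P7 extension - index - spacer - tail target
PCR2_REVERSE_ADDED = "CAAGCAGAAGACGGCATACGAGAT"
PCR2_INDEX_LENGTH = 6
PCR2_SPACER = "GTGACT"

#: length of the sequenced 16S region (E. coli reference coordinates)
REGION_LENGTH = 467
#: printed PCR-1 product length (region + fusion-primer tails)
PCR1_PRODUCT_LENGTH = 522


def reverse_site_on_plus_strand() -> str:
    """The reverse-primer binding site as it appears on the amplicon's
    plus strand (reverse complement of the reverse primer)."""
    return reverse_complement(REVERSE_16S_PRIMER)


def pcr2_product_length(pcr1_length: int = PCR1_PRODUCT_LENGTH) -> int:
    """Final library fragment length after PCR-2.

    PCR-2 adds the remaining P5 segment on one side and the remaining P7
    segment, the sample index and the spacer on the other; the segment
    lengths are derived from the primer sequences themselves.
    """
    return (
        pcr1_length
        + len(PCR2_FORWARD_ADDED)
        + len(PCR2_REVERSE_ADDED)
        + PCR2_INDEX_LENGTH
        + len(PCR2_SPACER)
    )
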