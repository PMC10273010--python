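"""Published annotation tables for the two Pylorgus mitogenomes
(GenBank OP793792, 15,174 bp; OQ064783, 15,399 bp), transcribed from the
deposited records' feature layouts.

Row format: (gene, start, end, strand, direction, printed_intergenic,
start/stop codons).  ``printed_intergenic`` is the intergenic-nucleotide
value as published for the row's gene relative to the preceding gene; it is
kept verbatim so ledgers recomputed from the coordinates can be checked
against it.  Note: the OQ064783 trnY row publishes 10, while its own
coordinates (trnC ends 1297, trnY starts 1305) imply 7 — a known internal
inconsistency in the published table.
"""

from __future__ import annotations

from .genome_model import Direction, GeneFeature
from .vocabulary import GENE_TYPES

PORRECTUS_ACCESSION = "OP793792"
PORRECTUS_LENGTH = 15174

SORDIDUS_ACCESSION = "OQ064783"
SORDIDUS_LENGTH = 15399

Row = tuple[str, int, int, str, str, int, str]

PORRECTUS_TABLE: tuple[Row, ...] = (
    ("trnI",      1,    64, "N", "forward",   0, ""),
    ("trnQ",     62,   130, "J", "reverse",  -3, ""),
    ("trnM",    131,   200, "N", "forward",   0, ""),
    ("nad2",    201,  1187, "N", "forward",   0, "ATT/TAA"),
    ("trnW",   1178,  1241, "N", "forward", -10, ""),
    ("trnC",   1234,  1296, "J", "reverse",  -8, ""),
    ("trnY",   1303,  1370, "J", "reverse",   6, ""),
    ("cox1",   1374,  2907, "N", "forward",   3, "TTG/T-"),
    ("trnL2",  2908,  2972, "N", "forward",   0, ""),
    ("cox2",   2973,  3648, "N", "forward",   0, "ATA/T-"),
    ("trnK",   3649,  3713, "N", "forward",   0, ""),
    ("trnD",   3714,  3774, "N", "forward",   0, ""),
    ("atp8",   3775,  3933, "N", "forward",   0, "ATA/TAA"),
    ("atp6",   3927,  4592, "N", "forward",  -7, "ATG/TAA"),
    ("cox3",   4601,  5378, "N", "forward",   8, "ATT/T-"),
    ("trnG",   5379,  5443, "N", "forward",   0, ""),
    ("nad3",   5444,  5797, "N", "forward",   0, "ATA/TAG"),
    ("trnA",   5796,  5860, "N", "forward",  -2, ""),
    ("trnR",   5861,  5920, "N", "forward",   0, ""),
    ("trnN",   5923,  5990, "N", "forward",   2, ""),
    ("trnS1",  5990,  6058, "N", "forward",  -1, ""),
    ("trnE",   6058,  6121, "N", "forward",  -1, ""),
    ("trnF",   6122,  6184, "J", "reverse",   0, ""),
    ("nad5",   6185,  7882, "J", "reverse",   0, "ATT/TAA"),
    ("trnH",   7886,  7949, "J", "reverse",   3, ""),
    ("nad4",   7987,  9303, "J", "reverse",  37, "ATG/TAA"),
    ("nad4l",  9297,  9605, "J", "reverse",  -7, "TTG/TAA"),
    ("trnT",   9581,  9643, "N", "forward", -25, ""),
    ("trnP",   9644,  9706, "J", "reverse",   0, ""),
    ("nad6",   9709, 10170, "N", "forward",   2, "ATC/TAA"),
    ("cob",   10170, 11306, "N", "forward",  -1, "ATG/TAG"),
    ("trnS2", 11305, 11374, "N", "forward",  -2, ""),
    ("nad1",  11396, 12319, "J", "reverse",  21, "ATC/TAA"),
    ("trnL1", 12320, 12384, "J", "reverse",   0, ""),
    ("rrnL",  12392, 13612, "J", "reverse",   7, ""),
    ("trnV",  13635, 13700, "J", "reverse",  22, ""),
    ("rrnS",  13726, 14315, "J", "reverse",  25, ""),
)

SORDIDUS_TABLE: tuple[Row, ...] = (
    ("trnI",      1,    64, "N", "forward",   0, ""),
    ("trnQ",     62,   130, "J", "reverse",  -3, ""),
    ("trnM",    131,   201, "N", "forward",   0, ""),
    ("nad2",    202,  1188, "N", "forward",   0, "ATT/TAA"),
    ("trnW",   1179,  1242, "N", "forward", -10, ""),
    ("trnC",   1235,  1297, "J", "reverse",  -8, ""),
    ("trnY",   1305,  1373, "J", "reverse",  10, ""),
    ("cox1",   1377,  2910, "N", "forward",   3, "TTG/T-"),
    ("trnL2",  2911,  2975, "N", "forward",   0, ""),
    ("cox2",   2976,  3651, "N", "forward",   0, "ATA/T-"),
    ("trnK",   3652,  3716, "N", "forward",   0, ""),
    ("trnD",   3717,  3777, "N", "forward",   0, ""),
    ("atp8",   3778,  3936, "N", "forward",   0, "ATA/TAA"),
    ("atp6",   3930,  4595, "N", "forward",  -7, "ATG/TAA"),
    ("cox3",   4604,  5381, "N", "forward",   8, "ATT/T-"),
    ("trnG",   5382,  5444, "N", "forward",   0, ""),
    ("nad3",   5445,  5798, "N", "forward",   0, "ATA/TAG"),
    ("trnA",   5797,  5860, "N", "forward",  -2, ""),
    ("trnR",   5861,  5920, "N", "forward",   0, ""),
    ("trnN",   5923,  5990, "N", "forward",   2, ""),
    ("trnS1",  5990,  6058, "N", "forward",  -1, ""),
    ("trnE",   6058,  6121, "N", "forward",  -1, ""),
    ("trnF",   6122,  6184, "J", "reverse",   0, ""),
    ("nad5",   6185,  7882, "J", "reverse",   0, "ATT/TAA"),
    ("trnH",   7886,  7949, "J", "reverse",   3, ""),
    ("nad4",   7988,  9304, "J", "reverse",  38, "ATG/TAA"),
    ("nad4l",  9298,  9606, "J", "reverse",  -7, "TTG/TAA"),
    ("trnT",   9582,  9644, "N", "forward", -25, ""),
    ("trnP",   9645,  9707, "J", "reverse",   0, ""),
    ("nad6",   9710, 10171, "N", "forward",   2, "ATC/TAA"),
    ("cob",   10171, 11307, "N", "forward",  -1, "ATG/TAG"),
    ("trnS2", 11306, 11375, "N", "forward",  -2, ""),
    ("nad1",  11397, 12320, "J", "reverse",  21, "ATC/TAA"),
    ("trnL1", 12321, 12385, "J", "reverse",   0, ""),
    ("rrnL",  12397, 13613, "J", "reverse",  11, ""),
    ("trnV",  13636, 13701, "J", "reverse",  22, ""),
    ("rrnS",  13727, 14316, "J", "reverse",  25, ""),
)


def features_from_rows(rows: tuple[Row, ...]) -> list[GeneFeature]:
    return [
        GeneFeature(
            name=gene,
            gene_type=GENE_TYPES[gene],
            start=start,
            end=end,
            strand_label=strand,
            direction=Direction(direction),
        )
        for gene, start, end, strand, direction, _, _ in rows
    ]


def porrectus_features() -> list[GeneFeature]:
    return features_from_rows(PORRECTUS_TABLE)


def sordidus_features() -> list[GeneFeature]:
    return features_from_rows(SORDIDUS_TABLE)
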