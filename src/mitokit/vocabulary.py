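"""Canonical gene vocabulary for the 37-gene insect mitochondrial genome.

Canonical names: 13 protein-coding genes (PCGs), 22 tRNAs (the duplicated
leucine and serine tRNAs carry distinct names ``trnL1``/``trnL2`` and
``trnS1``/``trnS2``), two rRNAs (``rrnL``, ``rrnS``) and the control
region (``d-loop``).
"""

from __future__ import annotations

import enum


class GeneType(enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


#: The 13 protein-coding genes in canonical concatenation order.
PCG_ORDER = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

TRNA_NAMES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK",
    "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF",
    "trnH", "trnT", "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")

CONTROL_NAME = "d-loop"

#: All 37 genes (control region excluded).
GENE_NAMES = PCG_ORDER + TRNA_NAMES + RRNA_NAMES

GENE_TYPES: dict[str, GeneType] = (
    {g: GeneType.PCG for g in PCG_ORDER}
    | {g: GeneType.TRNA for g in TRNA_NAMES}
    | {g: GeneType.RRNA for g in RRNA_NAMES}
    | {CONTROL_NAME: GeneType.CONTROL}
)

# Synonym map: lowercase alias -> canonical name.  Covers the usual GenBank
# spellings (COI/COX1/cytb/ND4L/16S...) plus amino-acid style tRNA names.
_SYNONYMS: dict[str, str] = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob", "cyt b": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4l", "nad5": "nad5", "nad6": "nad6",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "atpase 6": "atp6", "atpase 8": "atp8",
    "rrnl": "rrnL", "rrns": "rrnS",
    "16s": "rrnL", "12s": "rrnS",
    "16s rrna": "rrnL", "12s rrna": "rrnS",
    "l-rrna": "rrnL", "s-rrna": "rrnS",
    "lrrna": "rrnL", "srrna": "rrnS",
    "large subunit ribosomal rna": "rrnL",
    "small subunit ribosomal rna": "rrnS",
    "d-loop": CONTROL_NAME, "dloop": CONTROL_NAME,
    "control region": CONTROL_NAME, "a+t-rich region": CONTROL_NAME,
    "at-rich region": CONTROL_NAME, "misc_feature": CONTROL_NAME,
}

_TRNA_AA = {
    "ile": "trnI", "gln": "trnQ", "met": "trnM", "trp": "trnW",
    "cys": "trnC", "tyr": "trnY", "lys": "trnK", "asp": "trnD",
    "gly": "trnG", "ala": "trnA", "arg": "trnR", "asn": "trnN",
    "glu": "trnE", "phe": "trnF", "his": "trnH", "thr": "trnT",
    "pro": "trnP", "val": "trnV",
}
for _aa, _name in _TRNA_AA.items():
    _SYNONYMS[f"trna-{_aa}"] = _name
    _SYNONYMS[f"trn{_aa}"] = _name
# Duplicated tRNAs: convention trnL1 = Leu(CUN), trnL2 = Leu(UUR),
# trnS1 = Ser(AGN), trnS2 = Ser(UCN).
_SYNONYMS.update({
    "trna-leu(cun)": "trnL1", "trna-leu(uur)": "trnL2",
    "trna-ser(agn)": "trnS1", "trna-ser(ucn)": "trnS2",
    "trnl(cun)": "trnL1", "trnl(uur)": "trnL2",
    "trns(agn)": "trnS1", "trns(ucn)": "trnS2",
    "trnl1": "trnL1", "trnl2": "trnL2", "trns1": "trnS1", "trns2": "trnS2",
})
for _g in GENE_NAMES:
    _SYNONYMS.setdefault(_g.lower(), _g)


def canonical_name(name: str) -> str | None:
    """Resolve ``name`` to its canonical gene name, or ``None`` if unknown."""
    return _SYNONYMS.get(name.strip().lower())


def gene_type(name: str) -> GeneType | None:
    canon = canonical_name(name)
    return GENE_TYPES.get(canon) if canon else None


#: Putative ancestral insect mitochondrial gene arrangement, linearized at
#: trnI: circular list of (gene name, is_forward).  Forward means the
#: majority (gene-rich) strand.
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, bool], ...] = (
    ("trnI", True), ("trnQ", False), ("trnM", True), ("nad2", True),
    ("trnW", True), ("trnC", False), ("trnY", False), ("cox1", True),
    ("trnL2", True), ("cox2", True), ("trnK", True), ("trnD", True),
    ("atp8", True), ("atp6", True), ("cox3", True), ("trnG", True),
    ("nad3", True), ("trnA", True), ("trnR", True), ("trnN", True),
    ("trnS1", True), ("trnE", True), ("trnF", False), ("nad5", False),
    ("trnH", False), ("nad4", False), ("nad4l", False), ("trnT", True),
    ("trnP", False), ("nad6", True), ("cob", True), ("trnS2", True),
    ("nad1", False), ("trnL1", False), ("rrnL", False), ("trnV", False),
    ("rrnS", False),
)
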