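"""Canonical gene vocabulary, synonym normalization and genetic-code tables.

Gene-order comparison across mitogenomes only works over a fixed alphabet,
so every annotation source (GenBank qualifiers, tabular files, synthetic
specs) is normalized to the canonical 37-gene + control-region vocabulary
used throughout the package.
"""

from __future__ import annotations

# The 13 protein-coding genes.
PCG_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CytB",
)

# 22 tRNAs; leucine and serine each have two isoacceptors distinguished by
# the codon family they read (L1=CUN, L2=UUR, S1=AGN, S2=UCN).
TRNA_NAMES = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG", "trnH",
    "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP", "trnS1",
    "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNA_NAMES = ("rrnS", "rrnL")

CONTROL_REGION = "CR"

ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES
CANONICAL_NAMES = ALL_GENE_NAMES + (CONTROL_REGION,)

ROLE_PCG = "PCG"
ROLE_TRNA = "tRNA"
ROLE_RRNA = "rRNA"
ROLE_CR = "control_region"

ROLE_OF: dict[str, str] = {}
for _n in PCG_NAMES:
    ROLE_OF[_n] = ROLE_PCG
for _n in TRNA_NAMES:
    ROLE_OF[_n] = ROLE_TRNA
for _n in RRNA_NAMES:
    ROLE_OF[_n] = ROLE_RRNA
ROLE_OF[CONTROL_REGION] = ROLE_CR

# Amino-acid letter -> tRNA name (for "trnL-uur" style qualifiers).
_AA_TO_TRNA = {
    "ALA": "trnA", "ARG": "trnR", "ASN": "trnN", "ASP": "trnD",
    "CYS": "trnC", "GLU": "trnE", "GLN": "trnQ", "GLY": "trnG",
    "HIS": "trnH", "ILE": "trnI", "LYS": "trnK", "MET": "trnM",
    "PHE": "trnF", "PRO": "trnP", "THR": "trnT", "TRP": "trnW",
    "TYR": "trnY", "VAL": "trnV",
}

_SYNONYMS = {
    "COX1": "COI", "COX2": "COII", "COX3": "COIII",
    "CO1": "COI", "CO2": "COII", "CO3": "COIII",
    "COXI": "COI", "COXII": "COII", "COXIII": "COIII",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "NADH1": "ND1", "NADH2": "ND2", "NADH3": "ND3", "NADH4": "ND4",
    "NADH4L": "ND4L", "NADH5": "ND5", "NADH6": "ND6",
    "ATP8": "ATP8", "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE8": "ATP8",
    "COB": "CytB", "CYTB": "CytB", "CB": "CytB",
    "12S": "rrnS", "16S": "rrnL", "SSU": "rrnS", "LSU": "rrnL",
    "RRNS": "rrnS", "RRNL": "rrnL", "S-RRNA": "rrnS", "L-RRNA": "rrnL",
    "12S RRNA": "rrnS", "16S RRNA": "rrnL",
    "A+T-RICH REGION": "CR", "AT-RICH REGION": "CR", "CONTROL REGION": "CR",
    "D-LOOP": "CR", "CR": "CR",
    "TRNL1": "trnL1", "TRNL2": "trnL2", "TRNS1": "trnS1", "TRNS2": "trnS2",
    "TRNL(CUN)": "trnL1", "TRNL(UUR)": "trnL2",
    "TRNS(AGN)": "trnS1", "TRNS(UCN)": "trnS2",
    "TRNL-CUN": "trnL1", "TRNL-UUR": "trnL2",
    "TRNS-AGN": "trnS1", "TRNS-UCN": "trnS2",
}
for _aa, _t in _AA_TO_TRNA.items():
    _SYNONYMS["TRN-" + _aa] = _t
    _SYNONYMS["TRNA-" + _aa] = _t
for _t in TRNA_NAMES:
    _SYNONYMS[_t.upper()] = _t
for _n in ALL_GENE_NAMES:
    _SYNONYMS.setdefault(_n.upper(), _n)
_SYNONYMS["TRNA-LEU"] = "trnL2"   # ambiguous without codon qualifier; UUR default
_SYNONYMS["TRNA-SER"] = "trnS2"


def canonical_name(raw: str) -> str | None:
    """Map an annotation label to the canonical vocabulary, or None."""
    key = raw.strip().upper().replace("_", "")
    return _SYNONYMS.get(key)


# ---------------------------------------------------------------------------
# Invertebrate mitochondrial genetic code (NCBI translation table 5).
# Differences from the standard code: AGA/AGG = Ser, ATA = Met, TGA = Trp.
# Stop codons: TAA, TAG.
# ---------------------------------------------------------------------------

STOP_CODONS = ("TAA", "TAG")

_BASES = "TCAG"
_STANDARD_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)


def _table5() -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                table[b1 + b2 + b3] = _STANDARD_AA[i]
                i += 1
    table["AGA"] = "S"
    table["AGG"] = "S"
    table["ATA"] = "M"
    table["TGA"] = "W"
    return table


CODON_TO_AA: dict[str, str] = _table5()
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, a in CODON_TO_AA.items() if a != "*")
)
assert len(SENSE_CODONS) == 62

#: synonymous family of each amino acid under table 5 (Ser is 8-fold here,
#: since AGN joins the UCN family; Leu is 6-fold; Met and Trp are 2-fold).
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_FAMILIES.setdefault(CODON_TO_AA[_c], ())
AA_FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa))
    for aa in AA_FAMILIES
}

CANONICAL_START_CODONS = ("ATA", "ATT", "ATG", "ATC")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(COMPLEMENT)[::-1]


IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
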