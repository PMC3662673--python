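"""Ground-truth synthetic data: genomes, alignments and trees.

Every generator is a pure function of its spec and seed.  The genome
generator emulates a typical insect mitogenome: 37 genes + control region
on a circular molecule, codon-structured protein genes with configurable
start/stop codons (including incomplete stops), planned junction overlaps
and spacers, a planted conserved overlap motif, and an AT-rich control
region carrying planted microsatellites and approximate repeat copies.
Defaults follow the magnitudes typical of lacewing mitogenomes: a
16.2 kb molecule at ~77% A+T overall with a ~1.36 kb control region at
~88.5% A+T in the ancestral insect gene arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .gene_order import GeneOrder, ancestral_insect_order
from .model import AlignmentBlock, GeneFeature, MitoGenome, ValidationError
from .vocab import (
    ROLE_CR,
    ROLE_OF,
    ROLE_PCG,
    ROLE_RRNA,
    ROLE_TRNA,
    STOP_CODONS,
    revcomp,
)

_BASES = "ACGT"

# Interior-codon base distributions per codon position (A, C, G, T).
# Chosen to give the T>A ranking and per-position A+T levels characteristic
# of insect mitochondrial protein genes (~68/66/89 % A+T at positions 1-3).
DEFAULT_CODON_POSITION_DISTS = (
    {"A": 0.30, "C": 0.14, "G": 0.18, "T": 0.38},
    {"A": 0.26, "C": 0.20, "G": 0.14, "T": 0.40},
    {"A": 0.409, "C": 0.065, "G": 0.046, "T": 0.48},
)

#: default per-gene lengths (bp); protein genes include start + stop
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 1023, "COI": 1536, "COII": 688, "ATP8": 159, "ATP6": 678,
    "COIII": 789, "ND3": 354, "ND5": 1735, "ND4": 1339, "ND4L": 291,
    "ND6": 525, "CytB": 1135, "ND1": 942,
    "rrnL": 1325, "rrnS": 798, "CR": 1358,
    "trnI": 66, "trnQ": 69, "trnM": 68, "trnW": 68, "trnC": 64,
    "trnY": 66, "trnL2": 66, "trnK": 71, "trnD": 67, "trnG": 65,
    "trnA": 64, "trnR": 65, "trnN": 65, "trnS1": 67, "trnE": 66,
    "trnF": 65, "trnH": 66, "trnT": 64, "trnP": 64, "trnS2": 68,
    "trnL1": 65, "trnV": 67,
}

#: start codons per protein gene (COI non-canonical, as in several lacewings)
DEFAULT_START_PLAN: dict[str, str] = {
    "ND2": "ATT", "COI": "TCG", "COII": "ATG", "ATP8": "ATT", "ATP6": "ATG",
    "COIII": "ATG", "ND3": "ATT", "ND5": "ATT", "ND4": "ATG", "ND4L": "ATG",
    "ND6": "ATC", "CytB": "ATG", "ND1": "ATG",
}

#: stop codons: TAA/TAG complete, "T"/"TA" incomplete
DEFAULT_STOP_PLAN: dict[str, str] = {
    "ND2": "TAA", "COI": "TAA", "COII": "T", "ATP8": "TAA", "ATP6": "TAA",
    "COIII": "TAA", "ND3": "TAG", "ND5": "T", "ND4": "T", "ND4L": "TAA",
    "ND6": "TAA", "CytB": "T", "ND1": "TAG",
}

OVERLAP_MOTIF = "ATGATAA"  # planted ATGNTAA-consensus overlap, 7 bp

#: junction gap plan: negative = overlap, positive = spacer (bp); a string
#: value plants that literal spacer sequence.  11 overlaps totalling 38 bp,
#: 13 spacers totalling 128 bp; all other junctions abut.
DEFAULT_JUNCTION_PLAN: dict[tuple[str, str], int | str] = {
    ("ND2", "trnW"): -1, ("trnW", "trnC"): -8, ("trnC", "trnY"): -1,
    ("COI", "trnL2"): -5, ("COIII", "trnG"): -1, ("ND3", "trnA"): -2,
    ("trnN", "trnS1"): -1, ("ND4L", "trnT"): -2, ("ND1", "trnL1"): -3,
    ("ATP8", "ATP6"): -7, ("ND4", "ND4L"): -7,
    ("trnI", "trnQ"): 63, ("trnS1", "trnE"): 20,
    ("trnS2", "ND1"): "ATTAAATATTATAAGATT",  # carries TTAAATNNNNTNAGAT motif
    ("trnQ", "trnM"): 2, ("trnM", "ND2"): 1, ("trnY", "COI"): 3,
    ("trnL2", "COII"): 1, ("trnK", "trnD"): 1, ("trnD", "ATP8"): 2,
    ("ATP6", "COIII"): 3, ("trnG", "ND3"): 4, ("trnA", "trnR"): 4,
    ("trnR", "trnN"): 6,
}

# two ~90%-identical 41-nt copies, as AT-rich control regions often carry
REPEAT_COPY_A = "ATTTTAAAGAAATAAATTTAAAATCGCAGTTTCTCCCTAAA"
REPEAT_COPY_B = "ATTTAAAAAGAATAAATTTAAAACCGCAGTTTCTCCCTAAA"

#: control-region plant plan: (kind, sequence, CR-relative offset)
DEFAULT_CR_PLAN: tuple[tuple[str, str, int], ...] = (
    ("approximate_copy", REPEAT_COPY_A, 224),
    ("approximate_copy", REPEAT_COPY_B, 428),
    ("microsatellite", "ATTTT" * 4, 620),
    ("microsatellite", "TAATATAA" * 2, 700),
    ("microsatellite", "AT" * 8, 800),
    ("microsatellite", "AT" * 6, 900),
)


@dataclass
class GenomeSpec:
    """Everything generate_genome needs; defaults give a lacewing-like genome."""

    genome_id: str = "synthetic_mitogenome"
    order: GeneOrder = field(default_factory=ancestral_insect_order)
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    junction_plan: dict[tuple[str, str], int | str] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_PLAN))
    start_plan: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_PLAN))
    stop_plan: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STOP_PLAN))
    cr_plan: tuple[tuple[str, str, int], ...] = DEFAULT_CR_PLAN
    codon_position_dists: tuple[dict[str, float], ...] = (
        DEFAULT_CODON_POSITION_DISTS)
    trna_at: float = 0.774
    rrna_at: float = 0.804
    cr_at: float = 0.885
    spacer_at: float = 0.80
    at_skew: float = -0.05   # J-strand AT skew of non-coding classes
    gc_skew: float = 0.10
    plant_overlap_motif: bool = True
    seed: int = 0


def _conditional_position_at(
    dists: tuple[dict[str, float], ...]
) -> list[float]:
    """Exact per-position A+T fraction of interior codons.

    Interior codons are drawn from the per-position base distributions with
    stop codons rejected, which shifts the realized marginals slightly off
    the nominal ones; this is the corrected expectation the truth record
    carries."""
    total = 0.0
    at = [0.0, 0.0, 0.0]
    for c1 in _BASES:
        for c2 in _BASES:
            for c3 in _BASES:
                if c1 + c2 + c3 in STOP_CODONS:
                    continue
                p = dists[0][c1] * dists[1][c2] * dists[2][c3]
                total += p
                for k, b in enumerate((c1, c2, c3)):
                    if b in "AT":
                        at[k] += p
    return [a / total for a in at]


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    if not 0 < at < 1:
        raise ValidationError("AT fraction must be in (0,1)")
    a = at * (1 + at_skew) / 2
    t = at * (1 - at_skew) / 2
    g = (1 - at) * (1 + gc_skew) / 2
    c = (1 - at) * (1 - gc_skew) / 2
    return np.array([a, c, g, t])


def _sample_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    idx = rng.choice(4, size=n, p=probs / probs.sum())
    return "".join(_BASES[i] for i in idx)


def _sample_codon(rng: np.random.Generator,
                  dists: tuple[dict[str, float], ...]) -> str:
    while True:
        codon = "".join(
            _BASES[rng.choice(4, p=[d["A"], d["C"], d["G"], d["T"]])]
            for d in dists
        )
        if codon not in STOP_CODONS:
            return codon


def _pcg_coding(rng: np.random.Generator, spec: GenomeSpec, gene: str,
                force_prefix: str = "", force_suffix: str = "") -> str:
    length = spec.gene_lengths[gene]
    start = spec.start_plan[gene]
    stop = spec.stop_plan[gene]
    interior = length - 3 - len(stop)
    if interior < 3 or interior % 3:
        raise ValidationError(
            f"{gene}: length {length} incompatible with start+stop plan")
    codons = [_sample_codon(rng, spec.codon_position_dists)
              for _ in range(interior // 3)]
    seq = start + "".join(codons) + stop
    if force_prefix:
        seq = force_prefix + seq[len(force_prefix):]
    if force_suffix:
        seq = seq[: len(seq) - len(force_suffix)] + force_suffix
    # repair any in-frame stop created by forcing (edit a non-forced base)
    body_end = len(seq) - len(stop)
    chars = list(seq)
    for i in range(3, body_end - 2, 3):
        if "".join(chars[i : i + 3]) in STOP_CODONS:
            if i >= len(force_prefix) and i < len(seq) - len(force_suffix):
                chars[i] = "C"  # CAA/CAG are sense codons
    return "".join(chars)


def _build_cr(rng: np.random.Generator, spec: GenomeSpec) -> tuple[str, list[dict]]:
    length = spec.gene_lengths["CR"]
    probs = _base_probs(spec.cr_at, spec.at_skew, spec.gc_skew)
    chars = list(_sample_seq(rng, length, probs))
    truth = []
    for kind, planted, offset in spec.cr_plan:
        if offset + len(planted) > length:
            raise ValidationError("planted CR feature exceeds CR length")
        chars[offset : offset + len(planted)] = planted
        truth.append({"kind": kind, "sequence": planted, "offset": offset,
                      "length": len(planted)})
    return "".join(chars), truth


def generate_genome(spec: GenomeSpec) -> tuple[MitoGenome, dict]:
    """Generate an annotated circular mitogenome plus its truth record."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    elements = spec.order.elements
    names = [n for n, _ in elements]
    strand_of = dict(elements)

    # forced coding prefixes/suffixes keeping planned overlaps consistent
    force_prefix: dict[str, str] = {}
    force_suffix: dict[str, str] = {}
    if spec.plant_overlap_motif:
        for up, down in spec.junction_plan:
            if spec.junction_plan[(up, down)] == -len(OVERLAP_MOTIF):
                up_role = ROLE_OF.get(up)
                down_role = ROLE_OF.get(down)
                if up_role == ROLE_PCG and down_role == ROLE_PCG:
                    if strand_of[up] == "J" and strand_of[down] == "J":
                        force_suffix[up] = OVERLAP_MOTIF
                        force_prefix[down] = OVERLAP_MOTIF
                    elif strand_of[up] == "N" and strand_of[down] == "N":
                        force_prefix[up] = OVERLAP_MOTIF
                        force_suffix[down] = OVERLAP_MOTIF

    cr_truth: list[dict] = []
    genome_piece: dict[str, str] = {}  # forward-strand sequence per element
    for name in names:
        role = ROLE_OF.get(name)
        if role == ROLE_PCG:
            coding = _pcg_coding(rng, spec, name,
                                 force_prefix.get(name, ""),
                                 force_suffix.get(name, ""))
            genome_piece[name] = (coding if strand_of[name] == "J"
                                  else revcomp(coding))
        elif role == ROLE_TRNA:
            probs = _base_probs(spec.trna_at, spec.at_skew, spec.gc_skew)
            genome_piece[name] = _sample_seq(rng, spec.gene_lengths[name], probs)
        elif role == ROLE_RRNA:
            probs = _base_probs(spec.rrna_at, spec.at_skew, spec.gc_skew)
            genome_piece[name] = _sample_seq(rng, spec.gene_lengths[name], probs)
        elif role == ROLE_CR:
            genome_piece[name], cr_truth = _build_cr(rng, spec)
        else:
            raise ValidationError(f"unknown element {name!r}")

    # assemble around the circle, honouring the junction plan
    spacer_probs = _base_probs(spec.spacer_at, spec.at_skew, spec.gc_skew)
    parts: list[str] = []
    starts: dict[str, int] = {}
    cursor = 0
    junction_truth: dict[str, int | str] = {}
    for i, name in enumerate(names):
        piece = genome_piece[name]
        if i == 0:
            parts.append(piece)
            starts[name] = 0
            cursor = len(piece)
            continue
        gap = spec.junction_plan.get((names[i - 1], name), 0)
        if isinstance(gap, str):
            parts.append(gap)
            cursor += len(gap)
            junction_truth[f"{names[i - 1]}/{name}"] = gap
            gap_len = 0
        elif gap > 0:
            parts.append(_sample_seq(rng, gap, spacer_probs))
            cursor += gap
            junction_truth[f"{names[i - 1]}/{name}"] = gap
            gap_len = 0
        elif gap < 0:
            gap_len = -gap
            assembled_tail = parts[-1][-gap_len:] if len(parts[-1]) >= gap_len else ""
            if piece[:gap_len] != assembled_tail:
                down_role = ROLE_OF.get(name)
                if down_role == ROLE_PCG:
                    raise ValidationError(
                        f"inconsistent overlap at {names[i - 1]}/{name}")
                piece = assembled_tail + piece[gap_len:]
            junction_truth[f"{names[i - 1]}/{name}"] = gap
            starts[name] = cursor - gap_len
            parts.append(piece[gap_len:])
            cursor += len(piece) - gap_len
            continue
        else:
            gap_len = 0
        starts[name] = cursor
        parts.append(piece)
        cursor += len(piece)
    # closing junction (last element back to first) must be planned as abutting
    closing = spec.junction_plan.get((names[-1], names[0]), 0)
    if closing != 0:
        raise ValidationError("closing junction must abut in this generator")

    sequence = "".join(parts)
    features = [
        GeneFeature(name=n, role=ROLE_OF[n], start=starts[n],
                    end=starts[n] + spec.gene_lengths[n],
                    strand=strand_of[n])
        for n in names
    ]
    genome = MitoGenome(id=spec.genome_id, sequence=sequence,
                        features=features, topology="circular")
    truth = {
        "seed": spec.seed,
        "order": [list(e) for e in elements],
        "gene_lengths": dict(spec.gene_lengths),
        "starts": dict(starts),
        "junctions": junction_truth,
        "start_plan": dict(spec.start_plan),
        "stop_plan": dict(spec.stop_plan),
        "cr_plants": cr_truth,
        "cr_start": starts.get("CR"),
        "targets": {
            "trna_at": spec.trna_at, "rrna_at": spec.rrna_at,
            "cr_at": spec.cr_at,
            "codon_position_at": _conditional_position_at(
                spec.codon_position_dists),
        },
    }
    return genome, truth


def langii_like_spec(seed: int = 0) -> GenomeSpec:
    """Preset emulating the magnitudes of a lacewing mitogenome: 16,221 bp,
    ancestral insect gene order, 1,358 bp control region at 88.5% A+T."""
    return GenomeSpec(genome_id=f"langii_like_seed{seed}", seed=seed)


def wc_swapped_spec(seed: int = 0) -> GenomeSpec:
    """Derived arrangement with tRNA-Trp/tRNA-Cys transposed (C before W)."""
    anc = ancestral_insect_order().elements
    swapped = []
    for name, strand in anc:
        if name == "trnW":
            swapped.append(("trnC", "N"))
        elif name == "trnC":
            swapped.append(("trnW", "J"))
        else:
            swapped.append((name, strand))
    plan = dict(DEFAULT_JUNCTION_PLAN)
    # junction plan entries touching the swapped genes no longer apply
    for pair in [("ND2", "trnW"), ("trnW", "trnC"), ("trnC", "trnY")]:
        plan.pop(pair, None)
    return GenomeSpec(genome_id=f"wc_swapped_seed{seed}",
                      order=GeneOrder(tuple(swapped)),
                      junction_plan=plan, seed=seed)


# ---------------------------------------------------------------------------
# Alignments with directional substitution bias
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSpec:
    """Codon-aware alignment with per-taxon direction bias delta.

    delta = 0 gives symmetric substitution (homogeneous composition);
    delta > 0 tilts substitutions toward A/T for that taxon, creating the
    base-compositional heterogeneity the disparity index detects.
    """

    n_taxa: int = 11
    n_codons: int = 300
    rates: tuple[float, float, float] = (0.15, 0.10, 0.45)
    deltas: tuple[float, ...] | None = None  # default: all zero
    codon_position_dists: tuple[dict[str, float], ...] = (
        DEFAULT_CODON_POSITION_DISTS)
    taxon_prefix: str = "taxon"
    seed: int = 0


def _substitute(rng: np.random.Generator, base: str, delta: float) -> str:
    others = [b for b in _BASES if b != base]
    if delta > 0 and rng.random() < delta:
        at_targets = [b for b in "AT" if b != base]
        return at_targets[rng.integers(len(at_targets))]
    return others[rng.integers(3)]


def generate_alignment(spec: AlignmentSpec) -> tuple[AlignmentBlock, list[int], dict]:
    """(alignment, codon-position map, truth record)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    deltas = spec.deltas or tuple(0.0 for _ in range(spec.n_taxa))
    if len(deltas) != spec.n_taxa:
        raise ValidationError("deltas length must equal n_taxa")
    ancestor = "".join(
        _sample_codon(rng, spec.codon_position_dists)
        for _ in range(spec.n_codons)
    )
    n_cols = 3 * spec.n_codons
    pos_map = [1 + (c % 3) for c in range(n_cols)]
    taxa = [f"{spec.taxon_prefix}{i:02d}" for i in range(spec.n_taxa)]
    rows = []
    for t, delta in enumerate(deltas):
        chars = list(ancestor)
        for c in range(n_cols):
            if rng.random() < spec.rates[c % 3]:
                chars[c] = _substitute(rng, chars[c], delta)
        rows.append("".join(chars))
    block = AlignmentBlock(taxa=taxa, rows=rows)
    truth = {
        "seed": spec.seed,
        "deltas": {taxa[i]: deltas[i] for i in range(spec.n_taxa)},
        "rates": list(spec.rates),
        "n_codons": spec.n_codons,
    }
    return block, pos_map, truth


# ---------------------------------------------------------------------------
# Trees with planted root-to-tip depth multipliers
# ---------------------------------------------------------------------------


@dataclass
class TreeSpec:
    n_tips: int = 11
    base_depth: float = 0.5
    multipliers: tuple[float, ...] | None = None  # default: all 1.0
    taxon_prefix: str = "taxon"
    seed: int = 0


@dataclass
class _TreeNode:
    name: str | None            # tip label, None for internal nodes
    height: float               # depth of this node below the global root
    children: tuple["_TreeNode", ...] = ()

    @property
    def max_parent_height(self) -> float:
        # a parent must sit strictly above this node
        return self.height


def generate_tree(spec: TreeSpec) -> tuple[str, dict]:
    """Random rooted bifurcating topology whose tip depths equal
    base_depth x multiplier exactly; returns (newick, truth)."""
    mult = spec.multipliers or tuple(1.0 for _ in range(spec.n_tips))
    if len(mult) != spec.n_tips:
        raise ValidationError("multipliers length must equal n_tips")
    if any(m <= 0 for m in mult):
        raise ValidationError("multipliers must be positive")
    if spec.n_tips < 2:
        raise ValidationError("need at least two tips")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    taxa = [f"{spec.taxon_prefix}{i:02d}" for i in range(spec.n_tips)]
    targets = {t: spec.base_depth * m for t, m in zip(taxa, mult)}

    # Build bottom-up by random joins.  Every node carries its final depth
    # below the root ("height"); a join places the new internal node at a
    # random fraction of the lower of its children's heights, so all edge
    # lengths stay positive.  The last join is the root at height 0.
    nodes: list[_TreeNode] = [
        _TreeNode(name=t, height=targets[t]) for t in taxa
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        cap = min(a.max_parent_height, b.max_parent_height)
        height = float(rng.uniform(0.1, 0.9)) * cap
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(_TreeNode(name=None, height=height, children=(a, b)))
    root = _TreeNode(name=None, height=0.0, children=tuple(nodes))

    def to_newick(node: _TreeNode, parent_height: float) -> str:
        edge = node.height - parent_height
        if node.name is not None:
            return f"{node.name}:{edge:.8f}"
        inner = ",".join(to_newick(c, node.height) for c in node.children)
        return f"({inner}):{edge:.8f}"

    newick = to_newick(root, 0.0) + ";"
    truth = {"seed": spec.seed, "targets": targets,
             "multipliers": {t: m for t, m in zip(taxa, mult)}}
    return newick, truth
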