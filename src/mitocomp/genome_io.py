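"""Readers and writers for the external formats the pipeline touches.

GenBank and FASTA parsing is delegated to Biopython; this module only
normalizes coordinates (to 0-based half-open, with origin-spanning
circular features encoded as end > genome length) and gene labels (to the
canonical 37-gene + CR vocabulary).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import AlignmentBlock, FormatError, GeneFeature, MitoGenome, ValidationError
from .vocab import ROLE_CR, ROLE_OF, ROLE_PCG, ROLE_RRNA, ROLE_TRNA, canonical_name

_GB_ROLE = {"CDS": ROLE_PCG, "tRNA": ROLE_TRNA, "rRNA": ROLE_RRNA}


def _feature_label(feat) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        for raw in feat.qualifiers.get(key, []):
            hit = canonical_name(raw)
            if hit is not None:
                return hit
    return None


def read_genbank(path: str | Path) -> MitoGenome:
    """Read a single-record GenBank flat file into a MitoGenome.

    Features that cannot be mapped onto the canonical vocabulary are kept
    with a warning flag rather than dropped.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise FormatError(f"{path}: record has no sequence")
    topology = rec.annotations.get("topology", "circular")
    n = len(seq)

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene"):
            continue
        if feat.type == "gene":
            # gene features duplicate CDS/tRNA/rRNA annotations
            continue
        name = _feature_label(feat)
        if feat.type == "D-loop":
            name = "CR"
        start, end = _location_bounds(feat, n, topology)
        if name is None:
            if feat.type == "misc_feature":
                continue
            features.append(
                GeneFeature(
                    name=f"unmapped_{feat.type}_{start}",
                    role=_GB_ROLE.get(feat.type, ROLE_CR),
                    start=start,
                    end=end,
                    strand="J" if feat.location.strand != -1 else "N",
                    warning="unmappable feature label",
                )
            )
            continue
        role = ROLE_OF[name]
        if name in seen:
            raise ValidationError(f"{path}: duplicate canonical gene name {name}")
        seen.add(name)
        features.append(
            GeneFeature(
                name=name,
                role=role,
                start=start,
                end=end,
                strand="J" if feat.location.strand != -1 else "N",
            )
        )
    features.sort(key=lambda f: (f.start, -f.span))
    return MitoGenome(id=rec.id or rec.name, sequence=seq, features=features,
                      topology=topology)


def _location_bounds(feat, n: int, topology: str) -> tuple[int, int]:
    loc = feat.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..n, 1..y)
        if len(parts) == 2 and int(parts[1].end) == n and int(parts[0].start) == 0:
            return int(parts[1].start), n + int(parts[0].end)
        return int(loc.start), int(loc.end)
    return int(loc.start), int(loc.end)


def read_fasta_with_table(fasta: str | Path, table: str | Path) -> MitoGenome:
    """Read a plain FASTA genome plus a TSV annotation table.

    The table dialect is 1-based inclusive with columns
    ``name  role  start  end  strand``; on circular genomes a row with
    start > end denotes an origin-spanning feature.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if not records:
        raise FormatError(f"{fasta}: empty FASTA")
    rec = records[0]
    seq = str(rec.seq).upper()
    n = len(seq)

    features: list[GeneFeature] = []
    with open(table) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{table}:{lineno}: expected 5 columns")
            name, role, start_s, end_s, strand = parts
            start1, end1 = int(start_s), int(end_s)
            if start1 < 1 or end1 < 1 or start1 > n or end1 > n:
                raise ValidationError(
                    f"{table}:{lineno}: interval {start1}..{end1} outside 1..{n}"
                )
            if end1 >= start1:
                start, end = start1 - 1, end1
            else:
                # wraps the origin
                start, end = start1 - 1, end1 + n
            features.append(
                GeneFeature(name=name, role=role, start=start, end=end, strand=strand)
            )
    features.sort(key=lambda f: (f.start, -f.span))
    return MitoGenome(id=rec.id, sequence=seq, features=features)


def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """5'->3' coding-strand sequence of one feature (wraps; revcomps N strand)."""
    return genome.feature_sequence(feature)


def read_alignment(path: str | Path) -> AlignmentBlock:
    """Read an aligned FASTA file (equal-length rows)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty alignment file")
    return AlignmentBlock(
        taxa=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
    )


def write_alignment(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(block.taxa, block.rows):
            fh.write(f">{taxon}\n{row}\n")


def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    """Write annotations in the 1-based inclusive TSV dialect."""
    n = genome.length
    with open(path, "w") as fh:
        fh.write("name\trole\tstart\tend\tstrand\n")
        for f in genome.features:
            start1 = f.start + 1
            end1 = f.end if f.end <= n else f.end - n
            fh.write(f"{f.name}\t{f.role}\t{start1}\t{end1}\t{f.strand}\n")


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a minimal GenBank flat file round-trippable by read_genbank."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic mitogenome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    n = genome.length
    type_of = {ROLE_PCG: "CDS", ROLE_TRNA: "tRNA", ROLE_RRNA: "rRNA",
               ROLE_CR: "D-loop"}
    for f in genome.features:
        strand = 1 if f.strand == "J" else -1
        if f.end <= n:
            loc = FeatureLocation(f.start, f.end, strand=strand)
        else:
            loc = CompoundLocation([
                FeatureLocation(f.start, n, strand=strand),
                FeatureLocation(0, f.end - n, strand=strand),
            ])
        sf = SeqFeature(loc, type=type_of[f.role])
        if f.role != ROLE_CR:
            sf.qualifiers["gene"] = [f.name]
        rec.features.append(sf)
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Deterministic report output
# ---------------------------------------------------------------------------


def _fmt(value: Any) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_report(results: Any, path: str | Path, format: str = "tsv") -> None:
    """Serialize a stage result (list of dicts, or dict) deterministically.

    TSV columns follow the key order of the first row; floats use a fixed
    6-decimal format so identical inputs give byte-identical files.
    """
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=_fmt)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if isinstance(results, dict):
        rows = [{"key": k, "value": results[k]} for k in results]
    else:
        rows = list(results)
    with open(path, "w") as fh:
        if not rows:
            fh.write("\n")
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in cols) + "\n")
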