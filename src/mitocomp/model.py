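"""Core in-memory containers shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

from .vocab import ROLE_CR, ROLE_OF, revcomp

VALID_BASES = frozenset("ACGTN")
ALIGN_CHARS = frozenset("ACGT-N")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed input violates a model invariant."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a (possibly circular) mitogenome.

    Coordinates are 0-based half-open on the forward (J) strand of the
    genome sequence.  An origin-spanning feature on a circular genome is
    encoded with ``end > genome length``; the extracted sequence wraps.
    Strand 'J' is the majority strand, 'N' the minority strand (the
    feature's coding sequence is the reverse complement of the slice).
    """

    name: str
    role: str
    start: int
    end: int
    strand: str = "J"
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"feature {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("J", "N"):
            raise ValidationError(f"feature {self.name}: strand must be J or N")
        expected = ROLE_OF.get(self.name)
        if expected is not None and expected != self.role:
            raise ValidationError(
                f"feature {self.name}: role {self.role!r} inconsistent with "
                f"canonical role {expected!r}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """A mitogenome: sequence plus ordered, strand-aware annotations."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise FormatError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.id}: invalid sequence characters {sorted(bad)}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValidationError("topology must be 'circular' or 'linear'")
        self._validate_features()

    def _validate_features(self) -> None:
        n = len(self.sequence)
        names = [f.name for f in self.features if f.warning is None]
        dup = sorted({x for x in names if names.count(x) > 1})
        if dup:
            raise ValidationError(f"duplicate canonical gene names: {dup}")
        cr = [f for f in self.features if f.role == ROLE_CR]
        if len(cr) > 1:
            raise ValidationError("more than one control_region feature")
        for f in self.features:
            if not (0 <= f.start < n):
                raise ValidationError(
                    f"feature {f.name}: start {f.start} outside [0, {n})"
                )
            if f.end > n and self.topology != "circular":
                raise ValidationError(
                    f"feature {f.name}: extends past the end of a linear genome"
                )
            if f.end > 2 * n:
                raise ValidationError(f"feature {f.name}: span exceeds genome length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def slice_circular(self, start: int, end: int) -> str:
        """Forward-strand slice; wraps across the origin when end > length."""
        n = self.length
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]

    def feature_sequence(self, feature: GeneFeature) -> str:
        """5'->3' coding-strand sequence of a feature."""
        raw = self.slice_circular(feature.start, feature.end)
        return revcomp(raw) if feature.strand == "N" else raw


@dataclass
class AlignmentBlock:
    """A multiple alignment: equal-length rows over {A,C,G,T,-,N}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels")
        self.rows = [r.upper() for r in self.rows]
        if self.rows:
            width = len(self.rows[0])
            for taxon, row in zip(self.taxa, self.rows):
                if len(row) != width:
                    raise FormatError(
                        f"ragged alignment: row for {taxon!r} has length "
                        f"{len(row)}, expected {width}"
                    )
                bad = set(row) - ALIGN_CHARS
                if bad:
                    raise FormatError(
                        f"row for {taxon!r}: invalid characters {sorted(bad)}"
                    )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def select_columns(self, cols: list[int]) -> "AlignmentBlock":
        return AlignmentBlock(
            taxa=list(self.taxa),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )
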