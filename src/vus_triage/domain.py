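"""Core data model for panel variants and minimal cDNA-coordinate helpers.

The unit of analysis throughout the package is one *observed variant*: a
single nucleotide substitution or small indel seen in one or more patients of
a gene-panel cohort, identified by transcript + cDNA (c.) notation.  The cDNA
parser here is deliberately minimal — substitutions, del, dup, ins, delins and
intronic +/- offsets — because that is all a diagnostic annotation table
contains.  Anything else is kept verbatim and flagged unparsed by the readers.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import DataError, HgvsParseError


class Tier(str, Enum):
    """Five-tier clinical classification (benign .. pathogenic)."""

    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    SPLICE_CANONICAL = "splice_canonical"


class VusSubclass(str, Enum):
    """Follow-up priority subclasses for variants of uncertain significance."""

    LOW = "low"
    SEMI_HIGH = "semi_high"
    HIGH = "high"
    SPLICE = "splice"


# --------------------------------------------------------------------------
# cDNA (HGVS-style) notation, minimal grammar
# --------------------------------------------------------------------------

_POS_RE = r"(?P<star{i}>\*)?(?P<base{i}>-?\d+)(?P<off{i}>[+-]\d+)?"
_EDIT_RE = (
    r"(?P<sub>[ACGTN]>[ACGTN])"
    r"|(?P<delins>delins[ACGTN]+)"
    r"|(?P<del>del[ACGTN]*)"
    r"|(?P<dup>dup[ACGTN]*)"
    r"|(?P<ins>ins[ACGTN]+)"
)
_CDNA_RE = re.compile(
    r"^c\."
    + _POS_RE.format(i=1)
    + r"(?:_" + _POS_RE.format(i=2) + r")?"
    + r"(?:" + _EDIT_RE + r")$"
)


@dataclass(frozen=True)
class CdnaPosition:
    """A cDNA coordinate: base number plus optional intronic offset."""

    base: int
    offset: int = 0
    utr3: bool = False  # '*' prefix (3'UTR numbering)

    def format(self) -> str:
        s = ("*" if self.utr3 else "") + str(self.base)
        if self.offset:
            s += f"{self.offset:+d}"
        return s


@dataclass(frozen=True)
class CdnaChange:
    """Parsed single-substitution or small-indel cDNA notation."""

    start: CdnaPosition
    end: CdnaPosition | None
    edit: str

    def format(self) -> str:
        s = "c." + self.start.format()
        if self.end is not None:
            s += "_" + self.end.format()
        return s + self.edit


def parse_cdna(hgvs_c: str) -> CdnaChange:
    """Parse a cDNA notation string into its coordinates and edit.

    Raises :class:`HgvsParseError` naming the offending token for anything
    outside the supported grammar.
    """
    m = _CDNA_RE.match(hgvs_c.strip())
    if not m:
        raise HgvsParseError(f"cannot parse cDNA notation {hgvs_c!r}")
    start = CdnaPosition(
        base=int(m.group("base1")),
        offset=int(m.group("off1") or 0),
        utr3=bool(m.group("star1")),
    )
    end = None
    if m.group("base2") is not None:
        end = CdnaPosition(
            base=int(m.group("base2")),
            offset=int(m.group("off2") or 0),
            utr3=bool(m.group("star2")),
        )
    edit = next(g for g in (m.group("sub"), m.group("delins"),
                            m.group("del"), m.group("dup"), m.group("ins"))
                if g is not None)
    return CdnaChange(start=start, end=end, edit=edit)


@dataclass(frozen=True)
class ExonContext:
    """Position of a variant relative to the nearest exon-intron junction.

    Intronic positions carry a signed offset (negative = upstream of an
    acceptor, positive = downstream of a donor).  Exonic positions may carry
    a distance to the nearest junction, but only when an exon map supplied
    it — the cDNA notation alone cannot tell how far a plain exonic
    coordinate is from a junction, so ``exonic_distance`` is None until
    resolved.
    """

    region: str  # "intronic" | "exonic"
    signed_offset: int | None = None
    exonic_distance: int | None = None

    def __post_init__(self):
        if self.region not in ("intronic", "exonic"):
            raise DataError(f"unknown region {self.region!r}")
        if self.region == "intronic":
            if self.signed_offset is None or self.exonic_distance is not None:
                raise DataError("intronic context requires signed_offset only")
            if self.signed_offset == 0:
                raise DataError("intronic offset cannot be zero")
        else:
            if self.signed_offset is not None:
                raise DataError("exonic context cannot carry an intronic offset")
            if self.exonic_distance is not None and self.exonic_distance < 0:
                raise DataError("exonic_distance must be non-negative")

    @property
    def is_intronic(self) -> bool:
        return self.region == "intronic"

    @property
    def is_canonical_site(self) -> bool:
        """True at the invariant +/-1,2 splice dinucleotides."""
        return self.is_intronic and abs(self.signed_offset) in (1, 2)


def parse_cdna_offset(hgvs_c: str) -> ExonContext:
    """Locate a cDNA notation relative to exon-intron junctions.

    Returns an intronic context with the signed offset when the notation
    carries a +/- offset, and an exonic context (distance unresolved)
    otherwise.  Multi-position notations use the first position.
    """
    change = parse_cdna(hgvs_c)
    if change.start.offset != 0:
        return ExonContext(region="intronic", signed_offset=change.start.offset)
    return ExonContext(region="exonic")


# --------------------------------------------------------------------------
# Variant record
# --------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One observed variant: identity, consequence, depth, population frequency.

    ``patient_ids`` holds every cohort patient carrying the variant; a variant
    seen in several patients is still one record (counts of "unique variants"
    are counts of records).  ``population`` is an (allele_count, allele_number)
    pair from the reference population database, or None when the variant is
    absent from it — absence is meaningful and drives subclassification.
    """

    variant_id: str
    patient_ids: frozenset[str]
    gene: str
    transcript: str
    hgvs_c: str
    consequence: Consequence
    hgvs_p: str | None = None
    sca_type: str | None = None
    read_depth: int | None = None
    population: tuple[int, int] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.patient_ids, (list, tuple, set)):
            self.patient_ids = frozenset(self.patient_ids)
        if not self.patient_ids:
            raise DataError(f"{self.variant_id}: patient_ids must be non-empty")
        if self.read_depth is not None and self.read_depth < 0:
            raise DataError(f"{self.variant_id}: read_depth must be non-negative")
        if self.population is not None:
            ac, an = self.population
            if an <= 0:
                raise DataError(f"{self.variant_id}: allele_number must be positive")
            if ac < 0 or ac > an:
                raise DataError(
                    f"{self.variant_id}: allele_count must lie in [0, allele_number]"
                )
        self._check_canonical_consistency()

    def _check_canonical_consistency(self):
        # splice_canonical <=> intronic offset magnitude in {1,2}; only
        # checkable when the notation parses.
        try:
            ctx = parse_cdna_offset(self.hgvs_c)
        except HgvsParseError:
            return
        if self.consequence is Consequence.SPLICE_CANONICAL and not ctx.is_canonical_site:
            raise DataError(
                f"{self.variant_id}: splice_canonical requires an intronic "
                f"offset of magnitude 1 or 2 ({self.hgvs_c})"
            )
        if ctx.is_canonical_site and self.consequence not in (
            Consequence.SPLICE_CANONICAL,
        ):
            raise DataError(
                f"{self.variant_id}: {self.hgvs_c} lies at a canonical splice "
                f"site; consequence must be splice_canonical"
            )

    @property
    def maf(self) -> float | None:
        """Allele frequency allele_count/allele_number, or None if absent."""
        if self.population is None:
            return None
        ac, an = self.population
        return ac / an

    @property
    def exon_context(self) -> ExonContext:
        return parse_cdna_offset(self.hgvs_c)


def make_variant_id(transcript: str, hgvs_c: str) -> str:
    """Canonical variant key used to join tables (transcript:cDNA)."""
    return f"{transcript}:{hgvs_c}"
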