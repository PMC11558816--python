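"""Classify target-site amplicons into cardinal-locus allele classes.

Sequenced amplicons spanning the gRNA target are called as canonical wild
type, the defined SNP haplotype, a single contiguous indel near the cut site
(an NHEJ allele), or UNKNOWN. Drive presence is established separately from
the two cassette-junction amplicons; an allele-level drive call never comes
from the cardinal-locus amplicon (the cassette interrupts it).

Internally coordinates are 0-based half-open; protospacer positions in
reference definitions and outputs are 1-based, matching how target-site SNPs
are conventionally reported (e.g. "position 17 of the protospacer").
Indels are left-aligned: when several placements of the same indel explain
the sequence, the leftmost is reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

_VALID_BASES = set("ACGTN")


class CallClass(enum.Enum):
    WT_CANON = "wt"
    WT_SNP = "wt_snp"
    INDEL = "indel"
    DRIVE_JUNCTION = "drive_junction"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class TargetSiteRef:
    """Reference description of the gRNA target region.

    ``snp_defs`` holds known silent haplotypes as (1-based protospacer
    position, ref base, alt base). Cas9 cuts between protospacer positions
    17 and 18, i.e. 3 bp 5' of the PAM; ``cut_offset`` is that boundary as a
    0-based offset into the protospacer.
    """

    protospacer: str
    pam: str
    flank_left: str
    flank_right: str
    snp_defs: tuple[tuple[int, str, str], ...] = ()
    cut_offset: int = 17

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise ValueError("PAM must match NGG")
        if self.cut_offset != 17:
            raise ValueError("cut site is fixed 3 bp 5' of the PAM (17/18 boundary)")
        for pos, ref_base, _alt in self.snp_defs:
            if not 1 <= pos <= 20:
                raise ValueError(f"SNP position {pos} outside protospacer 1..20")
            if self.protospacer[pos - 1] != ref_base:
                raise ValueError(
                    f"SNP ref base mismatch at protospacer position {pos}"
                )

    @property
    def sequence(self) -> str:
        """Full reference amplicon."""
        return self.flank_left + self.protospacer + self.pam + self.flank_right

    @property
    def cut_position(self) -> int:
        """Cut-site coordinate in full-amplicon (0-based, between-base) space."""
        return len(self.flank_left) + self.cut_offset

    def apply_snp(self, i: int) -> str:
        """Reference sequence carrying snp_defs[i]."""
        pos, _ref, alt = self.snp_defs[i]
        j = len(self.flank_left) + pos - 1
        s = self.sequence
        return s[:j] + alt + s[j + 1:]


# A synthetic target-site reference with the geometry of the cardinal-locus
# assay (20-nt protospacer with an A at position 17, NGG PAM, 60-nt flanks).
# The flanking sequence is invented; only the geometry and the defined A->T
# transversion at protospacer position 17 matter to the analysis.
DEFAULT_TARGET_SITE = TargetSiteRef(
    protospacer="GCTTACGGTCAGTTCGAATC",
    pam="TGG",
    flank_left=(
        "ATGCGTCCTAGGATTCAGCTGTACCGGATAAGCTTGCACTCCGGTTAGACTGCAATGCGT"
    ),
    flank_right=(
        "CCATTGACGTAGCTTCAGGATCCGAATTGCCTAGCATCGGATTACGCTTGAGCCATAGCA"
    ),
    snp_defs=((17, "A", "T"),),
)


@dataclass(frozen=True)
class AlleleCall:
    """Classification of one amplicon (or junction evidence)."""

    call: CallClass
    indel_size: int = 0               # signed; deletions negative
    indel_span: tuple[int, int] | None = None  # half-open, ref coordinates
    snp_id: int | None = None         # index into TargetSiteRef.snp_defs
    in_frame: bool = False            # informational only

    def __post_init__(self) -> None:
        if self.call is CallClass.INDEL and self.indel_size == 0:
            raise ValueError("INDEL calls must have nonzero indel_size")


@dataclass(frozen=True)
class JunctionCall:
    """Drive-cassette junction PCR evidence (left and right homology arms)."""

    present: bool
    consistent: bool


@dataclass(frozen=True)
class GenotypeCall:
    """Individual-level call from 0-2 amplicon alleles plus junction evidence."""

    alleles: tuple[CallClass, ...]
    resolved: bool


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _common_suffix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


def classify_allele(seq: str, ref: TargetSiteRef, window: int = 10) -> AlleleCall:
    """Call one amplicon sequence against the target-site reference.

    Exact match -> WT_CANON; exact match except one defined SNP substitution
    -> WT_SNP; a single contiguous, left-aligned indel whose span intersects
    [cut - window, cut + window] -> INDEL with signed size and span. Anything
    else (substitutions outside the SNP definitions, indels far from the cut,
    multi-indel or complex differences) -> UNKNOWN, never a forced call.
    """
    seq = seq.upper()
    if not seq or set(seq) - _VALID_BASES:
        raise ValueError("sequence must be non-empty and contain only ACGTN")
    full = ref.sequence
    if seq == full:
        return AlleleCall(CallClass.WT_CANON)
    if len(seq) == len(full):
        diffs = [i for i in range(len(full)) if seq[i] != full[i]]
        if len(diffs) == 1:
            for snp_id in range(len(ref.snp_defs)):
                if seq == ref.apply_snp(snp_id):
                    return AlleleCall(CallClass.WT_SNP, snp_id=snp_id)
        return AlleleCall(CallClass.UNKNOWN)
    # length difference: test for a single contiguous indel via longest
    # common prefix/suffix; equivalent to an optimal global alignment with
    # one gap, with ties broken by leftmost placement
    size = len(seq) - len(full)
    short, long_ = (seq, full) if size < 0 else (full, seq)
    lcp = _common_prefix_len(seq, full)
    lcs = _common_suffix_len(seq, full)
    d = abs(size)
    lo = len(long_) - d - lcs  # leftmost admissible placement in the longer string
    if max(lo, 0) > min(lcp, len(short)):
        return AlleleCall(CallClass.UNKNOWN)  # not explicable by one indel
    start = max(lo, 0)
    # span in reference coordinates (deletion: removed bases; insertion: point)
    span = (start, start + d) if size < 0 else (start, start)
    cut = ref.cut_position
    if size < 0:
        overlaps = span[0] <= cut + window and span[1] >= cut - window
    else:
        overlaps = cut - window <= start <= cut + window
    if not overlaps:
        return AlleleCall(CallClass.UNKNOWN)
    return AlleleCall(
        CallClass.INDEL,
        indel_size=size,
        indel_span=span,
        in_frame=(size % 3 == 0),
    )


def detect_drive_junction(
    left_amplicon_present: bool, right_amplicon_present: bool
) -> JunctionCall:
    """Drive presence from the two homology-arm/cassette junction amplicons.

    Present only when both junctions amplify; one-sided amplification is
    flagged inconsistent (and treated as drive-negative by callers).
    """
    both = left_amplicon_present and right_amplicon_present
    neither = not left_amplicon_present and not right_amplicon_present
    return JunctionCall(present=both, consistent=both or neither)


def call_genotype(
    allele_calls: list[AlleleCall], junction: JunctionCall | bool
) -> GenotypeCall:
    """Combine 0-2 cardinal-locus allele calls with junction evidence.

    Junction-positive with one amplicon allele -> drive hemizygote; with no
    amplicon allele -> drive homozygote. Junction-negative requires exactly
    two amplicon alleles. Anything else is reported unresolved, not dropped.
    """
    if isinstance(junction, bool):
        junction = JunctionCall(present=junction, consistent=True)
    calls = tuple(c.call for c in allele_calls)
    if not junction.consistent or len(calls) > 2:
        return GenotypeCall(alleles=calls, resolved=False)
    if junction.present:
        if len(calls) == 0:
            return GenotypeCall(
                (CallClass.DRIVE_JUNCTION, CallClass.DRIVE_JUNCTION), resolved=True
            )
        if len(calls) == 1:
            return GenotypeCall(
                (CallClass.DRIVE_JUNCTION, calls[0]),
                resolved=calls[0] is not CallClass.UNKNOWN,
            )
        return GenotypeCall(calls, resolved=False)
    if len(calls) == 2:
        return GenotypeCall(
            calls, resolved=CallClass.UNKNOWN not in calls
        )
    return GenotypeCall(alleles=calls, resolved=False)
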