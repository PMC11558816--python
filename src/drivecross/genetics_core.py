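"""Domain types for the cardinal-locus drive system and the genotype→phenotype map.

The drive cassette is inserted at the autosomal *cardinal* eye-pigment locus and
carries a dominant CFP marker. Five allele classes matter downstream:

* ``DRIVE`` — the cassette itself; cardinal loss-of-function, CFP-marked.
* ``WT_CANON`` — the canonical wild-type target site.
* ``WT_SNP`` — wild type carrying the A→T transversion at protospacer
  position 17 (segregates in the NDOKAYO background); phenotypically black,
  its only distinction is potential resistance to gRNA recognition.
* ``NHEJ_FUNC`` — an end-joining repair allele that preserves cardinal
  function (black eyes).
* ``NHEJ_LOF`` — an end-joining allele that destroys cardinal function.

Eye colour is read from the *somatic* state: individuals with two
loss-of-function alleles (or a fully mutated soma) show red "cardinal" eyes;
partial somatic mosaicism shows as small or big "tears" of missing pigment.
Parent of origin is tracked on every genotype because maternally deposited
Cas9/gRNA acts specifically on the paternally contributed allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class AlleleClass(enum.Enum):
    """Cardinal-locus allele classes."""

    DRIVE = "drive"
    WT_CANON = "wt"
    WT_SNP = "wt_snp"
    NHEJ_FUNC = "nhej_r1"
    NHEJ_LOF = "nhej_r2"

    @property
    def is_functional(self) -> bool:
        """True if the allele supports cardinal (black-eye) pigment function."""
        return self in _FUNCTIONAL

    @property
    def is_lof(self) -> bool:
        return self in _LOF

    @property
    def is_wt_class(self) -> bool:
        """True for unmodified wild-type target sites (canonical or SNP)."""
        return self in (AlleleClass.WT_CANON, AlleleClass.WT_SNP)

    @property
    def is_cfp_marked(self) -> bool:
        return self is AlleleClass.DRIVE


_FUNCTIONAL = frozenset(
    {AlleleClass.WT_CANON, AlleleClass.WT_SNP, AlleleClass.NHEJ_FUNC}
)
_LOF = frozenset({AlleleClass.DRIVE, AlleleClass.NHEJ_LOF})


class Mosaic(enum.Enum):
    """Extent of somatic cardinal loss-of-function in eye tissue.

    ``SMALL``/``LARGE`` are the categorical tear classes separated at the
    screening boundary of >25% missing pigment; ``FULL`` means every eye cell
    carries a loss-of-function lesion (cardinal eyes despite a functional
    inherited allele).
    """

    NONE = "none"
    SMALL = "small"
    LARGE = "large"
    FULL = "full"


class Eye(enum.Enum):
    BLACK = "black"
    SMALL_TEAR = "small_tear"
    BIG_TEAR = "big_tear"
    CARDINAL = "cardinal"


class Cfp(enum.Enum):
    POS = "pos"
    NEG = "neg"


class Sex(enum.Enum):
    M = "M"
    F = "F"


class Lineage(enum.Enum):
    """Which parent of the founding cross carried the drive."""

    MALE_DRIVE_PARENT = "male_drive_parent"
    FEMALE_DRIVE_PARENT = "female_drive_parent"


@dataclass(frozen=True, slots=True)
class Genotype:
    """Diploid cardinal-locus state with parent-of-origin and somatic mosaicism.

    ``maternal``/``paternal`` record the heritable alleles; ``mosaic`` records
    somatic loss-of-function acquired in the embryo (maternal deposition or
    leaky Cas9), which affects the eye but not necessarily the germ line.
    """

    maternal: AlleleClass
    paternal: AlleleClass
    mosaic: Mosaic = Mosaic.NONE

    def __post_init__(self) -> None:
        if self.mosaic is not Mosaic.NONE and not (
            self.maternal.is_functional or self.paternal.is_functional
        ):
            raise ValueError(
                "somatic mosaicism requires at least one functional inherited "
                f"allele; got ({self.maternal.value}, {self.paternal.value}, "
                f"{self.mosaic.value})"
            )

    @property
    def has_drive(self) -> bool:
        return AlleleClass.DRIVE in (self.maternal, self.paternal)

    @property
    def alleles(self) -> tuple[AlleleClass, AlleleClass]:
        return (self.maternal, self.paternal)


@dataclass(frozen=True, slots=True)
class Phenotype:
    """Screened pupal phenotype: eye class, CFP fluorescence, optional sex."""

    eye: Eye
    cfp: Cfp
    sex: Sex | None = None


@dataclass(frozen=True)
class CrossSpec:
    """Identity and genetics of one introduction/introgression cross.

    ``hybrid_male_sterile`` encodes Haldane's rule: F1 hybrid males of an
    introgression into the heterogametic-incompatible sibling species
    (*An. arabiensis* Dongola in the source experiments) are sterile, so no
    F2 can be produced. ``snp_freq`` is the frequency of the target-site SNP
    haplotype among wild-type alleles of the background strain.
    """

    background: str
    lineage: Lineage
    hybrid_male_sterile: bool = False
    snp_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.snp_freq <= 1.0:
            raise ValueError(f"snp_freq must be in [0, 1], got {self.snp_freq}")


def phenotype_from_genotype(g: Genotype) -> Phenotype:
    """Deterministic genotype→phenotype map used by screening and simulation.

    CFP is strictly dominant and strictly a function of drive presence. Eye
    colour reads the somatic state: cardinal when both inherited alleles are
    loss-of-function or the soma is fully mutated, tears for partial
    mosaicism, black otherwise. The SNP haplotype is phenotypically silent.
    """
    cfp = Cfp.POS if g.has_drive else Cfp.NEG
    both_lof = g.maternal.is_lof and g.paternal.is_lof
    if both_lof or g.mosaic is Mosaic.FULL:
        eye = Eye.CARDINAL
    elif g.mosaic is Mosaic.LARGE:
        eye = Eye.BIG_TEAR
    elif g.mosaic is Mosaic.SMALL:
        eye = Eye.SMALL_TEAR
    else:
        eye = Eye.BLACK
    return Phenotype(eye=eye, cfp=cfp)


def enumerate_genotype_space() -> list[Genotype]:
    """All representable (maternal, paternal, mosaic) states.

    The full 5×5×4 grid minus states where mosaicism is claimed without any
    functional inherited allele to mutate.
    """
    out: list[Genotype] = []
    for mat in AlleleClass:
        for pat in AlleleClass:
            for mos in Mosaic:
                try:
                    out.append(Genotype(mat, pat, mos))
                except ValueError:
                    continue
    return out
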