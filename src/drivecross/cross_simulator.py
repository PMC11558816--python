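"""Forward simulator of the three-generation cage-cross design.

Reproduces the experimental structure used to characterise a Cas9/gRNA homing
drive: reciprocal parental crosses (75 homozygous drive adults x 75 wild types
per cage, three replicate cages), an F1 intercross of ~150 randomly chosen
hybrids per replicate, phenotype-specific backcrosses of 15-20 F1 males to
wild-type females, and phenotype-stratified sequencing subsamples.

Drive genetics model
--------------------
Germline, per wild-type-class allele in a drive-carrying germ line: the
target is cut with probability ``c``; a cut is resolved by homology-directed
repair (copying the drive) with probability ``h``, otherwise by end joining,
which is loss-of-function with probability ``beta``. The composite germline
conversion rate is ``e = c*h``. Pre-existing end-joining alleles are never
re-cut; the SNP haplotype escapes cutting when ``snp_cleavable`` is false.

Embryonic (maternal) effect: eggs from drive-carrying mothers contain
deposited Cas9/gRNA that cleaves the *paternally* contributed functional
allele with probability ``m``. The embryonic repair is loss-of-function with
probability ``beta``; loss-of-function events produce visible somatic
mosaicism (small tear / big tear / fully cardinal eyes, drawn from
``dep_outcome``) and reach the germ line with per-category probability
``g_germ`` (a fully mutated soma always carries the lesion in the germ line).
In-frame functional repair leaves the eye black; such alleles reach the germ
line with probability ``g_germ_func``. Paternal-lineage "leaky" somatic Cas9
activity produces small tears at rate ``lam`` with no heritable consequence.

Each individual therefore tracks three paternal-slot states: the zygotic
allele (what the father's gamete carried — determines the inherited-genotype
phenotype), the somatic call (what carcass sequencing reports), and the
germline allele (what enters this individual's own gametes).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics_core import (
    AlleleClass,
    Cfp,
    CrossSpec,
    Eye,
    Genotype,
    Lineage,
    Mosaic,
    Phenotype,
    Sex,
    phenotype_from_genotype,
)

# CSV schemas shared with the I/O layer.
COUNT_COLUMNS = [
    "cross_id",
    "background",
    "lineage",
    "generation",
    "replicate",
    "eye",
    "cfp",
    "count",
]
SUBSET_COLUMNS = [
    "cross_id",
    "generation",
    "replicate",
    "eye",
    "cfp",
    "individual_id",
    "allele_m",
    "allele_p",
    "mosaic",
]

_DEP_CATEGORIES = (Mosaic.SMALL, Mosaic.LARGE, Mosaic.FULL)


@dataclass(frozen=True)
class SimParams:
    """All drive-dynamics rates and cage design sizes.

    Rates are probabilities in [0, 1]. ``c`` and ``h`` are not separately
    measurable from phenotype data; the defaults here (with ``m``, ``beta``,
    ``dep_outcome``, ``g_germ`` and ``lam``) were chosen once to place the
    simulated F1/F2 phenotype spectra inside the ranges the cage experiments
    produced, and are documented as fitted-by-eye in the methods note.
    """

    c: float = 0.995          # germline cut probability per cleavable allele
    h: float = 0.995          # HDR fraction given a germline cut (e = c*h)
    beta: float = 0.93        # loss-of-function fraction of NHEJ repairs
    m: float = 0.84           # maternal-deposition cleavage probability
    dep_outcome: tuple[float, float, float] = (0.36, 0.54, 0.10)
    g_germ: tuple[float, float, float] = (0.10, 0.15, 1.0)
    g_germ_func: float = 1.0  # germline carriage of functional embryonic repairs
    lam: float = 0.004        # paternal-lineage leaky somatic mosaicism rate
    snp_cleavable: bool = True
    n_parents: int = 75       # adults per sex per parental cage
    n_f1_intercross: int = 150
    n_backcross: int = 18     # males per phenotype-specific backcross
    replicates: int = 3
    mean_progeny: float = 1500.0  # expected scored progeny per cage
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "beta", "m", "lam", "g_germ_func"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.dep_outcome) != 3 or any(p < 0 for p in self.dep_outcome):
            raise ValueError("dep_outcome must be 3 non-negative probabilities")
        if abs(sum(self.dep_outcome) - 1.0) > 1e-9:
            raise ValueError("dep_outcome must sum to 1 within 1e-9")
        if len(self.g_germ) != 3 or any(not 0 <= p <= 1 for p in self.g_germ):
            raise ValueError("g_germ must be 3 probabilities in [0, 1]")
        if self.mean_progeny <= 0:
            raise ValueError("mean_progeny must be > 0")
        for name in ("n_parents", "n_f1_intercross", "n_backcross", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(slots=True)
class Individual:
    """One mosquito: zygotic, somatic and germline cardinal-locus state.

    The maternal slot is never modified post-zygotically (deposition acts on
    the male-contributed allele only), so a single ``maternal`` field serves
    all three roles.
    """

    maternal: AlleleClass
    paternal: AlleleClass          # zygotic (father's gamete)
    somatic_paternal: AlleleClass  # what carcass sequencing reports
    germline_paternal: AlleleClass  # what this individual transmits
    mosaic: Mosaic
    sex: Sex

    @property
    def phenotype(self) -> Phenotype:
        return phenotype_from_genotype(
            Genotype(self.maternal, self.paternal, self.mosaic)
        )

    @property
    def heritable(self) -> Genotype:
        """Genotype whose alleles enter this individual's gametes."""
        return Genotype(self.maternal, self.germline_paternal, Mosaic.NONE)

    @property
    def has_drive(self) -> bool:
        return AlleleClass.DRIVE in (self.maternal, self.paternal)


def _cleavable(allele: AlleleClass, params: SimParams) -> bool:
    """Wild-type-class alleles recognisable by the gRNA."""
    if allele is AlleleClass.WT_CANON:
        return True
    if allele is AlleleClass.WT_SNP:
        return params.snp_cleavable
    return False


def gametes_of(parent: Genotype, params: SimParams) -> dict[AlleleClass, float]:
    """Closed-form gamete allele distribution of ``parent``.

    Drive-carrying hemizygotes convert a cleavable wild-type-class partner
    allele: DRIVE with (1 + c*h)/2, NHEJ (split beta : 1-beta into
    loss-of-function : functional) with c*(1-h)/2, unmodified with (1-c)/2.
    Parents without a drive allele (no Cas9 source) and pre-existing NHEJ
    alleles segregate without modification.
    """
    a, b = parent.maternal, parent.paternal
    if not parent.has_drive:
        dist: dict[AlleleClass, float] = {}
        for allele in (a, b):
            dist[allele] = dist.get(allele, 0.0) + 0.5
        return dist
    other = b if a is AlleleClass.DRIVE else a
    if other is AlleleClass.DRIVE:
        return {AlleleClass.DRIVE: 1.0}
    if not _cleavable(other, params):
        return {AlleleClass.DRIVE: 0.5, other: 0.5}
    c, h, beta = params.c, params.h, params.beta
    dist = {
        AlleleClass.DRIVE: (1.0 + c * h) / 2.0,
        AlleleClass.NHEJ_LOF: c * (1.0 - h) * beta / 2.0,
        AlleleClass.NHEJ_FUNC: c * (1.0 - h) * (1.0 - beta) / 2.0,
        other: (1.0 - c) / 2.0,
    }
    return {k: v for k, v in dist.items() if v > 0.0}


def _draw_from(dist: dict[AlleleClass, float], rng: np.random.Generator) -> AlleleClass:
    u = rng.random()
    acc = 0.0
    last = None
    for allele, p in dist.items():
        acc += p
        last = allele
        if u < acc:
            return allele
    return last  # numerical slack


def apply_maternal_deposition(
    zygote: Individual, mother_has_drive: bool, params: SimParams, rng: np.random.Generator
) -> Individual:
    """Apply embryonic Cas9/gRNA deposition to the paternal allele in place.

    Only embryos from drive-carrying mothers whose paternal allele is a
    cleavable wild-type-class allele are affected. Loss-of-function repair
    yields a somatic mosaic category (small/large/full) and, with the
    per-category germline-carriage probability, a heritable NHEJ_LOF allele
    (always heritable for a fully mutated soma). Functional repair leaves the
    eye black and is heritable with probability ``g_germ_func``.
    """
    if not mother_has_drive or params.m == 0.0:
        return zygote
    if not _cleavable(zygote.paternal, params):
        return zygote
    if rng.random() >= params.m:
        return zygote
    if rng.random() < params.beta:  # loss-of-function embryonic repair
        u = rng.random()
        if u < params.dep_outcome[0]:
            cat = 0
        elif u < params.dep_outcome[0] + params.dep_outcome[1]:
            cat = 1
        else:
            cat = 2
        if cat == 2:  # fully mutated soma: cardinal eyes, always germline
            zygote.mosaic = Mosaic.FULL
            zygote.somatic_paternal = AlleleClass.NHEJ_LOF
            zygote.germline_paternal = AlleleClass.NHEJ_LOF
        else:
            zygote.mosaic = _DEP_CATEGORIES[cat]
            # majority of somatic cells keep the zygotic allele; the carcass
            # call stays zygotic, only the germ line may carry the lesion
            if rng.random() < params.g_germ[cat]:
                zygote.germline_paternal = AlleleClass.NHEJ_LOF
    else:  # functional embryonic repair: black eyes, detectable by sequencing
        zygote.somatic_paternal = AlleleClass.NHEJ_FUNC
        if rng.random() < params.g_germ_func:
            zygote.germline_paternal = AlleleClass.NHEJ_FUNC
    return zygote


def _make_offspring(
    mother: Individual,
    father: Individual,
    params: SimParams,
    rng: np.random.Generator,
) -> Individual:
    mat = _draw_from(gametes_of(mother.heritable, params), rng)
    pat = _draw_from(gametes_of(father.heritable, params), rng)
    ind = Individual(
        maternal=mat,
        paternal=pat,
        somatic_paternal=pat,
        germline_paternal=pat,
        mosaic=Mosaic.NONE,
        sex=Sex.M if rng.random() < 0.5 else Sex.F,
    )
    mother_has_drive = mother.heritable.has_drive
    if mother_has_drive:
        apply_maternal_deposition(ind, True, params, rng)
    elif (
        params.lam > 0.0
        and ind.has_drive
        and (ind.maternal.is_functional or ind.paternal.is_functional)
        and rng.random() < params.lam
    ):
        # leaky/paternal somatic Cas9: small pigment tears, no heritable change
        ind.mosaic = Mosaic.SMALL
    return ind


def _wt_individual(spec: CrossSpec, sex: Sex, rng: np.random.Generator) -> Individual:
    def wt_allele() -> AlleleClass:
        if spec.snp_freq > 0.0 and rng.random() < spec.snp_freq:
            return AlleleClass.WT_SNP
        return AlleleClass.WT_CANON

    a, b = wt_allele(), wt_allele()
    return Individual(a, b, b, b, Mosaic.NONE, sex)


def _drive_individual(sex: Sex) -> Individual:
    d = AlleleClass.DRIVE
    return Individual(d, d, d, d, Mosaic.NONE, sex)


def _count_rows(
    pop: list[Individual],
    spec: CrossSpec,
    generation: str,
    replicate: int,
) -> list[dict]:
    counts = Counter((ind.phenotype.eye, ind.phenotype.cfp) for ind in pop)
    cross_id = f"{spec.background}_{spec.lineage.value}"
    return [
        {
            "cross_id": cross_id,
            "background": spec.background,
            "lineage": spec.lineage.value,
            "generation": generation,
            "replicate": replicate,
            "eye": eye.value,
            "cfp": cfp.value,
            "count": n,
        }
        for (eye, cfp), n in sorted(counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
    ]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=COUNT_COLUMNS)


def run_parental_cross(
    spec: CrossSpec, params: SimParams
) -> tuple[pd.DataFrame, dict[int, list[Individual]]]:
    """Simulate the replicate parental cages and score the F1 progeny.

    Each replicate cage holds ``n_parents`` homozygous drive adults of the
    lineage-defining sex and ``n_parents`` wild types of the opposite sex;
    scored progeny totals are Poisson around ``mean_progeny``. Returns the
    phenotype count table and the F1 population per replicate.
    """
    rows: list[dict] = []
    f1: dict[int, list[Individual]] = {}
    for r in range(params.replicates):
        rng = np.random.default_rng(params.seed + r)
        if spec.lineage is Lineage.FEMALE_DRIVE_PARENT:
            mothers = [_drive_individual(Sex.F) for _ in range(params.n_parents)]
            fathers = [_wt_individual(spec, Sex.M, rng) for _ in range(params.n_parents)]
        else:
            mothers = [_wt_individual(spec, Sex.F, rng) for _ in range(params.n_parents)]
            fathers = [_drive_individual(Sex.M) for _ in range(params.n_parents)]
        n = int(rng.poisson(params.mean_progeny))
        pop = [
            _make_offspring(
                mothers[rng.integers(len(mothers))],
                fathers[rng.integers(len(fathers))],
                params,
                rng,
            )
            for _ in range(n)
        ]
        rows.extend(_count_rows(pop, spec, "F1", r))
        f1[r] = pop
    return pd.DataFrame(rows, columns=COUNT_COLUMNS), f1


def run_f1_intercross(
    f1: dict[int, list[Individual]], spec: CrossSpec, params: SimParams
) -> tuple[pd.DataFrame, dict[int, list[Individual]]]:
    """Intercross ~``n_f1_intercross`` random F1 hybrids per replicate.

    Gametes are drawn from heritable genotypes (somatic mosaicism does not
    transmit); drive-carrying F1 mothers deposit Cas9 into their embryos. A
    Haldane's-rule cross (``hybrid_male_sterile``) yields an empty table and
    no F2 — the sterility is the result, not an error.
    """
    if spec.hybrid_male_sterile:
        return _empty_table(), {r: [] for r in f1}
    rows: list[dict] = []
    f2: dict[int, list[Individual]] = {}
    for r, pop in f1.items():
        rng = np.random.default_rng(params.seed + 1009 + r)
        if not pop:
            f2[r] = []
            continue
        k = min(params.n_f1_intercross, len(pop))
        cage = [pop[i] for i in rng.choice(len(pop), size=k, replace=False)]
        mothers = [i for i in cage if i.sex is Sex.F]
        fathers = [i for i in cage if i.sex is Sex.M]
        if not mothers or not fathers:
            f2[r] = []
            continue
        n = int(rng.poisson(params.mean_progeny))
        prog = [
            _make_offspring(
                mothers[rng.integers(len(mothers))],
                fathers[rng.integers(len(fathers))],
                params,
                rng,
            )
            for _ in range(n)
        ]
        rows.extend(_count_rows(prog, spec, "F2", r))
        f2[r] = prog
    return pd.DataFrame(rows, columns=COUNT_COLUMNS), f2


def run_backcross(
    f1_males: list[Individual],
    spec: CrossSpec,
    params: SimParams,
    replicate: int = 0,
) -> tuple[pd.DataFrame, list[Individual]]:
    """Backcross phenotype-selected F1 males to wild-type females.

    Drive inheritance among the progeny reflects the males' heritable
    genotypes: a male whose germ line carries (drive, NHEJ) transmits the
    drive to 50% of progeny regardless of conversion parameters, because
    end-joining alleles are never re-cut.
    """
    if not f1_males:
        return _empty_table(), []
    phenos = {(m.phenotype.eye, m.phenotype.cfp) for m in f1_males}
    if len(phenos) > 1:
        raise ValueError("backcross males must share one phenotype class")
    rng = np.random.default_rng(params.seed + 2003 + replicate)
    k = min(params.n_backcross, len(f1_males))
    males = [f1_males[i] for i in rng.choice(len(f1_males), size=k, replace=False)]
    females = [_wt_individual(spec, Sex.F, rng) for _ in range(params.n_backcross)]
    n = int(rng.poisson(params.mean_progeny))
    prog = [
        _make_offspring(
            females[rng.integers(len(females))],
            males[rng.integers(len(males))],
            params,
            rng,
        )
        for _ in range(n)
    ]
    return pd.DataFrame(_count_rows(prog, spec, "BC", replicate), columns=COUNT_COLUMNS), prog


def sequence_subsample(
    pop: list[Individual],
    eye: Eye,
    cfp: Cfp,
    n: int,
    rng: np.random.Generator,
    *,
    spec: CrossSpec | None = None,
    generation: str = "",
    replicate: int = 0,
) -> pd.DataFrame:
    """Uniform sample (without replacement) of a phenotype class for sequencing.

    Rows report the carcass-sequencing allele calls (maternal allele and the
    somatic paternal call); all of the class if fewer than ``n`` members.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    members = [
        (i, ind)
        for i, ind in enumerate(pop)
        if ind.phenotype.eye is eye and ind.phenotype.cfp is cfp
    ]
    if n < len(members):
        idx = rng.choice(len(members), size=n, replace=False)
        members = [members[i] for i in sorted(idx)]
    cross_id = f"{spec.background}_{spec.lineage.value}" if spec else ""
    rows = [
        {
            "cross_id": cross_id,
            "generation": generation,
            "replicate": replicate,
            "eye": eye.value,
            "cfp": cfp.value,
            "individual_id": f"{generation or 'ind'}_{replicate}_{i}",
            "allele_m": ind.maternal.value,
            "allele_p": ind.somatic_paternal.value,
            "mosaic": ind.mosaic.value,
        }
        for i, ind in members
    ]
    return pd.DataFrame(rows, columns=SUBSET_COLUMNS)


def emit_amplicons(subset: pd.DataFrame, ref, rng: np.random.Generator):
    """Synthesise target-site amplicon sequences for a sequenced subset.

    One FASTA record per non-drive allele per individual: the canonical
    reference for WT, the defined transversion haplotype for the SNP allele,
    and a random 1-12 bp indel overlapping the cut site for NHEJ alleles
    (Cas9 cuts between protospacer positions 17 and 18, 3 bp from the PAM).
    Drive alleles produce no cardinal-locus amplicon; they are reported via a
    per-individual junction-positive flag. Returns ``(records, junctions)``.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    full = ref.sequence
    cut = ref.cut_position
    records: list[SeqRecord] = []
    junctions: dict[str, bool] = {}
    for row in subset.itertuples(index=False):
        ind_id = row.individual_id
        junctions.setdefault(ind_id, False)
        for slot, code in (("m", row.allele_m), ("p", row.allele_p)):
            allele = AlleleClass(code)
            if allele is AlleleClass.DRIVE:
                junctions[ind_id] = True
                continue
            if allele is AlleleClass.WT_CANON:
                seq = full
            elif allele is AlleleClass.WT_SNP:
                seq = ref.apply_snp(0)
            else:  # NHEJ allele: random small indel spanning the cut
                size = int(rng.integers(1, 13))
                if rng.random() < 0.5:  # deletion
                    start = int(rng.integers(cut - size, cut + 1))
                    start = max(0, min(start, len(full) - size))
                    seq = full[:start] + full[start + size:]
                else:  # insertion at the cut
                    ins = "".join(rng.choice(list("ACGT"), size=size))
                    seq = full[:cut] + ins + full[cut:]
            records.append(
                SeqRecord(Seq(seq), id=f"{ind_id}|{slot}|{code}", description="")
            )
    return records, junctions


def phenotype_class_fractions(pop: list[Individual]) -> dict[tuple[Eye, Cfp], float]:
    """Observed phenotype-class fractions of a population (sums to 1)."""
    if not pop:
        return {}
    counts = Counter((ind.phenotype.eye, ind.phenotype.cfp) for ind in pop)
    total = len(pop)
    return {k: v / total for k, v in counts.items()}
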