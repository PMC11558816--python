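"""Forward cage-cross simulator: gametogenesis, deposition, cross designs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drivecross import (
    AlleleClass,
    Cfp,
    CrossSpec,
    Eye,
    Genotype,
    Individual,
    Lineage,
    Mosaic,
    Sex,
    SimParams,
    apply_maternal_deposition,
    gametes_of,
    phenotype_from_genotype,
    run_backcross,
    run_f1_intercross,
    run_parental_cross,
    sequence_subsample,
)
from drivecross.cross_simulator import _draw_from

A = AlleleClass


def hemizygote(other=A.WT_CANON, germline=None):
    g = germline if germline is not None else other
    return Individual(A.DRIVE, other, other, g, Mosaic.NONE, Sex.M)


# ---------------------------------------------------------------------------
# gametes_of


def test_gamete_distribution_homozygotes():
    p = SimParams()
    assert gametes_of(Genotype(A.DRIVE, A.DRIVE), p) == {A.DRIVE: 1.0}
    assert gametes_of(Genotype(A.WT_CANON, A.WT_CANON), p) == {A.WT_CANON: 1.0}


def test_gamete_distribution_full_conversion():
    p = SimParams(c=1.0, h=1.0)
    assert gametes_of(Genotype(A.DRIVE, A.WT_CANON), p) == {A.DRIVE: 1.0}


def test_gamete_distribution_hemizygote_closed_form():
    # frozen arithmetic: P(DRIVE)=(1+ch)/2, NHEJ split beta:1-beta, WT (1-c)/2
    p = SimParams(c=0.99, h=0.98, beta=0.8)
    d = gametes_of(Genotype(A.DRIVE, A.WT_CANON), p)
    assert d[A.DRIVE] == pytest.approx(0.9851)
    assert d[A.NHEJ_LOF] == pytest.approx(0.00792)
    assert d[A.NHEJ_FUNC] == pytest.approx(0.00198)
    assert d[A.WT_CANON] == pytest.approx(0.005)


def test_snp_allele_escapes_conversion_when_uncleavable():
    p = SimParams(snp_cleavable=False)
    d = gametes_of(Genotype(A.DRIVE, A.WT_SNP), p)
    assert d == {A.DRIVE: 0.5, A.WT_SNP: 0.5}
    # cleavable SNP behaves like canonical wild type
    p2 = SimParams(snp_cleavable=True, c=0.9, h=0.9)
    d2 = gametes_of(Genotype(A.DRIVE, A.WT_SNP), p2)
    assert d2[A.DRIVE] == pytest.approx((1 + 0.81) / 2)


def test_nhej_alleles_never_recut():
    p = SimParams(c=1.0, h=1.0)
    for allele in (A.NHEJ_FUNC, A.NHEJ_LOF):
        assert gametes_of(Genotype(A.DRIVE, allele), p) == {A.DRIVE: 0.5, allele: 0.5}


def test_nondrive_parents_segregate_mendelian():
    p = SimParams(c=1.0, h=1.0)
    d = gametes_of(Genotype(A.NHEJ_FUNC, A.WT_CANON), p)
    assert d == {A.NHEJ_FUNC: 0.5, A.WT_CANON: 0.5}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    c=st.floats(0, 1), h=st.floats(0, 1), beta=st.floats(0, 1),
    other=st.sampled_from([A.WT_CANON, A.WT_SNP, A.NHEJ_FUNC, A.NHEJ_LOF]),
)
def test_gamete_distribution_is_normalised(c, h, beta, other):
    p = SimParams(c=c, h=h, beta=beta)
    d = gametes_of(Genotype(A.DRIVE, other), p)
    assert all(v >= 0 for v in d.values())
    assert sum(d.values()) == pytest.approx(1.0)


def test_simulated_gamete_frequencies_match_closed_form(rng):
    """Chi-square of 1e5 sampled gametes against the analytic distribution."""
    p = SimParams(c=0.9, h=0.8, beta=0.6)
    dist = gametes_of(Genotype(A.DRIVE, A.WT_CANON), p)
    alleles = list(dist)
    draws = [_draw_from(dist, rng) for _ in range(100_000)]
    obs = np.array([draws.count(a) for a in alleles])
    exp = np.array([dist[a] * 100_000 for a in alleles])
    _, pval = stats.chisquare(obs, exp)
    assert pval > 0.001


# ---------------------------------------------------------------------------
# maternal deposition


def _fresh_zygote():
    return Individual(A.DRIVE, A.WT_CANON, A.WT_CANON, A.WT_CANON, Mosaic.NONE, Sex.F)


def test_deposition_noop_cases(rng):
    z = _fresh_zygote()
    out = apply_maternal_deposition(z, True, SimParams(m=0.0), rng)
    assert out.mosaic is Mosaic.NONE and out.germline_paternal is A.WT_CANON
    out = apply_maternal_deposition(_fresh_zygote(), False, SimParams(m=1.0), rng)
    assert out.mosaic is Mosaic.NONE and out.germline_paternal is A.WT_CANON


def test_deposition_all_full_gives_cardinal_cfp_positive(rng):
    p = SimParams(m=1.0, beta=1.0, dep_outcome=(0.0, 0.0, 1.0))
    for _ in range(50):
        z = apply_maternal_deposition(_fresh_zygote(), True, p, rng)
        assert z.mosaic is Mosaic.FULL
        assert z.germline_paternal is A.NHEJ_LOF
        ph = phenotype_from_genotype(Genotype(z.maternal, z.paternal, z.mosaic))
        assert ph.eye is Eye.CARDINAL and ph.cfp is Cfp.POS


def test_deposition_spares_uncleavable_snp(rng):
    p = SimParams(m=1.0, snp_cleavable=False)
    z = Individual(A.DRIVE, A.WT_SNP, A.WT_SNP, A.WT_SNP, Mosaic.NONE, Sex.F)
    out = apply_maternal_deposition(z, True, p, rng)
    assert out.mosaic is Mosaic.NONE and out.germline_paternal is A.WT_SNP


def test_deposition_functional_repair_keeps_black_eye(rng):
    # beta=0: every embryonic repair is in-frame functional -> black eyes,
    # sequencing-detectable functional NHEJ allele
    p = SimParams(m=1.0, beta=0.0, g_germ_func=1.0)
    z = apply_maternal_deposition(_fresh_zygote(), True, p, rng)
    assert z.mosaic is Mosaic.NONE
    assert z.somatic_paternal is A.NHEJ_FUNC
    assert z.germline_paternal is A.NHEJ_FUNC
    assert phenotype_from_genotype(Genotype(z.maternal, z.paternal, z.mosaic)).eye is Eye.BLACK


# ---------------------------------------------------------------------------
# cross designs


def test_parental_cross_all_f1_cfp_positive(female_lineage_spec, male_lineage_spec):
    params = SimParams(seed=5, mean_progeny=400.0)
    for spec in (female_lineage_spec, male_lineage_spec):
        table, f1 = run_parental_cross(spec, params)
        assert set(table["cfp"]) == {"pos"}
        for pop in f1.values():
            for ind in pop:
                assert ind.has_drive
                # allele conservation: one allele from each parental pool
                if spec.lineage is Lineage.FEMALE_DRIVE_PARENT:
                    assert ind.maternal is A.DRIVE
                    assert ind.paternal is not A.DRIVE
                else:
                    assert ind.paternal is A.DRIVE
                    assert ind.maternal is not A.DRIVE


def test_male_lineage_small_tear_rate_matches_leak_rate(male_lineage_spec):
    lam = 0.004
    params = SimParams(seed=9, lam=lam, mean_progeny=40_000.0, replicates=1)
    table, _ = run_parental_cross(male_lineage_spec, params)
    total = table["count"].sum()
    tears = table.loc[table["eye"] == "small_tear", "count"].sum()
    lo, hi = stats.binom.interval(0.999, total, lam)
    assert lo <= tears <= hi


def test_sterile_cross_yields_no_f2(female_lineage_spec, default_params):
    spec = CrossSpec("AaDON", Lineage.FEMALE_DRIVE_PARENT, hybrid_male_sterile=True)
    _, f1 = run_parental_cross(spec, default_params)
    table, f2 = run_f1_intercross(f1, spec, default_params)
    assert table.empty
    assert all(len(pop) == 0 for pop in f2.values())


def test_f2_fully_driven_when_conversion_complete(female_lineage_spec):
    params = SimParams(c=1.0, h=1.0, m=0.0, lam=0.0, seed=3,
                       mean_progeny=2000.0, replicates=1)
    _, f1 = run_parental_cross(female_lineage_spec, params)
    table, _ = run_f1_intercross(f1, female_lineage_spec, params)
    assert set(table["cfp"]) == {"pos"}


def test_backcross_nhej_carrier_males_transmit_mendelian(female_lineage_spec):
    # heritable (drive, NHEJ_LOF): the resistant allele is never re-cut,
    # so the drive is inherited by ~50% regardless of conversion rates
    params = SimParams(c=0.99, h=0.98, seed=17, mean_progeny=20_000.0)
    males = [hemizygote(A.WT_CANON, germline=A.NHEJ_LOF) for _ in range(18)]
    table, _ = run_backcross(males, female_lineage_spec, params)
    pos = table.loc[table["cfp"] == "pos", "count"].sum()
    total = table["count"].sum()
    lo, hi = stats.binom.interval(0.999, total, 0.5)
    assert lo <= pos <= hi


def test_backcross_wt_carrier_males_transmit_super_mendelian(female_lineage_spec):
    params = SimParams(c=0.99, h=0.98, seed=19, mean_progeny=20_000.0)
    males = [hemizygote(A.WT_CANON) for _ in range(18)]
    table, _ = run_backcross(males, female_lineage_spec, params)
    pos = table.loc[table["cfp"] == "pos", "count"].sum()
    total = table["count"].sum()
    expected = (1 + 0.99 * 0.98) / 2
    lo, hi = stats.binom.interval(0.999, total, expected)
    assert lo <= pos <= hi


def test_backcross_contracts(female_lineage_spec, default_params):
    table, prog = run_backcross([], female_lineage_spec, default_params)
    assert table.empty and prog == []
    mixed = [hemizygote(A.WT_CANON), hemizygote(A.NHEJ_LOF)]  # black vs cardinal
    with pytest.raises(ValueError):
        run_backcross(mixed, female_lineage_spec, default_params)


# ---------------------------------------------------------------------------
# sequencing subsample


def test_sequence_subsample_contracts(rng, female_lineage_spec):
    params = SimParams(seed=23, mean_progeny=600.0, replicates=1)
    _, f1 = run_parental_cross(female_lineage_spec, params)
    pop = f1[0]
    empty = sequence_subsample(pop, Eye.BLACK, Cfp.POS, 0, rng)
    assert empty.empty
    sub = sequence_subsample(pop, Eye.BLACK, Cfp.POS, 30, rng,
                             spec=female_lineage_spec, generation="F1")
    assert len(sub) <= 30
    assert set(sub["eye"]) <= {"black"}
    # sequenced calls are phenotype-consistent (mosaic recorded alongside)
    for row in sub.itertuples(index=False):
        g = Genotype(A(row.allele_m), A(row.allele_p), Mosaic(row.mosaic))
        ph = phenotype_from_genotype(g)
        assert ph.eye.value == row.eye and ph.cfp.value == row.cfp


def test_female_lineage_black_class_mixes_wt_and_functional_nhej(rng, female_lineage_spec):
    params = SimParams(seed=29, mean_progeny=4000.0, replicates=1)
    _, f1 = run_parental_cross(female_lineage_spec, params)
    sub = sequence_subsample(f1[0], Eye.BLACK, Cfp.POS, 10_000, rng)
    calls = set(sub["allele_p"])
    assert A.WT_CANON.value in calls
    assert A.NHEJ_FUNC.value in calls
    assert A.NHEJ_LOF.value not in calls  # loss-of-function soma is never black


def test_sim_params_validation():
    with pytest.raises(ValueError):
        SimParams(c=1.5)
    with pytest.raises(ValueError):
        SimParams(dep_outcome=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimParams(mean_progeny=0.0)
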