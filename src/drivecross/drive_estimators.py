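"""Estimation layer for cage-cross phenotype tables and sequenced subsets.

Implements the quantities the cage experiments report: phenotype proportions
(pooled across replicate cages or per replicate), drive inheritance as the
CFP+ fraction, the Pearson chi-square test against the Mendelian 3:1
expectation for a hemizygote intercross, weighted-composite NHEJ/drive
allele-frequency estimators with replicate confidence intervals, pairwise
between-background rate comparisons, and target-site SNP frequency tracking
across generations.

The composite estimators weight phenotype-class population fractions by
allele fractions measured in a sequenced subsample of each class. Allele
fractions are at the allele level: a homozygote of the target class
contributes 1.0, a hemizygous carrier 0.5. In the F1 maternal-effect
estimator every individual carries one maternal drive allele, so NHEJ can
occupy at most the paternal slot and individual-level carriage is halved to
convert to allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics_core import AlleleClass

# Replicate-CI clamp bounds, on the fraction scale (0.0001% and 99.999%).
CI_CLAMP_LOW = 1e-6
CI_CLAMP_HIGH = 0.99999


@dataclass(frozen=True)
class ReplicateEstimate:
    """Mean and 95% confidence interval across replicate cages.

    The CI is the t-interval (df = n_replicates - 1) on the per-replicate
    values, clamped to [0.0001%, 99.999%] so that sampling noise near the
    boundaries never reports an impossible frequency.
    """

    values: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.mean, 100 * self.ci_low, 100 * self.ci_high)


def ci_from_replicates(values: Sequence[float]) -> ReplicateEstimate:
    """t-based 95% CI of the mean of per-replicate fractions (n >= 2)."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError("need at least 2 replicate values")
    n = len(vals)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    lo = min(max(mean - half, CI_CLAMP_LOW), CI_CLAMP_HIGH)
    hi = min(max(mean + half, CI_CLAMP_LOW), CI_CLAMP_HIGH)
    return ReplicateEstimate(values=vals, mean=mean, ci_low=lo, ci_high=hi)


def _check_count_table(t: pd.DataFrame) -> None:
    if t.empty:
        raise ValueError("count table is empty")
    missing = {"eye", "cfp", "count", "replicate"} - set(t.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")


def phenotype_proportions(t: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Proportions per (eye, cfp) cell of one cross/generation count table.

    ``pooled=True`` sums replicate cages before dividing (the convention of
    the printed tables, whose parenthetical counts are three-replicate sums);
    ``pooled=False`` returns per-replicate fractions. Fractions sum to 1 per
    cage (or per pooled cross).
    """
    _check_count_table(t)
    if pooled:
        g = t.groupby(["eye", "cfp"], as_index=False)["count"].sum()
        g["fraction"] = g["count"] / g["count"].sum()
        return g
    g = t.groupby(["replicate", "eye", "cfp"], as_index=False)["count"].sum()
    totals = g.groupby("replicate")["count"].transform("sum")
    g["fraction"] = g["count"] / totals
    return g


def drive_inheritance(t: pd.DataFrame, pooled: bool = True):
    """Fraction of progeny carrying at least one drive copy (CFP+).

    Pooled: a single fraction. Per replicate: a Series indexed by replicate.
    """
    _check_count_table(t)
    if pooled:
        total = t["count"].sum()
        pos = t.loc[t["cfp"] == "pos", "count"].sum()
        return float(pos) / float(total)
    g = t.groupby("replicate").apply(
        lambda d: d.loc[d["cfp"] == "pos", "count"].sum() / d["count"].sum(),
        include_groups=False,
    )
    return g


def chi_square_mendelian(
    n_pos: int, n_neg: int, expected_pos: float = 0.75
) -> tuple[float, float, int]:
    """Pearson goodness-of-fit of CFP+/CFP- counts against a Mendelian ratio.

    Two cells, df = 1, no continuity correction. The default 3:1 expectation
    is the Mendelian outcome of a hemizygote x hemizygote intercross for a
    dominant marker. p-values below float resolution are reported as 0.0 and
    should be displayed as "< 2.2e-16".
    """
    total = n_pos + n_neg
    if total <= 0:
        raise ValueError("need at least one observation")
    exp = np.array([expected_pos * total, (1 - expected_pos) * total])
    obs = np.array([n_pos, n_neg], dtype=float)
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p), 1


def nhej_allele_freq_f1(
    blk_frac: Sequence[float] | float,
    blk_nhej: Sequence[float] | float,
    cd_frac: Sequence[float] | float,
    cd_nhej: Sequence[float] | float,
):
    """Maternal-effect NHEJ allele frequency among F1 from female drive lineages.

    Weighted composite over the two sequenced phenotype classes:
    (black-eye/CFP+ population fraction x NHEJ carrier fraction among
    sequenced black-eye/CFP+) + (cardinal-eye/CFP+ fraction x NHEJ carrier
    fraction among sequenced cardinal-eye/CFP+), halved to convert
    individual-level carriage to allele frequency (every F1 carries one
    maternal drive allele, so an NHEJ allele can occupy only the paternal
    slot). Tear-eye classes are deliberately excluded, replicating the
    published estimator. Scalar inputs give a pooled scalar estimate; vector
    inputs (one value per replicate) give a :class:`ReplicateEstimate`.
    """
    scalars = all(np.isscalar(x) for x in (blk_frac, blk_nhej, cd_frac, cd_nhej))

    def composite(bf, bn, cf, cn) -> float:
        for v in (bf, bn, cf, cn):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"inputs must be fractions in [0, 1], got {v}")
        return 0.5 * (bf * bn + cf * cn)

    if scalars:
        return composite(blk_frac, blk_nhej, cd_frac, cd_nhej)
    per_rep = [
        composite(bf, bn, cf, cn)
        for bf, bn, cf, cn in zip(blk_frac, blk_nhej, cd_frac, cd_nhej, strict=True)
    ]
    return ci_from_replicates(per_rep)


def class_allele_fraction(
    subset: pd.DataFrame, target: str
) -> float:
    """Allele-level target fraction among sequenced individuals of one class.

    ``target`` is "nhej" or "drive". Homozygote = 1.0, hemizygous carrier =
    0.5, non-carrier = 0, averaged over individuals.
    """
    if subset.empty:
        return 0.0
    if target == "nhej":
        hits = {AlleleClass.NHEJ_FUNC.value, AlleleClass.NHEJ_LOF.value}
    elif target == "drive":
        hits = {AlleleClass.DRIVE.value}
    elif target == "wt":
        hits = {AlleleClass.WT_CANON.value, AlleleClass.WT_SNP.value}
    else:
        raise ValueError(f"unknown target {target!r}")
    dosage = (
        subset["allele_m"].isin(hits).astype(float)
        + subset["allele_p"].isin(hits).astype(float)
    ) / 2.0
    return float(dosage.mean())


def allele_freq_f2(
    phenotype_fracs: dict[str, Sequence[float] | float],
    class_allele_fracs: dict[str, Sequence[float] | float],
    target: str = "nhej",
):
    """Population allele frequency from phenotype-stratified sequencing.

    Sum over phenotype classes of (class population fraction x allele-level
    target fraction in that class's sequenced subset). Keys of the two dicts
    must agree; classes absent from ``class_allele_fracs`` contribute zero
    only if their population fraction is also absent. Scalar values give a
    pooled scalar; per-replicate vectors give a :class:`ReplicateEstimate`.
    ``target`` is echoed for interface symmetry with the subset reduction.
    """
    if set(phenotype_fracs) != set(class_allele_fracs):
        raise ValueError("phenotype classes and subset classes must match")
    keys = sorted(phenotype_fracs, key=repr)  # class keys need not be orderable
    scalars = all(
        np.isscalar(phenotype_fracs[k]) and np.isscalar(class_allele_fracs[k])
        for k in keys
    )
    if scalars:
        return float(
            sum(phenotype_fracs[k] * class_allele_fracs[k] for k in keys)
        )
    mat_f = np.array([np.atleast_1d(phenotype_fracs[k]) for k in keys], dtype=float)
    mat_a = np.array([np.atleast_1d(class_allele_fracs[k]) for k in keys], dtype=float)
    if mat_f.shape != mat_a.shape:
        raise ValueError("per-replicate vectors must have equal length")
    per_rep = (mat_f * mat_a).sum(axis=0)
    return ci_from_replicates(per_rep.tolist())


def pairwise_rate_tests(groups: dict[str, Sequence[float]]) -> pd.DataFrame:
    """Two-sample t-tests on per-replicate rates for every group pair.

    Bonferroni correction multiplies each raw p-value by the number of pairs
    (capped at 1). Degenerate comparisons with zero variance in both groups
    report p = 1 for identical means and p = 0 for different means (the
    limiting t outcome) rather than NaN.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if len(groups[g]) < 2:
            raise ValueError("each group needs >= 2 replicate values")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if np.ptp(xa) == 0.0 and np.ptp(xb) == 0.0:
            p_raw = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            p_raw = float(stats.ttest_ind(xa, xb).pvalue)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, n_pairs * p_raw),
            }
        )
    return pd.DataFrame(rows)


def snp_frequency_tracking(
    parental_alleles: Iterable[str], f2_wt_alleles: Iterable[str]
) -> dict:
    """Track the target-site SNP among wild-type-class alleles across generations.

    Inputs are allele-class codes restricted to wild-type-class alleles
    ("wt" / "wt_snp"); anything else is rejected. Returns both frequencies
    and a two-proportion z-test of their difference (pooled-variance normal
    approximation). A drive-cleavable SNP confers no transmission advantage,
    so stable frequency across generations is the no-resistance expectation.
    """
    wt_codes = {AlleleClass.WT_CANON.value, AlleleClass.WT_SNP.value}

    def freq(alleles: Iterable[str]) -> tuple[float, int, int]:
        alleles = list(alleles)
        bad = set(alleles) - wt_codes
        if bad:
            raise ValueError(f"non-wild-type-class allele codes: {sorted(bad)}")
        n = len(alleles)
        k = sum(a == AlleleClass.WT_SNP.value for a in alleles)
        return (k / n if n else 0.0), k, n

    p1, k1, n1 = freq(parental_alleles)
    p2, k2, n2 = freq(f2_wt_alleles)
    if n1 == 0 or n2 == 0:
        raise ValueError("both allele sets must be non-empty")
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = (p1 - p2) / se
        p = float(2 * stats.norm.sf(abs(z)))
    return {
        "parental_snp_freq": p1,
        "f2_snp_freq": p2,
        "z": float(z),
        "p_value": p,
        "n_parental": n1,
        "n_f2": n2,
    }
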