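"""Divergence Island SNP (DIS) ancestry profiling.

The DIS panel genotypes 14 SNPs fixed between *An. coluzzii* and
*An. gambiae*, distributed over three linkage groups (X — including the 28S
marker — 2L and 3L). Per-individual calls are homozygous coluzzii (CC),
homozygous gambiae (GG), heterozygous (CG) or missing (ND). The module
computes allele-weighted strain ancestry proportions, per-marker genotype
profiles with polymorphism flags, and Hardy–Weinberg tests (exact by
default, chi-square for large samples) with a heterozygote excess/deficit
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VALID_CALLS = ("CC", "GG", "CG", "ND")

# Marker ids and linkage groups of the 14-SNP panel. Coordinates follow the
# chrom:position naming used in introgression surveys of the
# coluzzii/gambiae divergence islands.
DEFAULT_MARKERS: tuple[tuple[str, str], ...] = (
    ("28S", "X"),
    ("X:00294573", "X"),
    ("X:00383517", "X"),
    ("X:00480307", "X"),
    ("X:00554395", "X"),
    ("2L:00743820", "2L"),
    ("2L:01489454", "2L"),
    ("2L:02084305", "2L"),
    ("2L:03043435", "2L"),
    ("3L:00597648", "3L"),
    ("3L:00672923", "3L"),
    ("3L:00791481", "3L"),
    ("3L:00918119", "3L"),
    ("3L:01033818", "3L"),
)


@dataclass(frozen=True)
class DISMatrix:
    """Genotype calls at the 14-marker panel for one strain sample.

    ``calls`` is individuals x markers with cells in {CC, GG, CG, ND};
    marker columns must match the panel (14 markers).
    """

    calls: pd.DataFrame
    markers: tuple[tuple[str, str], ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        marker_ids = [m for m, _ in self.markers]
        if len(marker_ids) != 14:
            raise ValueError("the DIS panel has exactly 14 markers")
        if list(self.calls.columns) != marker_ids:
            raise ValueError(
                "call matrix columns must be the 14 panel marker ids in order"
            )
        bad = set(self.calls.values.ravel()) - set(VALID_CALLS)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")

    def linkage_group(self, marker: str) -> str:
        return dict(self.markers)[marker]


def ancestry_proportion(m: DISMatrix) -> tuple[float, float]:
    """Allele-weighted (% coluzzii, % gambiae) over all called genotypes.

    CC contributes two coluzzii alleles, GG two gambiae, CG one of each;
    ND calls are excluded. The two proportions sum to 100% of called
    alleles. Allele weighting (rather than marker-majority counting) is what
    yields ancestry values that are not multiples of 1/14.
    """
    flat = m.calls.values.ravel()
    col = 2 * np.sum(flat == "CC") + np.sum(flat == "CG")
    gam = 2 * np.sum(flat == "GG") + np.sum(flat == "CG")
    total = col + gam
    if total == 0:
        raise ValueError("no called genotypes (all ND)")
    return (100.0 * col / total, 100.0 * gam / total)


def ancestry_proportion_per_individual(m: DISMatrix) -> pd.DataFrame:
    """Per-individual coluzzii/gambiae allele proportions (ND excluded)."""
    rows = []
    for ind, row in m.calls.iterrows():
        flat = row.values
        col = 2 * np.sum(flat == "CC") + np.sum(flat == "CG")
        gam = 2 * np.sum(flat == "GG") + np.sum(flat == "CG")
        total = col + gam
        rows.append(
            {
                "individual": ind,
                "pct_coluzzii": 100.0 * col / total if total else np.nan,
                "pct_gambiae": 100.0 * gam / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _hw_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy–Weinberg p-value (conditional on allele counts).

    Standard enumeration of the conditional distribution of the heterozygote
    count given the minor-allele count; the p-value sums probabilities of
    outcomes no more probable than the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice moot
    n_a = min(n_a, 2 * n - n_a)
    hets = [h for h in range(n_a % 2, n_a + 1, 2)]

    def log_prob(h: int) -> float:
        # P(h | n, n_a) up to a constant: 2^h * n! / (hom_a! hom_A! h!)
        hom_a = (n_a - h) // 2
        hom_A = n - hom_a - h
        from math import lgamma, log
        return (
            h * log(2.0)
            - lgamma(hom_a + 1)
            - lgamma(hom_A + 1)
            - lgamma(h + 1)
        )

    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets.index(n_Aa)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hardy_weinberg(
    n_AA: int, n_Aa: int, n_aa: int, method: str = "auto", chisq_threshold: int = 1000
) -> tuple[float, int]:
    """Test genotype counts against Hardy–Weinberg proportions.

    Returns ``(p_value, direction)`` where direction is the sign of
    (observed heterozygotes - expected heterozygotes): +1 for heterozygote
    excess, -1 for deficit, 0 at exact agreement. ``method`` is "exact",
    "chisq" or "auto" (exact below ``chisq_threshold`` total individuals, the
    typical strain sample of ~45-50 falls here). Monomorphic samples are
    vacuously in equilibrium (p = 1).
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("need at least one genotyped individual")
    p_hat = (2 * n_AA + n_Aa) / (2 * n)
    exp_het = 2 * p_hat * (1 - p_hat) * n
    direction = int(np.sign(n_Aa - exp_het)) if abs(n_Aa - exp_het) > 1e-9 else 0
    if p_hat in (0.0, 1.0):
        return 1.0, 0
    if method == "auto":
        method = "exact" if n <= chisq_threshold else "chisq"
    if method == "exact":
        return _hw_exact_p(n_AA, n_Aa, n_aa), direction
    if method == "chisq":
        expected = np.array(
            [p_hat**2 * n, 2 * p_hat * (1 - p_hat) * n, (1 - p_hat) ** 2 * n]
        )
        obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        return float(stats.chi2.sf(chi2, df=1)), direction
    raise ValueError(f"unknown method {method!r}")


def strain_profile(m: DISMatrix) -> pd.DataFrame:
    """Per-marker genotype counts/fractions with a polymorphism flag.

    A marker is polymorphic when both species' alleles are observed among
    called genotypes (any CG, or both CC and GG present).
    """
    rows = []
    n_ind = len(m.calls)
    for marker_id, lg in m.markers:
        col = m.calls[marker_id]
        counts = {c: int((col == c).sum()) for c in VALID_CALLS}
        called = n_ind - counts["ND"]
        poly = counts["CG"] > 0 or (counts["CC"] > 0 and counts["GG"] > 0)
        row = {
            "marker": marker_id,
            "linkage_group": lg,
            "n": n_ind,
            "n_called": called,
            "polymorphic": bool(poly),
        }
        for c in VALID_CALLS:
            row[f"n_{c}"] = counts[c]
            row[f"f_{c}"] = counts[c] / n_ind if n_ind else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_dis_matrix(
    n_individuals: int,
    marker_col_freq: dict[str, float],
    rng: np.random.Generator,
    nd_rate: float = 0.01,
    markers: tuple[tuple[str, str], ...] = DEFAULT_MARKERS,
) -> DISMatrix:
    """Synthetic DIS matrix: per-marker coluzzii allele frequencies, H-W sampling.

    Emulates a colony strain sample: genotypes drawn under Hardy–Weinberg at
    each marker's coluzzii-allele frequency, with a small independent missing
    (ND) rate. Real strains deviate from H-W at some markers; such deviations
    are what the tests detect, not what this generator produces.
    """
    data = {}
    for marker_id, _lg in markers:
        p = marker_col_freq.get(marker_id, 1.0)
        g = rng.random((n_individuals, 2)) < p  # True = coluzzii allele
        calls = np.where(
            g.sum(axis=1) == 2, "CC", np.where(g.sum(axis=1) == 0, "GG", "CG")
        )
        nd = rng.random(n_individuals) < nd_rate
        calls = np.where(nd, "ND", calls)
        data[marker_id] = calls
    df = pd.DataFrame(data, index=[f"ind{i}" for i in range(n_individuals)])
    return DISMatrix(calls=df, markers=markers)
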