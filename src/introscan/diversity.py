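"""Population diversity summaries and differentiation statistics.

Heterozygosities, percent polymorphism and F_IS per population; per-site
classification of polymorphism sharing between sympatric population pairs;
the Weir–Cockerham F_ST estimator (variance components a, b, c with the
ratio-of-sums multilocus convention); and the three-population f3 admixture
statistic, whose systematically negative values indicate the target
population is a mixture of the two sources.

All statistics ignore missing genotypes site-wise rather than imputing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, dosage_allele_frequency


@dataclass(frozen=True)
class PopDiversity:
    """Observed/expected heterozygosity, percent polymorphism, inbreeding."""

    H_O: float
    H_E: float
    pctP: float
    F_IS: float
    n_sites: int


@dataclass(frozen=True)
class PolymorphismClasses:
    """Mutually exclusive per-site classes for a population pair.

    ``shared + private_popA + private_popB + fixed_differences + monomorphic``
    equals the number of sites typed in both populations; ``untyped`` counts
    sites missing in at least one whole population (excluded from the
    partition).
    """

    shared: int
    private_popA: int
    private_popB: int
    fixed_differences: int
    monomorphic: int
    untyped: int

    @property
    def total(self) -> int:
        return (
            self.shared
            + self.private_popA
            + self.private_popB
            + self.fixed_differences
            + self.monomorphic
        )


@dataclass
class F3Result:
    """Per-SNP f3 = (t - s1)(t - s2) and its genome-wide median."""

    f3: np.ndarray
    median: float
    frac_negative: float
    admixture_consistent: bool


# ---------------------------------------------------------------------------


def population_diversity(gm: GenotypeMatrix, population: str) -> PopDiversity:
    """H_O, H_E, %P and F_IS for one population.

    Per site, H_E = 2p(1-p) from the sample allele frequency and H_O is the
    fraction of heterozygotes; both are averaged over sites with >=2 typed
    genotypes.  %P is the fraction of such sites with 0 < p < 1 in this
    population.  F_IS = (H_E - H_O) / H_E from the averages over polymorphic
    sites.
    """
    dos = gm.population_dosages(population)
    typed = dos != MISSING
    n = typed.sum(axis=1)
    ok = n >= 2
    if not ok.any():
        raise ValueError(f"population {population!r} has no usable sites")
    dos, typed, n = dos[ok], typed[ok], n[ok]
    p = np.where(typed, dos, 0).sum(axis=1) / (2.0 * n)
    he_site = 2.0 * p * (1.0 - p)
    ho_site = np.where(typed, dos == 1, False).sum(axis=1) / n
    poly = (p > 0) & (p < 1)
    H_E = float(he_site.mean())
    H_O = float(ho_site.mean())
    pctP = float(poly.mean())
    if poly.any():
        he_p, ho_p = float(he_site[poly].mean()), float(ho_site[poly].mean())
        F_IS = (he_p - ho_p) / he_p if he_p > 0 else float("nan")
    else:
        F_IS = float("nan")
    return PopDiversity(H_O, H_E, pctP, F_IS, int(ok.sum()))


def classify_polymorphisms(
    gm: GenotypeMatrix, popA: str, popB: str
) -> PolymorphismClasses:
    """Classify each site as shared / private / fixed difference / monomorphic
    from the two population allele-frequency pairs."""
    pA = gm.allele_frequency(popA)
    pB = gm.allele_frequency(popB)
    untyped = ~np.isfinite(pA) | ~np.isfinite(pB)
    segA = (pA > 0) & (pA < 1)
    segB = (pB > 0) & (pB < 1)
    shared = segA & segB & ~untyped
    privA = segA & ~segB & ~untyped
    privB = segB & ~segA & ~untyped
    fixed = ~segA & ~segB & (pA != pB) & ~untyped
    mono = ~segA & ~segB & (pA == pB) & ~untyped
    return PolymorphismClasses(
        int(shared.sum()),
        int(privA.sum()),
        int(privB.sum()),
        int(fixed.sum()),
        int(mono.sum()),
        int(untyped.sum()),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------


def _wc_components(dos_by_pop: list[np.ndarray]):
    """Per-site Weir–Cockerham variance components for r populations.

    Returns (a, b, c) arrays; sites where any population has <2 typed
    genotypes are NaN.
    """
    r = len(dos_by_pop)
    n_i, p_i, h_i = [], [], []
    for dos in dos_by_pop:
        typed = dos != MISSING
        ni = typed.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi = np.where(typed, dos, 0).sum(axis=1) / (2.0 * ni)
            hi = np.where(typed, dos == 1, False).sum(axis=1) / ni
        n_i.append(ni)
        p_i.append(pi)
        h_i.append(hi)
    n_i = np.vstack(n_i)  # (r, sites)
    p_i = np.vstack(p_i)
    h_i = np.vstack(h_i)
    valid = np.all(n_i >= 2, axis=0)
    n_sum = n_i.sum(axis=0)
    nbar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_sum
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


@dataclass
class FstResult:
    per_site: np.ndarray
    multilocus: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray


def fst_weir_cockerham(gm: GenotypeMatrix, popA: str, popB: str) -> FstResult:
    """Weir–Cockerham F_ST between two populations.

    Per-site theta = a / (a + b + c); the multilocus estimate is the ratio of
    sums over sites where the denominator is nonzero (sites monomorphic in
    both populations contribute nothing and are excluded).  Per-site values
    with zero denominator are NaN, not zero.
    """
    blocks = [gm.population_dosages(popA), gm.population_dosages(popB)]
    for pop, dos in zip((popA, popB), blocks):
        if not np.any((dos != MISSING).sum(axis=1) >= 2):
            raise ValueError(f"population {pop!r} has <2 typed individuals everywhere")
    a, b, c = _wc_components(blocks)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(
            np.isfinite(denom) & (np.abs(denom) > 0), a / denom, np.nan
        )
    use = np.isfinite(denom) & (np.abs(denom) > 0)
    multilocus = float(np.nansum(a[use]) / np.nansum(denom[use])) if use.any() else float("nan")
    return FstResult(per_site, multilocus, a, b, c)


# ---------------------------------------------------------------------------
# f3 admixture statistic
# ---------------------------------------------------------------------------


def f3_statistic(
    gm: GenotypeMatrix,
    target_pop: str,
    source1_pop: str,
    source2_pop: str,
    bias_correction: bool = False,
) -> F3Result:
    """Per-SNP f3(target; source1, source2) = (t - s1)(t - s2) and median.

    A negative median is consistent with the target being admixed between the
    two sources.  ``bias_correction`` subtracts the within-target sampling
    heterozygosity term t(1-t)/(2n-1) (off by default).
    """
    if len({target_pop, source1_pop, source2_pop}) != 3:
        raise ValueError("target and sources must be three distinct populations")
    t = gm.allele_frequency(target_pop)
    s1 = gm.allele_frequency(source1_pop)
    s2 = gm.allele_frequency(source2_pop)
    for pop, freq in ((target_pop, t), (source1_pop, s1), (source2_pop, s2)):
        if np.mean(~np.isfinite(freq)) > 0.5:
            warnings.warn(f"population {pop!r} untyped at >50% of sites")
    f3 = (t - s1) * (t - s2)
    if bias_correction:
        typed = gm.population_dosages(target_pop) != MISSING
        n = typed.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f3 = f3 - t * (1 - t) / (2.0 * n - 1)
    ok = np.isfinite(f3)
    med = float(np.median(f3[ok]))
    frac_neg = float((f3[ok] < 0).mean())
    return F3Result(f3, med, frac_neg, med < 0)


def diversity_table(gm: GenotypeMatrix, populations: list[str] | None = None) -> pd.DataFrame:
    """Per-population summary table (one row per population)."""
    pops = populations or sorted(set(gm.populations.values()))
    rows = []
    for pop in pops:
        d = population_diversity(gm, pop)
        rows.append((pop, gm.taxon_of(pop), d.H_O, d.H_E, d.pctP, d.F_IS, d.n_sites))
    return pd.DataFrame(
        rows, columns=["population", "taxon", "H_O", "H_E", "pctP", "F_IS", "n_sites"]
    )
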