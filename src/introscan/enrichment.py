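"""Permutation and bootstrap tests for candidate-locus enrichment.

Two null schemes, each preserving the marginal structure its test conditions
on: circular rotation of the called-region set (interval vs. interval tests,
e.g. domestication-candidate genes inside introgressed regions) and SNP
resampling without replacement (SNP-set tests, e.g. environment-associated
SNPs).  Empirical p-values use the (b + 1) / (n + 1) estimator and are never
zero.  Also implements the Bayes-factor percentile rule that defines
environment-associated candidate SNPs from replicate association runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .region_calling import GenomicRegion


@dataclass
class EnrichmentResult:
    """Observed statistic against a permutation/bootstrap null."""

    observed: float
    null_mean: float
    null_quantiles: dict[str, float]
    p_enrichment: float  # P(null >= observed)
    p_depletion: float  # P(null <= observed)
    p_two_sided: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_quantiles": self.null_quantiles,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "p_two_sided": self.p_two_sided,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _empirical_p(null: np.ndarray, observed: float) -> tuple[float, float, float]:
    n = len(null)
    p_enr = (np.sum(null >= observed) + 1) / (n + 1)
    p_dep = (np.sum(null <= observed) + 1) / (n + 1)
    return float(p_enr), float(p_dep), float(min(1.0, 2 * min(p_enr, p_dep)))


def _result(null: np.ndarray, observed: float, n_perm: int, seed: int) -> EnrichmentResult:
    p_enr, p_dep, p_two = _empirical_p(null, observed)
    qs = {q: float(np.quantile(null, float(q))) for q in ("0.025", "0.5", "0.975")}
    return EnrichmentResult(
        float(observed), float(null.mean()), qs, p_enr, p_dep, p_two, n_perm, seed
    )


# ---------------------------------------------------------------------------
# Interval-vs-interval permutation test (circular rotation null)
# ---------------------------------------------------------------------------


def _count_overlapping_candidates(
    region_ivs: Mapping[str, np.ndarray], cand: pd.DataFrame
) -> int:
    n = 0
    for chrom, grp in cand.groupby("chrom", sort=False):
        ivs = region_ivs.get(str(chrom))
        if ivs is None or ivs.size == 0:
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # candidate overlaps any region interval
        for cs, ce in zip(s, e):
            if np.any((ivs[:, 0] < ce) & (cs < ivs[:, 1])):
                n += 1
    return n


def _rotate(ivs: np.ndarray, offset: int, L: int) -> np.ndarray:
    """Circularly rotate intervals by ``offset`` on a chromosome of length L,
    splitting any interval that wraps.  Total bp is preserved exactly."""
    out = []
    for s, e in ivs:
        s2, e2 = (s + offset) % L, (e + offset) % L
        if s2 < e2:
            out.append((s2, e2))
        else:  # wrapped
            if e2 > 0:
                out.append((0, e2))
            out.append((s2, L))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def permutation_enrichment(
    regions: Sequence[GenomicRegion],
    candidate_intervals: pd.DataFrame,
    genome_layout: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Are candidate intervals over/under-represented inside called regions?

    Observed statistic: number of candidates overlapping >= 1 region.  Null:
    the region set is circularly rotated by one uniform offset per chromosome
    per permutation, preserving region lengths and spacing while randomizing
    placement relative to the candidates.
    """
    if len(candidate_intervals) == 0:
        raise ValueError("candidate interval list is empty")
    rng = np.random.default_rng(seed)
    region_ivs = {
        chrom: np.array(
            [(r.start, r.end) for r in regions if r.chrom == chrom], dtype=np.int64
        ).reshape(-1, 2)
        for chrom in genome_layout
    }
    observed = _count_overlapping_candidates(region_ivs, candidate_intervals)
    null = np.empty(n_perm)
    for b in range(n_perm):
        rotated = {
            chrom: _rotate(ivs, int(rng.integers(genome_layout[chrom])),
                           genome_layout[chrom])
            for chrom, ivs in region_ivs.items()
            if ivs.size
        }
        null[b] = _count_overlapping_candidates(rotated, candidate_intervals)
    return _result(null, observed, n_perm, seed)


# ---------------------------------------------------------------------------
# Bayes-factor percentile rule
# ---------------------------------------------------------------------------


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    v = np.sort(values)
    k = int(np.ceil(pct / 100.0 * len(v)))
    return float(v[max(k, 1) - 1])


def bayenv_candidate_filter(
    bf: pd.DataFrame,
    per_run_pct: float = 95.0,
    mean_pct: float = 99.0,
) -> list:
    """Candidate SNPs from replicate Bayes-factor runs.

    A SNP is kept iff its Bayes factor reaches that run's ``per_run_pct``
    percentile in EVERY run and its across-run mean reaches the ``mean_pct``
    percentile of mean Bayes factors.  Percentiles are nearest-rank over all
    SNPs.  ``bf`` is indexed by SNP id with one column per run.
    """
    if bf.shape[1] < 2:
        raise ValueError("need at least two replicate runs")
    vals = bf.to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("Bayes factors must be positive")
    keep = np.ones(len(bf), dtype=bool)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.allclose(col, col[0]):
            warnings.warn(f"run {bf.columns[j]!r} has constant Bayes factors")
            continue
        keep &= col >= _nearest_rank_percentile(col, per_run_pct)
    means = vals.mean(axis=1)
    keep &= means >= _nearest_rank_percentile(means, mean_pct)
    return list(bf.index[keep])


# ---------------------------------------------------------------------------
# SNP-set bootstrap test
# ---------------------------------------------------------------------------


def candidate_snp_enrichment(
    candidates: Sequence,
    regions: Sequence[GenomicRegion],
    all_snps: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Are candidate SNPs over-represented inside called regions?

    Observed statistic: fraction of candidate SNPs falling inside a region.
    Null: resample ``len(candidates)`` SNPs from ``all_snps`` (columns
    snp_id/chrom/bp) without replacement per iteration.
    """
    if len(candidates) == 0:
        raise ValueError("candidate SNP set is empty")
    ids = all_snps["snp_id"].to_numpy()
    id_set = set(ids)
    missing = [c for c in candidates if c not in id_set]
    if missing:
        raise ValueError(f"candidates not in all_snps: {missing[:5]}")
    inside = np.zeros(len(all_snps), dtype=bool)
    for chrom, grp in all_snps.groupby("chrom", sort=False):
        ivs = np.array(
            [(r.start, r.end) for r in regions if r.chrom == str(chrom)],
            dtype=np.int64,
        ).reshape(-1, 2)
        if ivs.size == 0:
            continue
        pos0 = grp["bp"].to_numpy() - 1  # 1-based SNP vs half-open interval
        hit = np.zeros(len(grp), dtype=bool)
        for s, e in ivs:
            hit |= (pos0 >= s) & (pos0 < e)
        inside[grp.index.to_numpy()] = hit
    in_by_id = dict(zip(ids, inside))
    observed = float(np.mean([in_by_id[c] for c in candidates]))
    rng = np.random.default_rng(seed)
    k = len(candidates)
    # vectorized resampling without replacement: the k smallest of n uniforms
    keys = rng.random((n_boot, len(ids)))
    picks = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null = inside[picks].mean(axis=1)
    return _result(null, observed, n_boot, seed)
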