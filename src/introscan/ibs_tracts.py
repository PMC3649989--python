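"""Seed-and-extend identity-by-state (IBS) segment detection.

For every (query haplotype, donor haplotype) pair, maximal runs of matching
alleles containing at least ``seed_len`` consecutive exact matches are
retained if they span at least ``min_cM`` on the genetic map.  Per-site IBS
profiles against two donor panels and their site-by-site differential then
show which donor each query group resembles more, region by region.

Missing alleles count as mismatches when seeding (seeds must be
high-confidence) but as wildcards during extension (sporadic missingness does
not truncate a real segment); both behaviours are flag-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HaplotypePanel


@dataclass(frozen=True)
class IBSSegment:
    """A retained IBS run between one query and one donor haplotype."""

    query: int
    donor: int
    chrom: str
    start_idx: int  # first/last site index within the chromosome
    end_idx: int  # inclusive
    start_bp: int
    end_bp: int
    length_cM: float
    n_snps: int


def _pair_segments(
    match_code: np.ndarray,
    cm: np.ndarray,
    bp: np.ndarray,
    seed_len: int,
    min_cM: float,
):
    """Maximal no-mismatch runs (code >= 1) containing >= seed_len consecutive
    exact matches (code == 2), retained at >= min_cM span.

    ``match_code``: 2 = exact match, 1 = wildcard (missing), 0 = mismatch.
    Yields (i0, i1) inclusive site-index bounds.
    """
    n = len(match_code)
    ok = match_code != 0
    if not ok.any():
        return
    edges = np.diff(ok.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)  # inclusive
    if ok[0]:
        starts = np.concatenate([[0], starts])
    if ok[-1]:
        ends = np.concatenate([ends, [n - 1]])
    spans = cm[ends] - cm[starts]
    for i, j in zip(starts[spans >= min_cM], ends[spans >= min_cM]):
        # require seed_len consecutive exact matches somewhere in the run
        exact = match_code[i : j + 1] == 2
        if exact.sum() < seed_len:
            continue
        csum = np.concatenate([[0], np.cumsum(exact)])
        if seed_len <= len(exact) and np.any(
            csum[seed_len:] - csum[:-seed_len] == seed_len
        ):
            yield int(i), int(j)


def seed_extend_ibs(
    query_haps: HaplotypePanel,
    donor_haps: HaplotypePanel,
    seed_len: int = 5,
    min_cM: float = 3.0,
    missing_seeds: bool = False,
    missing_extends: bool = True,
) -> list[IBSSegment]:
    """All retained IBS segments between every query/donor haplotype pair.

    ``missing_seeds``: count a missing allele as an exact match when looking
    for the seed (default off).  ``missing_extends``: let missing alleles
    extend a run as wildcards rather than break it (default on).
    """
    if not np.array_equal(
        query_haps.sites[["chrom", "bp"]].to_numpy(),
        donor_haps.sites[["chrom", "bp"]].to_numpy(),
    ):
        raise ValueError("query and donor panels must share the same sites")
    sites = query_haps.sites
    segments: list[IBSSegment] = []
    for chrom in pd.unique(sites["chrom"]):
        sel = (sites["chrom"] == chrom).to_numpy()
        bp = sites["bp"].to_numpy()[sel]
        cm = sites["cM"].to_numpy()[sel]
        q_block = query_haps.haplotypes[:, sel]
        d_block = donor_haps.haplotypes[:, sel]
        for qi in range(q_block.shape[0]):
            q = q_block[qi]
            for di in range(d_block.shape[0]):
                d = d_block[di]
                missing = (q < 0) | (d < 0)
                exact = (q == d) & ~missing
                code = np.where(exact, 2, 0)
                if missing_seeds:
                    code = np.where(missing, 2, code)
                elif missing_extends:
                    code = np.where(missing, 1, code)
                for i0, i1 in _pair_segments(code, cm, bp, seed_len, min_cM):
                    segments.append(
                        IBSSegment(
                            qi, di, str(chrom), i0, i1,
                            int(bp[i0]), int(bp[i1]),
                            float(cm[i1] - cm[i0]), i1 - i0 + 1,
                        )
                    )
    return segments


# ---------------------------------------------------------------------------
# Per-site IBS profiles
# ---------------------------------------------------------------------------


def site_ibs_profile(
    segments: Sequence[IBSSegment],
    sites: pd.DataFrame,
    n_query: int,
    n_donor: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site IBS coverage: fraction of (query, donor) pairs whose retained
    segments cover each site.

    Returns (profile over all pairs (n_sites,), per-query-haplotype profile
    (n_query, n_sites)).
    """
    per_query = np.zeros((n_query, len(sites)))
    chrom_offsets: dict[str, np.ndarray] = {}
    for chrom in pd.unique(sites["chrom"]):
        chrom_offsets[str(chrom)] = np.flatnonzero(
            (sites["chrom"] == chrom).to_numpy()
        )
    for seg in segments:
        idx = chrom_offsets[seg.chrom]
        per_query[seg.query, idx[seg.start_idx] : idx[seg.end_idx] + 1] += 1
    per_query /= max(n_donor, 1)
    return per_query.mean(axis=0), per_query


def ibs_differential(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    groups: Mapping[str, Sequence[int]],
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-group site-by-site IBS differential between two donor panels.

    ``profile_a``/``profile_b`` are per-query-haplotype profiles (n_query x
    n_sites) against donors A and B on the same sites.  Returns, per group,
    the mean per-site difference IBS(A) - IBS(B) and the fraction of sites
    where the group shows greater IBS with donor A.
    """
    if profile_a.shape != profile_b.shape:
        raise ValueError("profiles are not aligned")
    diff_by_group: dict[str, np.ndarray] = {}
    frac_positive: dict[str, float] = {}
    for group, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {group!r} has no query haplotypes")
        d = profile_a[members].mean(axis=0) - profile_b[members].mean(axis=0)
        diff_by_group[group] = d
        frac_positive[group] = float((d > 0).mean())
    return diff_by_group, frac_positive


def segments_to_frame(segments: Sequence[IBSSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.query, s.donor, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.length_cM)
            for s in segments
        ],
        columns=["query", "donor", "chrom", "start_bp", "end_bp", "n_snps", "cM"],
    )
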