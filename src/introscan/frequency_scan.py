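"""Frequency-based linkage-aware ancestry scan (second, independent method).

SNPs are grouped into haplotype loci separated by at least 5 kb (multi-SNP
haplotypes behave as multi-allelic markers, sidestepping local LD), and each
phased chromosome copy is assigned ancestry by a two-state HMM over loci:
emissions are smoothed taxon-specific haplotype-allele frequencies estimated
from the reference panels, and the ancestry prior along the chromosome is a
symmetric two-state Markov chain in genetic-map distance.  This provides a
scan independent of the haplotype-copying model with which it is intersected
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry_hmm import AncestryTrack
from .io_formats import HaplotypePanel

TAXA = ("maize", "mexicana")


@dataclass
class HaplotypeBlock:
    """One locus: a run of SNPs closer than the gap threshold."""

    chrom: str
    site_indices: np.ndarray  # global indices into the site table
    start_bp: int
    end_bp: int
    cM: float  # midpoint genetic position
    catalog: dict[tuple, int]  # observed haplotype allele -> catalog index
    freqs: np.ndarray  # (n_alleles, 2): smoothed frequency per taxon
    unseen_mass: np.ndarray  # (2,): emission mass for alleles not in catalog


@dataclass
class HaplotypeBlockSet:
    """All loci plus the site table they were built from."""

    sites: pd.DataFrame
    blocks: list[HaplotypeBlock]
    min_gap_bp: int

    @property
    def n_loci(self) -> int:
        return len(self.blocks)

    @property
    def mean_alleles_per_locus(self) -> float:
        return float(np.mean([len(b.catalog) for b in self.blocks]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (b.chrom, b.start_bp, b.end_bp, len(b.site_indices), len(b.catalog))
            for b in self.blocks
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "n_alleles"]
        )


def _hap_allele(hap: np.ndarray, idx: np.ndarray) -> tuple:
    return tuple(int(a) for a in hap[idx])


def block_haplotypes(
    panel_maize: HaplotypePanel,
    panel_mexicana: HaplotypePanel,
    min_gap_bp: int = 5_000,
) -> HaplotypeBlockSet:
    """Group SNPs into haplotype loci separated by at least ``min_gap_bp``.

    Greedy left-to-right per chromosome: a block absorbs the next SNP while
    the inter-SNP gap is < min_gap_bp and closes at the first gap >= min_gap_bp.
    The allele catalog of a locus is every haplotype string observed in either
    reference panel; per-taxon frequencies get +0.5 pseudocount per catalog
    allele (so unseen alleles never zero out a likelihood).
    """
    if not np.array_equal(
        panel_maize.sites[["chrom", "bp"]].to_numpy(),
        panel_mexicana.sites[["chrom", "bp"]].to_numpy(),
    ):
        raise ValueError("panels must share the same SNP positions")
    sites = panel_maize.sites
    blocks: list[HaplotypeBlock] = []
    for chrom in pd.unique(sites["chrom"]):
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        bp = sites["bp"].to_numpy()[idx]
        cm = sites["cM"].to_numpy()[idx]
        start = 0
        for i in range(1, len(idx) + 1):
            if i == len(idx) or bp[i] - bp[i - 1] >= min_gap_bp:
                members = idx[start:i]
                blocks.append(
                    _build_block(
                        str(chrom),
                        members,
                        int(bp[start]),
                        int(bp[i - 1]),
                        float(cm[start:i].mean()),
                        panel_maize,
                        panel_mexicana,
                    )
                )
                start = i
    return HaplotypeBlockSet(sites, blocks, min_gap_bp)


def _build_block(
    chrom: str,
    members: np.ndarray,
    start_bp: int,
    end_bp: int,
    cm: float,
    panel_maize: HaplotypePanel,
    panel_mexicana: HaplotypePanel,
) -> HaplotypeBlock:
    catalog: dict[tuple, int] = {}
    counts = [[], []]  # per taxon: catalog index per observed haplotype
    for t, panel in enumerate((panel_maize, panel_mexicana)):
        for hap in panel.haplotypes:
            allele = _hap_allele(hap, members)
            counts[t].append(catalog.setdefault(allele, len(catalog)))
    n_alleles = len(catalog)
    freqs = np.empty((n_alleles, 2))
    unseen = np.empty(2)
    for t, panel in enumerate((panel_maize, panel_mexicana)):
        tally = np.bincount(np.asarray(counts[t]), minlength=n_alleles).astype(float)
        denom = tally.sum() + 0.5 * n_alleles
        freqs[:, t] = (tally + 0.5) / denom
        # an allele outside the catalog behaves as one extra pseudocount entry
        unseen[t] = 0.5 / (tally.sum() + 0.5 * (n_alleles + 1))
    return HaplotypeBlock(
        chrom, members, start_bp, end_bp, cm, catalog, freqs, unseen
    )


# ---------------------------------------------------------------------------
# Two-state assignment HMM
# ---------------------------------------------------------------------------


def _emissions(
    blocks: list[HaplotypeBlock], haps: np.ndarray
) -> np.ndarray:
    """Per-locus emission likelihood (n_loci, B, 2) for a haplotype batch."""
    B = haps.shape[0]
    out = np.empty((len(blocks), B, 2))
    for l, blk in enumerate(blocks):
        for b in range(B):
            allele = _hap_allele(haps[b], blk.site_indices)
            j = blk.catalog.get(allele)
            out[l, b] = blk.freqs[j] if j is not None else blk.unseen_mass
    return out


def linkage_assignment(
    blocks: HaplotypeBlockSet,
    individual_haplotypes: np.ndarray,
    switch_rate_per_cM: float = 1.0,
    mexicana_prior: float = 0.5,
) -> np.ndarray:
    """Posterior mexicana-ancestry probability per locus per haplotype copy.

    A two-state (maize/mexicana) HMM per chromosome copy: emission is the
    smoothed taxon frequency of the copy's haplotype allele; between loci the
    ancestry relaxes toward the stationary distribution pi = (1 - q, q) with
    q = ``mexicana_prior`` (the admixture proportion, playing the role of the
    linkage model's per-individual ancestry fraction): P(i -> j) =
    s pi_j + (1 - s) delta_ij with s = 1 - exp(-2 r d) over d cM.  As the
    switch rate r grows this tends to independent per-locus assignment under
    the prior pi; with q = 1/2 it is the symmetric two-state chain.  Returns
    (B, n_loci) posteriors for state "mexicana" (state probabilities sum to 1,
    so the maize posterior is the complement).
    """
    if not 0 < mexicana_prior < 1:
        raise ValueError("mexicana_prior must be in (0, 1)")
    haps = np.atleast_2d(np.asarray(individual_haplotypes))
    blks = blocks.blocks
    emis = _emissions(blks, haps)  # (L, B, 2)
    B = haps.shape[0]
    L = len(blks)
    post = np.empty((B, L))
    chroms = np.array([b.chrom for b in blks])
    cm = np.array([b.cM for b in blks])
    pi = np.array([1.0 - mexicana_prior, mexicana_prior])
    for chrom in pd.unique(chroms):
        li = np.flatnonzero(chroms == chrom)
        e = emis[li]  # (l, B, 2)
        d = np.diff(cm[li])
        s_relax = 1.0 - np.exp(-2.0 * switch_rate_per_cM * np.maximum(d, 0.0))
        n = len(li)
        fwd = np.empty((n, B, 2))
        f = pi[None, :] * e[0]
        fwd[0] = f / f.sum(axis=1, keepdims=True)
        for t in range(1, n):
            s = s_relax[t - 1]
            f = fwd[t - 1]
            pred = s * pi[None, :] * f.sum(axis=1, keepdims=True) + (1 - s) * f
            f = pred * e[t]
            fwd[t] = f / f.sum(axis=1, keepdims=True)
        bwd = np.ones((B, 2))
        w = fwd[n - 1]
        post[:, li[n - 1]] = w[:, 1] / w.sum(axis=1)
        for t in range(n - 2, -1, -1):
            s = s_relax[t]
            g = bwd * e[t + 1]
            bwd = s * (g * pi[None, :]).sum(axis=1, keepdims=True) + (1 - s) * g
            bwd = bwd / bwd.sum(axis=1, keepdims=True)
            w = fwd[t] * bwd
            post[:, li[t]] = w[:, 1] / w.sum(axis=1)
    return post


@dataclass
class AssignmentTrack:
    """Per-locus population ancestry from the frequency scan."""

    blocks: HaplotypeBlockSet
    hap_posterior: np.ndarray  # (n_haps, n_loci) P(mexicana)
    individuals: list[str]
    population: str
    direction: str  # donor taxon

    @property
    def diploid_fraction(self) -> np.ndarray:
        """(n_loci, n_individuals) donor fraction per individual."""
        p = self.hap_posterior if self.direction == "mexicana" else 1 - self.hap_posterior
        return ((p[0::2] + p[1::2]) / 2.0).T

    @property
    def mean(self) -> np.ndarray:
        return self.diploid_fraction.mean(axis=1)

    def to_site_track(self) -> AncestryTrack:
        """Expand per-locus posteriors onto member SNPs (aligns the frequency
        scan with per-SNP tracks for consensus and resistance calling)."""
        sites = self.blocks.sites
        n_ind = len(self.individuals)
        dosage = np.full((len(sites), n_ind), np.nan)
        dip = self.diploid_fraction  # (L, n_ind)
        for l, blk in enumerate(self.blocks.blocks):
            dosage[blk.site_indices, :] = 2.0 * dip[l]
        return AncestryTrack(
            sites=sites,
            dosage=dosage,
            mean=dosage.mean(axis=1) / 2.0,
            individuals=self.individuals,
            population=self.population,
            direction=self.direction,
            method="freq",
        )


def scan_population_freq(
    blocks: HaplotypeBlockSet,
    pop_haplotypes: HaplotypePanel,
    donor_taxon: str,
    switch_rate_per_cM: float = 1.0,
    donor_prior: float = 0.5,
    population: str | None = None,
) -> AssignmentTrack:
    """Frequency-scan a whole population and aggregate per-locus means.

    ``donor_prior`` is the stationary weight of the donor taxon in the
    ancestry chain (0.5 = uninformative; the study design passes its
    admixture proportion, as the linkage model's ancestry fractions would).
    """
    if donor_taxon not in TAXA:
        raise ValueError(f"unknown donor taxon {donor_taxon!r}")
    mex_prior = donor_prior if donor_taxon == "mexicana" else 1.0 - donor_prior
    post = linkage_assignment(
        blocks, pop_haplotypes.haplotypes, switch_rate_per_cM, mex_prior
    )
    return AssignmentTrack(
        blocks=blocks,
        hap_posterior=post,
        individuals=list(pop_haplotypes.samples),
        population=population or pop_haplotypes.taxon,
        direction=donor_taxon,
    )
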