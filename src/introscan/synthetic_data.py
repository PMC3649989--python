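"""Tract-based simulator of two diverged taxa with asymmetric admixture.

The simulator emulates the sampling design of a sympatric crop–wild study:
two source taxa (here labelled maize and mexicana) diverged under a
Balding–Nichols allele-frequency model, allopatric reference panels for each,
and a set of sympatric population pairs in which each taxon has received
introgression from the other.  Local ancestry is generated as an explicit
two-state Markov tract process along the genetic map, so the true ancestry of
every haplotype segment is recorded exactly (:class:`TruthTracts`) — the
ground truth against which the two ancestry scans are scored.

Defaults follow the study conditions: nine sympatric pairs, ~1 SNP per 80 kb,
~20% mexicana-into-maize and ~10% maize-into-mexicana admixture, 100
generations since admixture, and marker ascertainment biased toward maize
polymorphism so that the receiving taxon looks more diverse on the chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    GeneticMap,
    GenotypeMatrix,
    HaplotypePanel,
)

TAXA = ("maize", "mexicana")

Direction = Literal["maize", "mexicana"]  # the DONOR taxon


@dataclass(frozen=True)
class SharedTract:
    """A forced-ancestry interval applied to every population of the
    recipient taxon.

    Within [start_bp, end_bp) each haplotype is forced to ``donor`` ancestry
    with probability ``frequency`` and to recipient ancestry otherwise, so
    ``frequency`` close to 1 models a tract shared across populations and
    ``frequency = 0`` models a locus resistant to introgression.
    """

    chrom: str
    start_bp: int
    end_bp: int
    frequency: float
    donor: Direction

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("tract frequency must be in [0, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("tract start must precede end")


def default_shared_tracts() -> list[SharedTract]:
    # two mexicana->maize tracts shared at high frequency, plus one interval
    # per direction held introgression-free (a resistant locus)
    return [
        SharedTract("chr1", 40_000_000, 52_000_000, 0.95, "mexicana"),
        SharedTract("chr2", 96_000_000, 108_000_000, 0.95, "mexicana"),
        SharedTract("chr1", 110_000_000, 122_000_000, 0.0, "mexicana"),
        SharedTract("chr1", 110_000_000, 122_000_000, 0.0, "maize"),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    ``admixture_proportion`` maps donor taxon -> genome-wide introgression
    fraction into the other taxon.  ``admixture_time`` is generations since
    admixture, either one value for all populations or one per population
    pair.  ``ascertainment_bias`` in (0, 1] multiplicatively shrinks the
    mexicana minor-allele frequency, emulating a maize-discovered SNP chip
    (1.0 = no bias).
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 160_000_000
    snp_density: float = 1.0 / 80_000
    divergence_scale: float = 0.30
    n_reference_haplotypes: int = 24
    n_populations: int = 9
    n_individuals: int = 20
    admixture_proportion: dict[str, float] = field(
        default_factory=lambda: {"mexicana": 0.20, "maize": 0.10}
    )
    admixture_time: float | Sequence[float] = 100.0
    shared_tract_spec: list[SharedTract] = field(default_factory=default_shared_tracts)
    reference_contamination_fraction: float = 0.0
    ascertainment_bias: float = 0.7
    n_founders: int = 8
    founder_switch_rate: float = 3.0  # founder-mosaic switches per Morgan
    founder_mutation_rate: float = 0.003
    copy_error_rate: float = 0.002
    missing_rate: float = 0.02
    cm_per_mb: float = 1.0
    genetic_map: GeneticMap | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for d, p in self.admixture_proportion.items():
            if d not in TAXA or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad admixture proportion {d}={p}")
        times = np.atleast_1d(np.asarray(self.admixture_time, dtype=float))
        if np.any(times < 1):
            raise ValueError("admixture_time must be >= 1 generation")
        if self.snp_density <= 0 or self.chromosome_length_bp <= 0:
            raise ValueError("densities and lengths must be positive")
        if not 0 < self.ascertainment_bias <= 1:
            raise ValueError("ascertainment_bias must be in (0, 1]")
        if not 0 <= self.reference_contamination_fraction <= 1:
            raise ValueError("contamination fraction must be in [0, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosomes}

    def map_(self) -> GeneticMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return GeneticMap.uniform(self.chrom_lengths, self.cm_per_mb)

    def time_for(self, pop_index: int) -> float:
        times = np.atleast_1d(np.asarray(self.admixture_time, dtype=float))
        return float(times[pop_index % len(times)])


# ---------------------------------------------------------------------------
# Truth tracking
# ---------------------------------------------------------------------------


@dataclass
class TruthTracts:
    """Exact ancestry segments per haplotype: for every chromosome,
    ``tracts[chrom][hap]`` is a list of (start_bp, end_bp, ancestry) tuples
    tiling [0, chrom_length) without gaps or overlap."""

    tracts: dict[str, list[list[tuple[int, int, str]]]]
    chrom_lengths: dict[str, int]

    @property
    def n_haplotypes(self) -> int:
        first = next(iter(self.tracts.values()))
        return len(first)

    def validate(self) -> None:
        for chrom, per_hap in self.tracts.items():
            L = self.chrom_lengths[chrom]
            for segs in per_hap:
                if segs[0][0] != 0 or segs[-1][1] != L:
                    raise AssertionError(f"tracts do not tile {chrom}")
                for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
                    if e0 != s1 or s0 >= e0:
                        raise AssertionError(f"gap/overlap in tracts on {chrom}")

    def donor_fraction(self, donor: str) -> float:
        """Genome-wide fraction of sequence with ``donor`` ancestry,
        averaged over haplotypes."""
        tot = 0.0
        donor_bp = 0.0
        for chrom, per_hap in self.tracts.items():
            for segs in per_hap:
                for s, e, a in segs:
                    tot += e - s
                    if a == donor:
                        donor_bp += e - s
        return donor_bp / tot

    def site_donor_indicator(self, sites: pd.DataFrame, donor: str) -> np.ndarray:
        """(n_sites x n_haplotypes) boolean: site falls in a donor tract."""
        out = np.zeros((len(sites), self.n_haplotypes), dtype=bool)
        for chrom, per_hap in self.tracts.items():
            idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
            if idx.size == 0:
                continue
            bp = sites["bp"].to_numpy()[idx]
            for h, segs in enumerate(per_hap):
                bounds = np.array([s for s, _, _ in segs] + [segs[-1][1]])
                anc = np.array([a == donor for _, _, a in segs])
                seg_of = np.searchsorted(bounds, bp, side="right") - 1
                seg_of = np.clip(seg_of, 0, len(anc) - 1)
                out[idx, h] = anc[seg_of]
        return out

    def overlap_bp(self, chrom: str, start: int, end: int, donor: str) -> float:
        """Mean donor-ancestry bp overlap of [start, end) across haplotypes."""
        per_hap = self.tracts[chrom]
        tot = 0.0
        for segs in per_hap:
            for s, e, a in segs:
                if a == donor:
                    tot += max(0, min(e, end) - max(s, start))
        return tot / len(per_hap)


# ---------------------------------------------------------------------------
# Source taxa and reference panels
# ---------------------------------------------------------------------------


def _draw_site_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    gmap = cfg.map_()
    frames = []
    for chrom in cfg.chromosomes:
        L = cfg.chrom_lengths[chrom]
        n = max(2, int(round(L * cfg.snp_density)))
        bp = np.sort(rng.integers(1, L, size=n, dtype=np.int64))
        while len(np.unique(bp)) < n:  # resample collisions (rare at this density)
            bp = np.unique(bp)
            extra = rng.integers(1, L, size=n - len(bp), dtype=np.int64)
            bp = np.sort(np.concatenate([bp, extra]))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bp": bp,
                    "cM": gmap.interpolate(chrom, bp),
                    "ref": "A",
                    "alt": "G",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _balding_nichols(p_anc: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return p_anc.copy()
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def _shrink_maf(p: np.ndarray, factor: float) -> np.ndarray:
    """Pull allele frequencies toward the nearest boundary (lower MAF)."""
    return np.where(p < 0.5, p * factor, 1.0 - (1.0 - p) * factor)


def _founder_mosaics(
    founders: np.ndarray,
    n_haps: int,
    sites: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Panel haplotypes as Markov mosaics of a small founder set.

    Real reference panels share recent ancestry, so any panel haplotype is
    well approximated piecewise by other panel haplotypes — the property the
    haplotype-copying model exploits.  Founder switches occur at
    ``founder_switch_rate`` per Morgan and a small per-site mutation rate
    keeps haplotypes distinct.
    """
    n_sites = len(sites)
    out = np.empty((n_haps, n_sites), dtype=np.int8)
    cm = sites["cM"].to_numpy(dtype=float)
    for chrom in pd.unique(sites["chrom"]):
        idx = np.flatnonzero((sites["chrom"] == chrom).to_numpy())
        cm_c = cm[idx]
        for h in range(n_haps):
            pos = cm_c[0]
            lo = 0
            while lo < len(idx):
                founder = int(rng.integers(cfg.n_founders))
                pos += rng.exponential(100.0 / cfg.founder_switch_rate)
                hi = int(np.searchsorted(cm_c, pos, side="right"))
                out[h, idx[lo:hi]] = founders[founder, idx[lo:hi]]
                lo = max(hi, lo)
    if cfg.founder_mutation_rate > 0:
        flips = rng.random(out.shape) < cfg.founder_mutation_rate
        out = np.where(flips, 1 - out, out).astype(np.int8)
    return out


def simulate_ancestral_panels(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Draw the shared SNP set and phased reference panels for both taxa.

    Per-site taxon frequencies follow a Balding–Nichols model around a common
    ancestral frequency with differentiation ``divergence_scale``; the maize
    frequency is kept away from fixation (chip discovered in maize) and the
    mexicana minor-allele frequency is shrunk by ``ascertainment_bias`` so
    maize shows higher chip polymorphism, as in maize-ascertained data.
    Within each taxon, haplotypes are founder mosaics (see
    :func:`_founder_mosaics`) so panels carry realistic haplotype sharing.

    Returns (maize_panel, mexicana_panel).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sites = _draw_site_table(cfg, rng)
    n = len(sites)
    p_anc = rng.uniform(0.05, 0.95, size=n)
    p_maize = np.clip(_balding_nichols(p_anc, cfg.divergence_scale, rng), 0.05, 0.95)
    p_mex = np.clip(_balding_nichols(p_anc, cfg.divergence_scale, rng), 0.0, 1.0)
    p_mex = _shrink_maf(p_mex, cfg.ascertainment_bias)
    k = cfg.n_reference_haplotypes
    founders_maize = (rng.random((cfg.n_founders, n)) < p_maize).astype(np.int8)
    founders_mex = (rng.random((cfg.n_founders, n)) < p_mex).astype(np.int8)
    hap_maize = _founder_mosaics(founders_maize, k, sites, cfg, rng)
    hap_mex = _founder_mosaics(founders_mex, k, sites, cfg, rng)
    return (
        HaplotypePanel(sites, hap_maize, "maize"),
        HaplotypePanel(sites, hap_mex, "mexicana"),
    )


# ---------------------------------------------------------------------------
# Admixed haplotypes
# ---------------------------------------------------------------------------


def _simulate_ancestry_segments(
    cm_length: float,
    generations: float,
    donor_fraction: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, int]]:
    """Two-state Markov tract process in cM; 1 = donor ancestry.

    Exit rates per Morgan: recipient->donor = T*m, donor->recipient = T*(1-m),
    giving stationary donor fraction m and mean donor tract length
    100/(T*(1-m)) cM — the standard exponential tract model for admixture T
    generations ago.
    """
    if donor_fraction <= 0.0:
        return [(0.0, cm_length, 0)]
    if donor_fraction >= 1.0:
        return [(0.0, cm_length, 1)]
    rate = {0: generations * donor_fraction, 1: generations * (1 - donor_fraction)}
    state = int(rng.random() < donor_fraction)
    pos = 0.0
    segs: list[tuple[float, float, int]] = []
    while pos < cm_length:
        step = rng.exponential(100.0 / rate[state])  # rate is per Morgan
        end = min(pos + step, cm_length)
        segs.append((pos, end, state))
        pos = end
        state = 1 - state
    return segs


def _cm_to_bp(gmap: GeneticMap, chrom: str, cm: np.ndarray) -> np.ndarray:
    anchors = gmap.anchors[chrom]
    return np.interp(cm, anchors[:, 1], anchors[:, 0])


def _copy_from_panel(
    panel_haps: np.ndarray,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    out: np.ndarray,
) -> None:
    src = rng.integers(panel_haps.shape[0])
    out[lo:hi] = panel_haps[src, lo:hi]


def simulate_admixed_population(
    panels: tuple[HaplotypePanel, HaplotypePanel],
    cfg: SimConfig,
    pop_index: int,
    recipient_taxon: str = "maize",
    rng: np.random.Generator | None = None,
    name: str | None = None,
) -> "SimulatedPopulation":
    """One sympatric population of the recipient taxon with known ancestry.

    Haplotypes are mosaics: ancestry tracts from the exponential tract model,
    alleles copied from a random reference haplotype of the tract's source
    taxon with ``copy_error_rate`` per-site flips, forced tracts overwritten
    per ``shared_tract_spec``.  Diploids pair consecutive haplotypes; the
    returned genotype matrix adds uniform missingness at ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1000 + pop_index) if rng is None else rng
    maize_panel, mex_panel = panels
    if not np.array_equal(
        maize_panel.sites[["chrom", "bp"]].to_numpy(),
        mex_panel.sites[["chrom", "bp"]].to_numpy(),
    ):
        raise ValueError("panels must share the same SNP positions")
    if recipient_taxon not in TAXA:
        raise ValueError(f"unknown taxon {recipient_taxon!r}")
    donor_taxon = "mexicana" if recipient_taxon == "maize" else "maize"
    donor_frac = cfg.admixture_proportion[donor_taxon]
    generations = cfg.time_for(pop_index)
    panel_of = {"maize": maize_panel, "mexicana": mex_panel}
    sites = maize_panel.sites
    gmap = cfg.map_()
    n_hap = 2 * cfg.n_individuals
    n_sites = len(sites)
    haps = np.zeros((n_hap, n_sites), dtype=np.int8)
    tracts: dict[str, list[list[tuple[int, int, str]]]] = {
        c: [] for c in cfg.chromosomes
    }

    forced = [
        t
        for t in cfg.shared_tract_spec
        if t.donor == donor_taxon
    ]
    for t in forced:
        if t.chrom not in cfg.chrom_lengths:
            raise ValueError(f"forced tract on unknown chromosome {t.chrom}")
        if t.end_bp > cfg.chrom_lengths[t.chrom]:
            raise ValueError(
                f"forced tract {t.chrom}:{t.start_bp}-{t.end_bp} exceeds "
                f"chromosome length {cfg.chrom_lengths[t.chrom]}"
            )

    for chrom in cfg.chromosomes:
        L = cfg.chrom_lengths[chrom]
        site_mask = (sites["chrom"] == chrom).to_numpy()
        site_idx = np.flatnonzero(site_mask)
        site_bp = sites["bp"].to_numpy()[site_idx]
        cm_len = float(gmap.interpolate(chrom, L))
        chrom_forced = [t for t in forced if t.chrom == chrom]
        for h in range(n_hap):
            segs_cm = _simulate_ancestry_segments(cm_len, generations, donor_frac, rng)
            bounds_cm = np.array([s for s, _, _ in segs_cm] + [cm_len])
            bounds_bp = np.round(_cm_to_bp(gmap, chrom, bounds_cm)).astype(np.int64)
            bounds_bp[0], bounds_bp[-1] = 0, L
            states = [st for _, _, st in segs_cm]
            # ancestry label per bp segment, then apply forced tracts
            segs_bp: list[tuple[int, int, int]] = [
                (int(bounds_bp[i]), int(bounds_bp[i + 1]), states[i])
                for i in range(len(states))
                if bounds_bp[i + 1] > bounds_bp[i]
            ]
            for t in chrom_forced:
                force_state = int(rng.random() < t.frequency)
                segs_bp = _overwrite_interval(
                    segs_bp, t.start_bp, t.end_bp, force_state, L
                )
            # copy alleles segment by segment
            for s_bp, e_bp, st in segs_bp:
                lo = int(np.searchsorted(site_bp, s_bp, side="left"))
                hi = int(np.searchsorted(site_bp, e_bp, side="left"))
                if hi > lo:
                    src_panel = panel_of[donor_taxon if st else recipient_taxon]
                    block = site_idx[lo:hi]
                    _copy_from_panel(
                        src_panel.haplotypes, block[0], block[-1] + 1, rng,
                        haps[h],
                    )
            seg_labels = [
                (s, e, donor_taxon if st else recipient_taxon)
                for s, e, st in segs_bp
            ]
            tracts[chrom].append(seg_labels)

    if cfg.copy_error_rate > 0:
        flips = rng.random(haps.shape) < cfg.copy_error_rate
        haps = np.where(flips, 1 - haps, haps).astype(np.int8)

    truth = TruthTracts(tracts, dict(cfg.chrom_lengths))
    pop_name = name or f"{recipient_taxon}_pop{pop_index}"
    samples = [f"{pop_name}_ind{i}" for i in range(cfg.n_individuals)]
    dosages = (haps[0::2].astype(np.int16) + haps[1::2].astype(np.int16)).T
    if cfg.missing_rate > 0:
        drop = rng.random(dosages.shape) < cfg.missing_rate
        dosages = np.where(drop, MISSING, dosages)
    gm = GenotypeMatrix(
        sites.copy(),
        dosages,
        samples,
        {s: pop_name for s in samples},
        {pop_name: f"admixed_{recipient_taxon}"},
    )
    hap_panel = HaplotypePanel(sites.copy(), haps, recipient_taxon, samples)
    return SimulatedPopulation(pop_name, recipient_taxon, gm, hap_panel, truth)


def _overwrite_interval(
    segs: list[tuple[int, int, int]], start: int, end: int, state: int, L: int
) -> list[tuple[int, int, int]]:
    """Force ancestry ``state`` over [start, end), preserving the tiling."""
    out: list[tuple[int, int, int]] = []
    for s, e, st in segs:
        if e <= start or s >= end:
            out.append((s, e, st))
        else:
            if s < start:
                out.append((s, start, st))
            if e > end:
                out.append((end, e, st))
    out.append((max(0, start), min(end, L), state))
    out.sort()
    merged: list[tuple[int, int, int]] = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


@dataclass
class SimulatedPopulation:
    """A simulated sympatric population: genotypes, phased haplotypes, truth."""

    name: str
    taxon: str
    genotypes: GenotypeMatrix
    haplotypes: HaplotypePanel
    truth: TruthTracts


# ---------------------------------------------------------------------------
# Reference-panel contamination
# ---------------------------------------------------------------------------


def contaminate_reference(
    panel: HaplotypePanel,
    fraction: float,
    donor_panel: HaplotypePanel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypePanel, TruthTracts]:
    """Introgress donor tracts into ``round(fraction * n)`` panel haplotypes.

    Contaminated haplotypes receive donor tracts by the same exponential
    tract process used for admixed individuals, at the donor taxon's
    configured admixture proportion.  Returns the new panel and the exact
    contamination truth (uncontaminated haplotypes are single recipient
    tracts).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 7777) if rng is None else rng
    n = panel.n_haplotypes
    n_cont = int(round(fraction * n))
    chosen = rng.choice(n, size=n_cont, replace=False) if n_cont else np.array([], int)
    chosen_set = set(int(i) for i in chosen)
    haps = panel.haplotypes.copy()
    donor_frac = cfg.admixture_proportion[donor_panel.taxon]
    generations = cfg.time_for(0)
    gmap = cfg.map_()
    sites = panel.sites
    tracts: dict[str, list[list[tuple[int, int, str]]]] = {}
    for chrom in cfg.chromosomes:
        L = cfg.chrom_lengths[chrom]
        site_mask = (sites["chrom"] == chrom).to_numpy()
        site_idx = np.flatnonzero(site_mask)
        site_bp = sites["bp"].to_numpy()[site_idx]
        cm_len = float(gmap.interpolate(chrom, L))
        per_hap: list[list[tuple[int, int, str]]] = []
        for h in range(n):
            if h not in chosen_set:
                per_hap.append([(0, L, panel.taxon)])
                continue
            segs_cm = _simulate_ancestry_segments(cm_len, generations, donor_frac, rng)
            bounds_cm = np.array([s for s, _, _ in segs_cm] + [cm_len])
            bounds_bp = np.round(_cm_to_bp(gmap, chrom, bounds_cm)).astype(np.int64)
            bounds_bp[0], bounds_bp[-1] = 0, L
            labels: list[tuple[int, int, str]] = []
            for i, (_, _, st) in enumerate(segs_cm):
                s_bp, e_bp = int(bounds_bp[i]), int(bounds_bp[i + 1])
                if e_bp <= s_bp:
                    continue
                labels.append((s_bp, e_bp, donor_panel.taxon if st else panel.taxon))
                if st:
                    lo = int(np.searchsorted(site_bp, s_bp, side="left"))
                    hi = int(np.searchsorted(site_bp, e_bp, side="left"))
                    if hi > lo:
                        block = site_idx[lo:hi]
                        _copy_from_panel(
                            donor_panel.haplotypes, block[0], block[-1] + 1, rng,
                            haps[h],
                        )
            # merge adjacent same-label segments
            merged: list[tuple[int, int, str]] = []
            for seg in labels:
                if merged and merged[-1][2] == seg[2]:
                    merged[-1] = (merged[-1][0], seg[1], seg[2])
                else:
                    merged.append(list(seg))  # type: ignore[arg-type]
                    merged[-1] = tuple(merged[-1])  # type: ignore[assignment]
            per_hap.append([tuple(m) for m in merged])
        tracts[chrom] = per_hap
    truth = TruthTracts(tracts, dict(cfg.chrom_lengths))
    return HaplotypePanel(sites.copy(), haps, panel.taxon, list(panel.samples)), truth


# ---------------------------------------------------------------------------
# Annotation intervals
# ---------------------------------------------------------------------------


def simulate_annotations(
    cfg: SimConfig,
    regions_to_enrich: pd.DataFrame,
    n_genes: int,
    enrichment_factor: float = 1.0,
    seed: int | None = None,
    gene_length_bp: int = 5_000,
) -> pd.DataFrame:
    """Place gene-like intervals with density scaled inside target regions.

    A factor of 1 gives uniform placement; >1 enriches and <1 depletes genes
    inside ``regions_to_enrich`` (columns chrom, start, end).  Returns a
    DataFrame (chrom, start, end, name) with exactly ``n_genes`` rows.
    """
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be >= 0")
    rng = np.random.default_rng(cfg.seed + 31 if seed is None else seed)
    lengths = cfg.chrom_lengths
    chroms = list(lengths)
    # per-chromosome enriched intervals, merged
    enriched: dict[str, np.ndarray] = {}
    for c in chroms:
        sub = regions_to_enrich[regions_to_enrich["chrom"] == c]
        ivs = np.array(sorted(zip(sub["start"], sub["end"])), dtype=np.int64).reshape(
            -1, 2
        )
        enriched[c] = ivs
    total_in = sum((iv[:, 1] - iv[:, 0]).sum() for iv in enriched.values())
    total = sum(lengths.values())
    total_out = total - total_in
    w_in = enrichment_factor * total_in
    w_out = float(total_out)
    if w_in + w_out <= 0:
        raise ValueError("no genome available for placement")
    rows = []
    for g in range(n_genes):
        inside = rng.random() < w_in / (w_in + w_out)
        if inside:
            # choose enriched interval weighted by its length
            flat = [
                (c, int(s), int(e))
                for c in chroms
                for s, e in enriched[c]
            ]
            lens = np.array([e - s for _, s, e in flat], dtype=float)
            k = rng.choice(len(flat), p=lens / lens.sum())
            c, s, e = flat[k]
            start = int(rng.integers(s, max(s + 1, e - gene_length_bp)))
        else:
            # rejection-sample a start outside enriched intervals
            while True:
                c = chroms[rng.choice(len(chroms), p=np.array(
                    [lengths[x] for x in chroms], dtype=float) / total)]
                start = int(rng.integers(0, lengths[c] - gene_length_bp))
                ivs = enriched[c]
                end = start + gene_length_bp
                if ivs.size == 0 or not np.any(
                    (ivs[:, 0] < end) & (start < ivs[:, 1])
                ):
                    break
        rows.append((c, start, min(start + gene_length_bp, lengths[c]), f"gene{g}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# Whole-study convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """Full synthetic cohort: panels, all sympatric populations, and a merged
    genotype matrix (admixed individuals plus diploidized reference samples)."""

    cfg: SimConfig
    maize_panel: HaplotypePanel
    mexicana_panel: HaplotypePanel
    populations: list[SimulatedPopulation]
    genotypes: GenotypeMatrix
    reference_truth: dict[str, TruthTracts]

    def populations_of(self, taxon: str) -> list[SimulatedPopulation]:
        return [p for p in self.populations if p.taxon == taxon]


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Simulate the complete study design from one config and seed."""
    rng = np.random.default_rng(cfg.seed)
    maize_panel, mex_panel = simulate_ancestral_panels(cfg, rng)
    ref_truth: dict[str, TruthTracts] = {}
    if cfg.reference_contamination_fraction > 0:
        maize_panel, t_m = contaminate_reference(
            maize_panel, cfg.reference_contamination_fraction, mex_panel, cfg,
            np.random.default_rng(cfg.seed + 11),
        )
        mex_panel, t_x = contaminate_reference(
            mex_panel, cfg.reference_contamination_fraction, maize_panel, cfg,
            np.random.default_rng(cfg.seed + 12),
        )
        ref_truth = {"maize": t_m, "mexicana": t_x}
    pops: list[SimulatedPopulation] = []
    for i in range(cfg.n_populations):
        for taxon in TAXA:
            pops.append(
                simulate_admixed_population(
                    (maize_panel, mex_panel),
                    cfg,
                    i,
                    recipient_taxon=taxon,
                    rng=np.random.default_rng(
                        cfg.seed + 1000 + 10 * i + (0 if taxon == "maize" else 5)
                    ),
                    name=f"pair{i}_{taxon}",
                )
            )
    genotypes = _merge_study_genotypes(maize_panel, mex_panel, pops)
    return SimulatedStudy(cfg, maize_panel, mex_panel, pops, genotypes, ref_truth)


def _merge_study_genotypes(
    maize_panel: HaplotypePanel,
    mex_panel: HaplotypePanel,
    pops: list[SimulatedPopulation],
) -> GenotypeMatrix:
    sites = maize_panel.sites.copy()
    blocks = [maize_panel.dosages(), mex_panel.dosages()]
    individuals = [f"maize_ref{i}" for i in range(maize_panel.n_individuals)]
    individuals += [f"mexicana_ref{i}" for i in range(mex_panel.n_individuals)]
    populations = {s: "reference_maize" for s in individuals[: maize_panel.n_individuals]}
    populations.update(
        {s: "reference_mexicana" for s in individuals[maize_panel.n_individuals:]}
    )
    roles = {
        "reference_maize": "reference_maize",
        "reference_mexicana": "reference_mexicana",
    }
    for p in pops:
        blocks.append(p.genotypes.dosages)
        individuals.extend(p.genotypes.individuals)
        populations.update(p.genotypes.populations)
        roles.update(p.genotypes.roles)
    return GenotypeMatrix(sites, np.hstack(blocks), individuals, populations, roles)
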