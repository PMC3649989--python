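"""Turn per-site ancestry tracks into called genomic regions.

Introgressed regions are maximal runs of markers whose population mean donor
fraction meets the 50% threshold; introgression-resistant regions are markers
at or below 5% donor fraction in at least k (default 7) populations under
both scans; the two scans are reconciled by interval intersection, and
cross-population sharing is computed with a coverage-depth sweep.  Region
boundaries are placed at inter-marker midpoints and reported as 0-based
half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry_hmm import AncestryTrack


@dataclass
class GenomicRegion:
    """Half-open interval with signal, direction and provenance."""

    chrom: str
    start: int
    end: int
    mean_signal: float = 0.0
    direction: str = ""
    method: str = "hmm"
    populations_supporting: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def support(self) -> int:
        return len(self.populations_supporting)

    @property
    def length(self) -> int:
        return self.end - self.start


def regions_to_frame(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.start, r.end, r.mean_signal, r.direction, r.method,
         r.support, ",".join(r.populations_supporting))
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "mean_signal", "direction", "method",
                 "support", "populations"],
    )


def total_bp(regions: Iterable[GenomicRegion]) -> int:
    return sum(r.length for r in regions)


# ---------------------------------------------------------------------------
# Run -> region conversion
# ---------------------------------------------------------------------------


def _runs_to_regions(
    bp: np.ndarray,
    mask: np.ndarray,
    values: np.ndarray | None,
    min_sites: int,
    chrom_length: int | None,
):
    """Maximal runs of True in ``mask`` (>= min_sites markers) as (start, end,
    mean_value) with midpoint boundaries, clamped at chromosome ends."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        if j - i >= min_sites:
            start = 0 if i == 0 else int((bp[i - 1] + bp[i]) // 2)
            if j == n:
                end = int(chrom_length) if chrom_length else int(bp[n - 1])
            else:
                end = int((bp[j - 1] + bp[j]) // 2)
            mean_val = float(np.nanmean(values[i:j])) if values is not None else float("nan")
            out.append((start, end, mean_val, i, j))
        i = j
    return out


def call_regions(
    track: AncestryTrack,
    threshold: float = 0.5,
    min_sites: int = 2,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """Introgressed regions: maximal runs of >= min_sites consecutive markers
    with population mean donor fraction >= threshold.

    Region bounds are midpoints to the flanking sub-threshold markers, clamped
    to [0, chromosome length) at the ends.  Markers with undefined signal
    count as sub-threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    chrom_lengths = chrom_lengths or track.chrom_lengths or {}
    regions: list[GenomicRegion] = []
    for chrom in pd.unique(track.sites["chrom"]):
        sel = (track.sites["chrom"] == chrom).to_numpy()
        bp = track.sites["bp"].to_numpy()[sel]
        v = track.mean[sel]
        mask = np.where(np.isfinite(v), v >= threshold, False)
        for start, end, mval, _, _ in _runs_to_regions(
            bp, mask, v, min_sites, chrom_lengths.get(str(chrom))
        ):
            regions.append(
                GenomicRegion(
                    str(chrom), start, end, mval,
                    direction=track.direction, method=track.method,
                    populations_supporting=[track.population],
                )
            )
    return regions


def call_resistant(
    tracks_by_population: Mapping[str, Mapping[str, AncestryTrack]],
    threshold: float = 0.05,
    k: int = 7,
    both_methods: bool = True,
    min_sites: int = 2,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicRegion]:
    """Introgression-resistant regions: markers with donor fraction <=
    threshold in >= k populations, confirmed by both scans.

    ``tracks_by_population`` maps population -> method -> aligned track.  A
    population supports a region only if its maximum signal across the region
    stays at or below the threshold under every required method.
    """
    pops = list(tracks_by_population)
    if k > len(pops):
        raise ValueError(f"k={k} exceeds the {len(pops)} populations provided")
    ref = next(iter(tracks_by_population.values()))
    ref_track = next(iter(ref.values()))
    sites = ref_track.sites
    chrom_lengths = chrom_lengths or ref_track.chrom_lengths or {}
    direction = ref_track.direction

    def pop_ok_matrix() -> np.ndarray:
        ok = np.ones((len(sites), len(pops)), dtype=bool)
        for j, pop in enumerate(pops):
            methods = tracks_by_population[pop]
            if both_methods and len(methods) < 2:
                raise ValueError(f"population {pop!r} lacks a second method track")
            for tr in methods.values():
                if len(tr.mean) != len(sites):
                    raise ValueError("tracks are not aligned across populations")
                ok[:, j] &= np.where(np.isfinite(tr.mean), tr.mean <= threshold, False)
        return ok

    ok = pop_ok_matrix()
    mask_all = ok.sum(axis=1) >= k
    regions: list[GenomicRegion] = []
    for chrom in pd.unique(sites["chrom"]):
        sel = (sites["chrom"] == chrom).to_numpy()
        bp = sites["bp"].to_numpy()[sel]
        ok_c = ok[sel]
        for start, end, _, i0, i1 in _runs_to_regions(
            bp, mask_all[sel], None, min_sites, chrom_lengths.get(str(chrom))
        ):
            # region-wise confirmation: a supporter stays below threshold
            # across the whole run
            supporters = [
                pops[j] for j in range(len(pops)) if ok_c[i0:i1, j].all()
            ]
            if len(supporters) >= k:
                regions.append(
                    GenomicRegion(
                        str(chrom), start, end,
                        mean_signal=float(len(supporters)) / len(pops),
                        direction=direction, method="resistant",
                        populations_supporting=supporters,
                    )
                )
    return regions


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------


def consensus_regions(
    regions_hmm: Sequence[GenomicRegion],
    regions_freq: Sequence[GenomicRegion],
) -> list[GenomicRegion]:
    """Interval intersection of the two scans' region lists (provenance
    ``consensus``); empty intersections are dropped."""
    out: list[GenomicRegion] = []
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions_freq:
        by_chrom.setdefault(r.chrom, []).append(r)
    for a in regions_hmm:
        for b in by_chrom.get(a.chrom, []):
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo < hi:
                out.append(
                    GenomicRegion(
                        a.chrom, lo, hi,
                        mean_signal=(a.mean_signal + b.mean_signal) / 2.0,
                        direction=a.direction, method="consensus",
                        populations_supporting=sorted(
                            set(a.populations_supporting)
                            | set(b.populations_supporting)
                        ),
                    )
                )
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def shared_across_populations(
    regions_by_population: Mapping[str, Sequence[GenomicRegion]],
    k: int = 7,
) -> list[GenomicRegion]:
    """Intervals covered by regions from >= k populations (coverage-depth
    sweep over each population's merged region set); supporting population
    labels are recorded on each output region."""
    chroms = sorted(
        {r.chrom for regs in regions_by_population.values() for r in regs}
    )
    out: list[GenomicRegion] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []  # (pos, +1/-1)
        pop_ivs: dict[str, list[tuple[int, int]]] = {}
        for pop, regs in regions_by_population.items():
            ivs = _merge_intervals([(r.start, r.end) for r in regs if r.chrom == chrom])
            pop_ivs[pop] = ivs
            for s, e in ivs:
                events.append((s, 1))
                events.append((e, -1))
        if not events:
            continue
        events.sort()
        depth = 0
        open_start: int | None = None
        segs: list[tuple[int, int]] = []
        for pos, delta in events:
            new_depth = depth + delta
            if depth < k <= new_depth:
                open_start = pos
            elif depth >= k > new_depth and open_start is not None:
                if pos > open_start:
                    segs.append((open_start, pos))
                open_start = None
            depth = new_depth
        for s, e in _merge_intervals(segs):
            supporters = sorted(
                pop
                for pop, ivs in pop_ivs.items()
                if any(s0 < e and s < e0 for s0, e0 in ivs)
            )
            direction = next(
                (r.direction for regs in regions_by_population.values()
                 for r in regs if r.chrom == chrom),
                "",
            )
            out.append(
                GenomicRegion(
                    chrom, s, e,
                    mean_signal=float(len(supporters)),
                    direction=direction, method="shared",
                    populations_supporting=supporters,
                )
            )
    return out


def overlap_annotations(
    regions: Sequence[GenomicRegion],
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Overlap of called regions with annotation intervals (half-open bp).

    ``annotations`` needs columns chrom, start, end and optionally name.
    Returns the per-pair overlap table and summary counts.
    """
    names = (
        annotations["name"]
        if "name" in annotations.columns
        else pd.Series([f"iv{i}" for i in range(len(annotations))])
    )
    rows = []
    hit_regions: set[int] = set()
    hit_annots: set[int] = set()
    for i, r in enumerate(regions):
        sub = annotations[annotations["chrom"] == r.chrom]
        for j, (s, e) in zip(sub.index, zip(sub["start"], sub["end"])):
            ov = min(r.end, int(e)) - max(r.start, int(s))
            if ov > 0:
                rows.append((r.chrom, r.start, r.end, names[j], int(s), int(e), ov))
                hit_regions.add(i)
                hit_annots.add(j)
    table = pd.DataFrame(
        rows,
        columns=["chrom", "region_start", "region_end", "annotation",
                 "annot_start", "annot_end", "overlap_bp"],
    )
    summary = {
        "n_regions": len(regions),
        "n_regions_with_overlap": len(hit_regions),
        "n_annotations": len(annotations),
        "n_annotations_hit": len(hit_annots),
        "total_overlap_bp": int(table["overlap_bp"].sum()) if len(table) else 0,
    }
    return table, summary
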