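"""End-to-end orchestration: simulate -> filter -> diversity -> two ancestry
scans -> jackknife correction -> region calling -> enrichment -> IBS.

A run is fully determined by its :class:`RunConfig` (including one root seed
from which every stage draws a named substream) and emits a JSON report with
per-stage summaries plus, on simulated data, recovery metrics against the
simulator's ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ancestry_hmm, diversity, enrichment, frequency_scan, region_calling
from . import ibs_tracts, io_formats, synthetic_data
from .ancestry_hmm import AncestryTrack, CopyingParams
from .io_formats import write_regions
from .region_calling import GenomicRegion
from .synthetic_data import SimConfig, SimulatedStudy

DEFAULT_T_GRID = (1.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0)


def subseed(root_seed: int, name: str) -> int:
    """Named, reproducible per-stage seed derived from the root seed."""
    return int((root_seed & 0x7FFFFFFF) ^ zlib.crc32(name.encode()) & 0x7FFFFFFF) % (
        2**31
    )


@dataclass
class RunConfig:
    """Everything a full run needs; serializable and sufficient to reproduce
    the run bit for bit."""

    sim: SimConfig = field(default_factory=SimConfig)
    introgression_threshold: float = 0.5
    resistance_threshold: float = 0.05
    k_populations: int = 7
    min_sites: int = 2
    max_missing_per_taxon: float = 0.10
    miscopy_rate: float = 0.002
    panel_switch_rate: float = 10.0
    switch_rate_per_cM: float = 1.0
    T_grid: Sequence[float] = DEFAULT_T_GRID
    n_perm: int = 1000
    n_annotation_genes: int = 484
    annotation_factor: float = 0.2
    n_ibs_populations: int = 2
    seed: int = 0
    output_dir: str | None = None

    def params_for(self, donor: str) -> CopyingParams:
        return CopyingParams(
            generations_T=self.sim.time_for(0),
            mix_prior=self.sim.admixture_proportion[donor],
            miscopy_rate=self.miscopy_rate,
            panel_switch_rate=self.panel_switch_rate,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["shared_tract_spec"] = [
            asdict(t) for t in self.sim.shared_tract_spec
        ]
        d["sim"].pop("genetic_map", None)
        d["T_grid"] = list(self.T_grid)
        return d


def _merged_union(regions: Sequence[GenomicRegion]) -> list[GenomicRegion]:
    out: list[GenomicRegion] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, GenomicRegion] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        meta.setdefault(r.chrom, r)
    for chrom, ivs in sorted(by_chrom.items()):
        for s, e in region_calling._merge_intervals(ivs):
            m = meta[chrom]
            out.append(
                GenomicRegion(chrom, s, e, direction=m.direction, method=m.method)
            )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline on a simulated study; returns the report."""
    report: dict = {"config": cfg.to_dict(), "stages": {}}
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, err: Exception) -> None:
        if outdir:
            (outdir / "report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True)
            )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # --- simulate ----------------------------------------------------------
    try:
        sim_cfg = cfg.sim
        if sim_cfg.seed != cfg.seed:
            from dataclasses import replace as _dc_replace

            sim_cfg = _dc_replace(sim_cfg, seed=cfg.seed)
        study = synthetic_data.simulate_study(sim_cfg)
        report["stages"]["simulate"] = {
            "n_sites": int(study.genotypes.n_sites),
            "n_individuals": int(study.genotypes.n_individuals),
            "n_population_pairs": sim_cfg.n_populations,
            "true_donor_fraction": {
                p.name: p.truth.donor_fraction(
                    "mexicana" if p.taxon == "maize" else "maize"
                )
                for p in study.populations
            },
        }
    except Exception as err:  # noqa: BLE001
        fail("simulate", err)

    # --- filter ------------------------------------------------------------
    try:
        filtered = io_formats.filter_sites(
            study.genotypes, cfg.max_missing_per_taxon, require_polymorphic=True
        )
        report["stages"]["filter"] = {
            "n_input_sites": int(study.genotypes.n_sites),
            "n_retained_sites": int(filtered.n_sites),
        }
    except Exception as err:  # noqa: BLE001
        fail("filter", err)

    # --- diversity ---------------------------------------------------------
    try:
        div = diversity.diversity_table(filtered)
        pairs = []
        for i in range(sim_cfg.n_populations):
            a, b = f"pair{i}_maize", f"pair{i}_mexicana"
            fst = diversity.fst_weir_cockerham(filtered, a, b)
            classes = diversity.classify_polymorphisms(filtered, a, b)
            f3 = diversity.f3_statistic(
                filtered, a, "reference_maize", "reference_mexicana"
            )
            pairs.append(
                {
                    "pair": i,
                    "fst": fst.multilocus,
                    "shared": classes.shared,
                    "private_maize": classes.private_popA,
                    "private_mexicana": classes.private_popB,
                    "fixed_differences": classes.fixed_differences,
                    "f3_median_maize_target": f3.median,
                    "f3_admixture_consistent": bool(f3.admixture_consistent),
                }
            )
        report["stages"]["diversity"] = {
            "per_population": div.to_dict(orient="records"),
            "per_pair": pairs,
        }
        if outdir:
            div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    except Exception as err:  # noqa: BLE001
        fail("diversity", err)

    # --- scans + correction + regions, per direction -----------------------
    results: dict[str, dict] = {}
    try:
        blocks = frequency_scan.block_haplotypes(
            study.maize_panel, study.mexicana_panel
        )
        report["stages"]["blocking"] = {
            "n_loci": blocks.n_loci,
            "mean_alleles_per_locus": blocks.mean_alleles_per_locus,
        }
        for recipient, donor in (("maize", "mexicana"), ("mexicana", "maize")):
            res = _scan_direction(cfg, study, blocks, recipient, donor)
            results[donor] = res
            report["stages"][f"scan_{donor}_into_{recipient}"] = res["summary"]
            if outdir:
                write_regions(
                    res["shared_regions"], outdir / f"shared_{donor}.bed"
                )
                write_regions(
                    res["resistant_regions"], outdir / f"resistant_{donor}.bed"
                )
                pd.concat(
                    [t.to_frame().assign(population=p)
                     for p, t in res["hmm_tracks"].items()]
                ).to_csv(outdir / f"hmm_track_{donor}.tsv", sep="\t", index=False)
    except Exception as err:  # noqa: BLE001
        fail("ancestry_scans", err)

    # --- detection asymmetry ------------------------------------------------
    genome_bp = sum(sim_cfg.chrom_lengths.values())
    report["stages"]["asymmetry"] = {
        donor: results[donor]["summary"]["mean_called_fraction_hmm"]
        for donor in ("mexicana", "maize")
    }

    # --- enrichment ---------------------------------------------------------
    try:
        target_regions = results["mexicana"]["consensus_union"]
        reg_df = region_calling.regions_to_frame(target_regions)
        genes = synthetic_data.simulate_annotations(
            sim_cfg,
            reg_df[["chrom", "start", "end"]],
            cfg.n_annotation_genes,
            cfg.annotation_factor,
            seed=subseed(cfg.seed, "annotations"),
        )
        enr = enrichment.permutation_enrichment(
            target_regions, genes, sim_cfg.chrom_lengths,
            n_perm=cfg.n_perm, seed=subseed(cfg.seed, "permutation"),
        )
        report["stages"]["enrichment"] = {
            "annotation_factor": cfg.annotation_factor,
            "domestication_gene_test": enr.to_dict(),
        }
        if outdir:
            genes.to_csv(outdir / "annotations.bed", sep="\t", index=False,
                         header=False)
    except Exception as err:  # noqa: BLE001
        fail("enrichment", err)

    # --- IBS ----------------------------------------------------------------
    try:
        report["stages"]["ibs"] = _ibs_stage(cfg, study)
    except Exception as err:  # noqa: BLE001
        fail("ibs", err)

    # --- truth recovery ------------------------------------------------------
    try:
        report["recovery"] = _recovery_metrics(cfg, study, results)
    except Exception as err:  # noqa: BLE001
        fail("recovery", err)

    report["genome_bp"] = genome_bp
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def _scan_direction(
    cfg: RunConfig,
    study: SimulatedStudy,
    blocks: frequency_scan.HaplotypeBlockSet,
    recipient: str,
    donor: str,
) -> dict:
    panel_recipient = study.maize_panel if recipient == "maize" else study.mexicana_panel
    panel_donor = study.mexicana_panel if donor == "mexicana" else study.maize_panel
    pops = study.populations_of(recipient)
    k_eff = min(cfg.k_populations, len(pops))
    params = cfg.params_for(donor)

    # admixture-time profile on the first population; scans use T_hat
    profile = ancestry_hmm.profile_admixture_time(
        pops[0].haplotypes, panel_recipient, panel_donor, cfg.T_grid, params
    )
    params = CopyingParams(
        generations_T=profile.T_hat,
        mix_prior=params.mix_prior,
        miscopy_rate=params.miscopy_rate,
        panel_switch_rate=params.panel_switch_rate,
    )

    baseline = ancestry_hmm.jackknife_reference_baseline(
        panel_recipient, panel_donor, params
    )

    hmm_tracks: dict[str, AncestryTrack] = {}
    freq_tracks: dict[str, AncestryTrack] = {}
    regions_hmm: dict[str, list[GenomicRegion]] = {}
    regions_freq: dict[str, list[GenomicRegion]] = {}
    consensus: dict[str, list[GenomicRegion]] = {}
    chrom_lengths = study.cfg.chrom_lengths
    for p in pops:
        raw = ancestry_hmm.scan_population(
            p.haplotypes, panel_recipient, panel_donor, params, population=p.name
        )
        corrected = ancestry_hmm.correct_track(raw, baseline)
        hmm_tracks[p.name] = corrected
        ft = frequency_scan.scan_population_freq(
            blocks, p.haplotypes, donor, cfg.switch_rate_per_cM,
            donor_prior=cfg.sim.admixture_proportion[donor], population=p.name,
        ).to_site_track()
        freq_tracks[p.name] = ft
        regions_hmm[p.name] = region_calling.call_regions(
            corrected, cfg.introgression_threshold, cfg.min_sites, chrom_lengths
        )
        regions_freq[p.name] = region_calling.call_regions(
            ft, cfg.introgression_threshold, cfg.min_sites, chrom_lengths
        )
        consensus[p.name] = region_calling.consensus_regions(
            regions_hmm[p.name], regions_freq[p.name]
        )

    shared = region_calling.shared_across_populations(consensus, k_eff)
    resistant = region_calling.call_resistant(
        {p: {"hmm": hmm_tracks[p], "freq": freq_tracks[p]} for p in hmm_tracks},
        cfg.resistance_threshold, k_eff,
        min_sites=cfg.min_sites, chrom_lengths=chrom_lengths,
    )
    genome_bp = sum(chrom_lengths.values())
    called_frac_hmm = float(
        np.mean([region_calling.total_bp(r) / genome_bp for r in regions_hmm.values()])
    )
    called_frac_freq = float(
        np.mean([region_calling.total_bp(r) / genome_bp for r in regions_freq.values()])
    )
    summary = {
        "T_hat": profile.T_hat,
        "k_populations_effective": k_eff,
        "mean_called_fraction_hmm": called_frac_hmm,
        "mean_called_fraction_freq": called_frac_freq,
        "n_shared_regions": len(shared),
        "shared_regions": region_calling.regions_to_frame(shared).to_dict(
            orient="records"
        ),
        "n_resistant_regions": len(resistant),
        "mean_recovered_donor_fraction": float(
            np.mean([t.mean.mean() for t in hmm_tracks.values()])
        ),
        "baseline_mean": float(baseline.mean()),
    }
    return {
        "summary": summary,
        "hmm_tracks": hmm_tracks,
        "freq_tracks": freq_tracks,
        "regions_hmm": regions_hmm,
        "regions_freq": regions_freq,
        "consensus": consensus,
        "consensus_union": _merged_union(
            [r for regs in consensus.values() for r in regs]
        ),
        "shared_regions": shared,
        "resistant_regions": resistant,
        "baseline": baseline,
    }


def _ibs_stage(cfg: RunConfig, study: SimulatedStudy) -> dict:
    """IBS of a few maize populations against the two reference panels."""
    pops = study.populations_of("maize")[: cfg.n_ibs_populations]
    sites = study.maize_panel.sites
    out = {}
    for p in pops:
        segs_mex = ibs_tracts.seed_extend_ibs(p.haplotypes, study.mexicana_panel)
        segs_maize = ibs_tracts.seed_extend_ibs(p.haplotypes, study.maize_panel)
        nq = p.haplotypes.n_haplotypes
        _, prof_mex = ibs_tracts.site_ibs_profile(
            segs_mex, sites, nq, study.mexicana_panel.n_haplotypes
        )
        _, prof_maize = ibs_tracts.site_ibs_profile(
            segs_maize, sites, nq, study.maize_panel.n_haplotypes
        )
        _, frac_pos = ibs_tracts.ibs_differential(
            prof_mex, prof_maize, {p.name: list(range(nq))}
        )
        out[p.name] = {
            "n_segments_vs_mexicana": len(segs_mex),
            "n_segments_vs_maize_reference": len(segs_maize),
            "fraction_sites_greater_ibs_with_mexicana": frac_pos[p.name],
        }
    return out


def _recovery_metrics(cfg: RunConfig, study: SimulatedStudy, results: dict) -> dict:
    """Score inferred ancestry and called regions against simulated truth."""
    out: dict = {}
    sites = study.maize_panel.sites
    for donor, recipient in (("mexicana", "maize"), ("maize", "mexicana")):
        res = results[donor]
        pops = study.populations_of(recipient)
        errs, agreements = [], []
        for p in pops:
            truth_ind = p.truth.site_donor_indicator(sites, donor)  # sites x haps
            truth_dosage = (
                truth_ind[:, 0::2].astype(float) + truth_ind[:, 1::2]
            )  # sites x individuals
            track = res["hmm_tracks"][p.name]
            true_frac = p.truth.donor_fraction(donor)
            errs.append(track.mean.mean() - true_frac)
            called = (
                track.carrier_prob >= 0.5
                if track.carrier_prob is not None
                else track.dosage >= 1.0
            )
            agreements.append(float((called == (truth_dosage >= 1.0)).mean()))
        # forced-tract recovery via shared consensus regions
        forced = [
            t for t in study.cfg.shared_tract_spec
            if t.donor == donor and t.frequency >= 0.9
        ]
        tract_recovery = []
        shared = res["shared_regions"]
        for t in forced:
            cover = sum(
                max(0, min(r.end, t.end_bp) - max(r.start, t.start_bp))
                for r in shared
                if r.chrom == t.chrom
            )
            tract_recovery.append(cover / (t.end_bp - t.start_bp))
        false_shared = [
            r for r in shared
            if not any(
                t.chrom == r.chrom
                and min(r.end, t.end_bp) - max(r.start, t.start_bp) > 0
                for t in forced
            )
        ]
        out[donor] = {
            "mean_donor_fraction_error": float(np.mean(errs)),
            "max_abs_donor_fraction_error": float(np.max(np.abs(errs))),
            "mean_site_ancestry_agreement": float(np.mean(agreements)),
            "forced_tract_recovery": tract_recovery,
            "n_false_shared_regions": len(false_shared),
        }
    return out
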