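"""Input/output for the introgression pipeline.

Genotypes come in as VCF 4.x or as a tabular dosage dialect (TSV with columns
``chrom, pos, cM, ref, alt`` followed by one dosage column per sample, ``.``
for missing).  Sample metadata is a TSV with columns ``sample, population,
role`` where role is one of ``admixed_maize``, ``admixed_mexicana``,
``reference_maize``, ``reference_mexicana``.

Coordinate conventions: SNP positions are 1-based (VCF); exported intervals
are 0-based half-open (BED).  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing diploid dosage
MISSING: int = -1

ROLES = frozenset(
    {"admixed_maize", "admixed_mexicana", "reference_maize", "reference_mexicana"}
)

SITE_COLUMNS = ["chrom", "bp", "cM", "ref", "alt"]


def taxon_of_role(role: str) -> str:
    """Species label (``maize`` or ``mexicana``) encoded in a role string."""
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {sorted(ROLES)}")
    return role.split("_", 1)[1]


@dataclass(frozen=True)
class SNPRecord:
    """A single biallelic site with physical and genetic-map coordinates."""

    chrom: str
    bp: int
    cM: float
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"alleles must differ at {self.chrom}:{self.bp}")
        if self.cM < 0:
            raise ValueError(f"negative cM at {self.chrom}:{self.bp}")


@dataclass
class GenotypeMatrix:
    """Sites x individuals allele-dosage table with population metadata.

    ``dosages`` counts copies of the alternate allele (0/1/2) with
    :data:`MISSING` marking untyped genotypes.  Sites are sorted by
    (chromosome, bp) and the cM coordinate is non-decreasing within each
    chromosome.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    individuals: list[str]
    populations: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        missing = [s for s in self.individuals if s not in self.populations]
        if missing:
            raise ValueError(f"samples without population assignment: {missing[:5]}")
        for role in self.roles.values():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        self._validate_sorted()

    def _validate_sorted(self) -> None:
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) < 0):
                i = int(np.flatnonzero(np.diff(bp) < 0)[0]) + 1
                raise ValueError(
                    f"sites unsorted on {chrom}: position {bp[i]} after {bp[i - 1]}"
                )
            cm = grp["cM"].to_numpy()
            if np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"cM not monotone on {chrom}")

    # -- basic geometry -----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def taxon_of(self, population: str) -> str:
        return taxon_of_role(self.roles[population])

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.individuals if self.populations[s] == population]

    def columns_for(self, samples: Sequence[str]) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.individuals)}
        return np.array([index[s] for s in samples], dtype=np.intp)

    def population_dosages(self, population: str) -> np.ndarray:
        """Dosage sub-matrix (sites x members) for one population."""
        cols = self.columns_for(self.samples_in(population))
        if cols.size == 0:
            raise KeyError(f"population {population!r} has no samples")
        return self.dosages[:, cols]

    def taxon_samples(self, taxon: str) -> list[str]:
        return [
            s
            for s in self.individuals
            if taxon_of_role(self.roles[self.populations[s]]) == taxon
        ]

    def allele_frequency(self, population: str) -> np.ndarray:
        """Per-site alt-allele frequency in one population (NaN if untyped)."""
        return dosage_allele_frequency(self.population_dosages(population))

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self, sites=self.sites.loc[mask], dosages=self.dosages[mask, :]
        )


@dataclass
class HaplotypePanel:
    """Phased haplotypes for one taxon at a shared site set.

    ``haplotypes`` is (n_haplotypes x n_sites) with 0 = ref, 1 = alt; rows
    2i and 2i+1 belong to individual i.  Used both for reference panels and
    for phased admixed individuals.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    taxon: str
    samples: list[str] | None = None

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype array does not match site table")
        if self.samples is None:
            n_ind = self.haplotypes.shape[0] // 2
            self.samples = [f"{self.taxon}_ref{i}" for i in range(n_ind)]

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2

    def chromosome_slice(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def drop_individual(self, index: int) -> "HaplotypePanel":
        """Panel with individual ``index`` (haplotypes 2i, 2i+1) removed."""
        keep = np.ones(self.n_haplotypes, dtype=bool)
        keep[2 * index : 2 * index + 2] = False
        samples = [s for i, s in enumerate(self.samples) if i != index]
        return HaplotypePanel(self.sites, self.haplotypes[keep], self.taxon, samples)

    def dosages(self) -> np.ndarray:
        """Diploid alt-dosage matrix (sites x individuals)."""
        h = self.haplotypes.astype(np.int16)
        return (h[0::2] + h[1::2]).T

    def write_tsv(self, path: str | Path) -> None:
        df = self.sites.copy()
        for k in range(self.n_haplotypes):
            df[f"{self.samples[k // 2]}_h{k % 2}"] = self.haplotypes[k]
        df.to_csv(path, sep="\t", index=False)


def dosage_allele_frequency(dos: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per row of a dosage block, ignoring missing."""
    typed = dos != MISSING
    n = typed.sum(axis=1)
    alt = np.where(typed, dos, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Per-chromosome (bp, cM) anchors with linear interpolation.

    Queries between anchors interpolate linearly; queries outside the anchored
    span extrapolate at the terminal inter-anchor rate.
    """

    anchors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"map for {chrom} needs >=2 (bp, cM) anchors")
            arr = arr[np.argsort(arr[:, 0])]
            if np.any(np.diff(arr[:, 1]) < 0):
                raise ValueError(f"cM anchors not monotone on {chrom}")
            clean[chrom] = arr
        self.anchors = clean

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map (default 1 cM/Mb) over the given chromosomes."""
        return cls(
            {
                c: np.array([[0.0, 0.0], [float(L), cm_per_mb * L / 1e6]])
                for c, L in chrom_lengths.items()
            }
        )

    def interpolate(self, chrom: str, bp) -> np.ndarray | float:
        """cM position(s) for physical position(s) on one chromosome."""
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        arr = self.anchors[chrom]
        x, y = arr[:, 0], arr[:, 1]
        q = np.asarray(bp, dtype=float)
        out = np.interp(q, x, y)
        # extrapolate at terminal rates outside the anchored span
        lo_rate = (y[1] - y[0]) / (x[1] - x[0])
        hi_rate = (y[-1] - y[-2]) / (x[-1] - x[-2])
        out = np.where(q < x[0], y[0] + (q - x[0]) * lo_rate, out)
        out = np.where(q > x[-1], y[-1] + (q - x[-1]) * hi_rate, out)
        out = np.maximum(out, 0.0)
        return float(out) if np.isscalar(bp) else out


def interpolate_cM(genetic_map: GeneticMap, chrom: str, bp) -> np.ndarray | float:
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return genetic_map.interpolate(chrom, bp)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_sample_metadata(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read the sample metadata TSV -> (sample->population, population->role)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "role"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    populations = dict(zip(meta["sample"], meta["population"]))
    roles: dict[str, str] = {}
    for pop, role in zip(meta["population"], meta["role"]):
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} for population {pop!r}")
        if roles.setdefault(pop, role) != role:
            raise ValueError(f"population {pop!r} assigned two different roles")
    return populations, roles


def read_genotypes(
    path: str | Path,
    metadata_path: str | Path,
    format: str | None = None,
) -> GenotypeMatrix:
    """Read genotypes (VCF or tabular dosage TSV) plus sample metadata.

    Multi-allelic and indel records are dropped with a logged warning count.
    Samples absent from the metadata raise an error.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "vcf" if (".vcf" in name) else "tsv"
    populations, roles = read_sample_metadata(metadata_path)
    if format == "vcf":
        gm = _read_vcf(path, populations, roles)
    elif format in ("tsv", "tabular"):
        gm = _read_dosage_tsv(path, populations, roles)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return gm


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 and ref != alts[0]


def _read_vcf(path: Path, populations, roles) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in populations]
    if unmapped:
        raise ValueError(f"VCF samples missing from metadata: {unmapped[:5]}")
    rows, dosages = [], []
    n_excluded = 0
    for var in vcf:
        if not _is_snp(var.REF, var.ALT):
            n_excluded += 1
            continue
        cm = var.INFO.get("CM")
        rows.append(
            (var.CHROM, var.POS, float(cm) if cm is not None else np.nan,
             var.REF, var.ALT[0])
        )
        # gt_types: 0=homref 1=het 2=unknown 3=homalt
        gt = var.gt_types
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dos.astype(np.int16))
    vcf.close()
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} non-biallelic-SNP records")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dos = (
        np.vstack(dosages) if dosages else np.empty((0, len(samples)), dtype=np.int16)
    )
    sites, dos = _sort_sites(sites, dos)
    return GenotypeMatrix(sites, dos, samples, populations, roles)


def _read_dosage_tsv(path: Path, populations, roles) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns[:5]) != SITE_COLUMNS:
        raise ValueError(f"dosage TSV must start with columns {SITE_COLUMNS}")
    samples = list(df.columns[5:])
    unmapped = [s for s in samples if s not in populations]
    if unmapped:
        raise ValueError(f"samples missing from metadata: {unmapped[:5]}")
    sites = df[SITE_COLUMNS].copy()
    block = df[samples].replace(".", MISSING).astype(np.int16).to_numpy()
    bad = ~np.isin(block, [0, 1, 2, MISSING])
    if bad.any():
        raise ValueError("dosage TSV contains values outside {0,1,2,.}")
    sites, block = _sort_sites(sites, block)
    return GenotypeMatrix(sites, block, samples, populations, roles)


def _sort_sites(sites: pd.DataFrame, dos: np.ndarray):
    order = np.lexsort((sites["bp"].to_numpy(), sites["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        sites = sites.iloc[order]
        dos = dos[order, :]
    return sites.reset_index(drop=True), dos


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------


def filter_sites(
    gm: GenotypeMatrix,
    max_missing_per_taxon: float = 0.10,
    require_polymorphic: bool = True,
) -> GenotypeMatrix:
    """Apply the chip-style site filters.

    Keeps sites that are polymorphic across the union of all samples (if
    requested) and have missingness strictly below ``max_missing_per_taxon``
    within each taxon separately.  Idempotent; preserves site order.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    for taxon in ("maize", "mexicana"):
        samples = gm.taxon_samples(taxon)
        if not samples:
            continue
        block = gm.dosages[:, gm.columns_for(samples)]
        miss = (block == MISSING).mean(axis=1)
        keep &= miss < max_missing_per_taxon
    if require_polymorphic:
        freq = dosage_allele_frequency(gm.dosages)
        poly = np.isfinite(freq) & (freq > 0) & (freq < 1)
        keep &= poly
    if not keep.any():
        raise ValueError(
            "no sites survive filtering; review max_missing_per_taxon "
            f"(={max_missing_per_taxon}) and polymorphism requirement"
        )
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_regions(regions: Iterable, path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open), sorted by (chrom, start).

    Accepts any objects exposing chrom/start/end plus optional name, score
    and direction attributes.
    """
    rows = []
    for r in regions:
        name = getattr(r, "name", None) or getattr(r, "method", ".")
        score = getattr(r, "mean_signal", getattr(r, "score", 0.0)) or 0.0
        strand = {"maize": "-", "mexicana": "+"}.get(getattr(r, "direction", ""), ".")
        rows.append((str(r.chrom), int(r.start), int(r.end), str(name),
                     float(score), strand))
    rows.sort(key=lambda t: (t[0], t[1], t[2]))
    seen: dict[tuple, int] = {}
    for chrom, start, end, name, _, _ in rows:
        if seen.get((chrom, start, end, name)):
            warnings.warn(f"duplicate region {name} {chrom}:{start}-{end}")
        seen[(chrom, start, end, name)] = 1
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in rows:
            fh.write("{}\t{}\t{}\t{}\t{:.6g}\t{}\n".format(*row))


def read_regions(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file written by :func:`write_regions`."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return df


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix in the tabular dosage dialect."""
    df = gm.sites.copy()
    block = gm.dosages.astype(object)
    block[gm.dosages == MISSING] = "."
    for j, s in enumerate(gm.individuals):
        df[s] = block[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal unphased VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i, row in gm.sites.iterrows():
            info = f"CM={row.cM:.6g}" if np.isfinite(row.cM) else "."
            gts = "\t".join(gt_code[int(d)] for d in gm.dosages[i])
            fh.write(
                f"{row.chrom}\t{row.bp}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


def write_sample_metadata(gm: GenotypeMatrix, path: str | Path) -> None:
    rows = [
        (s, gm.populations[s], gm.roles[gm.populations[s]]) for s in gm.individuals
    ]
    pd.DataFrame(rows, columns=["sample", "population", "role"]).to_csv(
        path, sep="\t", index=False
    )
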