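"""Phased haplotype container, VCF and genetic-map I/O.

The central object is :class:`HaplotypePanel`: a haplotype-by-site allele
matrix over biallelic SNPs, with two haplotypes per diploid sample.  Alleles
are coded 0 (reference), 1 (alternate) and ``MISSING`` (= -1) for a
haplotype-level missing allele (a *half-call* when only one side of a phased
genotype is observed).

VCF I/O goes through :mod:`pysam`.  Only phased, biallelic SNP records are
accepted; multiallelic records are skipped with a logged count, and an
unphased non-missing genotype is a format error.  Missing alleles are written
back as ``.`` inside a phased GT (``0|.`` / ``.|0``), which round-trips
exactly.

Genetic maps are whitespace-separated ``chrom  pos_bp  cM`` tables; physical
positions interpolate linearly between anchors and clamp beyond them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING: int = -1

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "Site",
    "HaplotypePanel",
    "GeneticMap",
    "VcfFormatError",
    "MapValidationError",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "read_population_labels",
]


class VcfFormatError(ValueError):
    """A VCF record violates the phased diploid biallelic-SNP contract."""


class MapValidationError(ValueError):
    """A genetic map violates monotonicity or has too few anchors."""


@dataclass
class Site:
    """One biallelic SNP: chromosome, 1-based position, alleles, optional cM."""

    chrom: str
    pos_bp: int
    ref_allele: str
    alt_allele: str
    cm: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-character SNP alleles are supported")


@dataclass
class HaplotypePanel:
    """Phased allele matrix: haplotypes x sites, two haplotypes per sample.

    Haplotype ``2*i`` and ``2*i + 1`` are the two phased sides of sample
    ``sample_ids[i]``.  Sites are ordered by chromosome (in order of first
    appearance) and strictly increasing position within each chromosome.
    """

    sites: list[Site]
    alleles: np.ndarray
    sample_ids: list[str]
    population_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x site matrix")
        if self.alleles.shape != (2 * len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"{len(self.sample_ids)} samples and {len(self.sites)} sites"
            )
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or MISSING")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos_bp <= last[s.chrom]:
                raise ValueError(
                    f"sites on chromosome {s.chrom} not strictly increasing at {s.pos_bp}"
                )
            last[s.chrom] = s.pos_bp

    # -- basic geometry -------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def haplotype_of(self, hap_index: int) -> tuple[str, int]:
        """Map a haplotype row index to ``(sample_id, side)`` with side 0/1."""
        return self.sample_ids[hap_index // 2], hap_index % 2

    def haplotype_index(self, sample_id: str, side: int) -> int:
        return 2 * self.sample_ids.index(sample_id) + side

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if not seen or seen[-1] != s.chrom:
                seen.append(s.chrom)
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        """Column slice of the allele matrix covering one chromosome."""
        idx = [i for i, s in enumerate(self.sites) if s.chrom == chrom]
        if not idx:
            raise KeyError(f"no sites on chromosome {chrom!r}")
        return slice(idx[0], idx[-1] + 1)

    def positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return np.array([s.pos_bp for s in self.sites[sl]], dtype=np.int64)

    # -- derived quantities ---------------------------------------------

    def alt_allele_frequency(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing alleles (NaN
        where no allele is observed)."""
        obs = self.alleles != MISSING
        n = obs.sum(axis=0)
        c = np.where(obs, self.alleles, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, c / np.maximum(n, 1), np.nan)

    def with_map(self, gmap: "GeneticMap") -> "HaplotypePanel":
        """Return a copy whose sites carry interpolated cM positions."""
        sites = [replace(s, cm=float(gmap.cm_at(s.chrom, s.pos_bp))) for s in self.sites]
        return HaplotypePanel(sites, self.alleles.copy(), list(self.sample_ids), dict(self.population_of))

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypePanel":
        rows: list[int] = []
        for sid in sample_ids:
            i = self.sample_ids.index(sid)
            rows += [2 * i, 2 * i + 1]
        return HaplotypePanel(
            [replace(s) for s in self.sites],
            self.alleles[rows],
            list(sample_ids),
            {sid: self.population_of[sid] for sid in sample_ids if sid in self.population_of},
        )

    def samples_in(self, population: str) -> list[str]:
        return [sid for sid in self.sample_ids if self.population_of.get(sid) == population]

    def equals(self, other: "HaplotypePanel") -> bool:
        """Equality on alleles, missingness, sample ids and site order."""
        return (
            self.sample_ids == other.sample_ids
            and len(self.sites) == len(other.sites)
            and all(
                a.chrom == b.chrom
                and a.pos_bp == b.pos_bp
                and a.ref_allele == b.ref_allele
                and a.alt_allele == b.alt_allele
                for a, b in zip(self.sites, other.sites)
            )
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class GeneticMap:
    """Per-chromosome anchors ``(pos_bp, cM)`` with linear interpolation.

    Anchors are strictly increasing in position and non-decreasing in cM.
    Queries before the first or after the last anchor clamp to the boundary
    value.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, cm) in self.anchors.items():
            pos = np.asarray(pos, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if pos.size < 2:
                raise MapValidationError(f"chromosome {chrom}: need >= 2 anchors")
            if np.any(np.diff(pos) <= 0):
                raise MapValidationError(f"chromosome {chrom}: positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise MapValidationError(f"chromosome {chrom}: cM not non-decreasing")
            clean[chrom] = (pos, cm)
        self.anchors = clean

    @classmethod
    def uniform(cls, chrom: str, length_bp: int, length_cm: float) -> "GeneticMap":
        """Constant-rate map over ``[1, length_bp]`` spanning ``length_cm``."""
        return cls({chrom: (np.array([1.0, float(length_bp)]), np.array([0.0, length_cm]))})

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray | float:
        pos, cm = self.anchors[chrom]
        return np.interp(pos_bp, pos, cm)

    def bp_at(self, chrom: str, cm_query) -> np.ndarray | float:
        """Inverse interpolation, cM -> bp (clamped; flat cM stretches map to
        their left edge)."""
        pos, cm = self.anchors[chrom]
        return np.interp(cm_query, cm, pos)

    def length_cm(self, chrom: str) -> float:
        pos, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])


def interpolate_cm(gmap: GeneticMap, chrom: str, pos_bp) -> np.ndarray | float:
    """Functional alias for :meth:`GeneticMap.cm_at`."""
    return gmap.cm_at(chrom, pos_bp)


# ---------------------------------------------------------------------------
# VCF I/O


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Retains biallelic SNP records only; multiallelic or non-SNP records are
    skipped and counted (``panel.n_skipped_records``, also logged).  Every
    retained genotype must be diploid and phased, except fully missing
    genotypes (``./.`` or ``.|.``) which carry no phase information.
    """
    sites: list[Site] = []
    columns: list[np.ndarray] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise VcfFormatError("VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            col = np.empty(2 * len(samples), dtype=np.int8)
            for i, sid in enumerate(samples):
                call = rec.samples[sid]
                gt = call.get("GT")
                if gt is None or len(gt) != 2:
                    raise VcfFormatError(
                        f"{rec.chrom}:{rec.pos} sample {sid}: genotype is not diploid"
                    )
                if not call.phased and any(a is not None for a in gt):
                    raise VcfFormatError(
                        f"{rec.chrom}:{rec.pos} sample {sid}: unphased genotype"
                    )
                for side in (0, 1):
                    col[2 * i + side] = MISSING if gt[side] is None else gt[side]
            sites.append(Site(rec.chrom, rec.pos, rec.ref, alts[0]))
            columns.append(col)
    if skipped:
        logger.info("read_phased_vcf(%s): skipped %d non-biallelic-SNP records", path, skipped)
    alleles = (
        np.stack(columns, axis=1) if columns else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    panel = HaplotypePanel(sites, alleles, samples)
    panel.n_skipped_records = skipped  # type: ignore[attr-defined]
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel as a VCF 4.2 with phased GTs, ``.`` for missing alleles."""
    header = pysam.VariantHeader()
    maxpos: dict[str, int] = {}
    for s in panel.sites:
        maxpos[s.chrom] = max(maxpos.get(s.chrom, 0), s.pos_bp)
    for chrom, mp in maxpos.items():
        header.add_line(f"##contig=<ID={chrom},length={mp + 1}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for sid in panel.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, site in enumerate(panel.sites):
            rec = vf.new_record(
                contig=site.chrom,
                start=site.pos_bp - 1,
                stop=site.pos_bp,
                alleles=(site.ref_allele, site.alt_allele),
            )
            for i, sid in enumerate(panel.sample_ids):
                a0 = int(panel.alleles[2 * i, j])
                a1 = int(panel.alleles[2 * i + 1, j])
                rec.samples[sid]["GT"] = (
                    None if a0 == MISSING else a0,
                    None if a1 == MISSING else a1,
                )
                rec.samples[sid].phased = True
            vf.write(rec)


# ---------------------------------------------------------------------------
# Genetic map and population labels


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a ``chrom pos_bp cM`` whitespace-separated table (extra columns
    ignored; a non-numeric first row is treated as a header)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise MapValidationError("genetic map needs >= 3 columns: chrom pos_bp cM")
    first = df.iloc[0, 1]
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby(0, sort=False):
        anchors[str(chrom)] = (
            grp[1].astype(np.float64).to_numpy(),
            grp[2].astype(np.float64).to_numpy(),
        )
    return GeneticMap(anchors)


def read_population_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id  population`` -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("population labels need 2 columns: sample_id, population")
    return dict(zip(df[0], df[1]))
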