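"""Greedy "jigsaw" reconstruction of full-ancestry chromosomes.

Target-ancestry fragments harvested from many admixed haplotypes are tiled,
without breaking or overlapping them and using each fragment only once, into
*rearranged chromosomes* of full target ancestry:

1. Fragments of one autosome are sorted by start position; fragments sharing
   a start position are ordered uniformly at random (this tie shuffle is the
   only randomness of a tiling iteration).
2. A single left-to-right pass places a fragment whenever its start is
   strictly greater than the end of the last placed fragment; placed
   fragments are consumed.  Stretches between placements (and before the
   first or after the last) are gaps, treated as missing sequence.
3. Passes repeat on the remaining pool until it is empty.  A rearranged
   chromosome is retained when its covered fraction of the chromosome span
   reaches a threshold (default 95% of base pairs).
4. The whole process runs for a number of independent iterations (default
   100); the best iteration is the one yielding the most chromosomes above
   the coverage threshold, ties broken by lowest iteration index.
5. Across autosomes, the autosome with the fewest retained chromosomes sets
   the population's chromosome count; half that number (rounded down) of
   diploid individuals is assembled by pairing randomly shuffled retained
   chromosomes.

Reconstructed genotypes are materialized by copying each placed fragment's
alleles from its source haplotype; sites inside gaps are missing.  Because
fragments are never broken, haplotype structure within a fragment is
preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .local_ancestry import Fragment
from .panel import MISSING, HaplotypePanel

__all__ = [
    "ChromSpan",
    "RearrangedChromosome",
    "IterationResult",
    "ReconstructedIndividual",
    "NoReconstructionPossibleError",
    "sort_pool",
    "tile_once",
    "rearrange_iteration",
    "best_iteration",
    "assemble_population",
    "materialize_genotypes",
    "materialize_population",
    "ReconstructionOutput",
    "reconstruct_population",
    "source_overlap",
    "write_gap_bed",
    "write_provenance",
    "write_iteration_report",
]


class NoReconstructionPossibleError(RuntimeError):
    """Raised when the retained-chromosome counts admit zero individuals."""


@dataclass(frozen=True)
class ChromSpan:
    """1-based inclusive span used as the coverage denominator."""

    chrom: str
    first_bp: int
    last_bp: int

    def __post_init__(self) -> None:
        if self.first_bp > self.last_bp:
            raise ValueError("ChromSpan: first_bp > last_bp")

    @property
    def length_bp(self) -> int:
        return self.last_bp - self.first_bp + 1

    @classmethod
    def from_panel(cls, panel: HaplotypePanel, chrom: str) -> "ChromSpan":
        pos = panel.positions(chrom)
        return cls(chrom, int(pos[0]), int(pos[-1]))


@dataclass
class RearrangedChromosome:
    """An ordered non-overlapping placement of fragments on one span."""

    span: ChromSpan
    placements: list[Fragment]
    gaps: list[tuple[int, int]]
    coverage: float
    retained: bool = False

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def covered_bp(self) -> int:
        return sum(f.length_bp for f in self.placements)


@dataclass
class IterationResult:
    """All rearranged chromosomes of one tiling iteration of one autosome."""

    iteration_index: int
    seed: int
    chromosomes: list[RearrangedChromosome]
    n_above_threshold: int

    @property
    def retained(self) -> list[RearrangedChromosome]:
        return [c for c in self.chromosomes if c.retained]


@dataclass
class ReconstructedIndividual:
    """One diploid reconstructed individual: a chromosome pair per autosome."""

    individual_id: str
    chromosome_pairs: dict[str, tuple[RearrangedChromosome, RearrangedChromosome]]

    def provenance(self) -> list[tuple[str, int, Fragment]]:
        """(autosome, haplotype side, fragment) for every placement."""
        out = []
        for chrom, pair in self.chromosome_pairs.items():
            for side, rc in enumerate(pair):
                for frag in rc.placements:
                    out.append((chrom, side, frag))
        return out


# ---------------------------------------------------------------------------
# tiling


def sort_pool(fragments: Sequence[Fragment], rng: np.random.Generator) -> list[Fragment]:
    """Order fragments by ascending start; ties permuted uniformly at random."""
    chroms = {f.chrom for f in fragments}
    if len(chroms) > 1:
        raise ValueError(f"sort_pool: fragments from multiple chromosomes {sorted(chroms)}")
    by_start: dict[int, list[Fragment]] = {}
    for f in fragments:
        by_start.setdefault(f.start_bp, []).append(f)
    pool: list[Fragment] = []
    for start in sorted(by_start):
        group = by_start[start]
        if len(group) > 1:
            group = [group[i] for i in rng.permutation(len(group))]
        pool.extend(group)
    return pool


def _gaps_for(placements: Sequence[Fragment], span: ChromSpan) -> list[tuple[int, int]]:
    gaps: list[tuple[int, int]] = []
    cursor = span.first_bp
    for f in placements:
        if f.start_bp > cursor:
            gaps.append((cursor, f.start_bp - 1))
        cursor = f.end_bp + 1
    if cursor <= span.last_bp:
        gaps.append((cursor, span.last_bp))
    return gaps


def tile_once(
    pool: Sequence[Fragment], span: ChromSpan
) -> tuple[RearrangedChromosome, list[Fragment]]:
    """One left-to-right greedy pass over an ordered pool.

    The first fragment is always placed; each subsequent fragment is placed
    iff its start is strictly greater than the end of the last placed
    fragment.  Returns the rearranged chromosome and the remaining pool (in
    order).  Gaps include any uncovered stretch of the span.
    """
    if not pool:
        raise ValueError("tile_once: empty pool")
    placements: list[Fragment] = []
    remaining: list[Fragment] = []
    last_end = None
    for frag in pool:
        if last_end is None or frag.start_bp > last_end:
            placements.append(frag)
            last_end = frag.end_bp
        else:
            remaining.append(frag)
    covered = sum(f.length_bp for f in placements)
    rc = RearrangedChromosome(
        span=span,
        placements=placements,
        gaps=_gaps_for(placements, span),
        coverage=covered / span.length_bp,
    )
    return rc, remaining


def rearrange_iteration(
    fragments: Sequence[Fragment],
    span: ChromSpan,
    threshold: float = 0.95,
    rng: np.random.Generator | None = None,
    iteration_index: int = 0,
    seed: int = 0,
) -> IterationResult:
    """Sort the pool once, then tile repeatedly until the pool is empty.

    Chromosomes reaching the coverage threshold are flagged retained and
    counted; below-threshold chromosomes keep their fragments consumed (the
    procedure optimizes across iterations, not within one).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bad = [f for f in fragments if f.start_bp < span.first_bp or f.end_bp > span.last_bp]
    if bad:
        raise ValueError(f"{len(bad)} fragments fall outside span {span}")
    pool = sort_pool(fragments, rng)
    chromosomes: list[RearrangedChromosome] = []
    while pool:
        rc, pool = tile_once(pool, span)
        rc.retained = rc.coverage >= threshold
        chromosomes.append(rc)
    n_above = sum(c.retained for c in chromosomes)
    return IterationResult(iteration_index, seed, chromosomes, n_above)


def best_iteration(
    fragments: Sequence[Fragment],
    span: ChromSpan,
    threshold: float = 0.95,
    n_iter: int = 100,
    master_seed: int = 0,
) -> IterationResult:
    """Run ``n_iter`` independent tiling iterations and return the one with
    the most retained chromosomes (ties: lowest iteration index).

    Per-iteration generators derive deterministically from ``master_seed``
    and the iteration index, so the result is bit-reproducible.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    best: IterationResult | None = None
    for it in range(n_iter):
        rng = derive_rng(master_seed, "jigsaw-iteration", it)
        res = rearrange_iteration(
            fragments, span, threshold, rng=rng, iteration_index=it, seed=master_seed
        )
        if best is None or res.n_above_threshold > best.n_above_threshold:
            best = res
    assert best is not None
    return best


def iteration_counts(
    fragments: Sequence[Fragment],
    span: ChromSpan,
    threshold: float = 0.95,
    n_iter: int = 100,
    master_seed: int = 0,
) -> list[int]:
    """Retained-chromosome count of every iteration (for reporting)."""
    counts = []
    for it in range(n_iter):
        rng = derive_rng(master_seed, "jigsaw-iteration", it)
        counts.append(
            rearrange_iteration(fragments, span, threshold, rng=rng, iteration_index=it).n_above_threshold
        )
    return counts


# ---------------------------------------------------------------------------
# diploid assembly


def assemble_population(
    per_autosome: Mapping[str, IterationResult],
    rng: np.random.Generator,
    id_prefix: str = "RECON",
) -> list[ReconstructedIndividual]:
    """Pair retained chromosomes into diploid reconstructed individuals.

    The autosome with the fewest retained chromosomes sets the population's
    chromosome count N; the number of individuals is floor(N / 2).  Per
    autosome, retained chromosomes are shuffled and consecutive pairs become
    one individual's pair; unpaired excess is discarded.
    """
    if not per_autosome:
        raise ValueError("assemble_population: no autosomes")
    n_chrom = min(res.n_above_threshold for res in per_autosome.values())
    n_ind = n_chrom // 2
    if n_ind == 0:
        worst = min(per_autosome, key=lambda c: per_autosome[c].n_above_threshold)
        raise NoReconstructionPossibleError(
            f"no reconstruction possible: autosome {worst} retained "
            f"{per_autosome[worst].n_above_threshold} chromosome(s)"
        )
    pairs_per_autosome: dict[str, list[tuple[RearrangedChromosome, RearrangedChromosome]]] = {}
    for chrom in sorted(per_autosome):
        retained = list(per_autosome[chrom].retained)
        order = rng.permutation(len(retained))
        chosen = [retained[i] for i in order[: 2 * n_ind]]
        pairs_per_autosome[chrom] = [(chosen[2 * i], chosen[2 * i + 1]) for i in range(n_ind)]
    return [
        ReconstructedIndividual(
            individual_id=f"{id_prefix}{i:04d}",
            chromosome_pairs={c: pairs_per_autosome[c][i] for c in pairs_per_autosome},
        )
        for i in range(n_ind)
    ]


@dataclass
class ReconstructionOutput:
    """Result of a full reconstruction run on one fragment pool."""

    individuals: list[ReconstructedIndividual]
    panel: HaplotypePanel
    per_autosome: dict[str, IterationResult]


def reconstruct_population(
    fragments: Sequence[Fragment],
    source_panel: HaplotypePanel,
    spans: Mapping[str, ChromSpan] | None = None,
    threshold: float = 0.95,
    n_iter: int = 100,
    master_seed: int = 0,
    population: str = "RECONSTRUCTED",
    id_prefix: str = "RECON",
) -> ReconstructionOutput:
    """Full reconstruction: per-autosome best iteration, diploid assembly and
    genotype materialization.

    ``spans`` overrides the per-chromosome coverage denominator; by default
    each chromosome spans its first to last panel site.
    """
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    per_autosome: dict[str, IterationResult] = {}
    for chrom in sorted(by_chrom):
        span = spans[chrom] if spans else ChromSpan.from_panel(source_panel, chrom)
        per_autosome[chrom] = best_iteration(
            by_chrom[chrom], span, threshold=threshold, n_iter=n_iter, master_seed=master_seed
        )
    individuals = assemble_population(
        per_autosome, derive_rng(master_seed, "assembly", population), id_prefix=id_prefix
    )
    panel = materialize_population(individuals, source_panel, population=population)
    return ReconstructionOutput(individuals, panel, per_autosome)


# ---------------------------------------------------------------------------
# genotype materialization


def materialize_genotypes(
    individual: ReconstructedIndividual, source_panel: HaplotypePanel
) -> np.ndarray:
    """Allele rows (2 x n_sites) for one reconstructed individual.

    Inside each placement the reconstructed haplotype copies the source
    haplotype's alleles site for site; sites inside gaps are MISSING.
    """
    out = np.full((2, source_panel.n_sites), MISSING, dtype=np.int8)
    for chrom, pair in individual.chromosome_pairs.items():
        sl = source_panel.chrom_slice(chrom)
        pos = source_panel.positions(chrom)
        for side, rc in enumerate(pair):
            for frag in rc.placements:
                lo = int(np.searchsorted(pos, frag.start_bp, side="left"))
                hi = int(np.searchsorted(pos, frag.end_bp, side="right"))
                if hi == lo:
                    continue  # span holds no panel sites; downstream sees a gap
                src = source_panel.haplotype_index(frag.source_sample, frag.source_side)
                cols = slice(sl.start + lo, sl.start + hi)
                out[side, cols] = source_panel.alleles[src, cols]
    return out


def materialize_population(
    individuals: Sequence[ReconstructedIndividual],
    source_panel: HaplotypePanel,
    population: str = "RECONSTRUCTED",
) -> HaplotypePanel:
    """Panel of all reconstructed individuals over the source panel's sites."""
    rows = [materialize_genotypes(ind, source_panel) for ind in individuals]
    alleles = (
        np.concatenate(rows, axis=0)
        if rows
        else np.empty((0, source_panel.n_sites), dtype=np.int8)
    )
    ids = [ind.individual_id for ind in individuals]
    return HaplotypePanel(
        [s for s in source_panel.sites],
        alleles,
        ids,
        {i: population for i in ids},
    )


# ---------------------------------------------------------------------------
# provenance diagnostics


def _source_intervals(
    individual: ReconstructedIndividual, side: int | None = None
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """(chrom, source_sample) -> merged placement intervals (one or both sides)."""
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, pair in individual.chromosome_pairs.items():
        sides = [pair[side]] if side is not None else list(pair)
        for rc in sides:
            for f in rc.placements:
                raw.setdefault((chrom, f.source_sample), []).append((f.start_bp, f.end_bp))
    merged: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for key, ivs in raw.items():
        ivs.sort()
        acc = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= acc[-1][1] + 1:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[key] = [(s, e) for s, e in acc]
    return merged


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def source_overlap(individuals: Sequence[ReconstructedIndividual]) -> np.ndarray:
    """Pairwise shared-source fraction matrix.

    Entry (i, j), i != j, is the fraction of total span base pairs where
    individuals i and j both carry fragments drawn from the same admixed
    source sample.  The diagonal applies the same measure between an
    individual's own two haplotypes.  This quantifies the kinship-like
    artifact of one real individual's sequence being split across several
    reconstructed individuals.
    """
    if len(individuals) < 2:
        raise ValueError("source_overlap needs >= 2 individuals")
    total_span = sum(
        pair[0].span.length_bp for pair in individuals[0].chromosome_pairs.values()
    )
    both = [_source_intervals(ind) for ind in individuals]
    n = len(individuals)
    mat = np.zeros((n, n))
    for i in range(n):
        h0 = _source_intervals(individuals[i], side=0)
        h1 = _source_intervals(individuals[i], side=1)
        shared = sum(
            _overlap_bp(h0[k], h1[k]) for k in set(h0) & set(h1)
        )
        mat[i, i] = shared / total_span
        for j in range(i + 1, n):
            shared = sum(
                _overlap_bp(both[i][k], both[j][k]) for k in set(both[i]) & set(both[j])
            )
            mat[i, j] = mat[j, i] = shared / total_span
    return mat


# ---------------------------------------------------------------------------
# report / provenance output


def write_gap_bed(individuals: Sequence[ReconstructedIndividual], path: str | Path) -> None:
    """Per-haplotype gaps as standard BED (0-based half-open)."""
    rows = []
    for ind in individuals:
        for chrom, pair in ind.chromosome_pairs.items():
            for side, rc in enumerate(pair):
                for start, end in rc.gaps:
                    rows.append((chrom, start - 1, end, f"{ind.individual_id}.h{side}"))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_provenance(individuals: Sequence[ReconstructedIndividual], path: str | Path) -> None:
    rows = []
    for ind in individuals:
        for chrom, side, frag in ind.provenance():
            rows.append(
                (
                    ind.individual_id,
                    chrom,
                    side,
                    frag.id,
                    frag.source_sample,
                    frag.source_side,
                    frag.start_bp,
                    frag.end_bp,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "individual",
            "autosome",
            "haplotype_side",
            "fragment_id",
            "source_sample",
            "source_side",
            "start_bp",
            "end_bp",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_iteration_report(
    counts_per_autosome: Mapping[str, Sequence[int]], path: str | Path
) -> None:
    rows = [
        (chrom, it, n)
        for chrom in sorted(counts_per_autosome)
        for it, n in enumerate(counts_per_autosome[chrom])
    ]
    pd.DataFrame(rows, columns=["autosome", "iteration", "n_above_threshold"]).to_csv(
        path, sep="\t", index=False
    )
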