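"""Synthetic admixed cohorts with known ancestry truth.

Real cohorts of this kind (urban admixed populations carrying a low
proportion of a vanished ancestry) are restricted-access, so every pipeline
stage is exercised against simulations with recorded ground truth:

* **Source panels** — differentiated ancestral populations are drawn under
  the Balding–Nichols model: each site has a base frequency ``p`` uniform on
  (0.05, 0.95), and each source's frequency is Beta-distributed around ``p``
  with spread set by its FST to the base.  Panel haplotypes are independent
  Bernoulli draws per site.

* **Admixed haplotypes** — a single admixture pulse ``G`` generations ago is
  approximated by the standard Markov tract model: ancestry switch points
  fall as a Poisson process of rate ``G`` per Morgan along the genetic map,
  and the ancestry of the leftmost tract and after every switch is an
  independent draw from the deme's admixture vector ``alpha``.  Within a
  tract, alleles are copied from one uniformly chosen donor haplotype of
  that source's panel.  A switch that redraws the same ancestry is invisible;
  the expected number of *visible* ancestry changes per haplotype is
  ``G * L * (1 - sum(alpha^2))`` for map length ``L`` Morgans.

* **Window calls** — ground-truth tracts are converted to the per-window
  posterior format a local-ancestry tool would emit: windows tile the map at
  a fixed cM width (default 0.2 cM) and each window's posterior mass sits on
  its majority-bp true ancestry.  A symmetric noise rate ``epsilon`` and a
  contamination knob (mislabeling non-target windows as target) support
  robustness and positive-control tests.

Two source populations may share one *ancestry label* (e.g. two
differentiated tribes both counted as the target continental ancestry);
local-ancestry calls then see only the shared label, while the truth retains
the source split — the basis of the differential-ancestry scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rng import derive_rng
from .local_ancestry import WindowCall
from .panel import GeneticMap, HaplotypePanel, Site

__all__ = [
    "SourcePop",
    "Deme",
    "SimConfig",
    "TruthTract",
    "TruthSegments",
    "simulate_source_panels",
    "simulate_admixed_cohort",
    "truth_to_window_calls",
    "count_visible_switches",
    "ancestry_fraction",
    "scenario_differential",
    "DifferentialFixture",
    "hudson_fst",
]


@dataclass(frozen=True)
class SourcePop:
    """An ancestral source population: label, FST to the base, panel size
    (haplotypes), and the ancestry label local-ancestry calls report for it
    (defaults to the population label itself)."""

    label: str
    fst: float
    n_haplotypes: int
    ancestry: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("FST must lie in (0, 1)")

    @property
    def ancestry_label(self) -> str:
        return self.ancestry if self.ancestry is not None else self.label


@dataclass(frozen=True)
class Deme:
    """One admixed deme: admixture vector over source labels, diploid count."""

    name: str
    alpha: Mapping[str, float]
    n_admixed: int

    def __post_init__(self) -> None:
        vals = np.array(list(self.alpha.values()), dtype=float)
        if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"deme {self.name}: alpha must be >= 0 and sum to 1")


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    Defaults are the desk-scale study conditions: one chromosome of 1 Morgan
    with 2,000 SNPs, an admixture pulse G = 20 generations ago, and three
    continental-scale sources.
    """

    sources: list[SourcePop]
    demes: list[Deme]
    chrom: str = "1"
    n_sites: int = 2000
    chrom_length_bp: int = 100_000_000
    length_cm: float = 100.0
    generations: int = 20
    master_seed: int = 0
    gmap: GeneticMap | None = None

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        labels = {s.label for s in self.sources}
        for d in self.demes:
            unknown = set(d.alpha) - labels
            if unknown:
                raise ValueError(f"deme {d.name}: alpha refers to unknown sources {unknown}")
        if self.gmap is None:
            self.gmap = GeneticMap.uniform(self.chrom, self.chrom_length_bp, self.length_cm)

    @property
    def ancestry_of(self) -> dict[str, str]:
        return {s.label: s.ancestry_label for s in self.sources}

    @property
    def ancestry_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.sources:
            if s.ancestry_label not in seen:
                seen.append(s.ancestry_label)
        return seen

    def site_positions(self) -> np.ndarray:
        pos = np.unique(np.linspace(1, self.chrom_length_bp, self.n_sites).round().astype(np.int64))
        return pos


@dataclass(frozen=True)
class TruthTract:
    """One ground-truth ancestry tract on one admixed haplotype."""

    start_bp: int
    end_bp: int
    source: str
    donor_haplotype: int


@dataclass
class TruthSegments:
    """Ground-truth tracts per admixed haplotype (keyed by haplotype row)."""

    chrom: str
    span_bp: tuple[int, int]
    tracts: dict[int, list[TruthTract]]

    def validate(self) -> None:
        lo, hi = self.span_bp
        for hap, trs in self.tracts.items():
            if not trs or trs[0].start_bp != lo or trs[-1].end_bp != hi:
                raise ValueError(f"haplotype {hap}: tracts do not span the chromosome")
            for t in trs:
                if t.end_bp < t.start_bp:
                    raise ValueError(f"haplotype {hap}: zero-length tract")
            for a, b in zip(trs, trs[1:]):
                if b.start_bp != a.end_bp + 1:
                    raise ValueError(f"haplotype {hap}: tracts do not partition the span")


# ---------------------------------------------------------------------------
# source panels


def simulate_source_panels(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, HaplotypePanel], np.ndarray]:
    """Balding–Nichols source panels and the shared base frequencies."""
    if rng is None:
        rng = derive_rng(config.master_seed, "source-panels")
    pos = config.site_positions()
    base = rng.uniform(0.05, 0.95, size=pos.size)
    cms = np.asarray(config.gmap.cm_at(config.chrom, pos), dtype=float)
    panels: dict[str, HaplotypePanel] = {}
    for src in config.sources:
        f = src.fst
        a = base * (1 - f) / f
        b = (1 - base) * (1 - f) / f
        freqs = rng.beta(a, b)
        alleles = (rng.random((src.n_haplotypes, pos.size)) < freqs).astype(np.int8)
        n_dip = src.n_haplotypes // 2
        if src.n_haplotypes % 2:
            raise ValueError(f"source {src.label}: panel size must be an even haplotype count")
        ids = [f"{src.label}{i:03d}" for i in range(n_dip)]
        sites = [Site(config.chrom, int(p), "A", "G", cm=float(c)) for p, c in zip(pos, cms)]
        panels[src.label] = HaplotypePanel(
            sites, alleles, ids, {i: src.label for i in ids}
        )
    return panels, base


# ---------------------------------------------------------------------------
# admixed cohort


def _draw_tracts(
    config: SimConfig,
    alpha_labels: list[str],
    alpha_probs: np.ndarray,
    panels: Mapping[str, HaplotypePanel],
    rng: np.random.Generator,
) -> list[TruthTract]:
    """One haplotype's tract mosaic: Poisson switch points at rate G per
    Morgan, ancestry redrawn from alpha at the left end and after each
    switch, donor haplotype uniform within the source panel."""
    L_morgan = config.length_cm / 100.0
    n_switch = rng.poisson(config.generations * L_morgan)
    cuts_cm = np.sort(rng.uniform(0.0, config.length_cm, size=n_switch))
    bounds_bp = np.asarray(config.gmap.bp_at(config.chrom, cuts_cm)).round().astype(np.int64)
    span_lo, span_hi = 1, config.chrom_length_bp
    edges = [span_lo - 1]
    for b in bounds_bp:
        if span_lo - 1 < b < span_hi:
            edges.append(int(b))
    edges.append(span_hi)
    # collapse duplicate cut points (zero-length tracts)
    edges = sorted(set(edges))
    tracts: list[TruthTract] = []
    for lo, hi in zip(edges, edges[1:]):
        label = alpha_labels[rng.choice(len(alpha_labels), p=alpha_probs)]
        donor = int(rng.integers(panels[label].n_haplotypes))
        tracts.append(TruthTract(lo + 1, hi, label, donor))
    return tracts


def simulate_admixed_cohort(
    panels: Mapping[str, HaplotypePanel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypePanel, TruthSegments]:
    """Mosaic admixed haplotypes for every deme, with recorded truth."""
    if rng is None:
        rng = derive_rng(config.master_seed, "admixed-cohort")
    ref = next(iter(panels.values()))
    pos = ref.positions(config.chrom)
    sample_ids: list[str] = []
    population_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    tracts: dict[int, list[TruthTract]] = {}
    hap = 0
    for deme in config.demes:
        labels = sorted(deme.alpha)
        probs = np.array([deme.alpha[l] for l in labels], dtype=float)
        for i in range(deme.n_admixed):
            sid = f"{deme.name}{i:04d}"
            sample_ids.append(sid)
            population_of[sid] = deme.name
            for _side in (0, 1):
                trs = _draw_tracts(config, labels, probs, panels, rng)
                row = np.empty(pos.size, dtype=np.int8)
                for t in trs:
                    lo = np.searchsorted(pos, t.start_bp, side="left")
                    hi = np.searchsorted(pos, t.end_bp, side="right")
                    row[lo:hi] = panels[t.source].alleles[t.donor_haplotype, lo:hi]
                rows.append(row)
                tracts[hap] = trs
                hap += 1
    sites = [Site(s.chrom, s.pos_bp, s.ref_allele, s.alt_allele, cm=s.cm) for s in ref.sites]
    cohort = HaplotypePanel(sites, np.stack(rows), sample_ids, population_of)
    truth = TruthSegments(config.chrom, (1, config.chrom_length_bp), tracts)
    return cohort, truth


def count_visible_switches(truth: TruthSegments, ancestry_of: Mapping[str, str]) -> np.ndarray:
    """Per haplotype, the number of adjacent tract pairs whose ancestry
    labels differ (same-ancestry redraws are invisible)."""
    out = []
    for hap in sorted(truth.tracts):
        trs = truth.tracts[hap]
        labs = [ancestry_of[t.source] for t in trs]
        out.append(sum(a != b for a, b in zip(labs, labs[1:])))
    return np.array(out)


def ancestry_fraction(truth: TruthSegments, ancestry_of: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Per haplotype, bp fraction of the chromosome in each ancestry."""
    lo, hi = truth.span_bp
    total = hi - lo + 1
    labels = sorted(set(ancestry_of.values()))
    fracs = {lab: [] for lab in labels}
    for hap in sorted(truth.tracts):
        counts = {lab: 0 for lab in labels}
        for t in truth.tracts[hap]:
            counts[ancestry_of[t.source]] += t.end_bp - t.start_bp + 1
        for lab in labels:
            fracs[lab].append(counts[lab] / total)
    return {lab: np.array(v) for lab, v in fracs.items()}


def source_fraction_within(
    truth: TruthSegments, ancestry_of: Mapping[str, str], ancestry: str
) -> dict[str, np.ndarray]:
    """Per haplotype, each source's share of the bp belonging to one
    ancestry label (NaN where the haplotype carries none of it)."""
    sources = sorted(l for l, a in ancestry_of.items() if a == ancestry)
    shares: dict[str, list[float]] = {s: [] for s in sources}
    for hap in sorted(truth.tracts):
        counts = {s: 0 for s in sources}
        for t in truth.tracts[hap]:
            if ancestry_of[t.source] == ancestry:
                counts[t.source] += t.end_bp - t.start_bp + 1
        tot = sum(counts.values())
        for s in sources:
            shares[s].append(counts[s] / tot if tot else np.nan)
    return {s: np.array(v) for s, v in shares.items()}


# ---------------------------------------------------------------------------
# truth -> window calls


def truth_to_window_calls(
    truth: TruthSegments,
    cohort: HaplotypePanel,
    config: SimConfig,
    window_cm: float = 0.2,
    epsilon: float = 0.0,
    mislabel_as: str | None = None,
    mislabel_rate: float = 0.0,
    mislabel_from: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[WindowCall]:
    """Emulate local-ancestry output from ground truth.

    Windows tile the map at ``window_cm``; each window's posterior mass sits
    on its majority-bp true ancestry.  With ``epsilon`` > 0 the mass becomes
    1 - epsilon on the truth and epsilon split over the other labels.  With
    ``mislabel_rate`` > 0, a window whose truth is *not* ``mislabel_as``
    (restricted to truth ``mislabel_from`` when given) swaps its posterior
    onto ``mislabel_as`` with that probability — a contamination positive
    control that injects one specific foreign ancestry.
    """
    if rng is None:
        rng = derive_rng(config.master_seed, "window-calls")
    labels = config.ancestry_labels
    ancestry_of = config.ancestry_of
    lo, hi = truth.span_bp
    cm_edges = np.arange(0.0, config.length_cm, window_cm)
    cm_edges = np.append(cm_edges, config.length_cm)
    bp_inner = np.asarray(config.gmap.bp_at(config.chrom, cm_edges[1:-1])).round().astype(np.int64)
    edges = [lo - 1] + [int(b) for b in bp_inner if lo - 1 < b < hi] + [hi]
    edges = sorted(set(edges))
    windows = [(a + 1, b) for a, b in zip(edges, edges[1:])]
    calls: list[WindowCall] = []
    n_others = max(len(labels) - 1, 1)
    for hap in sorted(truth.tracts):
        sid, side = cohort.haplotype_of(hap)
        trs = truth.tracts[hap]
        ti = 0
        for wlo, whi in windows:
            cover: dict[str, int] = {}
            while ti > 0 and trs[ti].start_bp > wlo:
                ti -= 1
            j = ti
            while j < len(trs) and trs[j].start_bp <= whi:
                ov = min(trs[j].end_bp, whi) - max(trs[j].start_bp, wlo) + 1
                if ov > 0:
                    lab = ancestry_of[trs[j].source]
                    cover[lab] = cover.get(lab, 0) + ov
                if trs[j].end_bp >= whi:
                    break
                j += 1
            ti = j
            # majority-bp ancestry; ties broken by label order for determinism
            best = max(cover.items(), key=lambda kv: (kv[1], -labels.index(kv[0])))[0]
            if (
                mislabel_as is not None
                and best != mislabel_as
                and (mislabel_from is None or best == mislabel_from)
                and mislabel_rate > 0.0
                and rng.random() < mislabel_rate
            ):
                best = mislabel_as
            post = {
                lab: (1.0 - epsilon) if lab == best else epsilon / n_others for lab in labels
            }
            calls.append(WindowCall(truth.chrom, wlo, whi, sid, side, post))
    return calls


# ---------------------------------------------------------------------------
# differential-ancestry scenario


@dataclass
class DifferentialFixture:
    """Everything the differential-ancestry end-to-end check needs."""

    config: SimConfig
    source_panels: dict[str, HaplotypePanel]
    cohort: HaplotypePanel
    truth: TruthSegments
    window_calls: list[WindowCall]
    target_ancestry: str
    target_sources: tuple[str, str]
    deme_share: dict[str, dict[str, float]]
    expected_direction: str


def scenario_differential(
    n_admixed_per_deme: int = 240,
    target_total: float = 0.3,
    share_high: float = 0.8,
    symmetric_null: bool = False,
    n_sites: int = 2000,
    panel_haplotypes: int = 40,
    master_seed: int = 0,
) -> DifferentialFixture:
    """Two demes drawing their target ancestry asymmetrically from two
    differentiated target sources (J and T), plus two distractor sources.

    Deme A takes its target ancestry ``share_high``/``1 - share_high`` from
    (J, T); deme B the reverse — so donor-sharing comparisons should find
    deme A receiving more from J and deme B more from T.  With
    ``symmetric_null`` both demes draw 50/50 and no difference is expected.
    """
    sj = share_high if not symmetric_null else 0.5
    share = {"demeA": {"J": sj, "T": 1 - sj}, "demeB": {"J": 1 - sj, "T": sj}}
    rest = 1.0 - target_total
    demes = [
        Deme(
            name,
            {
                "J": target_total * share[name]["J"],
                "T": target_total * share[name]["T"],
                "EUR": rest * 0.6,
                "AFR": rest * 0.4,
            },
            n_admixed_per_deme,
        )
        for name in ("demeA", "demeB")
    ]
    config = SimConfig(
        sources=[
            SourcePop("J", 0.10, panel_haplotypes, ancestry="NAT"),
            SourcePop("T", 0.15, panel_haplotypes, ancestry="NAT"),
            SourcePop("EUR", 0.05, panel_haplotypes),
            SourcePop("AFR", 0.05, panel_haplotypes),
        ],
        demes=demes,
        n_sites=n_sites,
        master_seed=master_seed,
    )
    panels, _base = simulate_source_panels(config)
    cohort, truth = simulate_admixed_cohort(panels, config)
    calls = truth_to_window_calls(truth, cohort, config)
    direction = (
        "no difference expected (symmetric null)"
        if symmetric_null
        else "demeA receives more from J; demeB receives more from T"
    )
    return DifferentialFixture(
        config=config,
        source_panels=panels,
        cohort=cohort,
        truth=truth,
        window_calls=calls,
        target_ancestry="NAT",
        target_sources=("J", "T"),
        deme_share=share,
        expected_direction=direction,
    )


# ---------------------------------------------------------------------------
# calibration helper


def hudson_fst(panel_a: HaplotypePanel, panel_b: HaplotypePanel) -> float:
    """Hudson's FST estimator (ratio of averages) between two panels."""
    pa = panel_a.alt_allele_frequency()
    pb = panel_b.alt_allele_frequency()
    na = panel_a.n_haplotypes
    nb = panel_b.n_haplotypes
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return float(num[ok].sum() / den[ok].sum())
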