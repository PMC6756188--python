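"""Validation statistics for reconstructed populations.

* ``site_pi`` — per-site nucleotide diversity within a population, the
  unbiased pairwise-difference form ``pi = 2 c (n - c) / (n (n - 1))`` for
  ``n`` observed alleles of which ``c`` are alternate (identical to the
  per-site output of ``vcftools --site-pi``); missing alleles are excluded
  from ``n`` and sites with fewer than two observed alleles are skipped.

* ``f4`` / ``f3`` — allele-frequency f-statistics with a weighted
  leave-one-block-out jackknife over genetic-map blocks for standard errors:
  ``f4(A,B;C,D) = mean (pA - pB)(pC - pD)`` and
  ``f3(T;A,B) = mean (pT - pA)(pT - pB)``.  The headline use is the
  residual-ancestry check ``f4(reconstructed, target source; distractor1,
  distractor2)``: under clean reconstruction the reconstructed population is
  a clade with the target source and |Z| stays small, while contaminating
  ancestry drives |Z| up.

* ``window_painting`` — a deliberately simple haplotype-painting surrogate:
  recipient haplotypes are cut into windows of a fixed number of sites and
  each window is assigned to the donor population containing the
  minimum-mismatch haplotype (ties split equally), accumulating copied
  genetic length (cM) per recipient individual and donor.  It reproduces the
  rank/direction behaviour of chunklength comparisons without a full
  Li–Stephens copying model.

* ``differential_ancestry_test`` — per donor and per pair of recipient
  populations, a two-sided Wilcoxon rank-sum test on the copied-length
  distributions, Bonferroni-corrected over all donor x pair tests, with
  significance declared below a corrected-p cutoff (default 0.005).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import MISSING, HaplotypePanel

__all__ = [
    "FStatResult",
    "site_pi",
    "site_pi_table",
    "f4",
    "f3",
    "window_painting",
    "differential_ancestry_test",
    "residual_ancestry_check",
]


@dataclass(frozen=True)
class FStatResult:
    """An f-statistic estimate with block-jackknife uncertainty."""

    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    def __str__(self) -> str:
        return (
            f"estimate={self.estimate:+.6f}  se={self.se:.6f}  "
            f"Z={self.z:+.2f}  blocks={self.n_blocks}  sites={self.n_sites}"
        )


# ---------------------------------------------------------------------------
# per-site diversity


def _freq_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n observed alleles, alternate count) per site."""
    obs = alleles != MISSING
    n = obs.sum(axis=0)
    c = np.where(obs, alleles, 0).sum(axis=0)
    return n, c


def site_pi(alleles: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity; NaN where < 2 alleles are observed."""
    alleles = np.asarray(alleles)
    n, c = _freq_counts(alleles)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def site_pi_table(panel: HaplotypePanel, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """``CHROM POS PI`` table (the vcftools ``--site-pi`` layout); sites with
    fewer than two observed alleles are dropped."""
    sub = panel if sample_ids is None else panel.subset_samples(list(sample_ids))
    pi = site_pi(sub.alleles)
    rows = [
        (s.chrom, s.pos_bp, float(p))
        for s, p in zip(sub.sites, pi)
        if np.isfinite(p)
    ]
    return pd.DataFrame(rows, columns=["CHROM", "POS", "PI"])


# ---------------------------------------------------------------------------
# f-statistics with weighted block jackknife


def _freqs(alleles: np.ndarray) -> np.ndarray:
    if alleles.shape[0] == 0:
        raise ValueError("population with zero haplotypes")
    n, c = _freq_counts(np.asarray(alleles))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, c / np.maximum(n, 1), np.nan)


def _block_jackknife(products: np.ndarray, block_ids: np.ndarray) -> FStatResult:
    """Weighted delete-one-block jackknife of a mean over sites."""
    ok = np.isfinite(products)
    products = products[ok]
    block_ids = block_ids[ok]
    n_total = products.size
    if n_total == 0:
        raise ValueError("no usable sites")
    blocks = np.unique(block_ids)
    if blocks.size < 2:
        raise ValueError("need >= 2 blocks with data for the jackknife")
    s_total = products.sum()
    est = s_total / n_total
    s_j = np.array([products[block_ids == b].sum() for b in blocks])
    n_j = np.array([(block_ids == b).sum() for b in blocks])
    theta_minus = (s_total - s_j) / (n_total - n_j)
    g = blocks.size
    h = n_total / n_j
    theta_jack = g * est - ((1.0 - n_j / n_total) * theta_minus).sum()
    tau = h * est - (h - 1.0) * theta_minus
    var = ((tau - theta_jack) ** 2 / (h - 1.0)).sum() / g
    se = float(np.sqrt(var))
    if se > 0:
        z = est / se
    else:
        z = 0.0 if est == 0 else np.inf * np.sign(est)
    return FStatResult(float(est), se, float(z), int(g), int(n_total))


def _block_ids(sites_cm: np.ndarray, block_size_cm: float) -> np.ndarray:
    sites_cm = np.asarray(sites_cm, dtype=float)
    return np.floor((sites_cm - sites_cm.min()) / block_size_cm).astype(int)


def f4(
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    alleles_c: np.ndarray,
    alleles_d: np.ndarray,
    sites_cm: np.ndarray,
    block_size_cm: float = 0.5,
) -> FStatResult:
    """f4(A, B; C, D) = mean over sites of (pA - pB)(pC - pD), jackknife SE.

    Sites where any population has no observed allele are skipped.
    """
    pa, pb, pc, pd_ = (_freqs(x) for x in (alleles_a, alleles_b, alleles_c, alleles_d))
    prod = (pa - pb) * (pc - pd_)
    return _block_jackknife(prod, _block_ids(sites_cm, block_size_cm))


def f3(
    alleles_t: np.ndarray,
    alleles_a: np.ndarray,
    alleles_b: np.ndarray,
    sites_cm: np.ndarray,
    block_size_cm: float = 0.5,
) -> FStatResult:
    """f3(T; A, B) = mean over sites of (pT - pA)(pT - pB), jackknife SE."""
    pt, pa, pb = (_freqs(x) for x in (alleles_t, alleles_a, alleles_b))
    prod = (pt - pa) * (pt - pb)
    return _block_jackknife(prod, _block_ids(sites_cm, block_size_cm))


def residual_ancestry_check(
    reconstructed: np.ndarray,
    target_source: np.ndarray,
    distractor1: np.ndarray,
    distractor2: np.ndarray,
    sites_cm: np.ndarray,
    block_size_cm: float = 0.5,
) -> FStatResult:
    """f4(reconstructed, target source; distractor1, distractor2).

    |Z| below the conventional cutoff of 4 is the "no residual ancestry"
    verdict: the reconstructed population forms a clade with its source
    against the two distractor ancestries.
    """
    return f4(reconstructed, target_source, distractor1, distractor2, sites_cm, block_size_cm)


# ---------------------------------------------------------------------------
# haplotype-painting surrogate


def window_painting(
    recipients: HaplotypePanel,
    donors: Mapping[str, HaplotypePanel],
    window_sites: int = 25,
) -> pd.DataFrame:
    """Copied genetic length (cM) per recipient individual and donor
    population, by minimum-mismatch window assignment.

    Recipient haplotypes are cut into consecutive windows of ``window_sites``
    sites; a window goes to the donor population holding the haplotype with
    the fewest mismatches over the window's observed sites (ties split
    equally).  Window lengths are measured on the genetic map between window
    start boundaries, so each recipient's row sum equals the painted map
    length (up to windows with no observed site, which contribute nothing).
    """
    if window_sites < 10:
        raise ValueError("window_sites must be >= 10")
    cms = np.array([s.cm for s in recipients.sites], dtype=float)
    if np.any(~np.isfinite(cms)):
        raise ValueError("recipient sites need cM positions (apply a genetic map)")
    n_sites = recipients.n_sites
    starts = list(range(0, n_sites, window_sites))
    if len(starts) > 1 and n_sites - starts[-1] < window_sites // 2:
        starts.pop()  # fold a short tail window into its neighbour
    bounds = [cms[i] for i in starts] + [cms[-1]]
    labels = list(donors)
    donor_mats = [np.asarray(donors[l].alleles) for l in labels]
    totals = np.zeros((recipients.n_samples, len(labels)))
    R = recipients.alleles
    for k, lo in enumerate(starts):
        hi = starts[k + 1] if k + 1 < len(starts) else n_sites
        w_len = bounds[k + 1] - bounds[k]
        rw = R[:, lo:hi]
        robs = rw != MISSING
        any_obs = robs.any(axis=1)
        best = np.full((R.shape[0], len(labels)), np.inf)
        for li, dm in enumerate(donor_mats):
            dw = dm[:, lo:hi]
            dobs = dw != MISSING
            # mismatches over jointly observed sites, recipient x donor hap
            mism = (
                (rw[:, None, :] != dw[None, :, :]) & robs[:, None, :] & dobs[None, :, :]
            ).sum(axis=2)
            best[:, li] = mism.min(axis=1)
        minv = best.min(axis=1)
        tied = best == minv[:, None]
        share = tied / tied.sum(axis=1, keepdims=True)
        share[~any_obs] = 0.0
        hap_tot = share * w_len
        totals += hap_tot[0::2] + hap_tot[1::2]
    return pd.DataFrame(totals, index=list(recipients.sample_ids), columns=labels)


# ---------------------------------------------------------------------------
# differential-ancestry comparison


def differential_ancestry_test(
    totals: pd.DataFrame,
    groups: Mapping[str, str],
    significance: float = 0.005,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of donor totals between recipient groups.

    For every donor and every unordered pair of groups, a two-sided Wilcoxon
    rank-sum (Mann–Whitney) test compares the copied-length distributions;
    p-values are Bonferroni-corrected over all performed tests and a
    comparison is significant when the corrected p falls below
    ``significance``.  Pairs where either group has fewer than
    ``min_group_size`` members are skipped with a warning.
    """
    by_group: dict[str, list[str]] = {}
    for sid in totals.index:
        g = groups.get(sid)
        if g is not None:
            by_group.setdefault(g, []).append(sid)
    if len(by_group) < 2:
        raise ValueError("need >= 2 recipient groups")
    rows = []
    for g1, g2 in combinations(sorted(by_group), 2):
        if len(by_group[g1]) < min_group_size or len(by_group[g2]) < min_group_size:
            warnings.warn(
                f"skipping pair ({g1}, {g2}): group smaller than {min_group_size}",
                stacklevel=2,
            )
            continue
        for donor in totals.columns:
            x = totals.loc[by_group[g1], donor].to_numpy()
            y = totals.loc[by_group[g2], donor].to_numpy()
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0  # identical distributions carry no evidence
            else:
                _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            direction = f"{g1} > {g2}" if x.mean() > y.mean() else f"{g2} > {g1}"
            rows.append((donor, g1, g2, len(x), len(y), float(p), direction))
    n_tests = len(rows)
    table = pd.DataFrame(
        rows, columns=["donor", "group1", "group2", "n1", "n2", "raw_p", "direction"]
    )
    table["corrected_p"] = np.minimum(table["raw_p"] * n_tests, 1.0)
    table["significant"] = table["corrected_p"] < significance
    return table[
        ["donor", "group1", "group2", "n1", "n2", "raw_p", "corrected_p", "direction", "significant"]
    ]
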