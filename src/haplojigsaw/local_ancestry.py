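"""Local-ancestry window calls and target-ancestry fragments.

Local-ancestry inference (RFMix-class software) emits, per phased haplotype,
a sequence of genomic windows each with a posterior probability over the
ancestral populations.  This module ingests those calls from a documented TSV
dialect, applies the posterior filter (keep a window only when the target
ancestry's posterior is *strictly greater* than the threshold, default 0.8),
and concatenates maximal runs of consecutive kept windows into
:class:`Fragment` objects carrying full provenance — which admixed sample and
which phased side each fragment came from.

"Consecutive" means adjacent in the haplotype's window sequence: two kept
windows separated by a discarded window are never merged.  A merged fragment
spans from the first window's start to the last window's end, including any
base pairs between windows of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WindowCall",
    "Fragment",
    "WindowValidationError",
    "read_window_calls",
    "write_window_calls",
    "filter_and_merge",
    "write_fragments",
    "read_fragments",
]

_POSTERIOR_TOL = 1e-6


class WindowValidationError(ValueError):
    """A window call violates the posterior or ordering invariants."""


@dataclass(frozen=True)
class WindowCall:
    """One local-ancestry window on one phased haplotype.

    Span is 1-based inclusive; ``posteriors`` maps ancestry label to posterior
    probability and sums to 1.
    """

    chrom: str
    start_bp: int
    end_bp: int
    sample_id: str
    side: int
    posteriors: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise WindowValidationError(
                f"window {self.chrom}:{self.start_bp}-{self.end_bp}: start > end"
            )
        if self.side not in (0, 1):
            raise WindowValidationError(f"side must be 0 or 1, got {self.side}")
        vals = np.array(list(self.posteriors.values()), dtype=float)
        if np.any(vals < 0) or np.any(vals > 1):
            raise WindowValidationError("posteriors must lie in [0, 1]")
        if abs(vals.sum() - 1.0) > _POSTERIOR_TOL:
            raise WindowValidationError(
                f"posteriors sum to {vals.sum():.6f}, expected 1"
            )

    @property
    def haplotype_ref(self) -> tuple[str, int]:
        return (self.sample_id, self.side)


@dataclass(frozen=True)
class Fragment:
    """A contiguous run of target-ancestry sequence on one source haplotype."""

    id: str
    chrom: str
    start_bp: int
    end_bp: int
    source_sample: str
    source_side: int
    ancestry: str
    n_windows: int = 1

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"fragment {self.id}: start_bp > end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _group_key(call: WindowCall) -> tuple[str, int, str]:
    return (call.sample_id, call.side, call.chrom)


def _validate_grouping(calls: Sequence[WindowCall]) -> dict[tuple[str, int, str], list[WindowCall]]:
    groups: dict[tuple[str, int, str], list[WindowCall]] = {}
    for c in calls:
        groups.setdefault(_group_key(c), []).append(c)
    for key, grp in groups.items():
        grp.sort(key=lambda c: c.start_bp)
        for prev, nxt in zip(grp, grp[1:]):
            if nxt.start_bp <= prev.end_bp:
                raise WindowValidationError(
                    f"haplotype {key}: windows {prev.start_bp}-{prev.end_bp} and "
                    f"{nxt.start_bp}-{nxt.end_bp} overlap"
                )
    return groups


def read_window_calls(path: str | Path) -> list[WindowCall]:
    """Read window calls from TSV.

    Columns: ``chrom  start_bp  end_bp  sample_id  side`` then one posterior
    column per ancestry label (the header row names the labels).  Calls are
    returned grouped per haplotype and ordered by start position; posterior
    and overlap invariants are checked, with errors naming the offending row.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "sample_id": str}, float_precision="round_trip"
    )
    fixed = ["chrom", "start_bp", "end_bp", "sample_id", "side"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise WindowValidationError(f"window-calls TSV missing columns {missing}")
    labels = [c for c in df.columns if c not in fixed]
    if not labels:
        raise WindowValidationError("window-calls TSV has no posterior columns")
    calls: list[WindowCall] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            calls.append(
                WindowCall(
                    chrom=str(d["chrom"]),
                    start_bp=int(d["start_bp"]),
                    end_bp=int(d["end_bp"]),
                    sample_id=str(d["sample_id"]),
                    side=int(d["side"]),
                    posteriors={lab: float(d[lab]) for lab in labels},
                )
            )
        except WindowValidationError as e:
            raise WindowValidationError(f"{path} line {row_no}: {e}") from e
    groups = _validate_grouping(calls)
    out: list[WindowCall] = []
    for key in sorted(groups):
        out.extend(groups[key])
    return out


def write_window_calls(calls: Sequence[WindowCall], path: str | Path) -> None:
    """Inverse of :func:`read_window_calls` (used by the simulator)."""
    labels = sorted({lab for c in calls for lab in c.posteriors}) if calls else []
    rows = [
        {
            "chrom": c.chrom,
            "start_bp": c.start_bp,
            "end_bp": c.end_bp,
            "sample_id": c.sample_id,
            "side": c.side,
            **{lab: c.posteriors.get(lab, 0.0) for lab in labels},
        }
        for c in calls
    ]
    cols = ["chrom", "start_bp", "end_bp", "sample_id", "side", *labels]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_and_merge(
    calls: Iterable[WindowCall],
    target: str,
    min_posterior: float = 0.8,
) -> list[Fragment]:
    """Keep target-ancestry windows above the posterior cutoff and merge
    consecutive kept windows into fragments.

    A window survives iff ``posteriors[target] > min_posterior`` (strict).
    Within one haplotype, each maximal run of kept windows that are adjacent
    in the window sequence becomes a single fragment spanning the run's first
    start to its last end.  Fragment provenance records the source haplotype.
    """
    calls = list(calls)
    if calls and not any(target in c.posteriors for c in calls):
        raise KeyError(f"target ancestry {target!r} not among posterior labels")
    groups = _validate_grouping(calls)
    fragments: list[Fragment] = []
    for (sample_id, side, chrom) in sorted(groups):
        grp = groups[(sample_id, side, chrom)]
        kept = [c.posteriors.get(target, 0.0) > min_posterior for c in grp]
        run_no = 0
        i = 0
        while i < len(grp):
            if not kept[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and kept[j + 1]:
                j += 1
            fragments.append(
                Fragment(
                    id=f"{sample_id}.{side}.{chrom}.{run_no}",
                    chrom=chrom,
                    start_bp=grp[i].start_bp,
                    end_bp=grp[j].end_bp,
                    source_sample=sample_id,
                    source_side=side,
                    ancestry=target,
                    n_windows=j - i + 1,
                )
            )
            run_no += 1
            i = j + 1
    return fragments


_FRAGMENT_COLS = [
    "chrom",
    "start_bp",
    "end_bp",
    "fragment_id",
    "source_sample",
    "source_side",
    "ancestry",
    "n_windows",
]


def write_fragments(fragments: Sequence[Fragment], path: str | Path) -> None:
    """Write fragments as a BED-like TSV (1-based inclusive spans)."""
    rows = [
        (f.chrom, f.start_bp, f.end_bp, f.id, f.source_sample, f.source_side, f.ancestry, f.n_windows)
        for f in fragments
    ]
    pd.DataFrame(rows, columns=_FRAGMENT_COLS).to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> list[Fragment]:
    """Read a fragments TSV written by :func:`write_fragments`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "source_sample": str})
    missing = [c for c in _FRAGMENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"fragments TSV missing columns {missing}")
    out: list[Fragment] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                Fragment(
                    id=str(row.fragment_id),
                    chrom=str(row.chrom),
                    start_bp=int(row.start_bp),
                    end_bp=int(row.end_bp),
                    source_sample=str(row.source_sample),
                    source_side=int(row.source_side),
                    ancestry=str(row.ancestry),
                    n_windows=int(row.n_windows),
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} line {row_no}: {e}") from e
    return out
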