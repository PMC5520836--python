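"""Sliding-window variant frequencies and high/low-frequency region calls.

Frequency in a window is the variant count divided by the number of
*covered* bases in the window (uncovered nucleotides are excluded), after
the genome-scan convention of a 100-kb window advanced in 50-kb steps.
Windows with zero covered bases have undefined frequency and are excluded
both from threshold estimation and from region calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import CoverageMask, natural_sort_key


@dataclass
class WindowStat:
    """Per-window covered-base-corrected variant frequency."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    covered_bases: int
    variant_count: int

    @property
    def frequency(self) -> float:
        """variant_count / covered_bases; NaN when no base is covered."""
        if self.covered_bases == 0:
            return math.nan
        return self.variant_count / self.covered_bases


@dataclass
class ExtremeRegion:
    """A merged run of same-kind extreme windows."""

    chrom: str
    start: int
    end: int
    kind: str  # "high" | "low"
    n_windows: int
    peak_frequency: float  # max frequency for high regions, min for low


def compute_window_frequencies(
    variants: Sequence[tuple],
    mask: CoverageMask,
    window_size: int = 100_000,
    step: int = 50_000,
    chrom_lengths: Optional[dict[str, int]] = None,
    lenient: bool = False,
) -> list[WindowStat]:
    """Tile each chromosome with sliding windows and count variants.

    ``variants`` is a sequence of ``(chrom, pos)`` with 1-based positions
    (any extra tuple elements are ignored, so record objects' key tuples
    work directly).  Windows start at position 1 and advance by ``step``;
    the final window is truncated at the chromosome end, taken from
    ``chrom_lengths`` when given, else from the mask's largest covered
    coordinate.  A variant at position p is counted in every window whose
    span contains p.  A variant on a chromosome absent from the mask
    raises, or is skipped when ``lenient``.
    """
    if not (window_size >= step >= 1):
        raise ValueError(f"need window_size >= step >= 1, got {window_size}, {step}")
    lengths = dict(chrom_lengths) if chrom_lengths else {}
    for chrom in mask.chroms:
        lengths.setdefault(chrom, mask.extent(chrom))

    counts: dict[str, np.ndarray] = {}
    n_windows: dict[str, int] = {}
    for chrom, L in lengths.items():
        # windows have starts 1, 1+step, ... while start <= L
        n_windows[chrom] = (L - 1) // step + 1 if L >= 1 else 0
        counts[chrom] = np.zeros(n_windows[chrom], dtype=np.int64)

    for item in variants:
        chrom, pos = item[0], item[1]
        if chrom not in counts:
            if lenient:
                continue
            raise ValueError(f"variant on chromosome {chrom!r} absent from the mask")
        # windows containing pos: start <= pos and start + window_size - 1 >= pos
        i_max = (pos - 1) // step
        i_min = max(0, -(-(pos - window_size) // step))  # ceil division
        i_max = min(i_max, n_windows[chrom] - 1)
        if i_min <= i_max:
            counts[chrom][i_min : i_max + 1] += 1

    stats = []
    for chrom in sorted(lengths, key=natural_sort_key):
        L = lengths[chrom]
        for i in range(n_windows[chrom]):
            start = 1 + i * step
            end = min(L, start + window_size - 1)
            stats.append(
                WindowStat(
                    chrom=chrom,
                    start=start,
                    end=end,
                    covered_bases=mask.covered_in(chrom, start, end),
                    variant_count=int(counts[chrom][i]),
                )
            )
    return stats


def call_extreme_regions(
    stats: Sequence[WindowStat],
    method: str = "quantile",
    alpha: float = 0.025,
    n_sd: float = 2.0,
    per_chromosome: bool = False,
    min_usable_windows: int = 8,
) -> list[ExtremeRegion]:
    """Call high/low-frequency regions from genome-wide window statistics.

    ``high`` windows exceed the (1 - alpha) quantile of usable window
    frequencies (strictly), ``low`` windows fall strictly below the alpha
    quantile; with ``method="mean_sd"`` the thresholds are mean +/- n_sd
    standard deviations instead.  Same-kind extreme windows whose spans
    overlap or abut are merged into one region.  Thresholds are estimated
    genome-wide by default; ``per_chromosome`` estimates them per
    chromosome.
    """
    if method not in ("quantile", "mean_sd"):
        raise ValueError(f"unknown method {method!r}")
    usable = [w for w in stats if w.covered_bases > 0]
    if len(usable) < min_usable_windows:
        raise ValueError(
            f"only {len(usable)} usable windows (< {min_usable_windows}); "
            "not enough to estimate thresholds"
        )
    groups: dict[Optional[str], list[WindowStat]] = {}
    if per_chromosome:
        for w in usable:
            groups.setdefault(w.chrom, []).append(w)
    else:
        groups[None] = usable

    extreme: list[tuple[WindowStat, str]] = []
    for ws in groups.values():
        freqs = np.array([w.frequency for w in ws])
        if method == "quantile":
            lo = float(np.quantile(freqs, alpha))
            hi = float(np.quantile(freqs, 1.0 - alpha))
        else:
            mu, sd = float(freqs.mean()), float(freqs.std(ddof=0))
            lo, hi = mu - n_sd * sd, mu + n_sd * sd
        for w in ws:
            if w.frequency > hi:
                extreme.append((w, "high"))
            elif w.frequency < lo:
                extreme.append((w, "low"))

    return _merge_extreme(extreme)


def _merge_extreme(extreme: list[tuple[WindowStat, str]]) -> list[ExtremeRegion]:
    regions: list[ExtremeRegion] = []
    keyed = sorted(
        extreme, key=lambda t: (t[1], natural_sort_key(t[0].chrom), t[0].start)
    )
    for w, kind in keyed:
        last = regions[-1] if regions else None
        if (
            last is not None
            and last.kind == kind
            and last.chrom == w.chrom
            and w.start <= last.end + 1
        ):
            last.end = max(last.end, w.end)
            last.n_windows += 1
            better = max if kind == "high" else min
            last.peak_frequency = better(last.peak_frequency, w.frequency)
        else:
            regions.append(
                ExtremeRegion(
                    chrom=w.chrom, start=w.start, end=w.end, kind=kind,
                    n_windows=1, peak_frequency=w.frequency,
                )
            )
    regions.sort(key=lambda r: (natural_sort_key(r.chrom), r.start, r.kind))
    return regions


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in stats],
            "start": [w.start for w in stats],
            "end": [w.end for w in stats],
            "covered": [w.covered_bases for w in stats],
            "count": [w.variant_count for w in stats],
            "frequency": [w.frequency for w in stats],
        }
    )


def regions_to_bed(regions: Sequence[ExtremeRegion]) -> str:
    """Regions as BED text (0-based half-open), name = kind, score = windows."""
    return "".join(
        f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.kind}\t{r.n_windows}\n"
        for r in regions
    )


def region_summary(
    regions_by_class: dict[str, Sequence[ExtremeRegion]],
    chroms: Sequence[str],
) -> pd.DataFrame:
    """Per-chromosome high/low region counts for each variant class, with a
    totals row (the shape used for genome scan summaries)."""
    chroms = sorted(chroms, key=natural_sort_key)
    data: dict[str, list[int]] = {}
    for cls, regions in regions_by_class.items():
        for kind in ("high", "low"):
            col = f"{cls}_{kind}"
            data[col] = [
                sum(1 for r in regions if r.chrom == c and r.kind == kind)
                for c in chroms
            ]
    df = pd.DataFrame(data, index=pd.Index(chroms, name="Chr"))
    df.loc["Total"] = df.sum()
    return df
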