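"""Recurrent changepoint regions across a cohort.

Each changepoint contributes a genomic range: a Gaussian kernel density
estimate (Silverman bandwidth) is fitted over the location evidence for that
changepoint (its bootstrap-replicate placements), and the range is the KDE
mean +/- one standard deviation of the smoothed density, i.e. the sample
standard deviation inflated by the bandwidth.  With a single location or zero
spread the range degrades to the changepoint's flanking-bin span.  Ranges
from all samples of a tissue are overlaid and counted in sliding windows; a
maximal run of windows where at least ``threshold`` distinct samples overlap
(default seven) is a recurrent region, reported at its maximum-count window
(leftmost on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import chrom_rank

logger = logging.getLogger("regionsig")

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 500_000
DEFAULT_THRESHOLD = 7


@dataclass(frozen=True)
class ChangepointRange:
    """The plausible genomic range of one sample's changepoint."""

    sample_id: str
    chrom: str
    start: float
    end: float
    source: int  # index of the changepoint within its sample's profile
    #: activity difference (right minus left) across the changepoint, used for
    #: per-region signature summaries when available
    activity_change: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("range start must precede end")


def changepoint_range(
    chrom: str,
    locations: Sequence[float],
    fallback_span: tuple[float, float],
    sample_id: str = "",
    source: int = 0,
    chrom_length: Optional[int] = None,
    activity_change: Optional[np.ndarray] = None,
) -> ChangepointRange:
    """KDE-derived range for a changepoint from its location evidence.

    ``locations`` must all lie on one chromosome (the caller passes per-
    chromosome vectors); ``fallback_span`` is the flanking-bin span used when
    the KDE is degenerate.  The returned interval always contains the
    changepoint locus (the mean location), widened if necessary.
    """
    locs = np.asarray(locations, dtype=float)
    if locs.size < 1:
        raise ValueError("need at least one location")
    lo_fb, hi_fb = float(fallback_span[0]), float(fallback_span[1])
    sd = locs.std(ddof=1) if locs.size > 1 else 0.0
    if locs.size < 2 or sd == 0.0:
        start, end = lo_fb, hi_fb
    else:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(locs, bw_method="silverman")
        # variance of the KDE mixture = sample variance * (1 + factor^2)
        s = sd * float(np.sqrt(1.0 + kde.factor**2))
        mean = float(locs.mean())
        start, end = mean - s, mean + s
        # the range must contain the reported locus
        start = min(start, lo_fb + 0.5 * (hi_fb - lo_fb))
        end = max(end, lo_fb + 0.5 * (hi_fb - lo_fb))
    if chrom_length is not None:
        start = max(0.0, start)
        end = min(float(chrom_length), end)
    if start >= end:
        start, end = lo_fb, hi_fb
    return ChangepointRange(sample_id, chrom, start, end, source, activity_change)


@dataclass(frozen=True)
class RecurrentRegion:
    """A genomic window shared by at least ``threshold`` samples' changepoints."""

    chrom: str
    window_start: int
    window_end: int
    region_start: int  # extent of the merged run of qualifying windows
    region_end: int
    n_samples: int
    samples: tuple[str, ...]
    mean_activity_change: Optional[np.ndarray] = None
    top_decrease: Optional[str] = None
    top_increase: Optional[str] = None


def find_recurrent_regions(
    ranges: Sequence[ChangepointRange],
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    threshold: int = DEFAULT_THRESHOLD,
    signature_names: Optional[Sequence[str]] = None,
) -> list[RecurrentRegion]:
    """Sliding-window scan for regions where >= threshold samples share a changepoint.

    A window counts a sample when any of that sample's ranges overlaps it
    (each sample at most once per window).  Maximal runs of consecutive
    qualifying windows merge into one region, reported at the window with the
    maximum count (leftmost on ties).  Output is independent of the order of
    the input ranges.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    regions: list[RecurrentRegion] = []
    chroms = sorted({r.chrom for r in ranges}, key=chrom_rank)
    for chrom in chroms:
        chrom_ranges = [r for r in ranges if r.chrom == chrom]
        hi = max(r.end for r in chrom_ranges)
        n_win = int(hi // step) + 1
        by_sample: dict[str, np.ndarray] = {}
        for r in chrom_ranges:
            marks = by_sample.setdefault(r.sample_id, np.zeros(n_win, dtype=bool))
            lo = max(0, int((r.start - window_size) // step) + 1)
            hi_k = min(n_win - 1, int(-(-r.end // step)) - 1)
            if hi_k >= lo:
                marks[lo : hi_k + 1] = True
        counts = np.sum(np.stack(list(by_sample.values())), axis=0)
        qualifying = counts >= threshold
        k = 0
        while k < n_win:
            if not qualifying[k]:
                k += 1
                continue
            k2 = k
            while k2 + 1 < n_win and qualifying[k2 + 1]:
                k2 += 1
            run = slice(k, k2 + 1)
            best_k = k + int(np.argmax(counts[run]))  # leftmost max
            w_start, w_end = best_k * step, best_k * step + window_size
            contributing = sorted(
                sid
                for sid, marks in by_sample.items()
                if marks[best_k]
            )
            deltas = [
                r.activity_change
                for r in chrom_ranges
                if r.sample_id in set(contributing)
                and r.start < w_end
                and w_start < r.end
                and r.activity_change is not None
            ]
            mean_delta = np.mean(np.stack(deltas), axis=0) if deltas else None
            top_dec = top_inc = None
            if mean_delta is not None and signature_names is not None:
                top_dec = signature_names[int(np.argmin(mean_delta))]
                top_inc = signature_names[int(np.argmax(mean_delta))]
            regions.append(
                RecurrentRegion(
                    chrom=chrom,
                    window_start=w_start,
                    window_end=w_end,
                    region_start=k * step,
                    region_end=k2 * step + window_size,
                    n_samples=int(counts[best_k]),
                    samples=tuple(contributing),
                    mean_activity_change=mean_delta,
                    top_decrease=top_dec,
                    top_increase=top_inc,
                )
            )
            k = k2 + 1
    return regions


def write_recurrent_regions(regions: Sequence[RecurrentRegion], path, signature_names=None) -> None:
    """BED-like TSV of recurrent regions with per-region signature summaries."""
    import pandas as pd

    rows = []
    for reg in regions:
        rows.append(
            {
                "chrom": reg.chrom,
                "region_start": reg.region_start,
                "region_end": reg.region_end,
                "window_start": reg.window_start,
                "window_end": reg.window_end,
                "n_samples": reg.n_samples,
                "samples": ",".join(reg.samples),
                "top_decrease": reg.top_decrease,
                "top_increase": reg.top_increase,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
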