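"""Optimal segmentation of a bin series into constant-activity segments.

The cost of a candidate segment is minus twice the maximised mixture
log-likelihood of its pooled channel counts (activities refitted per segment
by EM).  Segmentations minimise total cost plus a per-changepoint penalty,
by default the BIC charge ``(S-1) * log(N)`` for the S-1 free mixture
coefficients each extra segment introduces, with N the total number of
mutations in the series being segmented.

Constraints: every segment contains at least one bin, and no two changepoints
sit at adjacent bins (interior segments therefore span at least two bins).
The search is PELT — dynamic programming with cost-based pruning that is
exact because segment costs are superadditive (pooling never beats refitting
the parts separately).  Pruning of a candidate is deferred by one position so
that the adjacency constraint never invalidates the pruning argument.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .catalog96 import Bin, BinSeries
from .signature_model import ActivityVector, SignatureCatalog, changepoint_magnitude, em_fit

logger = logging.getLogger("regionsig")


@dataclass(frozen=True)
class Segment:
    """A maximal run of bins with a single fitted activity vector."""

    segment_id: int
    start_bin: int  # inclusive
    end_bin: int  # inclusive
    activity: ActivityVector
    log_likelihood: float
    chrom_start: str
    pos_start: int
    chrom_end: str
    pos_end: int


@dataclass(frozen=True)
class Changepoint:
    """A boundary between bins ``boundary-1`` and ``boundary``.

    The genomic interval is the union of the two flanking bins' spans
    (clipped to one chromosome when a genome-wise bin straddles a chromosome
    break), reflecting bin-scale positional uncertainty.  ``support`` is the
    bootstrap fraction, filled by the bootstrap module.
    """

    boundary: int
    chrom: str
    start: int
    end: int
    magnitude: float
    support: Optional[float] = None
    high_confidence: Optional[bool] = None


@dataclass(frozen=True)
class SegmentationResult:
    segments: tuple[Segment, ...]
    changepoints: tuple[Changepoint, ...]
    total_penalized_cost: float
    penalty_used: float

    def __post_init__(self) -> None:
        if len(self.changepoints) != len(self.segments) - 1:
            raise ValueError("changepoint count must be segment count - 1")


class _CostCache:
    """Pooled-count EM costs over bin ranges, via cumulative channel counts."""

    def __init__(self, count_matrix: np.ndarray, catalog: SignatureCatalog):
        self.cum = np.vstack([np.zeros(count_matrix.shape[1]), np.cumsum(count_matrix, axis=0)])
        self.catalog = catalog
        self._cache: dict[tuple[int, int], tuple[float, ActivityVector, float]] = {}

    def __call__(self, i: int, j: int) -> tuple[float, ActivityVector, float]:
        """(cost, activity, log_likelihood) for bins i..j inclusive."""
        key = (i, j)
        if key not in self._cache:
            counts = self.cum[j + 1] - self.cum[i]
            res = em_fit(counts, self.catalog)
            self._cache[key] = (-2.0 * res.log_likelihood, res.activity, res.log_likelihood)
        return self._cache[key]


def segment_cost(
    bins: BinSeries, i: int, j: int, catalog: SignatureCatalog
) -> tuple[float, ActivityVector]:
    """Cost ``-2 * max log-likelihood`` of pooling bins i..j, with the fitted activity."""
    if not (0 <= i <= j < len(bins)):
        raise ValueError("invalid bin range")
    cost, act, _ = _CostCache(bins.count_matrix, catalog)(i, j)
    return cost, act


def default_penalty(bins: BinSeries, catalog: SignatureCatalog) -> float:
    """BIC per-changepoint penalty ``(S-1) * log(N_mutations)`` on the -2 log L scale."""
    S = catalog.n_signatures
    if S == 1:
        logger.warning("single-signature catalog: no changepoint is identifiable")
        return math.inf
    return (S - 1) * math.log(bins.n_mutations)


def _admissible(s: int, t: int, B: int) -> bool:
    """May a segment run from boundary s to boundary t (bins s..t-1)?"""
    if t - s < 1:
        return False
    if s > 0 and t < B and t - s < 2:  # adjacent interior changepoints forbidden
        return False
    return True


def _pelt_boundaries(cost, B: int, penalty: float) -> tuple[list[int], float]:
    """Optimal changepoint boundaries for B bins under the given penalty.

    Returns (sorted interior boundaries, total penalized cost).
    """
    F = {0: -penalty}
    prev: dict[int, int] = {}
    candidates: list[int] = [0]
    pending_prune: dict[int, set[int]] = {}
    for t in range(1, B + 1):
        # apply prunes scheduled two steps ago; safe w.r.t. the adjacency rule
        for s in pending_prune.pop(t, ()):
            if s in candidates:
                candidates.remove(s)
        best, best_s = math.inf, None
        evals = {}
        for s in candidates:
            if not _admissible(s, t, B):
                continue
            val = F[s] + cost(s, t - 1)[0] + penalty
            evals[s] = val
            if val < best:
                best, best_s = val, s
        if best_s is None:  # only possible through pruning bugs; defensive
            raise RuntimeError("no admissible previous boundary")
        F[t] = best
        prev[t] = best_s
        if t < B and math.isfinite(penalty):
            doomed = {s for s, val in evals.items() if val - penalty > best}
            if doomed:
                pending_prune.setdefault(t + 2, set()).update(doomed)
            candidates.append(t)
        elif t < B:
            candidates.append(t)
    bounds = []
    t = B
    while t > 0:
        s = prev[t]
        if s > 0:
            bounds.append(s)
        t = s
    return sorted(bounds), F[B]


def _cp_interval(left: Bin, right: Bin) -> tuple[str, int, int]:
    """Reported (chrom, start, end) for the boundary between two bins."""
    L = left.chrom_end
    R = right.chrom_start
    if L == R:
        start = left.pos_start if left.chrom_start == L else 0
        end = right.pos_end if right.chrom_end == L else right.pos_start + 1
        return (L, start, max(end, start + 1))
    # genome-wise boundary coinciding with a chromosome break: report on the
    # right-hand chromosome from its origin
    end = right.pos_end if right.chrom_end == R else right.pos_start + 1
    return (R, 0, max(end, 1))


def _build_result(
    series: BinSeries,
    cost: _CostCache,
    boundaries: Sequence[int],
    total_cost: float,
    penalty: float,
    offset: int = 0,
) -> SegmentationResult:
    B = len(series)
    edges = [0, *boundaries, B]
    segments = []
    for sid, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        _, act, ll = cost(a, b - 1)
        first, last = series.bins[a], series.bins[b - 1]
        segments.append(
            Segment(
                segment_id=sid,
                start_bin=a + offset,
                end_bin=b - 1 + offset,
                activity=act,
                log_likelihood=ll,
                chrom_start=first.chrom_start,
                pos_start=first.pos_start,
                chrom_end=last.chrom_end,
                pos_end=last.pos_end,
            )
        )
    changepoints = []
    for k, b in enumerate(boundaries):
        chrom, start, end = _cp_interval(series.bins[b - 1], series.bins[b])
        mag = changepoint_magnitude(segments[k].activity, segments[k + 1].activity)
        changepoints.append(Changepoint(b + offset, chrom, start, end, mag))
    return SegmentationResult(
        segments=tuple(segments),
        changepoints=tuple(changepoints),
        total_penalized_cost=total_cost,
        penalty_used=penalty,
    )


def pelt_segment(
    bins: BinSeries, catalog: SignatureCatalog, penalty: Optional[float] = None
) -> SegmentationResult:
    """Optimal penalized segmentation of a bin series.

    Minimises ``sum(segment costs) + penalty * n_changepoints`` subject to the
    minimum-segment and non-adjacency constraints.  The result is identical to
    exhaustive dynamic programming; pruning only discards provably suboptimal
    candidates.
    """
    if len(bins) == 0:
        raise ValueError("empty bin series")
    if penalty is None:
        penalty = default_penalty(bins, catalog)
    cost = _CostCache(bins.count_matrix, catalog)
    B = len(bins)
    if B == 1 or not math.isfinite(penalty):
        c, _, _ = cost(0, B - 1)
        return _build_result(bins, cost, [], c, penalty)
    boundaries, total = _pelt_boundaries(cost, B, penalty)
    return _build_result(bins, cost, boundaries, total, penalty)


# ---------------------------------------------------------------------------
# Whole-profile orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileResult:
    """A sample's regional activity profile: bins, segments and changepoints.

    In chromosome-wise mode each chromosome is segmented independently (with
    its own BIC penalty) and the per-chromosome results are concatenated using
    global bin indices; chromosome boundaries are never changepoints.
    """

    series: BinSeries
    segments: tuple[Segment, ...]
    changepoints: tuple[Changepoint, ...]
    mode: str
    penalty_scale: float

    @property
    def sample_id(self) -> str:
        return self.series.sample_id


def run_profile(
    mutations,
    catalog: SignatureCatalog,
    bin_size: int = 100,
    mode: str = "chromosome_wise",
    penalty_scale: float = 1.0,
    penalty: Optional[float] = None,
    exclude_xy: bool = False,
) -> ProfileResult:
    """Bin a sample's mutations and segment the resulting activity series."""
    from .catalog96 import make_bins

    if exclude_xy:
        mutations = [m for m in mutations if m.chrom not in ("X", "Y")]
    series = make_bins(mutations, bin_size=bin_size, mode=mode)
    return segment_series(series, catalog, penalty_scale=penalty_scale, penalty=penalty)


def segment_series(
    series: BinSeries,
    catalog: SignatureCatalog,
    penalty_scale: float = 1.0,
    penalty: Optional[float] = None,
) -> ProfileResult:
    """Segment an existing bin series (used by bootstrap resampling too)."""
    segments: list[Segment] = []
    changepoints: list[Changepoint] = []
    if series.mode == "genome_wise":
        pen = penalty if penalty is not None else penalty_scale * default_penalty(series, catalog)
        res = pelt_segment(series, catalog, penalty=pen)
        segments.extend(res.segments)
        changepoints.extend(res.changepoints)
    else:
        sid_offset = 0
        for chrom, sl in series.chromosome_slices().items():
            sub = BinSeries(
                bins=tuple(
                    replace(b, bin_index=i) for i, b in enumerate(series.bins[sl])
                ),
                mode="chromosome_wise",
                bin_size=series.bin_size,
                sample_id=series.sample_id,
            )
            pen = penalty if penalty is not None else penalty_scale * default_penalty(sub, catalog)
            cost = _CostCache(sub.count_matrix, catalog)
            B = len(sub)
            if B == 1 or not math.isfinite(pen):
                c, _, _ = cost(0, B - 1)
                res = _build_result(sub, cost, [], c, pen, offset=sl.start)
            else:
                bounds, total = _pelt_boundaries(cost, B, pen)
                res = _build_result(sub, cost, bounds, total, pen, offset=sl.start)
            for seg in res.segments:
                segments.append(replace(seg, segment_id=sid_offset + seg.segment_id))
            sid_offset += len(res.segments)
            changepoints.extend(res.changepoints)
    return ProfileResult(
        series=series,
        segments=tuple(segments),
        changepoints=tuple(changepoints),
        mode=series.mode,
        penalty_scale=penalty_scale,
    )


def write_changepoint_table(profile: ProfileResult, catalog: SignatureCatalog, path) -> None:
    """Changepoint TSV: boundary, genomic interval, magnitude, top signature shifts."""
    import pandas as pd

    seg_by_end = {s.end_bin: s for s in profile.segments}
    seg_by_start = {s.start_bin: s for s in profile.segments}
    rows = []
    for cp in profile.changepoints:
        left = seg_by_end[cp.boundary - 1]
        right = seg_by_start[cp.boundary]
        delta = right.activity.activities - left.activity.activities
        rows.append(
            {
                "boundary": cp.boundary,
                "chrom": cp.chrom,
                "start": cp.start,
                "end": cp.end,
                "magnitude": cp.magnitude,
                "support": cp.support,
                "high_confidence": cp.high_confidence,
                "top_decrease": catalog.names[int(np.argmin(delta))],
                "top_increase": catalog.names[int(np.argmax(delta))],
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "boundary",
            "chrom",
            "start",
            "end",
            "magnitude",
            "support",
            "high_confidence",
            "top_decrease",
            "top_increase",
        ],
    ).to_csv(path, sep="\t", index=False)
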