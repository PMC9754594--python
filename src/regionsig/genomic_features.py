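"""Feature tracks used by the changepoint association tests.

Covers kataegis detection (localized hypermutation: runs of at least six
consecutive mutations with mean inter-mutation distance <= 1 kb), windowed
density tracks (genes, events), copy-number aberration extraction,
replication-timing consensus, A/B compartment recoding, and nearest-event
distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import FeatureInterval, GenomeLayout, Mutation, chrom_rank

logger = logging.getLogger("regionsig")

KATAEGIS_MIN_MUTATIONS = 6
KATAEGIS_MAX_MEAN_GAP = 1000.0


@dataclass(frozen=True)
class KataegisEvent:
    """A maximal run of clustered mutations meeting the rainfall criterion."""

    sample_id: str
    chrom: str
    start: int  # position of first mutation in the run (1-based)
    end: int  # position of last mutation in the run (1-based)
    n_mutations: int
    mean_intermutation_distance: float

    def as_interval(self) -> FeatureInterval:
        return FeatureInterval(self.chrom, self.start - 1, self.end, value=None)


@dataclass(frozen=True)
class DensityTrack:
    """Tiled/sliding-window numeric track over the genome."""

    windows: tuple[FeatureInterval, ...]
    window_size: int
    step: int
    normalized: bool = False

    def values(self) -> np.ndarray:
        return np.array([w.value for w in self.windows], dtype=float)

    def min_max_normalized(self) -> "DensityTrack":
        """Scale so the densest window is 1 and the sparsest 0."""
        v = self.values()
        lo, hi = v.min(), v.max()
        span = hi - lo if hi > lo else 1.0
        wins = tuple(
            FeatureInterval(w.chrom, w.start, w.end, (w.value - lo) / span) for w in self.windows
        )
        return DensityTrack(wins, self.window_size, self.step, normalized=True)


# ---------------------------------------------------------------------------
# Kataegis
# ---------------------------------------------------------------------------

def _qualifies(positions: np.ndarray, i: int, j: int) -> bool:
    n = j - i + 1
    if n < KATAEGIS_MIN_MUTATIONS:
        return False
    return (positions[j] - positions[i]) / (n - 1) <= KATAEGIS_MAX_MEAN_GAP


def detect_kataegis(mutations: Sequence[Mutation]) -> list[KataegisEvent]:
    """Detect kataegis events in a coordinate-sorted single-sample mutation list.

    Scanning left to right: from the first start index admitting any
    qualifying run, the run extended to the farthest qualifying end index is
    emitted, and the scan resumes after it.  Emitted events therefore satisfy
    the criterion, cannot be extended by one adjacent mutation while still
    satisfying it, and never overlap.
    """
    events: list[KataegisEvent] = []
    by_chrom: dict[str, list[Mutation]] = {}
    for m in mutations:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom in sorted(by_chrom, key=chrom_rank):
        ms = by_chrom[chrom]
        pos = np.array([m.pos for m in ms], dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValueError("mutations must be sorted by position within chromosome")
        n = len(pos)
        i = 0
        while i + KATAEGIS_MIN_MUTATIONS - 1 < n:
            j_best = -1
            j = i + KATAEGIS_MIN_MUTATIONS - 1
            while j < n:
                span = pos[j] - pos[i]
                if span <= KATAEGIS_MAX_MEAN_GAP * (j - i):
                    j_best = j
                elif span - KATAEGIS_MAX_MEAN_GAP * (j - i) > KATAEGIS_MAX_MEAN_GAP * (n - 1 - j):
                    break  # mean gap can no longer recover within this chromosome
                j += 1
            if j_best >= 0:
                events.append(
                    KataegisEvent(
                        sample_id=ms[0].sample_id,
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j_best]),
                        n_mutations=j_best - i + 1,
                        mean_intermutation_distance=float(
                            (pos[j_best] - pos[i]) / (j_best - i)
                        ),
                    )
                )
                i = j_best + 1
            else:
                i += 1
    return events


# ---------------------------------------------------------------------------
# Density tracks
# ---------------------------------------------------------------------------

def _window_counts(
    intervals: Sequence[FeatureInterval], layout: GenomeLayout, window: int, step: int
) -> list[FeatureInterval]:
    """Per-window counts of intervals overlapping each (tiled or sliding) window."""
    out: list[FeatureInterval] = []
    by_chrom: dict[str, list[FeatureInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, length in zip(layout.chroms, layout.lengths):
        n_win = max(1, -(-length // step))
        counts = np.zeros(n_win + 1, dtype=np.int64)
        for iv in by_chrom.get(chrom, ()):  # diff-array accumulation
            lo = max(0, (iv.start - window) // step + 1)
            hi = min(n_win - 1, -(-iv.end // step) - 1)
            if hi >= lo:
                counts[lo] += 1
                counts[hi + 1] -= 1
        counts = np.cumsum(counts[:-1])
        for k in range(n_win):
            start = k * step
            out.append(FeatureInterval(chrom, start, min(start + window, length), float(counts[k])))
    return out


def gene_density(
    genes: Sequence[FeatureInterval],
    layout: GenomeLayout,
    window: int = 1000,
    step: Optional[int] = None,
    normalize: bool = False,
) -> DensityTrack:
    """Gene counts in windows (default 1 kb tiles) across the genome."""
    step = window if step is None else step
    track = DensityTrack(tuple(_window_counts(genes, layout, window, step)), window, step)
    return track.min_max_normalized() if normalize else track


def event_density(
    events: Sequence[FeatureInterval],
    layout: GenomeLayout,
    window: int = 1_000_000,
    step: Optional[int] = None,
) -> DensityTrack:
    """Event counts (kataegis, CNAs, ...) in windows (default 1 Mb tiles)."""
    step = window if step is None else step
    return DensityTrack(tuple(_window_counts(events, layout, window, step)), window, step)


# ---------------------------------------------------------------------------
# CNA / replication timing / compartments
# ---------------------------------------------------------------------------

def cna_intervals(segments: Sequence[FeatureInterval]) -> list[FeatureInterval]:
    """Copy-number aberrations: autosomal segments with ploidy other than two.

    X and Y are removed because consensus copy-number calls cover autosomes
    only.
    """
    out = []
    for seg in segments:
        if seg.chrom in ("X", "Y"):
            continue
        if seg.value is None:
            raise ValueError("copy-number segment lacks a ploidy value")
        if float(seg.value) != 2.0:
            out.append(seg)
    return out


def replication_timing_consensus(tracks: Sequence[DensityTrack]) -> DensityTrack:
    """Per-segment median replication time across cell lines."""
    if not tracks:
        raise ValueError("need at least one track")
    ref = tracks[0]
    keys = [(w.chrom, w.start, w.end) for w in ref.windows]
    for t in tracks[1:]:
        if [(w.chrom, w.start, w.end) for w in t.windows] != keys:
            raise ValueError("tracks do not share a segmentation")
    values = np.median(np.stack([t.values() for t in tracks]), axis=0)
    wins = tuple(
        FeatureInterval(w.chrom, w.start, w.end, float(v)) for w, v in zip(ref.windows, values)
    )
    return DensityTrack(wins, ref.window_size, ref.step)


def recode_compartments(track: Sequence[FeatureInterval]) -> list[FeatureInterval]:
    """Recode A/B chromatin compartments numerically: A (open) -> 1, B (closed) -> 0."""
    out = []
    for iv in track:
        if iv.value == "A":
            v = 1.0
        elif iv.value == "B":
            v = 0.0
        else:
            raise ValueError(f"compartment label must be A or B, got {iv.value!r}")
        out.append(FeatureInterval(iv.chrom, iv.start, iv.end, v))
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def nearest_event_distance(
    changepoints: Sequence, events: Sequence[FeatureInterval], layout: GenomeLayout
) -> np.ndarray:
    """Distance in bp from each changepoint interval to its nearest event.

    Overlap gives distance zero; otherwise the gap between closest edges.
    Events on other chromosomes are measured along the genome-wise [1-22,X,Y]
    concatenated coordinate — a reporting convention that can exceed any
    single chromosome's length, not a physical distance.
    """
    if not events:
        raise ValueError("no events to measure distance to")
    if not changepoints:
        raise ValueError("no changepoints")
    ev = np.array(
        [
            (layout.concat_pos(e.chrom, e.start), layout.concat_pos(e.chrom, e.end))
            for e in events
        ],
        dtype=float,
    )
    out = np.empty(len(changepoints))
    for i, cp in enumerate(changepoints):
        s = layout.concat_pos(cp.chrom, cp.start)
        e = layout.concat_pos(cp.chrom, cp.end)
        gap = np.maximum(0.0, np.maximum(ev[:, 0] - e, s - ev[:, 1]))
        out[i] = gap.min()
    return out
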