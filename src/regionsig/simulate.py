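"""Synthetic genomes with planted signature-activity regimes.

The generator mirrors the analysis model: a genome is tiled by planted
segments, each carrying an activity vector over a signature catalog, and each
mutation's channel is drawn from the segment's mixture distribution
``sum_s pi_s mu_s``.  Positions are uniform within a segment ("uniform"
density) or scaled by per-segment rate multipliers ("piecewise"), which
decouples mutation-rate changes from composition changes.  Kataegis clusters
(tight runs of channel-biased mutations) and random feature tracks can be
injected.  Everything is deterministic given the config seed.

The bundled synthetic catalog places each signature's mass mainly on one
16-channel block with a tunable uniform overlap component, so pairwise
cosine similarity is controlled (0 at ``overlap=0``); a loader for real
COSMIC-style files lives in :mod:`regionsig.io_formats`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog96 import SBS96_INDEX, channel_to_mutation_parts
from .io_formats import FeatureInterval, GenomeLayout, Mutation, chrom_rank
from .signature_model import SignatureCatalog

logger = logging.getLogger("regionsig")


def default_layout() -> GenomeLayout:
    """A compact synthetic genome: four chromosomes, 80-120 Mb."""
    return GenomeLayout(
        chroms=("1", "2", "3", "4"),
        lengths=(120_000_000, 100_000_000, 90_000_000, 80_000_000),
    )


def synthetic_catalog(n_signatures: int = 6, overlap: float = 0.3) -> SignatureCatalog:
    """Deterministic synthetic signatures over the 96 channels.

    Signature ``s`` puts ``1 - overlap`` of its mass on a private 16-channel
    block (linearly decaying within the block) and spreads ``overlap``
    uniformly over all channels.  ``overlap=0`` gives mutually orthogonal
    signatures; larger values raise pairwise cosine similarity.
    """
    if not 1 <= n_signatures <= 6:
        raise ValueError("between 1 and 6 synthetic signatures are supported")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    emissions = np.zeros((n_signatures, 96))
    for s in range(n_signatures):
        block = np.zeros(96)
        w = np.arange(16, 0, -1, dtype=float)
        block[16 * s : 16 * (s + 1)] = w / w.sum()
        emissions[s] = (1 - overlap) * block + overlap / 96.0
    names = tuple(f"SYN{i + 1}" for i in range(n_signatures))
    return SignatureCatalog(names, emissions)


@dataclass(frozen=True)
class PlantedSegment:
    """A genomic interval with a constant planted activity vector."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    activities: tuple[float, ...]
    rate: float = 1.0  # relative positional mutation rate (piecewise density)
    n_mutations: Optional[int] = None  # explicit count; else drawn from totals


@dataclass(frozen=True)
class KataegisSpec:
    """A planted hypermutation cluster."""

    chrom: str
    locus: int
    n: int = 10
    mean_gap: float = 300.0
    #: channel bias of the cluster; None uses the modal channel of the local
    #: segment's mixture so the data stay possible under the catalog
    channel: Optional[int] = None


@dataclass(frozen=True)
class FeatureSpec:
    """A random feature track: n intervals of fixed length with optional values."""

    name: str
    n_intervals: int
    interval_length: int
    kind: str = "plain"  # plain | score | ab


@dataclass(frozen=True)
class SimulationConfig:
    layout: GenomeLayout
    catalog: SignatureCatalog
    segments: tuple[PlantedSegment, ...]
    n_mutations: int = 0  # total, when segments carry no explicit counts
    density: str = "uniform"  # uniform | piecewise
    kataegis: tuple[KataegisSpec, ...] = ()
    features: tuple[FeatureSpec, ...] = ()
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.catalog.n_channels != 96:
            raise ValueError("simulation requires a 96-channel catalog")
        covered: dict[str, list[tuple[int, int]]] = {}
        for seg in self.segments:
            if len(seg.activities) != self.catalog.n_signatures:
                raise ValueError("segment activity length does not match catalog")
            covered.setdefault(seg.chrom, []).append((seg.start, seg.end))
        for chrom, spans in covered.items():
            spans.sort()
            if spans[0][0] != 0 or spans[-1][1] != self.layout.length_of(chrom):
                raise ValueError(f"planted segments do not tile chromosome {chrom}")
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if e0 != s1:
                    raise ValueError(f"planted segments have a gap/overlap on chromosome {chrom}")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: changepoints, activities, kataegis, feature tracks."""

    changepoints: tuple[tuple[str, int], ...]  # (chrom, boundary position)
    segment_activities: tuple[tuple[float, ...], ...]
    kataegis: tuple[tuple[str, int, int, int], ...]  # (chrom, start, end, n)
    feature_tracks: dict[str, tuple[FeatureInterval, ...]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "changepoints": [list(cp) for cp in self.changepoints],
            "segment_activities": [list(a) for a in self.segment_activities],
            "kataegis": [list(k) for k in self.kataegis],
            "feature_tracks": {
                name: [[iv.chrom, iv.start, iv.end, iv.value] for iv in track]
                for name, track in self.feature_tracks.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


_DEFAULT_KATAEGIS_CHANNEL = SBS96_INDEX["T[C>T]A"]


def _simulate_features(
    specs: Sequence[FeatureSpec], layout: GenomeLayout, rng: np.random.Generator
) -> dict[str, tuple[FeatureInterval, ...]]:
    tracks: dict[str, tuple[FeatureInterval, ...]] = {}
    for spec in specs:
        ivs = []
        probs = np.array(layout.lengths, dtype=float)
        probs /= probs.sum()
        for _ in range(spec.n_intervals):
            chrom = layout.chroms[rng.choice(len(layout.chroms), p=probs)]
            L = layout.length_of(chrom)
            start = int(rng.integers(0, max(1, L - spec.interval_length)))
            value: Optional[object] = None
            if spec.kind == "score":
                value = float(rng.normal())
            elif spec.kind == "ab":
                value = "A" if rng.random() < 0.5 else "B"
            ivs.append(FeatureInterval(chrom, start, start + spec.interval_length, value))
        ivs.sort(key=lambda iv: (chrom_rank(iv.chrom), iv.start))
        tracks[spec.name] = tuple(ivs)
    return tracks


def simulate_sample(config: SimulationConfig) -> tuple[list[Mutation], GroundTruth]:
    """Emit a mutation list and the ground truth behind it."""
    rng = np.random.default_rng(config.seed)
    segments = sorted(config.segments, key=lambda s: (chrom_rank(s.chrom), s.start))

    explicit = [s.n_mutations for s in segments]
    if all(n is not None for n in explicit):
        seg_counts = [int(n) for n in explicit]
    else:
        if config.n_mutations < 1:
            raise ValueError("n_mutations must be set when segments carry no explicit counts")
        weights = np.array(
            [
                (s.end - s.start) * (s.rate if config.density == "piecewise" else 1.0)
                for s in segments
            ],
            dtype=float,
        )
        seg_counts = rng.multinomial(config.n_mutations, weights / weights.sum()).tolist()

    mutations: list[Mutation] = []
    for seg, n in zip(segments, seg_counts):
        if n < 1:
            logger.warning("planted segment %s:%d-%d receives no mutations", seg.chrom, seg.start, seg.end)
            continue
        mix = np.asarray(seg.activities) @ config.catalog.emissions
        mix = mix / mix.sum()
        positions = np.sort(rng.integers(seg.start + 1, seg.end + 1, size=n))
        channels = rng.choice(96, size=n, p=mix)
        for pos, ch in zip(positions, channels):
            ctx, ref, alt = channel_to_mutation_parts(int(ch))
            mutations.append(Mutation(config.sample_id, seg.chrom, int(pos), ref, alt, ctx))

    kataegis_truth = []
    for spec in config.kataegis:
        gaps = np.maximum(1, rng.poisson(spec.mean_gap, size=spec.n - 1))
        positions = spec.locus + np.concatenate([[0], np.cumsum(gaps)])
        if spec.channel is not None:
            ch = spec.channel
        else:
            host = next(
                (s for s in segments if s.chrom == spec.chrom and s.start <= spec.locus < s.end),
                None,
            )
            if host is not None:
                ch = int(np.argmax(np.asarray(host.activities) @ config.catalog.emissions))
            else:
                ch = _DEFAULT_KATAEGIS_CHANNEL
        ctx, ref, alt = channel_to_mutation_parts(ch)
        for pos in positions:
            mutations.append(Mutation(config.sample_id, spec.chrom, int(pos), ref, alt, ctx))
        kataegis_truth.append((spec.chrom, int(positions[0]), int(positions[-1]), spec.n))

    mutations.sort(key=lambda m: (chrom_rank(m.chrom), m.pos))

    changepoints = []
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and tuple(a.activities) != tuple(b.activities):
            changepoints.append((a.chrom, a.end))
    truth = GroundTruth(
        changepoints=tuple(changepoints),
        segment_activities=tuple(tuple(s.activities) for s in segments),
        kataegis=tuple(kataegis_truth),
        feature_tracks=_simulate_features(config.features, config.layout, rng),
    )
    return mutations, truth


def planted_switch_config(
    catalog: SignatureCatalog,
    left_activities: Sequence[float],
    right_activities: Sequence[float],
    n_left: int,
    n_right: int,
    chrom: str = "1",
    chrom_length: int = 100_000_000,
    seed: int = 0,
    sample_id: str = "sim",
    kataegis: tuple[KataegisSpec, ...] = (),
    features: tuple[FeatureSpec, ...] = (),
) -> SimulationConfig:
    """One chromosome, two planted regimes switching at the midpoint."""
    layout = GenomeLayout(chroms=(chrom,), lengths=(chrom_length,))
    half = chrom_length // 2
    return SimulationConfig(
        layout=layout,
        catalog=catalog,
        segments=(
            PlantedSegment(chrom, 0, half, tuple(left_activities), n_mutations=n_left),
            PlantedSegment(chrom, half, chrom_length, tuple(right_activities), n_mutations=n_right),
        ),
        kataegis=kataegis,
        features=features,
        seed=seed,
        sample_id=sample_id,
    )


def constant_config(
    catalog: SignatureCatalog,
    activities: Sequence[float],
    n_mutations: int,
    chrom: str = "1",
    chrom_length: int = 100_000_000,
    seed: int = 0,
    sample_id: str = "sim",
) -> SimulationConfig:
    """One chromosome with a single constant-activity regime (null control)."""
    layout = GenomeLayout(chroms=(chrom,), lengths=(chrom_length,))
    return SimulationConfig(
        layout=layout,
        catalog=catalog,
        segments=(PlantedSegment(chrom, 0, chrom_length, tuple(activities), n_mutations=n_mutations),),
        seed=seed,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryStats:
    precision: float
    recall: float
    n_matched: int
    n_detected: int
    n_true: int
    boundary_errors_bp: tuple[float, ...]
    precision_defined: bool  # False when nothing was detected (precision reported 1)


def evaluate_recovery(
    truth: GroundTruth,
    changepoints: Sequence,
    layout: GenomeLayout,
    tolerance_bp: float,
) -> RecoveryStats:
    """Precision/recall of detected changepoints against the planted truth.

    A detection (interval midpoint) matches a planted boundary when their
    genome-wise concatenated distance is within the tolerance; matching is the
    optimal one-to-one assignment.  With no detections, recall is 0 and
    precision is reported as 1 by convention, flagged via
    ``precision_defined``.
    """
    from scipy.optimize import linear_sum_assignment

    true_pos = [layout.concat_pos(c, p) for c, p in truth.changepoints]
    det_pos = [layout.concat_pos(cp.chrom, 0.5 * (cp.start + cp.end)) for cp in changepoints]
    n_true, n_det = len(true_pos), len(det_pos)
    if n_det == 0:
        return RecoveryStats(1.0, 0.0 if n_true else 1.0, 0, 0, n_true, (), precision_defined=False)
    if n_true == 0:
        return RecoveryStats(0.0, 1.0, 0, n_det, 0, (), precision_defined=True)
    dist = np.abs(np.subtract.outer(np.array(true_pos, dtype=float), np.array(det_pos, dtype=float)))
    big = 10 * (dist.max() + tolerance_bp + 1)
    cost = np.where(dist <= tolerance_bp, dist, big)
    rows, cols = linear_sum_assignment(cost)
    matched = [(r, c) for r, c in zip(rows, cols) if dist[r, c] <= tolerance_bp]
    errors = tuple(float(dist[r, c]) for r, c in matched)
    n_match = len(matched)
    return RecoveryStats(
        precision=n_match / n_det,
        recall=n_match / n_true,
        n_matched=n_match,
        n_detected=n_det,
        n_true=n_true,
        boundary_errors_bp=errors,
        precision_defined=True,
    )
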