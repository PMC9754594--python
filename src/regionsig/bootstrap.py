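"""Bootstrap confidence in changepoint placement, and cohort resampling robustness.

Within-bin resampling keeps the bin boundaries (and hence per-bin mutation
counts) fixed and redraws each bin's channel counts with replacement —
a multinomial redraw of the bin's channel histogram, which is exactly
equivalent to resampling the bin's mutations with replacement.  The full
segmentation is re-run on every replicate and a baseline changepoint's
support is the fraction of replicates that place a changepoint within one bin
of it.  A changepoint found in more than one bootstrap replicate is flagged
high-confidence.

All replicate randomness derives from a single user seed through a
counter-based scheme (``default_rng([seed, replicate_index])``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .catalog96 import BinSeries
from .segmentation import Changepoint, ProfileResult, SignatureCatalog, segment_series

logger = logging.getLogger("regionsig")

#: Bin-index tolerance for deciding two runs found "the same" changepoint.
MATCH_TOLERANCE_BINS = 1


def resample_series(series: BinSeries, rng: np.random.Generator) -> BinSeries:
    """Resample each bin's mutations with replacement; spans and sizes unchanged."""
    new_bins = []
    for b in series.bins:
        p = b.counts / b.n_mutations
        new_counts = rng.multinomial(b.n_mutations, p)
        new_bins.append(replace(b, counts=new_counts.astype(np.int64)))
    return replace(series, bins=tuple(new_bins))


@dataclass(frozen=True)
class BootstrapReport:
    """Per-changepoint bootstrap support for one sample's profile."""

    sample_id: str
    n_bootstraps: int
    seed: int
    changepoints: tuple[Changepoint, ...]  # baseline changepoints with support filled
    replicate_boundaries: tuple[tuple[int, ...], ...]  # boundaries found per replicate
    #: per baseline changepoint: genomic midpoints of the matched replicate
    #: changepoints (plus the baseline's own midpoint) — location evidence for
    #: the recurrence module's kernel density ranges
    changepoint_locations: tuple[tuple[float, ...], ...]


def _midpoint(cp: Changepoint) -> float:
    return 0.5 * (cp.start + cp.end)


def bootstrap_profile(
    baseline: ProfileResult,
    catalog: SignatureCatalog,
    n_bootstraps: int = 5,
    seed: int = 0,
    tolerance_bins: int = MATCH_TOLERANCE_BINS,
) -> BootstrapReport:
    """Quantify placement confidence of a profile's changepoints by resampling."""
    if n_bootstraps < 1:
        raise ValueError("need at least one bootstrap replicate")
    base_cps = baseline.changepoints
    match_counts = np.zeros(len(base_cps), dtype=int)
    locations: list[list[float]] = [[_midpoint(cp)] for cp in base_cps]
    rep_bounds: list[tuple[int, ...]] = []
    for r in range(n_bootstraps):
        rng = np.random.default_rng([seed, r])
        rep = segment_series(
            resample_series(baseline.series, rng), catalog, penalty_scale=baseline.penalty_scale
        )
        bounds = tuple(cp.boundary for cp in rep.changepoints)
        rep_bounds.append(bounds)
        for i, cp in enumerate(base_cps):
            hits = [rc for rc in rep.changepoints if abs(rc.boundary - cp.boundary) <= tolerance_bins]
            if hits:
                match_counts[i] += 1
                nearest = min(hits, key=lambda rc: abs(rc.boundary - cp.boundary))
                locations[i].append(_midpoint(nearest))
    annotated = tuple(
        replace(cp, support=match_counts[i] / n_bootstraps, high_confidence=bool(match_counts[i] > 1))
        for i, cp in enumerate(base_cps)
    )
    return BootstrapReport(
        sample_id=baseline.sample_id,
        n_bootstraps=n_bootstraps,
        seed=seed,
        changepoints=annotated,
        replicate_boundaries=tuple(rep_bounds),
        changepoint_locations=tuple(tuple(v) for v in locations),
    )


def write_bootstrap_table(report: BootstrapReport, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "boundary": [cp.boundary for cp in report.changepoints],
            "chrom": [cp.chrom for cp in report.changepoints],
            "start": [cp.start for cp in report.changepoints],
            "end": [cp.end for cp in report.changepoints],
            "support": [cp.support for cp in report.changepoints],
            "high_confidence": [cp.high_confidence for cp in report.changepoints],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohort resampling robustness
# ---------------------------------------------------------------------------

def resample_robustness(
    profiles: dict[str, ProfileResult],
    catalog: SignatureCatalog,
    n_resamples: int = 20,
    threshold: int = 7,
    window: int = 1_000_000,
    step: int = 500_000,
    seed: int = 0,
    tolerance_bins: int = MATCH_TOLERANCE_BINS,
    identity: bool = False,
):
    """Recovery of a cohort's recurrent changepoints under within-bin resampling.

    For every sample, ``n_resamples`` resampled profiles are built with the
    same bin layout and re-segmented.  Returns two tables mirroring a
    tissue-level and a sample-level view:

    * ``region_table`` — one row per baseline recurrent region, with how many
      distinct samples' resampled profiles recover it and whether it stays
      recurrent (>= ``threshold`` samples).
    * ``sample_table`` — one row per (sample, baseline changepoint) with the
      fraction of that sample's resampled profiles recovering it.

    ``identity=True`` disables the resampling (each replicate is the original
    series), a degenerate control under which recovery is total.  Returns
    empty tables with a notice when the cohort has no recurrent changepoints.
    """
    import pandas as pd

    from .recurrence import changepoint_range, find_recurrent_regions

    ranges = []
    for sid, prof in profiles.items():
        for k, cp in enumerate(prof.changepoints):
            ranges.append(
                changepoint_range(
                    chrom=cp.chrom,
                    locations=[0.5 * (cp.start + cp.end)],
                    fallback_span=(cp.start, cp.end),
                    sample_id=sid,
                    source=k,
                )
            )
    regions = find_recurrent_regions(ranges, window_size=window, step=step, threshold=threshold)
    if not regions:
        logger.warning("cohort has no recurrent changepoints; robustness report is empty")
        return pd.DataFrame(), pd.DataFrame()

    # resample every profile
    resampled: dict[str, list] = {}
    for si, (sid, prof) in enumerate(sorted(profiles.items())):
        reps = []
        for r in range(n_resamples):
            if identity:
                series = prof.series
            else:
                rng = np.random.default_rng([seed, si, r])
                series = resample_series(prof.series, rng)
            reps.append(segment_series(series, catalog, penalty_scale=prof.penalty_scale))
        resampled[sid] = reps

    region_rows = []
    for reg in regions:
        recovering = set()
        for sid, reps in resampled.items():
            for rep in reps:
                if any(
                    cp.chrom == reg.chrom and cp.start < reg.region_end and reg.region_start < cp.end
                    for cp in rep.changepoints
                ):
                    recovering.add(sid)
                    break
        region_rows.append(
            {
                "chrom": reg.chrom,
                "region_start": reg.region_start,
                "region_end": reg.region_end,
                "n_samples_original": reg.n_samples,
                "n_samples_resampled": len(recovering),
                "recovered_recurrent": len(recovering) >= threshold,
            }
        )

    sample_rows = []
    for sid, prof in sorted(profiles.items()):
        for cp in prof.changepoints:
            hits = sum(
                any(abs(rc.boundary - cp.boundary) <= tolerance_bins for rc in rep.changepoints)
                for rep in resampled[sid]
            )
            sample_rows.append(
                {
                    "sample_id": sid,
                    "boundary": cp.boundary,
                    "chrom": cp.chrom,
                    "start": cp.start,
                    "end": cp.end,
                    "recovery_fraction": hits / n_resamples,
                }
            )
    return pd.DataFrame(region_rows), pd.DataFrame(sample_rows)
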