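"""Randomization tests of changepoint association with genomic features.

Two frameworks:

1. **Overlap test** — does a larger-than-random proportion of a sample's
   changepoints overlap a discrete feature (CNAs, kataegis, TAD boundaries)?
   The null draws random changepoint sets of the same cardinality from the
   profile's admissible bin boundaries (non-adjacent, without replacement) and
   compares overlap proportions.

2. **Flank test** — does a feature's distribution differ between the
   changepoint-containing segment and an equal-width upstream/downstream
   segment?  The inner comparison is Fisher's exact test for count features
   and a two-sided Kolmogorov-Smirnov test for continuous ones; its p-value
   is referred to an empirical null of inner p-values from random
   (changepoint, partner) boundary pairs separated by at least one bin.

Empirical p-values use the add-one correction (never exactly zero); the plain
proportion is available with ``add_one=False``.  Per-changepoint results are
reported raw at alpha = 0.05; a Benjamini-Hochberg column is emitted in the
table writer for convenience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact, ks_2samp

from .catalog96 import BinSeries
from .io_formats import FeatureInterval, GenomeLayout
from .segmentation import Changepoint, _cp_interval

logger = logging.getLogger("regionsig")

DEFAULT_N_NULL = 10_000
DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Boundary machinery shared by both tests
# ---------------------------------------------------------------------------

def admissible_boundaries(bins: BinSeries) -> np.ndarray:
    """Bin boundaries where a changepoint could sit in this profile.

    All interior boundaries in genome-wise mode; in chromosome-wise mode only
    boundaries interior to a chromosome (chromosome edges are never
    changepoints).
    """
    B = len(bins)
    bounds = np.arange(1, B)
    if bins.mode == "chromosome_wise":
        keep = [
            b
            for b in bounds
            if bins.bins[b - 1].chrom_start == bins.bins[b].chrom_start
        ]
        bounds = np.array(keep, dtype=int)
    return bounds


def boundary_interval(bins: BinSeries, b: int) -> tuple[str, int, int]:
    """Genomic interval attributed to a changepoint at boundary b."""
    return _cp_interval(bins.bins[b - 1], bins.bins[b])


def sample_nonadjacent_boundaries(
    admissible: np.ndarray, m: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_sets`` random changepoint sets of size m (boundaries >= 2 apart).

    When the admissible set is the contiguous range 1..B-1 the draw is an
    exact uniform over all admissible sets via the standard combinatorial
    bijection (choose m of B-1-m+1, then spread).  Otherwise rejection
    sampling is used.
    """
    adm = np.sort(np.asarray(admissible))
    n_adm = adm.size
    contiguous = n_adm > 0 and adm[-1] - adm[0] == n_adm - 1
    max_m = (n_adm + 1) // 2
    if m > max_m:
        raise ValueError(
            f"cannot place {m} non-adjacent changepoints among {n_adm} admissible boundaries"
        )
    out = np.empty((n_sets, m), dtype=int)
    if contiguous:
        lo = adm[0]
        for i in range(n_sets):
            c = np.sort(rng.choice(n_adm - m + 1, size=m, replace=False))
            out[i] = lo + c + np.arange(m)
    else:
        for i in range(n_sets):
            for _ in range(100_000):
                pick = np.sort(rng.choice(adm, size=m, replace=False))
                if m == 1 or np.all(np.diff(pick) >= 2):
                    out[i] = pick
                    break
            else:
                raise RuntimeError("rejection sampling of non-adjacent boundaries failed")
    return out


def _feature_overlap_fn(feature: Sequence[FeatureInterval]):
    """Fast interval-overlap query against a feature track."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv in feature}:
        ivs = sorted((iv for iv in feature if iv.chrom == chrom), key=lambda x: x.start)
        starts = np.array([iv.start for iv in ivs])
        # running max of ends makes the "any interval reaches past x" query sound
        ends = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
        by_chrom[chrom] = (starts, ends)

    def overlaps(chrom: str, start: float, end: float) -> bool:
        if chrom not in by_chrom:
            return False
        starts, ends = by_chrom[chrom]
        i = int(np.searchsorted(starts, end, side="left"))  # intervals starting before `end`
        return i > 0 and ends[i - 1] > start

    return overlaps


# ---------------------------------------------------------------------------
# Overlap test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTestResult:
    sample_id: str
    feature_name: str
    observed_proportion: float
    n_null: int
    p_value: float
    significant: bool
    alpha: float


def overlap_test(
    changepoints: Sequence[Changepoint],
    feature: Sequence[FeatureInterval],
    bins: BinSeries,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    add_one: bool = True,
    feature_name: str = "feature",
) -> OverlapTestResult:
    """Test whether changepoints overlap a discrete feature more than expected.

    A changepoint overlaps the feature when any part of its genomic interval
    intersects any feature interval.  The p-value is the (add-one corrected)
    fraction of null overlap proportions at least as large as the observed.
    """
    if not changepoints:
        raise ValueError("need at least one changepoint")
    rng = np.random.default_rng(seed)
    overlaps = _feature_overlap_fn(feature)
    observed = float(
        np.mean([overlaps(cp.chrom, cp.start, cp.end) for cp in changepoints])
    )
    adm = admissible_boundaries(bins)
    indicator = {
        int(b): overlaps(*boundary_interval(bins, int(b))) for b in adm
    }
    m = len(changepoints)
    null_sets = sample_nonadjacent_boundaries(adm, m, n_null, rng)
    null_props = np.array(
        [np.mean([indicator[int(b)] for b in row]) for row in null_sets]
    )
    ge = int(np.sum(null_props >= observed - 1e-12))
    p = (1 + ge) / (n_null + 1) if add_one else max(ge, 0) / n_null
    return OverlapTestResult(
        sample_id=bins.sample_id,
        feature_name=feature_name,
        observed_proportion=observed,
        n_null=n_null,
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Flank test
# ---------------------------------------------------------------------------

def flank_segments(
    cp_mid: float, anchor_mid: float, chrom_length: Optional[int] = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Changepoint-containing and flank segments for one direction.

    With ``m`` the midpoint of the changepoint centre and the anchor centre
    (next changepoint, or the chromosome boundary when none), both segments
    have width ``|cp_mid - m|``: the changepoint segment is centred on the
    changepoint and the flank segment on the anchor.  Segments are clipped to
    chromosome bounds (logged).
    """
    m = 0.5 * (cp_mid + anchor_mid)
    w = abs(cp_mid - m)
    if w == 0:
        raise ValueError("coincident changepoint and anchor give a zero-width segment")
    cp_seg = (cp_mid - w / 2, cp_mid + w / 2)
    fl_seg = (anchor_mid - w / 2, anchor_mid + w / 2)

    def clip(seg):
        lo, hi = seg
        lo2 = max(0.0, lo)
        hi2 = min(float(chrom_length), hi) if chrom_length is not None else hi
        if (lo2, hi2) != (lo, hi):
            logger.debug("flank segment clipped to chromosome bounds: %s -> %s", seg, (lo2, hi2))
        return (lo2, hi2)

    return clip(cp_seg), clip(fl_seg)


@dataclass(frozen=True)
class FlankTestResult:
    boundary: int
    feature_name: str
    p_cd: Optional[float]  # inner p-value, downstream direction
    p_cu: Optional[float]  # inner p-value, upstream direction
    emp_p_down: Optional[float]
    emp_p_up: Optional[float]
    significant_downstream: bool
    significant_upstream: bool
    n_null: int
    alpha: float

    @property
    def significant_any(self) -> bool:
        return self.significant_downstream or self.significant_upstream


class _SegmentFeature:
    """Feature summaries over arbitrary genomic segments of one chromosome."""

    def __init__(self, feature: Sequence[FeatureInterval], kind: str, window: int = 1_000_000):
        if kind not in ("counts", "continuous"):
            raise ValueError("feature_kind must be 'counts' or 'continuous'")
        self.kind = kind
        self.window = window
        self.by_chrom: dict[str, list[FeatureInterval]] = {}
        for iv in feature:
            self.by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in self.by_chrom.values():
            ivs.sort(key=lambda x: x.start)

    def _overlapping(self, chrom: str, lo: float, hi: float) -> list[FeatureInterval]:
        return [iv for iv in self.by_chrom.get(chrom, ()) if iv.start < hi and lo < iv.end]

    def counts_row(self, chrom: str, lo: float, hi: float) -> Optional[tuple[int, int]]:
        """(events, windows-without-events) over the segment's tiling windows."""
        k_lo = int(lo // self.window)
        k_hi = int(-(-hi // self.window))
        n_windows = k_hi - k_lo
        if n_windows <= 0:
            return None
        events = self._overlapping(chrom, lo, hi)
        per_window = np.zeros(n_windows, dtype=int)
        for iv in events:
            a = max(k_lo, int(iv.start // self.window)) - k_lo
            b = min(k_hi - 1, int((iv.end - 1) // self.window)) - k_lo
            per_window[a] += 1  # an event is charged to the window of its start
        return int(per_window.sum()), int(np.sum(per_window == 0))

    def values(self, chrom: str, lo: float, hi: float) -> np.ndarray:
        return np.array(
            [float(iv.value) for iv in self._overlapping(chrom, lo, hi) if iv.value is not None]
        )


def _inner_test(seg_feat: _SegmentFeature, chrom: str, cp_seg, fl_seg) -> Optional[float]:
    if seg_feat.kind == "counts":
        row_c = seg_feat.counts_row(chrom, *cp_seg)
        row_f = seg_feat.counts_row(chrom, *fl_seg)
        if row_c is None or row_f is None:
            return None
        table = [[row_c[0], row_c[1]], [row_f[0], row_f[1]]]
        if (row_c[0] + row_f[0]) == 0 and (row_c[1] + row_f[1]) == 0:
            return None
        return float(fisher_exact(table, alternative="two-sided")[1])
    a = seg_feat.values(chrom, *cp_seg)
    b = seg_feat.values(chrom, *fl_seg)
    if a.size == 0 or b.size == 0:
        return None
    return float(ks_2samp(a, b, alternative="two-sided").pvalue)


def _boundary_mid(bins: BinSeries, b: int) -> tuple[str, float]:
    chrom, start, end = boundary_interval(bins, b)
    return chrom, 0.5 * (start + end)


def flank_test(
    changepoint: Changepoint,
    all_changepoints: Sequence[Changepoint],
    feature: Sequence[FeatureInterval],
    feature_kind: str,
    bins: BinSeries,
    layout: GenomeLayout,
    n_null: int = DEFAULT_N_NULL,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    window: int = 1_000_000,
    add_one: bool = True,
    feature_name: str = "feature",
) -> FlankTestResult:
    """Compare a feature's distribution across a changepoint against its flanks.

    For each direction the anchor is the nearest changepoint on the same
    chromosome, or the chromosome boundary when none exists.  The observed
    inner p-value is referred to an empirical null built from random
    (changepoint, partner) boundary pairs drawn from the profile's bins with
    at least one bin separating the pair; a direction is significant when the
    observed inner p-value ranks below ``alpha`` in that null.
    """
    seg_feat = _SegmentFeature(feature, feature_kind, window=window)
    chrom = changepoint.chrom
    L = layout.length_of(chrom)
    cp_mid = 0.5 * (changepoint.start + changepoint.end)

    same_chrom = sorted(
        (0.5 * (c.start + c.end) for c in all_changepoints if c.chrom == chrom and c is not changepoint)
    )
    down_anchor = next((m for m in same_chrom if m > cp_mid), float(L))
    up_anchor = next((m for m in reversed(same_chrom) if m < cp_mid), 0.0)

    p_obs: dict[str, Optional[float]] = {}
    for direction, anchor in (("down", down_anchor), ("up", up_anchor)):
        try:
            cp_seg, fl_seg = flank_segments(cp_mid, anchor, L)
        except ValueError:
            p_obs[direction] = None
            continue
        p = _inner_test(seg_feat, chrom, cp_seg, fl_seg)
        if p is None:
            logger.warning(
                "flank test (%s, boundary %d, %s): segment without feature windows; skipped",
                feature_name,
                changepoint.boundary,
                direction,
            )
        p_obs[direction] = p

    # empirical null of inner p-values from random boundary pairs
    rng = np.random.default_rng(seed)
    adm = admissible_boundaries(bins)
    pairs = []
    same_chrom_pairs = [
        (int(b1), int(b2))
        for i, b1 in enumerate(adm)
        for b2 in adm[i + 1 :]
        if b2 - b1 >= 2 and _boundary_mid(bins, int(b1))[0] == _boundary_mid(bins, int(b2))[0]
    ]
    null_p: list[float] = []
    if same_chrom_pairs:
        idx = rng.integers(0, len(same_chrom_pairs), size=n_null)
        mid_cache = {int(b): _boundary_mid(bins, int(b)) for b in adm}
        inner_cache: dict[tuple[int, int], Optional[float]] = {}
        for i in idx:
            pair = same_chrom_pairs[int(i)]
            if pair not in inner_cache:
                (c1, m1), (_, m2) = mid_cache[pair[0]], mid_cache[pair[1]]
                try:
                    cp_seg, fl_seg = flank_segments(m1, m2, layout.length_of(c1))
                    inner_cache[pair] = _inner_test(seg_feat, c1, cp_seg, fl_seg)
                except ValueError:
                    inner_cache[pair] = None
            if inner_cache[pair] is not None:
                null_p.append(inner_cache[pair])
    null_arr = np.array(null_p)

    def empirical(p: Optional[float]) -> Optional[float]:
        if p is None or null_arr.size == 0:
            return None
        # relative tolerance: p-values span many orders of magnitude
        le = int(np.sum(null_arr <= p * (1 + 1e-9)))
        return (1 + le) / (null_arr.size + 1) if add_one else le / null_arr.size

    emp_down = empirical(p_obs["down"])
    emp_up = empirical(p_obs["up"])
    return FlankTestResult(
        boundary=changepoint.boundary,
        feature_name=feature_name,
        p_cd=p_obs["down"],
        p_cu=p_obs["up"],
        emp_p_down=emp_down,
        emp_p_up=emp_up,
        significant_downstream=bool(emp_down is not None and emp_down < alpha),
        significant_upstream=bool(emp_up is not None and emp_up < alpha),
        n_null=n_null,
        alpha=alpha,
    )


def write_flank_table(results: Sequence[FlankTestResult], path) -> None:
    """Per-changepoint flank-test TSV with a Benjamini-Hochberg column."""
    import pandas as pd
    from scipy.stats import false_discovery_control

    df = pd.DataFrame(
        {
            "boundary": [r.boundary for r in results],
            "feature": [r.feature_name for r in results],
            "p_cd": [r.p_cd for r in results],
            "p_cu": [r.p_cu for r in results],
            "emp_p_down": [r.emp_p_down for r in results],
            "emp_p_up": [r.emp_p_up for r in results],
            "significant_downstream": [r.significant_downstream for r in results],
            "significant_upstream": [r.significant_upstream for r in results],
            "significant_any": [r.significant_any for r in results],
        }
    )
    best = df[["emp_p_down", "emp_p_up"]].min(axis=1)
    mask = best.notna()
    df["bh_adjusted"] = np.nan
    if mask.any():
        df.loc[mask, "bh_adjusted"] = false_discovery_control(best[mask].to_numpy(), method="bh")
    df.to_csv(path, sep="\t", index=False)
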