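"""Multinomial-mixture model of mutation channels.

A segment's channel counts are modelled as draws from a mixture
``p(k) = sum_s pi_s mu_s[k]`` where each mutational signature contributes a
fixed emission distribution ``mu_s`` over the channels and the mixture
coefficients ``pi`` are the signature activities (exposures).  With the
emissions fixed, the log-likelihood is concave in ``pi`` and EM from a uniform
start converges to the maximiser.  The multinomial coefficient is constant in
``pi`` and omitted throughout; channel counts are sufficient statistics, so
the per-mutation one-hot representation is collapsed to counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("regionsig")

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SignatureCatalog:
    """Reference signatures: S emission distributions over K channels (K=96 normally)."""

    names: tuple[str, ...]
    emissions: np.ndarray  # S x K

    def __post_init__(self) -> None:
        emissions = np.asarray(self.emissions, dtype=float)
        object.__setattr__(self, "emissions", emissions)
        if emissions.ndim != 2 or emissions.shape[0] != len(self.names):
            raise ValueError("emissions must be S x K with one row per signature name")
        if (emissions < 0).any():
            raise ValueError("emission probabilities must be non-negative")
        sums = emissions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _ROW_SUM_TOL):
            raise ValueError("each signature row must sum to 1 (use .normalized())")

    @classmethod
    def normalized(cls, names: Sequence[str], emissions: np.ndarray) -> "SignatureCatalog":
        emissions = np.asarray(emissions, dtype=float)
        sums = emissions.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("a signature row sums to zero")
        return cls(tuple(names), emissions / sums)

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    @property
    def n_channels(self) -> int:
        return self.emissions.shape[1]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(tuple(names), self.emissions[idx])


@dataclass(frozen=True)
class ActivityVector:
    """Signature activities (mixture coefficients) fitted on one segment."""

    activities: np.ndarray  # length S, sums to 1
    n_mutations: int

    def __post_init__(self) -> None:
        a = np.asarray(self.activities, dtype=float)
        object.__setattr__(self, "activities", a)
        if (a < -1e-12).any():
            raise ValueError("activities must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("activities must sum to 1")


@dataclass(frozen=True)
class EMResult:
    activity: ActivityVector
    log_likelihood: float
    n_iterations: int
    converged: bool


def log_likelihood(counts: np.ndarray, catalog: SignatureCatalog, activity: ActivityVector) -> float:
    """Categorical log-likelihood ``sum_k counts[k] log(sum_s pi_s mu_s[k])``.

    Returns -inf (with a warning) when a channel with positive count has zero
    mixture probability.
    """
    counts = np.asarray(counts, dtype=float)
    p = activity.activities @ catalog.emissions
    pos = counts > 0
    if np.any(p[pos] <= 0):
        logger.warning("zero mixture probability on a populated channel; log-likelihood is -inf")
        return float("-inf")
    return float(counts[pos] @ np.log(p[pos]))


def em_fit(
    counts: np.ndarray,
    catalog: SignatureCatalog,
    init: Optional[ActivityVector] = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> EMResult:
    """Fit signature activities on pooled channel counts by EM.

    E-step: responsibility of signature s for channel k is
    ``pi_s mu_s[k] / sum_t pi_t mu_t[k]``.  M-step: ``pi_s`` becomes the
    count-weighted mean responsibility.  Iteration stops when the
    log-likelihood improves by less than ``tol``.  The log-likelihood is
    non-decreasing across iterations (standard EM guarantee; asserted).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one mutation to fit activities")
    mu = catalog.emissions  # S x K
    S = catalog.n_signatures
    pos = counts > 0
    if np.any(mu[:, pos].sum(axis=0) <= 0):
        raise ValueError("a populated channel has zero probability under every signature")

    pi = np.full(S, 1.0 / S) if init is None else init.activities.copy()
    mu_pos = mu[:, pos]  # S x K+
    c_pos = counts[pos]

    def ll(pi_vec: np.ndarray) -> float:
        p = pi_vec @ mu_pos
        if np.any(p <= 0):
            return float("-inf")
        return float(c_pos @ np.log(p))

    prev = ll(pi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = pi @ mu_pos  # mixture probability per populated channel
        # E-step responsibilities folded directly into the M-step update
        resp_weighted = (pi[:, None] * mu_pos) / p[None, :]  # S x K+
        pi = (resp_weighted @ c_pos) / n
        cur = ll(pi)
        assert cur >= prev - 1e-8, "EM log-likelihood decreased"
        if cur - prev < tol:
            prev = cur
            converged = True
            break
        prev = cur
    return EMResult(
        activity=ActivityVector(pi / pi.sum(), int(round(n))),
        log_likelihood=prev,
        n_iterations=it,
        converged=converged,
    )


def changepoint_magnitude(left: ActivityVector, right: ActivityVector) -> float:
    """Cosine distance ``1 - cos(left, right)`` between flanking activity vectors."""
    a, b = left.activities, right.activities
    if a.shape != b.shape:
        raise ValueError("activity vectors have different lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("activity vector is all-zero")
    return float(1.0 - (a @ b) / (na * nb))


def select_active_signatures(
    counts_total: np.ndarray,
    catalog: SignatureCatalog,
    threshold: float = 0.05,
    active_names: Optional[Sequence[str]] = None,
) -> SignatureCatalog:
    """Restrict the catalog to signatures active in the sample.

    Fits the full catalog on the pooled sample counts and keeps signatures
    whose fitted activity is at least ``threshold`` (default 5%).  An explicit
    ``active_names`` list (e.g. a per-tissue lookup) bypasses the fit.
    """
    if active_names is not None:
        return catalog.subset(active_names)
    res = em_fit(counts_total, catalog)
    keep = [n for n, a in zip(catalog.names, res.activity.activities) if a >= threshold]
    if not keep:
        raise ValueError("no signature reaches the activity threshold; lower the threshold")
    return catalog.subset(keep)


def write_activity_table(segments, catalog: SignatureCatalog, path) -> None:
    """Activity TSV: one row per segment with per-signature activities."""
    import pandas as pd

    rows = []
    for seg in segments:
        row = {
            "segment_id": seg.segment_id,
            "start_bin": seg.start_bin,
            "end_bin": seg.end_bin,
            "chrom_start": seg.chrom_start,
            "pos_start": seg.pos_start,
            "chrom_end": seg.chrom_end,
            "pos_end": seg.pos_end,
            "log_likelihood": seg.log_likelihood,
        }
        row.update({n: a for n, a in zip(catalog.names, seg.activity.activities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
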