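"""SBS96 channel classification and equal-count genomic binning.

The 96 single-base-substitution channels combine one of six pyrimidine-
referenced substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) with the 5'
and 3' flanking bases, each in (A, C, G, T) order.  Mutations whose reference
base is a purine are strand-flipped (reverse complement of context, complement
of alt) before lookup, so classification is strand-involutive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_formats import Mutation, chrom_rank, revcomp

logger = logging.getLogger("regionsig")

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def _build_labels() -> tuple[str, ...]:
    labels = []
    for sub in _SUBSTITUTIONS:
        for five in _BASES:
            for three in _BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: The 96 canonical channel labels in canonical order.
SBS96_LABELS: tuple[str, ...] = _build_labels()
SBS96_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(SBS96_LABELS)}


def classify_sbs96(mutation: Mutation) -> int:
    """Channel index (0-95) of a mutation; requires a valid trinucleotide context."""
    if mutation.context is None:
        raise ValueError("mutation has no trinucleotide context")
    ctx = mutation.context.upper()
    alt = mutation.alt
    if "N" in ctx:
        raise ValueError(f"ambiguous context {ctx!r}")
    if ctx[1] in "AG":  # purine reference: flip to the pyrimidine strand
        ctx = revcomp(ctx)
        alt = revcomp(alt)
    label = f"{ctx[0]}[{ctx[1]}>{alt}]{ctx[2]}"
    return SBS96_INDEX[label]


def channel_label(index: int) -> str:
    return SBS96_LABELS[index]


def channel_to_mutation_parts(index: int) -> tuple[str, str, str]:
    """(context, ref, alt) on the pyrimidine strand for a channel index."""
    lab = SBS96_LABELS[index]
    five, rest = lab[0], lab[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def count_channels(mutations: Sequence[Mutation]) -> np.ndarray:
    """96-channel histogram of a mutation list."""
    counts = np.zeros(96, dtype=np.int64)
    for m in mutations:
        counts[classify_sbs96(m)] += 1
    return counts


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bin:
    """An ordered group of mutations with its 96-channel counts and genomic span.

    The span runs from the first contained mutation's position to one past the
    last contained mutation's position (0-based half-open).
    """

    bin_index: int
    chrom_start: str
    pos_start: int  # 0-based inclusive
    chrom_end: str
    pos_end: int  # 0-based exclusive
    n_mutations: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_mutations:
            raise ValueError("bin counts do not sum to n_mutations")

    @property
    def span(self) -> tuple[str, int, str, int]:
        return (self.chrom_start, self.pos_start, self.chrom_end, self.pos_end)


@dataclass(frozen=True)
class BinSeries:
    """Ordered bins for one sample, genome-wise or chromosome-wise."""

    bins: tuple[Bin, ...]
    mode: str  # "genome_wise" | "chromosome_wise"
    bin_size: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.mode not in ("genome_wise", "chromosome_wise"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def count_matrix(self) -> np.ndarray:
        """B x 96 channel-count matrix."""
        return np.stack([b.counts for b in self.bins])

    @property
    def n_mutations(self) -> int:
        return int(sum(b.n_mutations for b in self.bins))

    def chromosome_of_bin(self, i: int) -> str:
        return self.bins[i].chrom_start

    def chromosome_slices(self) -> dict[str, slice]:
        """Bin-index slice per chromosome (by a bin's starting chromosome)."""
        out: dict[str, slice] = {}
        start = 0
        cur = self.bins[0].chrom_start
        for i, b in enumerate(self.bins):
            if b.chrom_start != cur:
                out[cur] = slice(start, i)
                start, cur = i, b.chrom_start
        out[cur] = slice(start, len(self.bins))
        return out


def _bins_from_groups(groups: list[list[Mutation]], sample_id: str, mode: str, bin_size: int) -> BinSeries:
    bins = []
    for i, grp in enumerate(groups):
        counts = count_channels(grp)
        bins.append(
            Bin(
                bin_index=i,
                chrom_start=grp[0].chrom,
                pos_start=grp[0].pos - 1,
                chrom_end=grp[-1].chrom,
                pos_end=grp[-1].pos,
                n_mutations=len(grp),
                counts=counts,
            )
        )
    return BinSeries(bins=tuple(bins), mode=mode, bin_size=bin_size, sample_id=sample_id)


def _partition_equal_count(mutations: list[Mutation], bin_size: int) -> list[list[Mutation]]:
    """floor(N/bin_size) bins; the terminal bin absorbs the remainder."""
    n = len(mutations)
    n_bins = max(1, n // bin_size)
    groups = [mutations[i * bin_size : (i + 1) * bin_size] for i in range(n_bins - 1)]
    groups.append(mutations[(n_bins - 1) * bin_size :])
    return groups


def make_bins(
    mutations: Sequence[Mutation],
    bin_size: int = 100,
    mode: str = "genome_wise",
    chrom_order: Optional[Sequence[str]] = None,
) -> BinSeries:
    """Partition coordinate-sorted mutations into equal-count bins.

    Genome-wise: mutations are ordered along the [1-22,X,Y] concatenation
    (or ``chrom_order`` if given) and split into floor(N/bin_size) bins, the
    last absorbing the remainder.  Chromosome-wise: the same rule applies
    independently per chromosome; a chromosome with fewer than ``bin_size``
    mutations becomes a single undersized bin, flagged with a warning because
    activity estimates need on the order of 100 mutations to be reliable.
    """
    if not mutations:
        raise ValueError("cannot bin an empty mutation list")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    order = {c: i for i, c in enumerate(chrom_order)} if chrom_order else None

    def key(m: Mutation):
        return ((order[m.chrom] if order else chrom_rank(m.chrom)), m.pos)

    muts = sorted(mutations, key=key)
    sample_id = muts[0].sample_id

    if mode == "genome_wise":
        groups = _partition_equal_count(muts, bin_size)
    elif mode == "chromosome_wise":
        groups = []
        by_chrom: dict[str, list[Mutation]] = {}
        for m in muts:
            by_chrom.setdefault(m.chrom, []).append(m)
        for chrom in sorted(by_chrom, key=lambda c: order[c] if order else chrom_rank(c)):
            cms = by_chrom[chrom]
            if len(cms) < bin_size:
                logger.warning(
                    "chromosome %s has %d < %d mutations; kept as one undersized bin "
                    "(activity estimates need ~100 mutations per segment)",
                    chrom,
                    len(cms),
                    bin_size,
                )
            groups.extend(_partition_equal_count(cms, bin_size))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return _bins_from_groups(groups, sample_id, mode, bin_size)


def chromosome_order_shuffle(
    series: BinSeries, mutations: Sequence[Mutation], seed: int
) -> BinSeries:
    """Re-bin a genome-wise series under a seeded random chromosome permutation.

    Mutation content is conserved; only the concatenation order (and hence the
    bin partition) changes.  Used for bootstrapping the genome-wise setting.
    """
    if series.mode != "genome_wise":
        raise ValueError("chromosome shuffle applies to genome-wise series only")
    rng = np.random.default_rng(seed)
    present = sorted({m.chrom for m in mutations}, key=chrom_rank)
    perm = [present[i] for i in rng.permutation(len(present))]
    return make_bins(mutations, bin_size=series.bin_size, mode="genome_wise", chrom_order=perm)


def write_bin_table(series: BinSeries, path) -> None:
    """Bin table TSV: index, span, mutation count and the 96 channel counts."""
    import pandas as pd

    rows = []
    for b in series.bins:
        row = {
            "bin_index": b.bin_index,
            "chrom_start": b.chrom_start,
            "pos_start": b.pos_start,
            "chrom_end": b.chrom_end,
            "pos_end": b.pos_end,
            "n_mutations": b.n_mutations,
        }
        row.update({lab: int(c) for lab, c in zip(SBS96_LABELS, b.counts)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
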