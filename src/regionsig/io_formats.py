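"""Input/output for mutation calls, signature catalogs and genomic feature tracks.

All genomic intervals are held internally as 0-based half-open coordinates on
canonical chromosome labels ("1".."22", "X", "Y"); files written by this module
state their convention in a header comment.  Chromosome labels are normalised
by stripping a leading ``chr`` so UCSC-style and ensembl/PCAWG-style inputs
interoperate; non-canonical contigs (MT, alts, decoys) are dropped with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger("regionsig")

#: Canonical chromosome order used for genome-wise concatenation.
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CANONICAL_CHROMS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def normalize_chrom(label: str) -> Optional[str]:
    """Map a chromosome label onto the canonical set, or None if non-canonical."""
    c = str(label)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("23",):  # occasionally used for X in legacy tables
        c = "X"
    return c if c in _CHROM_RANK else None


def chrom_rank(chrom: str) -> int:
    return _CHROM_RANK[chrom]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mutation:
    """A somatic single-base substitution.

    ``pos`` is 1-based (as in VCF); ``context`` is the reference trinucleotide
    centred on the mutated base, whose middle base must equal ``ref``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")
        if self.context is not None:
            ctx = self.context.upper()
            if len(ctx) != 3:
                raise ValueError(f"context must be a 3-mer, got {ctx!r}")
            if ctx[1] != self.ref:
                raise ValueError(f"context middle base {ctx[1]} != ref {self.ref}")


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic interval with an optional numeric or categorical value.

    Coordinates are 0-based half-open.
    """

    chrom: str
    start: int
    end: int
    value: Optional[Union[float, str]] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "FeatureInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; supports genome-wise concatenation."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    centromeres: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        ranks = [_CHROM_RANK[c] for c in self.chroms]
        if ranks != sorted(ranks):
            raise ValueError("chromosomes must follow the canonical [1-22,X,Y] order")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.chroms.index(chrom)]

    def offset_of(self, chrom: str) -> int:
        """Cumulative genome-wise offset of a chromosome's origin."""
        i = self.chroms.index(chrom)
        return int(sum(self.lengths[:i]))

    def concat_pos(self, chrom: str, pos: int) -> int:
        """Genome-wise concatenated coordinate of a position."""
        return self.offset_of(chrom) + pos

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


# ---------------------------------------------------------------------------
# Mutation reading
# ---------------------------------------------------------------------------

def _mutation_sort_key(m: Mutation) -> tuple[int, int]:
    return (_CHROM_RANK[m.chrom], m.pos)


def _context_from_fasta(fasta, chrom: str, pos: int) -> Optional[str]:
    """Trinucleotide context around a 1-based position; None near edges."""
    try:
        seq = fasta[chrom][pos - 2 : pos + 1].seq.upper()
    except (KeyError, ValueError):
        return None
    return seq if len(seq) == 3 else None


def read_mutations(
    path: Union[str, Path],
    format: str = "tsv",
    reference: Optional[Union[str, Path]] = None,
    sample_id: Optional[str] = None,
) -> list[Mutation]:
    """Read somatic SNVs from a VCF or a tab-separated mutation table.

    Only biallelic single-base substitutions on canonical chromosomes are
    returned, sorted by (chromosome order, position).  Multi-allelic VCF
    records are split and only SNV alleles kept.  Records that are not SNVs,
    sit on non-canonical contigs, or have an ambiguous (N-containing) context
    are skipped and counted in a summary warning.  A reference FASTA is
    required when the input carries no trinucleotide context.
    """
    path = Path(path)
    fasta = None
    if reference is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(reference), sequence_always_upper=True)

    skipped = {"non_snv": 0, "non_canonical": 0, "bad_context": 0}
    out: list[Mutation] = []

    if format == "vcf":
        if fasta is None:
            raise ValueError("reading VCF requires a reference FASTA for context")
        import cyvcf2

        vcf = cyvcf2.VCF(str(path))
        default_sid = sample_id or (vcf.samples[0] if vcf.samples else path.stem)
        for rec in vcf:
            chrom = normalize_chrom(rec.CHROM)
            if chrom is None:
                skipped["non_canonical"] += 1
                continue
            ref = rec.REF.upper()
            for alt in rec.ALT:
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                    skipped["non_snv"] += 1
                    continue
                ctx = _fasta_ctx_or_none(fasta, chrom, rec.POS, ref)
                if ctx is None:
                    skipped["bad_context"] += 1
                    continue
                out.append(Mutation(default_sid, chrom, rec.POS, ref, alt, ctx))
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        cols = {c.lower(): c for c in df.columns}
        required = ["chrom", "pos", "ref", "alt"]
        for col in required:
            if col not in cols:
                raise ValueError(f"mutation table missing column {col!r}")
        has_ctx = "context" in cols
        if not has_ctx and fasta is None:
            raise ValueError("mutation table has no context column and no reference FASTA given")
        for row in df.itertuples(index=False):
            r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
            chrom = normalize_chrom(r[cols["chrom"]])
            if chrom is None:
                skipped["non_canonical"] += 1
                continue
            ref = str(r[cols["ref"]]).upper()
            alt = str(r[cols["alt"]]).upper()
            pos = int(r[cols["pos"]])
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                skipped["non_snv"] += 1
                continue
            sid = sample_id or (str(r[cols["sample"]]) if "sample" in cols else path.stem)
            if has_ctx:
                ctx = str(r[cols["context"]]).upper()
                if len(ctx) != 3 or "N" in ctx or ctx[1] != ref:
                    skipped["bad_context"] += 1
                    continue
            else:
                ctx = _fasta_ctx_or_none(fasta, chrom, pos, ref)
                if ctx is None:
                    skipped["bad_context"] += 1
                    continue
            out.append(Mutation(sid, chrom, pos, ref, alt, ctx))
    else:
        raise ValueError(f"unknown mutation format {format!r}")

    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.warning(
            "read_mutations(%s): skipped %d records (%s)",
            path.name,
            n_skipped,
            ", ".join(f"{k}={v}" for k, v in skipped.items() if v),
        )
    out.sort(key=_mutation_sort_key)
    return out


def _fasta_ctx_or_none(fasta, chrom: str, pos: int, ref: str) -> Optional[str]:
    key = chrom if chrom in fasta.keys() else f"chr{chrom}"
    if key not in fasta.keys():
        return None
    ctx = _context_from_fasta(fasta, key, pos)
    if ctx is None or "N" in ctx or ctx[1] != ref:
        return None
    return ctx


def write_mutations(mutations: Sequence[Mutation], path: Union[str, Path]) -> None:
    """Write mutations as the tab-separated table ``read_mutations`` accepts."""
    df = pd.DataFrame(
        {
            "sample": [m.sample_id for m in mutations],
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "context": [m.context for m in mutations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature catalog I/O
# ---------------------------------------------------------------------------

def read_signature_catalog(path: Union[str, Path]):
    """Read a COSMIC-style signature matrix (TSV, signatures x 96 channels).

    Accepts channels either as rows or as columns; channel labels must be the
    96 canonical ``X[R>A]Y`` labels.  Rows are renormalised to sum to one and
    mapped onto the canonical channel ordering regardless of file order.
    """
    from .catalog96 import SBS96_LABELS
    from .signature_model import SignatureCatalog

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    label_set = set(SBS96_LABELS)
    if set(df.index) == label_set:
        df = df.T  # channels were rows -> signatures x channels
    elif set(df.columns) != label_set:
        raise ValueError("signature matrix labels do not match the 96 canonical SBS channels")
    df = df[list(SBS96_LABELS)]
    mat = df.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("signature matrix contains negative entries")
    return SignatureCatalog.normalized(tuple(str(n) for n in df.index), mat)


def write_signature_catalog(catalog, path: Union[str, Path]) -> None:
    from .catalog96 import SBS96_LABELS

    df = pd.DataFrame(catalog.emissions, index=list(catalog.names), columns=list(SBS96_LABELS))
    df.index.name = "signature"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Feature track I/O
# ---------------------------------------------------------------------------

def read_feature_track(path: Union[str, Path], format: str = "bed") -> list[FeatureInterval]:
    """Read a feature track as a list of intervals.

    ``bed``/``bed_score`` are 0-based half-open (score or label preserved in
    ``value`` for bed_score); ``gff`` (GFF3/GTF, 1-based closed) is converted
    to 0-based half-open.  Overlapping input intervals are preserved as-is.
    """
    path = Path(path)
    out: list[FeatureInterval] = []
    if format in ("bed", "bed_score"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom = normalize_chrom(parts[0])
                if chrom is None:
                    logger.warning("%s:%d non-canonical contig %s dropped", path.name, lineno, parts[0])
                    continue
                start, end = int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError(f"{path.name}:{lineno}: empty interval {start}-{end}")
                value: Optional[Union[float, str]] = None
                if format == "bed_score" or len(parts) >= 4:
                    raw = parts[4] if len(parts) >= 5 else (parts[3] if len(parts) >= 4 else None)
                    if raw is not None:
                        try:
                            value = float(raw)
                        except ValueError:
                            value = raw
                out.append(FeatureInterval(chrom, start, end, value))
    elif format == "gff":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 8:
                    continue
                chrom = normalize_chrom(parts[0])
                if chrom is None:
                    continue
                start = int(parts[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(parts[4])
                if start >= end:
                    raise ValueError(f"{path.name}:{lineno}: empty interval after conversion")
                score = parts[5]
                value = None if score == "." else _maybe_float(score)
                out.append(FeatureInterval(chrom, start, end, value))
    else:
        raise ValueError(f"unknown track format {format!r}")
    out.sort(key=lambda iv: (_CHROM_RANK[iv.chrom], iv.start, iv.end))
    return out


def _maybe_float(s: str) -> Union[float, str]:
    try:
        return float(s)
    except ValueError:
        return s


def write_feature_track(intervals: Iterable[FeatureInterval], path: Union[str, Path]) -> None:
    """Write intervals as BED (0-based half-open); value goes in column 4."""
    with open(path, "w") as fh:
        fh.write("# regionsig feature track; coordinates are 0-based half-open (BED)\n")
        for iv in intervals:
            if iv.value is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.value}\n")


def write_gff(intervals: Iterable[FeatureInterval], path: Union[str, Path], source: str = "regionsig", feature: str = "gene") -> None:
    """Write intervals as GFF3 (converted back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            score = "." if iv.value is None else str(iv.value)
            fh.write(f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t{score}\t.\t.\t.\n")
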