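"""Readers, writers and lookup structures for the genomic formats the pipeline touches.

Variant lists arrive as VCF, BED (0-based half-open, with a ``ref/alt``
fourth column) or ANNOVAR avinput (1-based inclusive, 5 columns).  All
annotation resources are flat TSV tables or BED interval tracks.  Everything
downstream works on the in-memory types defined here: :class:`GenomicVariant`,
:class:`VariantSet`, :class:`IntervalTrack`, :class:`ScoreTable` and
:class:`GeneAnnotation`.

Coordinate conventions: ``GenomicVariant.pos`` is 1-based; interval tracks
are 0-based half-open as in BED.  Chromosome names are normalized (default:
strip a leading ``chr``) so that variant files and annotation sources using
different conventions still match.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Sentinel returned by :meth:`ScoreTable.lookup` when a key is absent.
#: Deliberately not 0 and not NaN-comparable by accident.
MISSING = object()

_VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed input lines; carries the offending line number."""


def normalize_chrom(chrom: str, strip_chr: bool = True) -> str:
    """Canonicalize a chromosome name.

    Annotation sources mix ``chr1`` and ``1``; a silent mismatch would zero
    out every feature, so both spellings are mapped to one canonical form.
    """
    chrom = chrom.strip()
    if strip_chr and chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class GenomicVariant:
    """A single substitution with a 1-based position."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or set(self.ref) - _VALID_ALLELES:
            raise ValueError(f"invalid ref allele {self.ref!r}")
        if not self.alt or set(self.alt) - _VALID_ALLELES:
            raise ValueError(f"invalid alt allele {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref})")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class VariantSet:
    """Ordered, deduplicated collection of variants.

    After construction, variants are sorted by (chrom, pos) and duplicate
    (chrom, pos, ref, alt) keys are dropped keeping the first occurrence;
    ``n_skipped`` counts non-SNV input records, ``n_duplicates`` counts the
    dropped duplicates.
    """

    variants: list[GenomicVariant]
    source_format: str = "memory"
    n_skipped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str, str]] = set()
        unique: list[GenomicVariant] = []
        for v in self.variants:
            if v.key in seen:
                self.n_duplicates += 1
                continue
            seen.add(v.key)
            unique.append(v)
        if self.n_duplicates:
            logger.warning("dropped %d duplicate variant keys", self.n_duplicates)
        unique.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        self.variants = unique

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[GenomicVariant]:
        return iter(self.variants)

    def __getitem__(self, i: int) -> GenomicVariant:
        return self.variants[i]

    @property
    def keys(self) -> list[tuple[str, int, str, str]]:
        return [v.key for v in self.variants]


@dataclass
class IntervalTrack:
    """A named set of genomic intervals (0-based half-open) with fast membership."""

    name: str
    intervals: list[tuple[str, int, int]]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"track {self.name}: interval ({chrom},{start},{end}) has start >= end"
                )
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def contains(self, v: GenomicVariant) -> int:
        """1 iff the variant's base (0-based ``pos - 1``) lies inside any interval."""
        tree = self._trees.get(v.chrom)
        if tree is None:
            return 0
        return 1 if tree.overlaps_point(v.pos - 1) else 0


def query_interval_membership(track: IntervalTrack, v: GenomicVariant) -> int:
    """Indicator in {0, 1} for whether ``v`` falls in any interval of ``track``."""
    return track.contains(v)


@dataclass
class ScoreTable:
    """Mapping from a variant key to a numeric score.

    ``key_mode`` is ``"allele"`` (match on chrom,pos,ref,alt — the default;
    pre-computed predictor scores are allele-specific) or ``"position"``
    (match on chrom,pos only).  Absent keys yield the :data:`MISSING`
    sentinel, never 0: downstream code decides how absence is handled
    (imputation, rule-based default, or EMR fill).
    """

    source: str
    scores: dict[tuple, float]
    key_mode: str = "allele"

    def __post_init__(self) -> None:
        if self.key_mode not in ("allele", "position"):
            raise ValueError(f"unknown key_mode {self.key_mode!r}")

    def lookup(self, v: GenomicVariant):
        key = v.key if self.key_mode == "allele" else (v.chrom, v.pos)
        return self.scores.get(key, MISSING)

    def __len__(self) -> int:
        return len(self.scores)


def lookup_score(table: ScoreTable, v: GenomicVariant):
    """Exact-key score lookup; returns :data:`MISSING` when the key is absent."""
    return table.lookup(v)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body interval, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_vcf(path: str | Path, strip_chr: bool) -> tuple[list[GenomicVariant], int]:
    from cyvcf2 import VCF

    variants: list[GenomicVariant] = []
    skipped = 0
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            chrom = normalize_chrom(rec.CHROM, strip_chr)
            ref = rec.REF.upper()
            vid = rec.ID
            for alt in rec.ALT:
                alt = alt.upper()
                if (
                    len(ref) != 1
                    or len(alt) != 1
                    or ref not in _VALID_ALLELES
                    or alt not in _VALID_ALLELES
                    or ref == alt
                ):
                    skipped += 1
                    continue
                variants.append(GenomicVariant(chrom, rec.POS, ref, alt, vid))
    finally:
        vcf.close()
    return variants, skipped


def _read_bed_variants(path: str | Path, strip_chr: bool) -> tuple[list[GenomicVariant], int]:
    # BED dialect: chrom, start, end (0-based half-open), optional 4th
    # column "REF/ALT".  Only single-base records with alleles are variants.
    variants: list[GenomicVariant] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if len(fields) < 4 or "/" not in fields[3] or end - start != 1:
                skipped += 1
                continue
            ref, _, alt = fields[3].partition("/")
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref == alt or {ref, alt} - _VALID_ALLELES:
                skipped += 1
                continue
            chrom = normalize_chrom(fields[0], strip_chr)
            # BED is 0-based half-open; the covered base is start, 1-based start+1
            variants.append(GenomicVariant(chrom, start + 1, ref, alt))
    return variants, skipped


def _read_avinput(path: str | Path, strip_chr: bool) -> tuple[list[GenomicVariant], int]:
    # ANNOVAR avinput: chrom, start, end (1-based inclusive), ref, alt.
    # Only start == end single-nucleotide rows are accepted as SNVs.
    variants: list[GenomicVariant] = []
    skipped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            ref, alt = fields[3].upper(), fields[4].upper()
            if (
                start != end
                or len(ref) != 1
                or len(alt) != 1
                or ref == alt
                or {ref, alt} - _VALID_ALLELES
            ):
                skipped += 1
                continue
            chrom = normalize_chrom(fields[0], strip_chr)
            variants.append(GenomicVariant(chrom, start, ref, alt))
    return variants, skipped


def read_variants(path: str | Path, format: str, strip_chr: bool = True) -> VariantSet:
    """Read a variant list in one of the supported dialects.

    Parameters
    ----------
    path
        Input file (plain text or gzipped).
    format
        One of ``vcf``, ``bed``, ``avinput``.
    strip_chr
        Canonicalize chromosome names by stripping a leading ``chr``.

    Returns
    -------
    VariantSet
        Sorted by (chrom, pos); biallelic SNVs only.  Multi-allelic VCF
        records are split into one variant per alternate allele; non-SNV
        records are skipped and counted in ``n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"vcf": _read_vcf, "bed": _read_bed_variants, "avinput": _read_avinput}
    if format not in readers:
        raise ValueError(f"unknown variant format {format!r}; expected one of {sorted(readers)}")
    variants, skipped = readers[format](path, strip_chr)
    if skipped:
        logger.info("%s: skipped %d non-SNV records", path, skipped)
    return VariantSet(variants, source_format=format, n_skipped=skipped)


def read_interval_track(path: str | Path, name: str, strip_chr: bool = True) -> IntervalTrack:
    """Load a BED file of intervals (e.g. ChIP-seq peaks for one histone mark)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"interval track {name!r}: {path} not found")
    intervals: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            intervals.append((normalize_chrom(fields[0], strip_chr), start, end))
    return IntervalTrack(name=name, intervals=intervals)


def read_score_table(
    path: str | Path,
    source: str,
    key_mode: str = "allele",
    score_column: str = "score",
    strip_chr: bool = True,
    value_range: tuple[float, float] | None = None,
) -> ScoreTable:
    """Load a per-variant score TSV with columns chrom, pos, ref, alt, <score>.

    In ``position`` key mode the ref/alt columns may be absent.  When several
    rows share a key (e.g. one eQTL per target gene), the maximum score is
    kept — the strongest evidence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if score_column not in df.columns:
        raise FormatError(f"{path}: missing score column {score_column!r}")
    if value_range is not None:
        lo, hi = value_range
        bad = df[(df[score_column] < lo) | (df[score_column] > hi)]
        if len(bad):
            raise ValueError(
                f"{path}: {len(bad)} scores outside [{lo}, {hi}] in column {score_column!r}"
            )
    scores: dict[tuple, float] = {}
    chroms = [normalize_chrom(c, strip_chr) for c in df["chrom"]]
    for i, row in enumerate(df.itertuples(index=False)):
        if key_mode == "allele":
            key = (chroms[i], int(row.pos), str(row.ref).upper(), str(row.alt).upper())
        else:
            key = (chroms[i], int(row.pos))
        val = float(getattr(row, score_column))
        if key not in scores or val > scores[key]:
            scores[key] = val
    return ScoreTable(source=source, scores=scores, key_mode=key_mode)


def read_gene_annotation(path: str | Path, strip_chr: bool = True) -> list[GeneAnnotation]:
    """Load a gene table with columns gene, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = [
        GeneAnnotation(str(r.gene), normalize_chrom(str(r.chrom), strip_chr), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def read_gene_score_table(path: str | Path, score_column: str = "score") -> dict[str, float]:
    """Load a simple gene→score TSV (columns: gene, <score>)."""
    df = pd.read_csv(path, sep="\t")
    if score_column not in df.columns:
        raise FormatError(f"{path}: missing score column {score_column!r}")
    return {str(r.gene): float(getattr(r, score_column)) for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write_ranked_output(
    records: pd.DataFrame,
    path: str | Path,
    score_column: str = "score",
    tie_break: Sequence[str] | None = None,
) -> None:
    """Write a ranked TSV, sorted by score descending with a stable tie-break.

    ``records`` must contain ``score_column``; ties are broken
    lexicographically on ``tie_break`` columns (default: (chrom, pos) when
    present, else gene id, else all remaining columns).
    """
    if score_column not in records.columns:
        raise ValueError(f"records lack score column {score_column!r}")
    if tie_break is None:
        if {"chrom", "pos"} <= set(records.columns):
            tie_break = ["chrom", "pos"]
        elif "gene" in records.columns:
            tie_break = ["gene"]
        else:
            tie_break = [c for c in records.columns if c != score_column]
    ordered = records.sort_values(
        [score_column, *tie_break],
        ascending=[False] + [True] * len(tie_break),
        kind="mergesort",
    )
    ordered.to_csv(path, sep="\t", index=False, float_format="%.6f")
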