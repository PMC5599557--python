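"""Readers and writers for the genomic formats the pipeline touches.

Internal conventions: point positions are 1-based (VCF-style); chromosome
names are stored without a leading ``chr`` prefix, with mitochondrial
aliases (``MT``, ``M``, ``chrM``) collapsed to ``MT``.  Interval inputs
are converted on read: BED is 0-based half-open, GFF3 is 1-based
inclusive; internally intervals are kept 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: annotation kinds given dedicated handling; anything else becomes "other"
KNOWN_KINDS = ("CDS", "exon", "splice_site", "start_codon", "stop_codon", "TSS", "gene")


def normalise_chrom(name: str) -> str:
    """Strip a leading ``chr`` and collapse mitochondrial aliases to ``MT``."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in {"M", "MT", "m", "mt"}:
        return "MT"
    return name


@dataclass
class MutationRecord:
    """A single-nucleotide variant with its catalogue metadata.

    ``recurrence`` counts independent observations of the identical
    variant (0 = unannotated); ``label`` is the training class and
    ``region_class`` the coding/non-coding routing decided against a set
    of annotations.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    recurrence: int = 0
    label: str = "unknown"
    region_class: str = "unassigned"

    def __post_init__(self):
        self.chrom = normalise_chrom(self.chrom)
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"alleles must be single nucleotides, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")
        if self.recurrence < 0:
            raise ValueError("recurrence must be non-negative")
        if self.label not in {"driver", "neutral", "unknown"}:
            raise ValueError(f"unknown label {self.label!r}")
        if self.region_class not in {"coding", "noncoding", "unassigned"}:
            raise ValueError(f"unknown region_class {self.region_class!r}")

    @property
    def key(self) -> tuple:
        """Identity of the variant: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_fields(self, **kw) -> "MutationRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) in 0-based coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        """True if the 1-based point position falls inside the interval."""
        return self.start <= pos - 1 < self.end


class AnnotationIndex:
    """Point-queryable index over genomic intervals, grouped by chromosome."""

    def __init__(self, intervals=()):
        self._trees: dict[str, IntervalTree] = {}
        self._by_kind: dict[str, dict[str, list]] = {}
        self.n_intervals = 0
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        chrom = normalise_chrom(iv.chrom)
        self._trees.setdefault(chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._by_kind.setdefault(chrom, {}).setdefault(iv.kind, []).append(iv)
        self.n_intervals += 1

    @property
    def chroms(self):
        return set(self._trees)

    def query(self, chrom: str, pos: int) -> list[GenomicInterval]:
        """All intervals overlapping a 1-based point position."""
        tree = self._trees.get(normalise_chrom(chrom))
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.at(pos - 1)),
                      key=lambda iv: (iv.start, iv.end, iv.kind))

    def intervals_of_kind(self, chrom: str, kind: str) -> list[GenomicInterval]:
        return sorted(self._by_kind.get(normalise_chrom(chrom), {}).get(kind, []),
                      key=lambda iv: (iv.start, iv.end))

    def kinds_at(self, chrom: str, pos: int) -> set[str]:
        return {iv.kind for iv in self.query(chrom, pos)}


class ScoreTrack:
    """Sparse per-position score track (e.g. a conservation score).

    Lookups at positions without data return ``None`` — missingness is
    explicit, never silently zero.
    """

    def __init__(self, name: str, values: dict | None = None):
        self.name = name
        # chrom -> {1-based pos: value}
        self._values: dict[str, dict[int, float]] = {}
        if values:
            for (chrom, pos), v in values.items():
                self.set(chrom, pos, v)

    def set(self, chrom: str, pos: int, value: float) -> None:
        self._values.setdefault(normalise_chrom(chrom), {})[int(pos)] = float(value)

    def get(self, chrom: str, pos: int):
        """Value at a 1-based position, or ``None`` when unscored."""
        return self._values.get(normalise_chrom(chrom), {}).get(int(pos))

    def window(self, chrom: str, pos: int, halfwidth: int) -> list[float]:
        """Values present in [pos - halfwidth, pos + halfwidth]."""
        chrom_vals = self._values.get(normalise_chrom(chrom), {})
        return [chrom_vals[p] for p in range(pos - halfwidth, pos + halfwidth + 1)
                if p in chrom_vals]

    def __len__(self) -> int:
        return sum(len(d) for d in self._values.values())

    def coverage_fraction(self, queries) -> float:
        """Fraction of the query (chrom, pos) pairs that carry a value."""
        queries = list(queries)
        if not queries:
            return 0.0
        hit = sum(1 for chrom, pos in queries if self.get(chrom, pos) is not None)
        return hit / len(queries)


# ---------------------------------------------------------------------------
# readers


def _parse_tsv_mutations(path) -> tuple[list[MutationRecord], int]:
    records, skipped = [], 0
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: tsv requires columns chrom/pos/ref/alt, found {list(df.columns)}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        ref, alt = str(d["ref"]).upper(), str(d["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES or ref == alt:
            skipped += 1
            continue
        try:
            rec = MutationRecord(
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=ref,
                alt=alt,
                recurrence=int(d.get("recurrence") or 0),
                label=str(d.get("label") or "unknown"),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        records.append(rec)
    return records, skipped


def _parse_vcf_mutations(path) -> tuple[list[MutationRecord], int]:
    records, skipped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES \
                        or alt not in NUCLEOTIDES or ref == alt:
                    skipped += 1
                    continue
                recurrence = 0
                if "RECUR" in rec.info:
                    recurrence = int(rec.info["RECUR"])
                records.append(MutationRecord(chrom=rec.chrom, pos=rec.pos,
                                              ref=ref, alt=alt, recurrence=recurrence))
    return records, skipped


def read_mutation_table(path, format: str = "tsv") -> list[MutationRecord]:
    """Read SNVs from a tab-delimited table or a VCF.

    Multi-allelic VCF rows become one record per alternate allele;
    non-SNV rows (indels, MNVs) are skipped and counted in the log.
    """
    if format == "tsv":
        records, skipped = _parse_tsv_mutations(path)
    elif format == "vcf":
        records, skipped = _parse_vcf_mutations(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if skipped:
        logger.info("read_mutation_table(%s): skipped %d non-SNV rows", path, skipped)
    if not records:
        warnings.warn(f"{path}: no SNV records read")
    return records


_BED_KIND_ALIASES = {k.lower(): k for k in KNOWN_KINDS}
_GFF_KIND_ALIASES = {
    **_BED_KIND_ALIASES,
    "five_prime_utr": "other",
    "three_prime_utr": "other",
    "mrna": "other",
    "transcription_start_site": "TSS",
}


def _resolve_kind(raw: str, path) -> str:
    kind = _BED_KIND_ALIASES.get(raw.strip().lower()) or _GFF_KIND_ALIASES.get(raw.strip().lower())
    if kind is None:
        warnings.warn(f"{path}: unknown feature kind {raw!r}, retained as 'other'")
        return "other"
    return kind


def read_annotations(path) -> AnnotationIndex:
    """Read BED (``.bed``) or GFF3 (anything else) into a point-queryable index."""
    path = str(path)
    index = AnnotationIndex()
    if path.endswith(".bed"):
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        for row in df.itertuples(index=False):
            kind = _resolve_kind(str(row[3]) if len(row) > 3 else "other", path)
            strand = str(row[5]) if len(row) > 5 else "."
            index.add(GenomicInterval(chrom=str(row[0]), start=int(row[1]),
                                      end=int(row[2]), strand=strand, kind=kind))
    else:  # GFF3: 1-based inclusive -> 0-based half-open
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         names=["seqid", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        for row in df.itertuples(index=False):
            kind = _resolve_kind(str(row.type), path)
            index.add(GenomicInterval(chrom=str(row.seqid), start=int(row.start) - 1,
                                      end=int(row.end), strand=str(row.strand), kind=kind))
    return index


def classify_region(m: MutationRecord, annotations: AnnotationIndex) -> str:
    """Route a mutation to ``coding`` or ``noncoding``.

    ``coding`` iff the position overlaps at least one CDS interval of any
    transcript; everything else (intronic, intergenic, UTR) is
    ``noncoding``.
    """
    chrom = normalise_chrom(m.chrom)
    if chrom not in annotations.chroms:
        warnings.warn(f"chromosome {chrom} absent from annotations; classifying as noncoding")
        return "noncoding"
    return "coding" if "CDS" in annotations.kinds_at(chrom, m.pos) else "noncoding"


def read_score_track(path, name: str | None = None) -> ScoreTrack:
    """Read a tab-delimited chrom/pos/value track (positions 1-based).

    Duplicate positions keep the last value seen (with a warning).
    """
    import os

    track = ScoreTrack(name or os.path.splitext(os.path.basename(str(path)))[0])
    duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected chrom<TAB>pos<TAB>value")
            try:
                chrom, pos, value = parts[0], int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if track.get(chrom, pos) is not None:
                duplicates += 1
            track.set(chrom, pos, value)
    if duplicates:
        warnings.warn(f"{path}: {duplicates} duplicate positions; last value wins")
    return track


# ---------------------------------------------------------------------------
# writers


def write_mutation_table(records, path) -> None:
    """Write records in the TSV dialect that :func:`read_mutation_table` reads."""
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.ref, r.alt, r.recurrence, r.label) for r in records],
        columns=["chrom", "pos", "ref", "alt", "recurrence", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_predictions(records, pscores, thresholds, path) -> None:
    """Write calibrated predictions as a tab-delimited table.

    ``call`` is driver when p >= 0.5; ``high_confidence`` is true when
    p >= tau or p <= 1 - tau for the cautious threshold tau.
    """
    pscores = list(pscores)
    if len(records) != len(pscores):
        raise ValueError(f"{len(records)} records but {len(pscores)} p-scores")
    tau = thresholds.cautious_tau
    rows = []
    for rec, p in zip(records, pscores):
        call = "driver" if p >= thresholds.default_tau else "passenger"
        high = p >= tau or p <= 1.0 - tau
        rows.append((rec.chrom, rec.pos, rec.ref, rec.alt, rec.region_class,
                     f"{p:.6f}", call, str(bool(high)).lower()))
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "region_class",
                                "p_score", "call", "high_confidence"]
                 ).to_csv(path, sep="\t", index=False)
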