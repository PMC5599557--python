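"""Per-mutation feature groups.

Each group is a named block of columns with an explicit missingness
mask.  Sequence groups (k-mer spectra, GC content, mutation-induced
spectrum disruption) are computed from a reference FASTA window centred
on the variant; context groups summarise distances to annotated
elements; track groups read per-position score tracks such as
conservation or mappability.  Groups are concatenated into a single
design matrix with group-traceable column spans, with mean imputation
and optional standardisation fitted strictly on a declared training row
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .io import AnnotationIndex, MutationRecord, ScoreTrack

_BASES = "ACGT"

CONTEXT_KINDS = ("CDS", "exon", "splice_site", "start_codon", "stop_codon", "TSS")


@dataclass(frozen=True)
class KmerConfig:
    """Spectrum settings: which k-mer sizes, how wide a window, counts or
    frequencies."""

    k_values: tuple = (1, 2, 3)
    window_halfwidth: int = 25
    normalise: bool = True

    def __post_init__(self):
        if any(k < 1 for k in self.k_values):
            raise ValueError("every k must be >= 1")
        if self.window_halfwidth < max(self.k_values):
            raise ValueError("window_halfwidth must be >= max(k)")

    @property
    def window_length(self) -> int:
        return 2 * self.window_halfwidth + 1


@dataclass
class FeatureGroup:
    """A named feature block: values, missingness mask and column names."""

    name: str
    matrix: np.ndarray
    missing_mask: np.ndarray
    column_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.matrix.shape != self.missing_mask.shape:
            raise ValueError(f"group {self.name}: matrix and mask shapes differ")
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError(f"group {self.name}: {self.matrix.shape[1]} columns, "
                             f"{len(self.column_names)} names")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError(f"group {self.name}: duplicate column names")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def _kmer_names(k: int) -> list[str]:
    return ["".join(t) for t in product(_BASES, repeat=k)]


def spectrum_features(seq: str, cfg: KmerConfig) -> np.ndarray:
    """k-mer spectrum of a sequence, all 4^k k-mers in lexicographic order
    per k, concatenated over cfg.k_values.

    Windows containing N skip the affected k-mer positions; frequency
    vectors are renormalised over the valid positions.
    """
    seq = seq.upper()
    if len(seq) < max(cfg.k_values):
        raise ValueError(f"sequence of length {len(seq)} shorter than max k")
    out = []
    for k in cfg.k_values:
        index = {km: i for i, km in enumerate(_kmer_names(k))}
        counts = np.zeros(4 ** k)
        valid = 0
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            counts[index[kmer]] += 1
            valid += 1
        if cfg.normalise and valid > 0:
            counts /= valid
        out.append(counts)
    return np.concatenate(out)


def gc_content(seq: str):
    """(#G + #C) / #non-N bases; ``None`` for an all-N window."""
    seq = seq.upper()
    counted = sum(1 for b in seq if b in _BASES)
    if counted == 0:
        return None
    return sum(1 for b in seq if b in "GC") / counted


def disruption_features(ref_window: str, alt_window: str, cfg: KmerConfig) -> np.ndarray:
    """Change in the local spectrum induced by the substitution:
    spectrum(alt) - spectrum(ref), plus the L1 norm of that difference
    and the GC change."""
    if len(ref_window) != len(alt_window):
        raise ValueError("windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(ref_window.upper(), alt_window.upper())) if a != b]
    if len(diffs) > 1:
        raise ValueError(f"windows must differ at at most one position, differ at {len(diffs)}")
    delta = spectrum_features(alt_window, cfg) - spectrum_features(ref_window, cfg)
    gc_ref, gc_alt = gc_content(ref_window), gc_content(alt_window)
    dgc = 0.0 if gc_ref is None or gc_alt is None else gc_alt - gc_ref
    return np.concatenate([delta, [np.abs(delta).sum(), dgc]])


def _nearest_signed_distance(pos: int, intervals) -> float | None:
    """Signed base distance from a 1-based point to the nearest interval.

    0 inside; positive when the interval lies left of the point (the
    point is downstream), negative when right.  ``None`` with no
    intervals.
    """
    if not intervals:
        return None
    best = None
    for iv in intervals:
        if iv.contains(pos):
            return 0.0
        if pos - 1 >= iv.end:          # interval to the left
            d = pos - iv.end           # 1-based pos just right of end is distance 1
        else:                          # interval to the right
            d = pos - (iv.start + 1)   # negative
        if best is None or abs(d) < abs(best):
            best = d
    return float(best)


def genomic_context_features(m: MutationRecord, annotations: AnnotationIndex,
                             cap: int = 10_000):
    """Overlap indicator and signed capped distance per annotation kind.

    Returns (values, missing) arrays of width 2 * len(CONTEXT_KINDS);
    distance columns are missing-masked on chromosomes lacking that kind.
    """
    values = np.zeros(2 * len(CONTEXT_KINDS))
    missing = np.zeros(2 * len(CONTEXT_KINDS), dtype=bool)
    overlapping = annotations.kinds_at(m.chrom, m.pos)
    for j, kind in enumerate(CONTEXT_KINDS):
        values[2 * j] = 1.0 if kind in overlapping else 0.0
        d = _nearest_signed_distance(m.pos, annotations.intervals_of_kind(m.chrom, kind))
        if d is None:
            missing[2 * j + 1] = True
        else:
            values[2 * j + 1] = float(np.clip(d, -cap, cap))
    return values, missing


def track_features(m: MutationRecord, tracks: list[ScoreTrack], halfwidth: int = 2):
    """Per track: value at the position, and the mean and max over the
    surrounding window (unscored positions excluded).  All-missing
    windows are missing-masked."""
    values = np.zeros(3 * len(tracks))
    missing = np.zeros(3 * len(tracks), dtype=bool)
    for j, track in enumerate(tracks):
        at = track.get(m.chrom, m.pos)
        window = track.window(m.chrom, m.pos, halfwidth)
        if at is None:
            missing[3 * j] = True
        else:
            values[3 * j] = at
        if not window:
            missing[3 * j + 1:3 * j + 3] = True
        else:
            values[3 * j + 1] = float(np.mean(window))
            values[3 * j + 2] = float(np.max(window))
    return values, missing


# ---------------------------------------------------------------------------
# group builders: callables mapping a list of records to a FeatureGroup


def _fetch_window(genome, chrom: str, pos: int, halfwidth: int) -> str:
    """Window of the reference around a 1-based position, N-padded at
    chromosome edges.  ``genome`` maps chromosome name -> sequence string
    (a pyfaidx.Fasta works via str())."""
    entry = genome[chrom]
    seq = entry if isinstance(entry, str) else str(entry[:])
    left = pos - 1 - halfwidth
    right = pos + halfwidth  # exclusive, 0-based
    pad_left = max(0, -left)
    pad_right = max(0, right - len(seq))
    return "N" * pad_left + seq[max(0, left):min(len(seq), right)] + "N" * pad_right


class SequenceWindows:
    """Access to reference windows, accepting a pyfaidx.Fasta or a plain
    {chrom: sequence} dict keyed by normalised names.  Pickles by file
    path when FASTA-backed."""

    def __init__(self, genome):
        self._genome = genome

    def window(self, m: MutationRecord, halfwidth: int) -> str:
        from .io import normalise_chrom
        chrom = m.chrom
        keys = None
        try:
            keys = list(self._genome.keys())
        except AttributeError:
            pass
        if keys is not None and chrom not in keys:
            for k in keys:
                if normalise_chrom(str(k)) == chrom:
                    chrom = k
                    break
        return _fetch_window(self._genome, chrom, m.pos, halfwidth)

    def __getstate__(self):
        path = getattr(self._genome, "filename", None)
        if path is not None:
            return {"fasta_path": str(path)}
        return {"genome": self._genome}

    def __setstate__(self, state):
        if "fasta_path" in state:
            from pyfaidx import Fasta
            self._genome = Fasta(state["fasta_path"])
        else:
            self._genome = state["genome"]


class SpectrumBuilder:
    """k-mer spectrum group from reference windows around each variant."""

    def __init__(self, genome, cfg: KmerConfig | None = None):
        self.cfg = cfg or KmerConfig()
        self.windows = SequenceWindows(genome)
        self.names = [f"k{k}_{km}" for k in self.cfg.k_values for km in _kmer_names(k)]

    def __call__(self, records) -> FeatureGroup:
        rows = [spectrum_features(self.windows.window(m, self.cfg.window_halfwidth),
                                  self.cfg) for m in records]
        mat = np.vstack(rows) if rows else np.empty((0, len(self.names)))
        return FeatureGroup("spectrum", mat, np.zeros_like(mat, dtype=bool), self.names)


class GCBuilder:
    def __init__(self, genome, halfwidth: int = 25):
        self.windows = SequenceWindows(genome)
        self.halfwidth = halfwidth

    def __call__(self, records) -> FeatureGroup:
        vals = np.zeros((len(records), 1))
        miss = np.zeros((len(records), 1), dtype=bool)
        for i, m in enumerate(records):
            gc = gc_content(self.windows.window(m, self.halfwidth))
            if gc is None:
                miss[i, 0] = True
            else:
                vals[i, 0] = gc
        return FeatureGroup("gc", vals, miss, ["gc_content"])


class DisruptionBuilder:
    """Mutation-induced spectrum-change group."""

    def __init__(self, genome, cfg: KmerConfig | None = None):
        self.cfg = cfg or KmerConfig()
        self.windows = SequenceWindows(genome)
        self.names = ([f"d_k{k}_{km}" for k in self.cfg.k_values for km in _kmer_names(k)]
                      + ["l1", "delta_gc"])

    def __call__(self, records) -> FeatureGroup:
        rows = []
        for m in records:
            ref_w = self.windows.window(m, self.cfg.window_halfwidth)
            centre = self.cfg.window_halfwidth
            alt_w = ref_w[:centre] + m.alt + ref_w[centre + 1:]
            rows.append(disruption_features(ref_w, alt_w, self.cfg))
        mat = np.vstack(rows) if rows else np.empty((0, len(self.names)))
        return FeatureGroup("disruption", mat, np.zeros_like(mat, dtype=bool), self.names)


class ContextBuilder:
    def __init__(self, annotations: AnnotationIndex, cap: int = 10_000):
        self.annotations = annotations
        self.cap = cap
        self.names = [f"{kind}_{suffix}" for kind in CONTEXT_KINDS
                      for suffix in ("overlap", "dist")]

    def __call__(self, records) -> FeatureGroup:
        vals = np.zeros((len(records), len(self.names)))
        miss = np.zeros((len(records), len(self.names)), dtype=bool)
        for i, m in enumerate(records):
            vals[i], miss[i] = genomic_context_features(m, self.annotations, cap=self.cap)
        return FeatureGroup("genomic_context", vals, miss, self.names)


class TrackBuilder:
    def __init__(self, track: ScoreTrack, halfwidth: int = 2):
        self.track = track
        self.halfwidth = halfwidth
        self.names = [f"{track.name}_{s}" for s in ("value", "win_mean", "win_max")]

    def __call__(self, records) -> FeatureGroup:
        vals = np.zeros((len(records), 3))
        miss = np.zeros((len(records), 3), dtype=bool)
        for i, m in enumerate(records):
            vals[i], miss[i] = track_features(m, [self.track], halfwidth=self.halfwidth)
        return FeatureGroup(self.track.name, vals, miss, self.names)


def make_spectrum_builder(genome, cfg: KmerConfig | None = None):
    return SpectrumBuilder(genome, cfg)


def make_gc_builder(genome, halfwidth: int = 25):
    return GCBuilder(genome, halfwidth)


def make_disruption_builder(genome, cfg: KmerConfig | None = None):
    return DisruptionBuilder(genome, cfg)


def make_context_builder(annotations: AnnotationIndex, cap: int = 10_000):
    return ContextBuilder(annotations, cap)


def make_track_builder(track: ScoreTrack, halfwidth: int = 2):
    return TrackBuilder(track, halfwidth)


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class FeatureMatrix:
    """Concatenated feature groups with block-traceable columns.

    Holds the raw values and masks; :meth:`design` produces the model
    input for a declared training-row set, imputing missing entries with
    the training column mean and optionally standardising with training
    statistics.  Test rows never contribute to those statistics.
    """

    group_names: list[str]
    data: np.ndarray
    missing_mask: np.ndarray
    block_index: dict[str, tuple[int, int]]
    column_names: list[str]
    standardisation: dict | None = None

    @property
    def shape(self):
        return self.data.shape

    def design(self, fit_rows=None, standardise: bool = False) -> np.ndarray:
        """Imputed (and optionally standardised) matrix for all rows.

        ``fit_rows``: indices whose statistics drive imputation/scaling
        (default: all rows).  Zero-variance columns pass through
        unscaled.
        """
        n = self.data.shape[0]
        fit_rows = np.arange(n) if fit_rows is None else np.asarray(fit_rows)
        X = self.data.copy()
        fit_vals = np.where(self.missing_mask[fit_rows], np.nan, self.data[fit_rows])
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(fit_vals, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        X[self.missing_mask] = np.take(col_mean, np.where(self.missing_mask)[1])
        if standardise:
            mu = X[fit_rows].mean(axis=0)
            sd = X[fit_rows].std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            X = (X - mu) / sd
            self.standardisation = {"mean": mu, "sd": sd, "n_fit": len(fit_rows)}
        return X

    def columns_of(self, group: str) -> np.ndarray:
        lo, hi = self.block_index[group]
        return self.data[:, lo:hi]


def assemble_matrix(records, builders: dict, standardise: bool = False,
                    fit_rows=None) -> FeatureMatrix:
    """Build every group in ``builders`` (name -> builder) and concatenate
    them in the given order."""
    records = list(records)
    blocks, masks, names, spans = [], [], [], {}
    offset = 0
    for gname, builder in builders.items():
        group = builder(records)
        if group.n_rows != len(records):
            raise ValueError(f"group {gname}: produced {group.n_rows} rows "
                             f"for {len(records)} records")
        blocks.append(group.matrix)
        masks.append(group.missing_mask)
        names.extend(f"{gname}:{c}" for c in group.column_names)
        spans[gname] = (offset, offset + group.width)
        offset += group.width
    data = np.hstack(blocks) if blocks else np.empty((len(records), 0))
    mask = np.hstack(masks) if masks else np.empty((len(records), 0), dtype=bool)
    fm = FeatureMatrix(list(builders), data, mask, spans, names)
    if standardise:
        fm.design(fit_rows=fit_rows, standardise=True)
    return fm
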