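"""Labelled dataset construction.

Positives (putative drivers) are retained when their catalogue
recurrence reaches a threshold r; negatives (putative neutrals) are
retained only when they fall within a window w of a surviving positive
on the same chromosome, which controls for genomic-location bias between
the two catalogues.  Defaults follow the coding/non-coding settings
r=5, w=10,000 and r=3, w=1,000 respectively.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationIndex, MutationRecord, classify_region

logger = logging.getLogger(__name__)

#: per-region-class defaults for (recurrence threshold, window in bases)
DEFAULT_THRESHOLDS = {"coding": (5, 10_000), "noncoding": (3, 1_000)}


@dataclass(frozen=True)
class DatasetConfig:
    region_class: str = "noncoding"
    recurrence_threshold: int = 3
    window: int = 1_000

    def __post_init__(self):
        if self.region_class not in {"coding", "noncoding"}:
            raise ValueError(f"region_class must be coding|noncoding, got {self.region_class!r}")
        if self.recurrence_threshold < 1 or self.window < 1:
            raise ValueError("recurrence_threshold and window must be >= 1")

    @classmethod
    def for_region(cls, region_class: str) -> "DatasetConfig":
        r, w = DEFAULT_THRESHOLDS[region_class]
        return cls(region_class=region_class, recurrence_threshold=r, window=w)


@dataclass
class LabelledDataset:
    """Driver/neutral records with the construction provenance."""

    records: list[MutationRecord]
    config: DatasetConfig | None = None
    stage_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chrom,pos,ref,alt) keys in dataset")
        for r in self.records:
            if r.label not in {"driver", "neutral"}:
                raise ValueError(f"dataset records must be labelled driver/neutral, got {r.label!r}")

    def __len__(self):
        return len(self.records)

    @property
    def chroms(self) -> list[str]:
        return sorted({r.chrom for r in self.records})

    def by_chrom(self, chrom: str) -> list[MutationRecord]:
        return [r for r in self.records if r.chrom == chrom]

    @property
    def labels(self) -> np.ndarray:
        """Binary labels: 1 = driver, 0 = neutral."""
        return np.array([1 if r.label == "driver" else 0 for r in self.records])

    def subset(self, indices) -> "LabelledDataset":
        return LabelledDataset([self.records[i] for i in indices], config=self.config)


def filter_by_recurrence(positives, r: int) -> list[MutationRecord]:
    """Keep positives observed at least r times; order preserved."""
    kept = [m for m in positives if m.recurrence >= r]
    if positives and not kept:
        warnings.warn(f"recurrence filter r={r} removed every positive")
    return kept


def match_negatives_by_window(negatives, positives, w: int) -> list[MutationRecord]:
    """Keep each negative lying within w bases (inclusive) of a positive
    on the same chromosome."""
    if not positives:
        warnings.warn("no positives to match against; all negatives dropped")
        return []
    pos_by_chrom: dict[str, list[int]] = {}
    for p in positives:
        pos_by_chrom.setdefault(p.chrom, []).append(p.pos)
    for v in pos_by_chrom.values():
        v.sort()
    kept = []
    for m in negatives:
        positions = pos_by_chrom.get(m.chrom)
        if not positions:
            continue
        # any positive in [pos - w, pos + w]?
        i = bisect_left(positions, m.pos - w)
        if i < len(positions) and positions[i] <= m.pos + w:
            kept.append(m)
    return kept


def deduplicate_against(test, train: LabelledDataset) -> list[MutationRecord]:
    """Drop test records whose (chrom,pos,ref,alt) occurs in the training set."""
    train_keys = {r.key for r in train.records}
    kept = [m for m in test if m.key not in train_keys]
    removed = len(test) - len(kept)
    if removed:
        logger.info("deduplicate_against: removed %d of %d test records", removed, len(test))
    return kept


def _collapse_duplicates(records) -> list[MutationRecord]:
    """Collapse identical variants, keeping the maximum recurrence.

    A key present in both classes is treated as a driver observation and
    removed from the neutral side (logged).
    """
    by_key: dict[tuple, MutationRecord] = {}
    conflicts = 0
    for m in records:
        prev = by_key.get(m.key)
        if prev is None:
            by_key[m.key] = m
            continue
        if prev.label != m.label:
            conflicts += 1
        winner = prev if prev.recurrence >= m.recurrence else m
        label = "driver" if "driver" in (prev.label, m.label) else winner.label
        by_key[m.key] = winner.with_fields(
            label=label, recurrence=max(prev.recurrence, m.recurrence))
    if conflicts:
        logger.info("collapsed %d driver/neutral key collisions as driver", conflicts)
    return list(by_key.values())


def build_dataset(positives, negatives, config: DatasetConfig,
                  annotations: AnnotationIndex) -> LabelledDataset:
    """Run the full construction pipeline for one region class.

    Order: classify regions -> restrict to the configured region class ->
    recurrence-filter positives -> window-match negatives against the
    *surviving* positives -> label and collapse duplicates.
    """
    counts = {"input_positives": len(positives), "input_negatives": len(negatives)}

    def in_region(m):
        return classify_region(m, annotations) == config.region_class

    pos = [m.with_fields(region_class=config.region_class) for m in positives if in_region(m)]
    neg = [m.with_fields(region_class=config.region_class) for m in negatives if in_region(m)]
    counts["region_positives"], counts["region_negatives"] = len(pos), len(neg)

    pos = filter_by_recurrence(pos, config.recurrence_threshold)
    counts["recurrent_positives"] = len(pos)
    if not pos:
        raise ValueError(
            f"no positives with recurrence >= {config.recurrence_threshold} "
            f"in {config.region_class} regions: dataset untrainable")

    neg = match_negatives_by_window(neg, pos, config.window)
    counts["window_matched_negatives"] = len(neg)
    if not neg:
        raise ValueError(
            f"no negatives within {config.window} bp of a surviving positive: "
            "dataset untrainable")

    labelled = ([m.with_fields(label="driver") for m in pos]
                + [m.with_fields(label="neutral") for m in neg])
    records = _collapse_duplicates(labelled)
    counts["final"] = len(records)
    for stage, n in counts.items():
        logger.info("build_dataset[%s]: %s = %d", config.region_class, stage, n)
    return LabelledDataset(records, config=config, stage_counts=counts)


def sample_balanced(ds: LabelledDataset, n_pos: int, n_neg: int, seed: int) -> LabelledDataset:
    """Uniform per-class subsample without replacement, drivers drawn first.

    When a class holds fewer records than requested, all of it is taken
    (with a warning); the same seed always reproduces the same sample.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    rng = np.random.default_rng(seed)
    chosen = []
    for label, n_req in (("driver", n_pos), ("neutral", n_neg)):
        members = [i for i, r in enumerate(ds.records) if r.label == label]
        if len(members) <= n_req:
            if len(members) < n_req:
                warnings.warn(f"requested {n_req} {label} records, only {len(members)} available")
            chosen.extend(members)
        else:
            draw = rng.choice(len(members), size=n_req, replace=False)
            chosen.extend(members[j] for j in draw)
    return ds.subset(sorted(chosen))
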