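"""Regions-of-interest scanner.

Positive (oncogenic) predictions cluster along the genome; a region is
flagged when the contiguous run of high-confidence positive p-scores it
contains has a very low expectation under the empirical score
distribution.  The null treats scored positions as exchangeable
Bernoulli(q) trials with q the genome-wide fraction of scores at or
above the confidence cutoff; the test statistic is the expected number
of maximal runs at least as long as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class RoIConfig:
    confidence_cutoff: float = 0.89
    alpha: float = 0.01
    min_run_length: int = 2
    max_gap: int = 0

    def __post_init__(self):
        if not 0.5 < self.confidence_cutoff <= 1.0:
            raise ValueError("confidence_cutoff must lie in (0.5, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.min_run_length < 1 or self.max_gap < 0:
            raise ValueError("min_run_length >= 1 and max_gap >= 0 required")


@dataclass
class RegionOfInterest:
    chrom: str
    start_pos: int          # 1-based inclusive over scored positions
    end_pos: int
    run_length: int
    q: float                # per-position exceedance probability under the null
    expected_count: float
    passes: bool

    def to_bed_row(self) -> tuple:
        """BED is 0-based half-open; score column holds -log10(E) capped
        at 1000."""
        import math
        if self.expected_count <= 0:
            score = 1000.0
        else:
            score = min(1000.0, -math.log10(self.expected_count))
        return (self.chrom, self.start_pos - 1, self.end_pos, "RoI",
                round(score, 4), ".")


def empirical_null(pscores, c: float) -> float:
    """Fraction of all scored positions with p >= c."""
    pscores = list(pscores)
    if not pscores:
        raise ValueError("empirical_null needs at least one scored position")
    return sum(1 for p in pscores if p >= c) / len(pscores)


def find_runs(positions, pscores, c: float, max_gap: int = 0) -> list[tuple[int, int, int]]:
    """Maximal runs of consecutive scored positions with p >= c.

    Returns (start_pos, end_pos, run_length) triples where run_length
    counts the scored positions inside the run (including tolerated
    sub-threshold gaps).  Up to ``max_gap`` consecutive sub-threshold
    scored positions are absorbed inside a run; any unscored gap
    (non-adjacent positions) breaks a run.
    """
    positions = list(positions)
    pscores = list(pscores)
    if len(positions) != len(pscores):
        raise ValueError("positions and pscores differ in length")
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be strictly increasing")
    runs = []
    i, n = 0, len(positions)
    while i < n:
        if pscores[i] < c:
            i += 1
            continue
        # start a run at i; extend while hits continue, absorbing short
        # sub-threshold stretches when the run resumes within max_gap
        j = i
        last_hit = i
        gap = 0
        while j + 1 < n and positions[j + 1] == positions[j] + 1:
            if pscores[j + 1] >= c:
                j += 1
                last_hit = j
                gap = 0
            elif gap < max_gap:
                j += 1
                gap += 1
            else:
                break
        runs.append((positions[i], positions[last_hit], last_hit - i + 1))
        i = last_hit + 1
    return runs


def run_expectation(L: int, q: float, N: int) -> float:
    """Expected number of maximal runs of length >= L among N i.i.d.
    Bernoulli(q) positions.

    A qualifying run starts at position 1 with probability q^L, or at
    position i in 2..N-L+1 with probability (1-q) * q^L (a failure
    immediately before L successes), giving
    E = q^L * (1 + (N - L) * (1 - q)), exact for all N, L, q.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if L < 1 or N < L:
        raise ValueError("require 1 <= L <= N")
    return (q ** L) * (1.0 + (N - L) * (1.0 - q))


def call_rois(track: dict, cfg: RoIConfig) -> list[RegionOfInterest]:
    """Scan per-position p-scores for regions of interest.

    ``track`` maps chromosome -> (positions, pscores) with positions
    strictly increasing.  The empirical null is pooled over all
    chromosomes; candidate runs come from :func:`find_runs`; each run is
    scored by its genome-wide expected count and passes when that
    expectation falls below alpha and the run is long enough.  Output is
    sorted by expectation, ascending.
    """
    all_scores = [p for positions, pscores in track.values() for p in pscores]
    if not all_scores:
        return []
    q = empirical_null(all_scores, cfg.confidence_cutoff)
    N = len(all_scores)
    rois = []
    for chrom in sorted(track):
        positions, pscores = track[chrom]
        for start, end, L in find_runs(positions, pscores, cfg.confidence_cutoff,
                                       cfg.max_gap):
            if L < cfg.min_run_length:
                continue
            expected = run_expectation(L, q, N)
            rois.append(RegionOfInterest(
                chrom=chrom, start_pos=start, end_pos=end, run_length=L,
                q=q, expected_count=expected,
                passes=expected < cfg.alpha))
    rois.sort(key=lambda r: (r.expected_count, r.chrom, r.start_pos))
    return rois


def write_rois(rois, bed_path, tsv_path=None) -> None:
    """BED6 output (0-based half-open, -log10 expectation in the score
    column) plus an optional TSV sidecar with exact values."""
    bed = pd.DataFrame([r.to_bed_row() for r in rois],
                       columns=["chrom", "start", "end", "name", "score", "strand"])
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    if tsv_path is not None:
        tsv = pd.DataFrame(
            [(r.chrom, r.start_pos, r.end_pos, r.run_length, r.q,
              r.expected_count, r.passes) for r in rois],
            columns=["chrom", "start_pos", "end_pos", "run_length", "q",
                     "expected_count", "passes"])
        tsv.to_csv(tsv_path, sep="\t", index=False)


def read_pscore_track(path) -> dict:
    """Read tab-delimited chrom/pos/p_score into the call_rois input form."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "pos", "p"])
    track = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        track[str(chrom)] = (sub["pos"].astype(int).tolist(), sub["p"].astype(float).tolist())
    return track
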