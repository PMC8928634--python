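"""G4Hunter scoring of potential quadruplex-forming sequences (PQS).

Each base in a run of k consecutive G scores +min(k,4); each base in a run
of k consecutive C scores -min(k,4); everything else (including N, which
breaks runs) scores 0. A sliding window of mean base scores flags PQS
wherever |mean| >= threshold; qualifying windows of the same sign that
share bases merge into one region. Defaults (window 25, threshold 1.2) are
the G4Hunter defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode
from .genome_io import GenomeRecord


@dataclass(frozen=True)
class PQSRegion:
    start: int  # 0-based half-open on the reference strand; may wrap (end > genome length)
    end: int
    strand: int  # +1 = G-rich on the reference strand, -1 = C-rich
    score: float  # extremal qualifying window mean within the region

    @property
    def length(self) -> int:
        return self.end - self.start


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base G4Hunter scores as an int8 array."""
    codes = encode(seq)
    n = len(codes)
    scores = np.zeros(n, dtype=np.int8)
    if n == 0:
        return scores
    for target, sign in ((2, 1), (1, -1)):  # G runs then C runs
        mask = codes == target
        if not mask.any():
            continue
        padded = np.concatenate([[False], mask, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            scores[a:b] = sign * min(b - a, 4)
    return scores


def find_pqs(
    rec: GenomeRecord | str,
    window: int = 25,
    threshold: float = 1.2,
    count_mode: str = "regions",
):
    """Locate PQS and report the per-1000-bp density.

    Returns (regions, density). In the default ``regions`` mode the density
    counts merged maximal regions of same-sign qualifying windows; in
    ``windows`` mode it counts raw qualifying windows (both conventions are
    in use for G4Hunter-style densities, so the mode is always reported
    alongside). Circular genomes are evaluated across the origin and the
    density denominator is the sequence length as provided.
    """
    if count_mode not in ("regions", "windows"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    seq = rec.seq if isinstance(rec, GenomeRecord) else rec
    circular = isinstance(rec, GenomeRecord) and rec.topology == "circular"
    n = len(seq)
    if n < window:
        return [], 0.0

    if circular:
        # pad >= 4 preserves the min(run, 4) cap for runs crossing the origin
        pad = min(n, 8)
        scores = g4_base_scores(seq[-pad:] + seq + seq[: window - 1]).astype(np.float64)[pad:]
    else:
        scores = g4_base_scores(seq).astype(np.float64)
    csum = np.concatenate([[0.0], np.cumsum(scores)])
    means = (csum[window:] - csum[:-window]) / window  # means[i] = window starting at base i
    qualify = np.abs(means) >= threshold
    starts = np.flatnonzero(qualify)
    n_windows = len(starts)

    regions: list[PQSRegion] = []
    for i in starts:
        i = int(i)
        s = 1 if means[i] > 0 else -1
        if regions and s == regions[-1].strand and i < regions[-1].end:
            last = regions[-1]
            best = last.score if abs(last.score) >= abs(means[i]) else float(means[i])
            regions[-1] = PQSRegion(last.start, max(last.end, i + window), s, best)
        else:
            regions.append(PQSRegion(i, i + window, s, float(means[i])))

    if circular and len(regions) >= 2:
        first, last = regions[0], regions[-1]
        if last.end > n and first.start < last.end - n and first.strand == last.strand:
            best = first.score if abs(first.score) >= abs(last.score) else last.score
            regions = [PQSRegion(last.start, max(last.end, first.end + n), last.strand, best)] + regions[1:-1]

    count = len(regions) if count_mode == "regions" else n_windows
    density = count / n * 1000.0
    return regions, density


__all__ = ["PQSRegion", "g4_base_scores", "find_pqs"]
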