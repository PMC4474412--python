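"""Log-odds PWM scanning: predict motif occurrences (TFBSs) on sequences.

Each motif's probability matrix is turned into a log2-odds matrix against
an order-0 background; every window on both strands is scored, windows at
or above the threshold become predicted sites, and overlapping same-motif
sites are greedily resolved to the best-scoring one (cross-motif overlaps
are allowed — co-factors co-occur).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .background import MarkovBackground
from .index import encode
from .io import Region
from .motifs import Motif

__all__ = ["PredictedSite", "scan", "max_score", "write_sites_bed"]


@dataclass
class PredictedSite:
    chrom: str
    start: int  # genomic (or region-local when the region has no coordinates)
    end: int
    strand: str
    motif_id: str
    score: float
    region_index: int = -1


def _logodds(motif: Motif, bg: MarkovBackground, pseudocount: float = 0.25) -> np.ndarray:
    q = np.clip(bg.initial_probs, 1e-9, None)
    return np.log2(motif.probs(pseudocount) / q[None, :])


def max_score(motif: Motif, bg: MarkovBackground, pseudocount: float = 0.25) -> float:
    return float(_logodds(motif, bg, pseudocount).max(axis=1).sum())


def _window_scores(codes: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Score of every window of length L; windows touching N score -inf."""
    L = W.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win >= 0, axis=1)
    scores = np.full(n, -np.inf)
    if np.any(valid):
        idx = np.clip(win[valid], 0, 3)
        scores[valid] = W[np.arange(L)[None, :], idx].sum(axis=1)
    return scores


def scan(
    motifs: Sequence[Motif],
    regions: Sequence[Region],
    background: MarkovBackground,
    score_threshold: float | Sequence[float] | None = None,
    threshold_frac: float = 0.7,
    pseudocount: float = 0.25,
) -> list[PredictedSite]:
    """Predict sites for each motif over all regions, both strands.

    ``score_threshold`` may be a single absolute value, one per motif, or
    None (then ``threshold_frac`` of each motif's maximum log-odds score is
    used).  Same-motif overlapping hits are greedily reduced to the best.
    """
    if score_threshold is None:
        thresholds = [threshold_frac * max_score(m, background, pseudocount) for m in motifs]
    elif np.isscalar(score_threshold):
        thresholds = [float(score_threshold)] * len(motifs)
    else:
        thresholds = [float(t) for t in score_threshold]
    sites: list[PredictedSite] = []
    encoded = [encode(r.sequence).astype(np.int64) for r in regions]
    for mi, motif in enumerate(motifs):
        W = _logodds(motif, background, pseudocount)
        Wrc = W[::-1, ::-1]
        L = motif.length
        motif_id = motif.name or f"motif_{mi + 1}"
        thr = thresholds[mi]
        for ridx, (region, codes) in enumerate(zip(regions, encoded)):
            if len(codes) < L:
                continue
            fwd = _window_scores(codes, W)
            rev = _window_scores(codes, Wrc)
            hits = []
            for p in np.flatnonzero(fwd >= thr):
                hits.append((float(fwd[p]), int(p), "+"))
            for p in np.flatnonzero(rev >= thr):
                hits.append((float(rev[p]), int(p), "-"))
            hits.sort(key=lambda h: (-h[0], h[1], h[2]))
            taken: list[tuple[int, int]] = []
            base = region.start if region.start is not None else 0
            chrom = region.chrom if region.chrom is not None else region.id
            for score, p, strand in hits:
                if any(p < e and p + L > s for s, e in taken):
                    continue
                taken.append((p, p + L))
                sites.append(
                    PredictedSite(
                        chrom=chrom,
                        start=base + p,
                        end=base + p + L,
                        strand=strand,
                        motif_id=motif_id,
                        score=score,
                        region_index=ridx,
                    )
                )
    sites.sort(key=lambda s: (s.chrom, s.start, s.motif_id, s.strand))
    return sites


def write_sites_bed(sites: Sequence[PredictedSite], path: str | Path) -> None:
    """BED6 output; scores rescaled to 0-1000 over the site set."""
    if sites:
        smin = min(s.score for s in sites)
        smax = max(s.score for s in sites)
        span = max(smax - smin, 1e-12)
    with open(path, "w") as fh:
        for s in sites:
            bed_score = int(round(1000 * (s.score - smin) / span)) if sites else 0
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.motif_id}\t{bed_score}\t{s.strand}\n")
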