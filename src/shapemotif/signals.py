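"""Signal-shape features of candidate seeds.

For every occurrence of a word, a fixed window around the occurrence centre
is cut out of a genome-wide signal track (DNase I, histone marks, ...),
per-bp values are summed across occurrences and discretised into fixed-size
bins.  This aggregate φ(X) — the word's *mark distribution* — is normalised
to unit mass and smoothed by a discrete Fourier transform that discards the
upper 5/8 of the frequency components, giving f(X).  Three scores summarise
its shape:

* intensity  S_I = Σ φ(X) / wc — average window signal per occurrence;
* kurtosis   S_K — excess kurtosis of f(X) read as a probability mass over
  bin positions (sharply peaked profiles score high, flat ones ≈ −1.2);
* asymmetry  S_A — symmetrised Kullback–Leibler divergence between the left
  half of f(X) and the mirrored right half (irregular, repeat-like profiles
  score high).

The combined seed score is S = β_I·S_I + β_K·S_K + β_A·S_A + S_W, with the
shape features z-normalised across the candidate set per track (and the
asymmetry score negated so that all β weights can stay non-negative while
high asymmetry is penalised).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Region, SignalTrack

__all__ = [
    "MarkDistribution",
    "aggregate_mark_distribution",
    "normalize_and_smooth",
    "intensity_score",
    "kurtosis_score",
    "asymmetry_score",
    "symmetrized_kl",
    "combined_score",
    "score_candidates",
]

KL_EPSILON = 1e-6  # pseudo-mass per bin before KL
KURTOSIS_CAP = 50.0  # zero-variance (single-bin) profiles map here
DEFAULT_KEEP_FRAC = 0.375  # fraction of non-negative DFT frequencies retained


class UnscorableWordError(ValueError):
    """A word with no usable occurrences cannot receive shape scores."""


@dataclass
class MarkDistribution:
    """Binned aggregate of one signal track around one word's occurrences."""

    word: str
    track_name: str
    bins: np.ndarray  # raw aggregate φ(X), length B
    bin_width: int
    halfwidth: int
    n_occurrences_used: int
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def _occurrence_center(offset: int, K: int) -> int:
    return offset + K // 2


def aggregate_mark_distribution(
    occurrences: Sequence[tuple[int, int, str]],
    regions: Sequence[Region],
    track: SignalTrack,
    K: int,
    halfwidth: int = 1000,
    bin_width: int = 25,
    word: str = "",
) -> MarkDistribution:
    """Sum per-bp signal windows over all occurrences and bin them.

    The window is [centre − halfwidth, centre + halfwidth) around the
    occurrence midpoint in genomic coordinates; minus-strand occurrence
    windows are reversed before binning so profiles align in motif
    orientation.  Windows that leave the track's covered span are
    zero-filled.
    """
    if halfwidth % bin_width != 0:
        raise ValueError("halfwidth must be a multiple of bin_width")
    if not occurrences:
        raise UnscorableWordError(f"word {word!r}: no occurrences to aggregate")
    width = 2 * halfwidth
    acc = np.zeros(width, dtype=float)
    used = 0
    for ridx, offset, strand in occurrences:
        region = regions[ridx]
        if region.chrom is None or region.start is None:
            raise ValueError(f"region {region.id} lacks genomic coordinates")
        centre = region.start + _occurrence_center(offset, K)
        window = track.query(region.chrom, centre - halfwidth, centre + halfwidth)
        if strand == "-":
            window = window[::-1]
        acc += window
        used += 1
    B = width // bin_width
    bins = acc.reshape(B, bin_width).sum(axis=1)
    return MarkDistribution(
        word=word,
        track_name=track.name,
        bins=bins,
        bin_width=bin_width,
        halfwidth=halfwidth,
        n_occurrences_used=used,
    )


def smooth_profile(normalized: np.ndarray, keep_frac: float = DEFAULT_KEEP_FRAC) -> np.ndarray:
    """DFT low-pass: keep the ⌈keep_frac·(B/2)⌉ lowest non-negative
    frequencies (DC always kept), zero the rest, floor at 0, renormalise."""
    B = len(normalized)
    spec = np.fft.rfft(normalized)
    n_keep = max(1, int(np.ceil(keep_frac * (B // 2))))
    spec[n_keep:] = 0.0
    sm = np.fft.irfft(spec, n=B)
    sm = np.maximum(sm, 0.0)
    total = sm.sum()
    if total <= 0:
        return np.full(B, 1.0 / B)
    return sm / total


def normalize_and_smooth(md: MarkDistribution, keep_frac: float = DEFAULT_KEEP_FRAC) -> MarkDistribution:
    """Fill ``normalized`` (unit mass) and ``smoothed`` (DFT low-pass)."""
    total = md.bins.sum()
    if total <= 0:
        warnings.warn(f"word {md.word!r}: all-zero profile on {md.track_name}; using uniform")
        md.normalized = np.full(md.n_bins, 1.0 / md.n_bins)
        md.smoothed = md.normalized.copy()
        return md
    md.normalized = md.bins / total
    md.smoothed = smooth_profile(md.normalized, keep_frac)
    return md


def intensity_score(md: MarkDistribution) -> float:
    """S_I: total aggregated signal per occurrence."""
    if md.n_occurrences_used < 1:
        raise UnscorableWordError(f"word {md.word!r}: no occurrences")
    return float(md.bins.sum() / md.n_occurrences_used)


def kurtosis_score(md: MarkDistribution) -> float:
    """S_K: excess kurtosis of the smoothed profile over bin positions."""
    if md.smoothed is None:
        raise ValueError("call normalize_and_smooth first")
    p = md.smoothed
    x = np.arange(len(p), dtype=float)
    mean = float(p @ x)
    mu2 = float(p @ (x - mean) ** 2)
    if mu2 <= 0:
        return KURTOSIS_CAP
    mu4 = float(p @ (x - mean) ** 4)
    return min(mu4 / mu2**2 - 3.0, KURTOSIS_CAP)


def symmetrized_kl(p: np.ndarray, q: np.ndarray, eps: float = KL_EPSILON) -> float:
    """½·D_KL(p‖q) + ½·D_KL(q‖p) with per-bin pseudo-mass ε."""
    p = np.asarray(p, dtype=float) + eps
    q = np.asarray(q, dtype=float) + eps
    p = p / p.sum()
    q = q / q.sum()
    lr = np.log(p / q)
    return float(0.5 * (p @ lr) + 0.5 * (q @ -lr))


def asymmetry_score(md: MarkDistribution) -> float:
    """S_A: symmetrised KL between the left half and the mirrored right half
    of the smoothed profile (each renormalised).  0 for mirror-symmetric
    profiles; large for irregular ones."""
    if md.smoothed is None:
        raise ValueError("call normalize_and_smooth first")
    B = len(md.smoothed)
    if B % 2 != 0:
        raise ValueError("profile must have an even number of bins")
    lhs = md.smoothed[: B // 2].copy()
    rhs = md.smoothed[B // 2 :][::-1].copy()  # mirrored about the centre
    return symmetrized_kl(lhs, rhs)


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def score_candidates(
    candidates: pd.DataFrame,
    index,
    regions: Sequence[Region],
    tracks: Sequence[SignalTrack],
    halfwidth: int = 1000,
    bin_width: int = 25,
    keep_frac: float = DEFAULT_KEEP_FRAC,
) -> tuple[pd.DataFrame, dict[tuple[str, str], MarkDistribution]]:
    """Raw per-track shape scores for every candidate word.

    Returns an augmented copy of ``candidates`` with columns
    ``SI_<track>``, ``SK_<track>``, ``SA_<track>`` and a mapping
    (word, track_name) → MarkDistribution for reuse (clustering, export).
    """
    out = candidates.copy()
    profiles: dict[tuple[str, str], MarkDistribution] = {}
    cols: dict[str, list[float]] = {}
    for track in tracks:
        cols[f"SI_{track.name}"] = []
        cols[f"SK_{track.name}"] = []
        cols[f"SA_{track.name}"] = []
    for word in out["word"]:
        occ = index.locate(word)
        for track in tracks:
            md = aggregate_mark_distribution(
                occ, regions, track, index.K, halfwidth, bin_width, word=word
            )
            normalize_and_smooth(md, keep_frac)
            profiles[(word, track.name)] = md
            cols[f"SI_{track.name}"].append(intensity_score(md))
            cols[f"SK_{track.name}"].append(kurtosis_score(md))
            cols[f"SA_{track.name}"].append(asymmetry_score(md))
    for name, vals in cols.items():
        out[name] = vals
    return out, profiles


def combined_score(
    scored: pd.DataFrame,
    track_names: Sequence[str],
    beta_I: float = 0.3,
    beta_K: float = 0.5,
    beta_A: float = 0.5,
) -> pd.DataFrame:
    """Combine S_W with z-normalised shape features into the overall score S.

    All four sub-scores live on incommensurable scales (S_I is
    track-scale-dependent, S_K unitless in [−2, ∞), S_A in nats, S_W a
    ratio), so each — S_W included — is z-normalised across the candidate
    set (per track for the shape features, which are then averaged across
    tracks); the asymmetry feature is negated so high asymmetry is
    penalised with β_A ≥ 0.  The combination is
    S = β_I·S_I + β_K·S_K + β_A·S_A + S_W on the normalised scale.  With
    all β = 0 (sequence-only mode) the ranking reduces to the S_W ranking
    (z-normalisation is monotone).
    """
    out = scored.copy()
    n = len(out)
    if track_names and n > 0:
        zi = np.zeros(n)
        zk = np.zeros(n)
        za = np.zeros(n)
        for t in track_names:
            zi += _zscore(out[f"SI_{t}"].to_numpy())
            zk += _zscore(out[f"SK_{t}"].to_numpy())
            za += _zscore(-out[f"SA_{t}"].to_numpy())
        zi /= len(track_names)
        zk /= len(track_names)
        za /= len(track_names)
    else:
        zi = zk = za = np.zeros(n)
    # a ratio is location-scale only on the log axis; z-normalising
    # log S_W keeps the over-representation term commensurate with the
    # shape features instead of dominated by its heavy upper tail
    zw = _zscore(np.log(out["S_W"].to_numpy()))
    out["feat_I"] = zi
    out["feat_K"] = zk
    out["feat_A"] = za
    out["feat_W"] = zw
    out["S"] = beta_I * zi + beta_K * zk + beta_A * za + zw
    return out.sort_values("S", ascending=False, kind="stable").reset_index(drop=True)
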