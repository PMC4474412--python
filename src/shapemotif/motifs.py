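"""From seeds to position-frequency-matrix motifs.

Each top-ranked seed word is generalised into a primary motif by counting
the occurrences of every single-base substitution variant (4·K lookups:
the seed base plus the 3 alternatives at each of the K positions).  Primary
motifs are then clustered to remove redundancy and form full-length motifs:
a pairwise dissimilarity is computed as 1 − (maximum Pearson correlation of
the overlapping probability columns over all offsets and both orientations),
optionally mixed with the symmetrised KL divergence between the motifs'
signal profiles; average-linkage agglomerative clustering follows, the
cluster count is chosen by the gap statistic, members of each cluster are
aligned to the highest-scoring seed and summed, and the merged motifs are
trimmed to drop ambiguous or low-count ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .index import KmerIndex, revcomp
from .signals import MarkDistribution, symmetrized_kl

__all__ = [
    "Motif",
    "generalize_seed",
    "motif_distance",
    "build_distance_matrix",
    "cluster_motifs",
    "merge_cluster",
    "trim_motif",
    "rank_motifs",
]

BASES = "ACGT"
DEFAULT_PSEUDOCOUNT = 0.25
MIN_MOTIF_LEN = 4  # trimming never goes below this
NO_OVERLAP_DISTANCE = 2.0  # sentinel: pairs without an admissible overlap never merge

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


@dataclass
class Motif:
    """A PFM motif: per-position base counts plus bookkeeping."""

    counts: np.ndarray  # (L, 4) floats, order A C G T
    support: float = 0.0
    seed_word: str = ""
    score: float = 0.0  # combined seed score S of the best member
    name: str = ""
    mark_distributions: dict[str, MarkDistribution] = field(default_factory=dict)
    member_seeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def probs(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        out = []
        for row in self.counts:
            best = row.max()
            ties = frozenset(BASES[i] for i in range(4) if row[i] == best)
            out.append(_IUPAC[ties])
        return "".join(out)

    def reverse_complement(self) -> "Motif":
        m = Motif(
            counts=self.counts[::-1, ::-1].copy(),
            support=self.support,
            seed_word=revcomp(self.seed_word) if set(self.seed_word) <= set("ACGTN") else self.seed_word,
            score=self.score,
            name=self.name,
            member_seeds=list(self.member_seeds),
        )
        m.mark_distributions = {
            t: MarkDistribution(
                word=md.word,
                track_name=md.track_name,
                bins=md.bins[::-1].copy(),
                bin_width=md.bin_width,
                halfwidth=md.halfwidth,
                n_occurrences_used=md.n_occurrences_used,
                normalized=None if md.normalized is None else md.normalized[::-1].copy(),
                smoothed=None if md.smoothed is None else md.smoothed[::-1].copy(),
            )
            for t, md in self.mark_distributions.items()
        }
        return m


def generalize_seed(seed_word: str, index: KmerIndex) -> Motif:
    """Single-substitution PFM around a seed.

    counts[i][b] is the occurrence count of the word with base b at
    position i and the seed's bases elsewhere — 4·K index lookups.  The
    motif's support is the count of the seed itself.
    """
    K = len(seed_word)
    if K != index.K:
        raise ValueError("seed length must equal index K")
    wc = index.count(seed_word)
    if wc == 0:
        raise KeyError(f"seed {seed_word!r} not present in the index")
    counts = np.zeros((K, 4))
    for i in range(K):
        for b, base in enumerate(BASES):
            variant = seed_word[:i] + base + seed_word[i + 1 :]
            counts[i, b] = index.count(variant)
    return Motif(counts=counts, support=float(wc), seed_word=seed_word, member_seeds=[seed_word])


# ---------------------------------------------------------------------------
# Pairwise distance
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb))


def motif_distance(
    m1: Motif,
    m2: Motif,
    use_marks: bool = False,
    beta_cluster: float = 0.2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_overlap: int | None = None,
) -> tuple[float, int, str]:
    """Best-alignment dissimilarity between two motifs.

    All relative offsets with overlap ≥ min_overlap and both orientations of
    ``m2`` are tried; the sequence distance is 1 − max Pearson correlation
    of the flattened overlapping probability columns.  With ``use_marks``
    the symmetrised KL between the motifs' smoothed profiles (rescaled to
    [0, 1) as KL/(1+KL)) is mixed in with weight ``beta_cluster``.

    Returns (distance, offset, orientation) where ``offset`` places column 0
    of (possibly reverse-complemented) m2 at column ``offset`` of m1.
    """
    p1 = m1.probs(pseudocount)
    L1, L2 = m1.length, m2.length
    if min_overlap is None:
        min_overlap = max(MIN_MOTIF_LEN, int(np.ceil(min(L1, L2) / 2)))
    best_r = -np.inf
    best_off, best_orient = 0, "+"
    for orient in ("+", "-"):
        p2 = m2.probs(pseudocount) if orient == "+" else m2.probs(pseudocount)[::-1, ::-1]
        for off in range(-(L2 - min_overlap), L1 - min_overlap + 1):
            lo1, hi1 = max(0, off), min(L1, off + L2)
            if hi1 - lo1 < min_overlap:
                continue
            lo2, hi2 = lo1 - off, hi1 - off
            r = _pearson(p1[lo1:hi1], p2[lo2:hi2])
            if r > best_r:
                best_r, best_off, best_orient = r, off, orient
    if not np.isfinite(best_r):
        return NO_OVERLAP_DISTANCE, 0, "+"
    d_seq = 1.0 - best_r
    if use_marks and m1.mark_distributions and m2.mark_distributions:
        kls = []
        shared = set(m1.mark_distributions) & set(m2.mark_distributions)
        for t in sorted(shared):
            a = m1.mark_distributions[t]
            b = m2.mark_distributions[t]
            pa = a.smoothed if a.smoothed is not None else a.bins / max(a.bins.sum(), 1e-12)
            pb = b.smoothed if b.smoothed is not None else b.bins / max(b.bins.sum(), 1e-12)
            if best_orient == "-":
                pb = pb[::-1]
            kls.append(symmetrized_kl(pa, pb))
        if kls:
            kl = float(np.mean(kls))
            d_marks = kl / (1.0 + kl)
            return (1 - beta_cluster) * d_seq + beta_cluster * d_marks, best_off, best_orient
    return d_seq, best_off, best_orient


def build_distance_matrix(
    motifs: Sequence[Motif],
    use_marks: bool = False,
    beta_cluster: float = 0.2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, dict[tuple[int, int], tuple[int, str]]]:
    """Symmetric dissimilarity matrix plus per-pair best alignments."""
    M = len(motifs)
    D = np.zeros((M, M))
    meta: dict[tuple[int, int], tuple[int, str]] = {}
    for i in range(M):
        for j in range(i + 1, M):
            d, off, orient = motif_distance(
                motifs[i], motifs[j], use_marks, beta_cluster, pseudocount
            )
            D[i, j] = D[j, i] = max(d, 0.0)  # guard float noise at r ≈ 1
            meta[(i, j)] = (off, orient)
    return D, meta


# ---------------------------------------------------------------------------
# Clustering (average linkage + gap statistic)
# ---------------------------------------------------------------------------

def _pooled_within_dispersion(D: np.ndarray, labels: np.ndarray) -> float:
    """W = Σ_clusters D_r / (2 n_r) with D_r the sum of pairwise distances."""
    W = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        W += sub.sum() / (2 * len(idx))
    return W


def _random_reference_motifs(M: int, L: int, rng: np.random.Generator) -> list[Motif]:
    """Uniform draws on the space of row-normalised L×4 matrices."""
    out = []
    for _ in range(M):
        probs = rng.dirichlet(np.ones(4), size=L)
        out.append(Motif(counts=probs * 100.0, support=100.0))
    return out


def choose_k_gap(
    D: np.ndarray,
    linkage_matrix: np.ndarray,
    reference_dispersions: np.ndarray,
    k_max: int,
) -> int:
    """Gap(k) = mean_b log W*_kb − log W_k; smallest k passing the
    one-standard-error rule, else argmax."""
    M = D.shape[0]
    ks = range(1, min(M, k_max) + 1)
    tiny = 1e-12
    gaps, sks = [], []
    for k in ks:
        labels = fcluster(linkage_matrix, t=k, criterion="maxclust") if k > 1 else np.ones(M, int)
        logW = np.log(max(_pooled_within_dispersion(D, labels), tiny))
        ref_logW = np.log(np.maximum(reference_dispersions[:, k - 1], tiny))
        gaps.append(ref_logW.mean() - logW)
        sks.append(ref_logW.std() * np.sqrt(1 + 1 / len(ref_logW)))
    gaps = np.asarray(gaps)
    sks = np.asarray(sks)
    for i in range(len(gaps) - 1):
        if gaps[i] >= gaps[i + 1] - sks[i + 1]:
            return i + 1
    return int(np.argmax(gaps)) + 1


def _has_sentinel_pair(D: np.ndarray, labels: np.ndarray) -> bool:
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > 1 and D[np.ix_(idx, idx)].max() >= NO_OVERLAP_DISTANCE - 1e-9:
            return True
    return False


def cluster_motifs(
    motifs: Sequence[Motif],
    D: np.ndarray,
    use_marks: bool = False,
    beta_cluster: float = 0.2,
    n_reference: int = 20,
    k_max: int = 30,
    distance_threshold: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[list[int]]:
    """Average-linkage clusters of motif indices; k chosen by gap statistic.

    With ``distance_threshold > 0`` the dendrogram is instead cut at that
    dissimilarity (the "more stringent clustering" escape hatch).
    Reference dispersions use the sequence-only distance on matrices drawn
    uniformly on the probability simplex.
    """
    M = len(motifs)
    if M == 0:
        return []
    if M == 1:
        return [[0]]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = linkage(squareform(D, checks=False), method="average")
    if distance_threshold > 0:
        labels = fcluster(Z, t=distance_threshold, criterion="distance")
    else:
        k_hi = min(M, k_max)
        L_med = int(np.median([m.length for m in motifs]))
        ref_disp = np.empty((n_reference, k_hi))
        for b in range(n_reference):
            ref = _random_reference_motifs(M, L_med, rng)
            Dref, _ = build_distance_matrix(ref, use_marks=False)
            Zref = linkage(squareform(Dref, checks=False), method="average")
            for k in range(1, k_hi + 1):
                lab = fcluster(Zref, t=k, criterion="maxclust") if k > 1 else np.ones(M, int)
                ref_disp[b, k - 1] = _pooled_within_dispersion(Dref, lab)
        k_star = choose_k_gap(D, Z, ref_disp, k_hi)
        labels = fcluster(Z, t=k_star, criterion="maxclust") if k_star > 1 else np.ones(M, int)
        # the no-overlap sentinel means "never merged": raise k until no
        # cluster contains a sentinel pair
        while k_star < M and _has_sentinel_pair(D, labels):
            k_star += 1
            labels = fcluster(Z, t=k_star, criterion="maxclust")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    # deterministic order: by best member score, then size
    out = sorted(
        clusters.values(),
        key=lambda idx: (-max(motifs[i].score for i in idx), -len(idx), idx[0]),
    )
    return out


def merge_cluster(
    members: Sequence[Motif],
    use_marks: bool = False,
    beta_cluster: float = 0.2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Motif:
    """Star-align cluster members to the highest-scoring seed and sum counts.

    Each member is aligned to the representative by its best pairwise
    offset/orientation; count matrices are summed column-wise over the
    union span, and mark distributions are support-weighted averages.
    """
    if not members:
        raise ValueError("empty cluster")
    rep_i = int(np.argmax([m.score for m in members]))
    rep = members[rep_i]
    placed: list[tuple[int, Motif]] = [(0, rep)]
    for i, m in enumerate(members):
        if i == rep_i:
            continue
        _, off, orient = motif_distance(rep, m, use_marks, beta_cluster, pseudocount)
        placed.append((off, m if orient == "+" else m.reverse_complement()))
    lo = min(off for off, _ in placed)
    hi = max(off + m.length for off, m in placed)
    counts = np.zeros((hi - lo, 4))
    for off, m in placed:
        counts[off - lo : off - lo + m.length] += m.counts
    support = float(sum(m.support for _, m in placed))
    merged = Motif(
        counts=counts,
        support=support,
        seed_word=rep.seed_word,
        score=max(m.score for m in members),
        member_seeds=[s for m in members for s in m.member_seeds],
    )
    tracks = set()
    for _, m in placed:
        tracks.update(m.mark_distributions)
    for t in sorted(tracks):
        mds = [(m.support, m.mark_distributions[t]) for _, m in placed if t in m.mark_distributions]
        w = np.array([s for s, _ in mds], dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(mds), 1 / len(mds))
        proto = mds[0][1]
        bins = sum(wi * md.bins for wi, (_, md) in zip(w, mds))
        sm_parts = [md.smoothed for _, md in mds if md.smoothed is not None]
        smoothed = None
        if len(sm_parts) == len(mds):
            smoothed = sum(wi * s for wi, s in zip(w, sm_parts))
            smoothed = smoothed / smoothed.sum()
        merged.mark_distributions[t] = MarkDistribution(
            word=merged.seed_word,
            track_name=t,
            bins=bins,
            bin_width=proto.bin_width,
            halfwidth=proto.halfwidth,
            n_occurrences_used=sum(md.n_occurrences_used for _, md in mds),
            smoothed=smoothed,
        )
    return merged


def _column_info(probs_row: np.ndarray) -> float:
    p = probs_row[probs_row > 0]
    return float(2.0 + (p * np.log2(p)).sum())


def trim_motif(
    motif: Motif,
    min_info: float = 0.3,
    min_support_frac: float = 0.1,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Motif:
    """Strip ambiguous or low-count end columns.

    A column is droppable when its information content (after pseudocounts)
    is below ``min_info`` bits or its count total is below
    ``min_support_frac`` of the best column's; trimming stops at 4 columns
    and a fully-droppable motif is returned untrimmed with a warning.
    """
    probs = motif.probs(pseudocount)
    col_support = motif.counts.sum(axis=1)
    max_support = col_support.max() if motif.length else 0.0
    ic = np.array([_column_info(row) for row in probs])
    droppable = (ic < min_info) | (col_support < min_support_frac * max_support)
    lo, hi = 0, motif.length
    while hi - lo > MIN_MOTIF_LEN and droppable[lo]:
        lo += 1
    while hi - lo > MIN_MOTIF_LEN and droppable[hi - 1]:
        hi -= 1
    if lo == 0 and hi == motif.length:
        return motif
    if np.all(droppable):
        import warnings

        warnings.warn(f"motif {motif.seed_word!r}: all columns droppable; left untrimmed")
        return motif
    return Motif(
        counts=motif.counts[lo:hi].copy(),
        support=motif.support,
        seed_word=motif.seed_word,
        score=motif.score,
        name=motif.name,
        mark_distributions=dict(motif.mark_distributions),
        member_seeds=list(motif.member_seeds),
    )


def rank_motifs(motifs: Sequence[Motif]) -> list[Motif]:
    """Order output motifs by total support × best member score."""
    return sorted(motifs, key=lambda m: -(m.support * max(m.score, 1e-12)))


_IUPAC_SETS = {code: set(bases) for bases, code in [(''.join(sorted(b)), c) for b, c in
               [("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
                ("AC", "M"), ("AG", "R"), ("AT", "W"), ("CG", "S"), ("CT", "Y"), ("GT", "K"),
                ("ACG", "V"), ("ACT", "H"), ("AGT", "D"), ("CGT", "B"), ("ACGT", "N")]]}


def consensus_mismatches(target: str, consensus: str) -> int:
    """Minimum mismatch count of ``target`` against an IUPAC ``consensus``
    over all alignments and both orientations.

    When the consensus is shorter than the target, uncovered target
    positions count as mismatches.
    """
    best = len(target)
    for t in (target, revcomp(target)):
        if len(consensus) >= len(t):
            for off in range(len(consensus) - len(t) + 1):
                mm = sum(
                    base not in _IUPAC_SETS.get(code, set())
                    for base, code in zip(t, consensus[off : off + len(t)])
                )
                best = min(best, mm)
        else:
            short = len(t) - len(consensus)
            for off in range(short + 1):
                mm = short + sum(
                    base not in _IUPAC_SETS.get(code, set())
                    for base, code in zip(t[off : off + len(consensus)], consensus)
                )
                best = min(best, mm)
    return best
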