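"""Site-level accuracy: binned confusion counts, ROC/AUROC, cross-validation
and the β-weight grid search.

Each ChIP-seq summit is flanked by 650 bp on both sides (1300 bp total,
13 bins of 100 bp).  The central bin — centred on the summit — is the TFBS
bin; the other 12 are flanking bins.  At one scanner threshold:

* TP = summits with a predicted-site midpoint closer than 50 bp;
* FP = flanking bins containing at least one predicted-site midpoint;
* FN = (one TFBS bin per summit) − TP;
* TN = (12 flanking bins per summit) − FP;

with sensitivity TP/(TP+FN) and specificity TN/(TN+FP).  Sweeping the
scanner threshold traces a ROC curve whose trapezoidal area (with (0,0)
and (1,1) anchors) is the AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .background import MarkovBackground
from .io import Region
from .motifs import Motif
from .scanner import PredictedSite, max_score, scan

__all__ = [
    "SiteEvalResult",
    "evaluate_sites",
    "roc_auroc",
    "cross_validate",
    "grid_search_betas",
]

DEFAULT_FLANK = 650
DEFAULT_BIN_WIDTH = 100


@dataclass
class SiteEvalResult:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auroc: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else 0.0


def evaluate_sites(
    predicted_sites: Sequence[PredictedSite],
    summits: Sequence[tuple[str, int]],
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> SiteEvalResult:
    """Confusion counts at a single threshold (see module docstring)."""
    if not summits:
        raise ValueError("no summits to evaluate against")
    half_bin = bin_width / 2
    n_flank_bins_per_summit = 2 * flank // bin_width - 1
    mids_by_chrom: dict[str, np.ndarray] = {}
    for s in predicted_sites:
        mids_by_chrom.setdefault(s.chrom, []).append((s.start + s.end) / 2)  # type: ignore[arg-type]
    mids_by_chrom = {c: np.sort(np.asarray(v)) for c, v in mids_by_chrom.items()}
    TP = 0
    FP = 0
    for chrom, pos in summits:
        mids = mids_by_chrom.get(chrom)
        if mids is None or len(mids) == 0:
            continue
        lo = np.searchsorted(mids, pos - flank, side="left")
        hi = np.searchsorted(mids, pos + flank, side="right")
        d = mids[lo:hi] - pos
        if len(d) == 0:
            continue
        central = np.abs(d) < half_bin
        if np.any(central):
            TP += 1
        flanking = d[~central]
        flanking = flanking[(flanking >= -flank) & (flanking < flank)]
        if len(flanking):
            bins = np.floor((flanking + flank) / bin_width).astype(int)
            FP += len(np.unique(bins))
    result = SiteEvalResult(
        TP=TP,
        FP=FP,
        FN=len(summits) - TP,
        TN=n_flank_bins_per_summit * len(summits) - FP,
    )
    return result


def _auroc_from_points(points: list[tuple[float, float]]) -> float:
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    order = np.lexsort((ys, xs))
    return float(np.trapezoid(ys[order], xs[order]))


def roc_auroc(
    motifs: Sequence[Motif],
    regions: Sequence[Region],
    summits: Sequence[tuple[str, int]],
    background: MarkovBackground,
    thresholds: Sequence[float] | None = None,
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN_WIDTH,
    pseudocount: float = 0.25,
) -> SiteEvalResult:
    """ROC over a threshold sweep and its trapezoidal area.

    ``thresholds`` are fractions of each motif's maximum log-odds score
    (default: 21 points from 0 to 1).  Sites are scanned once at the lowest
    threshold and filtered per sweep point.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    thresholds = sorted(float(t) for t in thresholds)
    if len(thresholds) < 2:
        import warnings

        warnings.warn("single-point ROC: AUROC from anchors only")
    max_by_id = {}
    for i, m in enumerate(motifs):
        max_by_id[m.name or f"motif_{i + 1}"] = max_score(m, background, pseudocount)
    base_sites = scan(
        motifs,
        regions,
        background,
        score_threshold=[thresholds[0] * max_by_id[m.name or f"motif_{i+1}"] for i, m in enumerate(motifs)],
        pseudocount=pseudocount,
    )
    points = []
    last = None
    for frac in thresholds:
        kept = [s for s in base_sites if s.score >= frac * max_by_id[s.motif_id]]
        res = evaluate_sites(kept, summits, flank, bin_width)
        points.append((1 - res.specificity, res.sensitivity))
        last = res
    out = SiteEvalResult(TP=last.TP, FP=last.FP, FN=last.FN, TN=last.TN)
    out.roc_points = points
    out.auroc = _auroc_from_points(points)
    return out


# ---------------------------------------------------------------------------
# Cross-validation and grid search
# ---------------------------------------------------------------------------

def _summits_in_regions(
    summits: Sequence[tuple[str, int]], regions: Sequence[Region]
) -> list[list[tuple[str, int]]]:
    """Assign each summit to the region whose interval contains it."""
    per_region: list[list[tuple[str, int]]] = [[] for _ in regions]
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        if r.chrom is None:
            continue
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for chrom, pos in summits:
        ivs = by_chrom.get(chrom, [])
        starts = [s for s, _, _ in ivs]
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0:
            s, e, i = ivs[j]
            if s <= pos < e:
                per_region[i].append((chrom, pos))
    return per_region


def cross_validate(
    regions: Sequence[Region],
    summits: Sequence[tuple[str, int]],
    config,
    tracks=None,
    n_partitions: int = 10,
    n_rotations: int | None = None,
    beta_grid: Sequence[tuple[float, float, float]] | None = None,
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN_WIDTH,
    seed: int | None = None,
) -> dict:
    """Partitioned train/validation/test evaluation of the whole pipeline.

    Data are split into ``n_partitions`` equal parts.  Per rotation, motifs
    are discovered on 8/10 of the data (top ``config.n_motifs_out`` by
    rank), the validation part optionally selects β weights from
    ``beta_grid``, and AUROC is reported on the held-out part.  Returns the
    per-fold AUROCs with their mean and standard deviation.
    """
    from .pipeline import discover

    if n_partitions < 3:
        raise ValueError("need at least 3 partitions for train/validation/test")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    order = rng.permutation(len(regions))
    parts = np.array_split(order, n_partitions)
    if any(len(p) == 0 for p in parts):
        raise ValueError("partition too small")
    per_region_summits = _summits_in_regions(summits, regions)
    rotations = range(n_partitions if n_rotations is None else min(n_rotations, n_partitions))
    fold_auroc = []
    fold_rows = []
    for t in rotations:
        test_idx = parts[t]
        val_idx = parts[(t + 1) % n_partitions]
        train_idx = np.concatenate(
            [parts[j] for j in range(n_partitions) if j != t and j != (t + 1) % n_partitions]
        )
        train_regions = [regions[i] for i in train_idx]
        val_regions = [regions[i] for i in val_idx]
        test_regions = [regions[i] for i in test_idx]
        val_summits = [s for i in val_idx for s in per_region_summits[i]]
        test_summits = [s for i in test_idx for s in per_region_summits[i]]
        if not test_summits:
            continue
        betas = (config.beta_I, config.beta_K, config.beta_A)
        if beta_grid and tracks:
            betas, _, _ = grid_search_betas(
                (train_regions, tracks, val_summits),
                (val_regions, tracks, val_summits),
                beta_grid,
                config,
                flank=flank,
                bin_width=bin_width,
            )
        cfg = _replace_betas(config, betas)
        result = discover(train_regions, tracks=tracks, config=cfg)
        top = result.motifs[: config.n_motifs_out]
        if not top:
            continue
        ev = roc_auroc(top, test_regions, test_summits, result.background, flank=flank, bin_width=bin_width)
        fold_auroc.append(ev.auroc)
        fold_rows.append({"fold": t, "betas": betas, "auroc": ev.auroc})
    return {
        "fold_auroc": fold_auroc,
        "mean_auroc": float(np.mean(fold_auroc)) if fold_auroc else float("nan"),
        "sd_auroc": float(np.std(fold_auroc)) if fold_auroc else float("nan"),
        "folds": fold_rows,
    }


def _replace_betas(config, betas):
    import copy

    cfg = copy.copy(config)
    cfg.beta_I, cfg.beta_K, cfg.beta_A = betas
    return cfg


def grid_search_betas(
    train_data,
    validation_data,
    grid: Sequence[tuple[float, float, float]],
    config,
    flank: int = DEFAULT_FLANK,
    bin_width: int = DEFAULT_BIN_WIDTH,
):
    """Exhaustive search of (β_I, β_K, β_A) maximising validation AUROC.

    ``train_data`` and ``validation_data`` are (regions, tracks, summits)
    triples.  Candidate features are computed once on the training data and
    re-combined per grid point, so only ranking, clustering and scanning are
    repeated.  Ties break toward the smallest L1-norm β.  Returns
    (best_betas, best_auroc, table).
    """
    from .pipeline import DiscoveryCache

    train_regions, tracks, _ = train_data
    val_regions, _, val_summits = validation_data
    if not grid:
        raise ValueError("empty grid")
    cache = DiscoveryCache(train_regions, tracks, config)
    rows = []
    best = None
    for betas in grid:
        result = cache.rank_and_build(betas)
        top = result.motifs[: config.n_motifs_out]
        if not top:
            auroc = 0.0
        else:
            ev = roc_auroc(
                top, val_regions, val_summits, result.background, flank=flank, bin_width=bin_width
            )
            auroc = ev.auroc
        rows.append({"beta_I": betas[0], "beta_K": betas[1], "beta_A": betas[2], "auroc": auroc})
        key = (auroc, -sum(abs(b) for b in betas))
        if best is None or key > best[0]:
            best = (key, betas, auroc)
    return best[1], best[2], rows
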