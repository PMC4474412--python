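"""End-to-end discovery driver.

Wires the stages together: k-mer index → Markov background + simulations →
over-representation table → (optional) signal-shape scoring → seed ranking
→ single-substitution generalisation → clustering → merging → trimming →
ranked motifs.  All randomness flows from the single seed in the run
configuration, so two runs with equal inputs and config are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .background import (
    MarkovBackground,
    compute_overrepresentation,
    fit_background,
    select_candidates,
)
from .index import KmerIndex, build_index
from .io import Region, RunConfig, SignalTrack
from .motifs import (
    Motif,
    build_distance_matrix,
    cluster_motifs,
    generalize_seed,
    merge_cluster,
    rank_motifs,
    trim_motif,
)
from .signals import combined_score, score_candidates

__all__ = ["DiscoveryResult", "DiscoveryCache", "discover"]


@dataclass
class DiscoveryResult:
    motifs: list[Motif]
    seed_scores: pd.DataFrame
    background: MarkovBackground
    index: KmerIndex
    mode: str
    report: dict = field(default_factory=dict)


class DiscoveryCache:
    """Stage cache: everything up to the raw candidate features is computed
    once; ranking, clustering and merging re-run per β setting (used by the
    grid search)."""

    def __init__(
        self,
        regions: Sequence[Region],
        tracks: Sequence[SignalTrack] | None,
        config: RunConfig,
    ):
        if not regions:
            raise ValueError("no input regions")
        self.regions = list(regions)
        self.tracks = list(tracks) if tracks else []
        self.config = config
        self.mode = config.mode
        if self.mode == "auto":
            self.mode = "signal" if self.tracks else "sequence"
        if self.mode == "signal" and not self.tracks:
            raise ValueError("signal mode requires at least one signal track (or use sequence mode)")
        self.index = build_index(self.regions, config.K, config.strand_mode)
        self.background = fit_background(self.regions, config.background_order)
        lengths = [len(r) for r in self.regions]
        stats = compute_overrepresentation(
            self.index,
            self.background,
            lengths,
            n_simulations=config.n_simulations,
            seed=np.random.default_rng(config.seed),
        )
        cand = select_candidates(stats, config.pvalue_threshold)
        self.n_candidates_total = len(cand)
        cand = cand.head(config.max_scored_candidates).reset_index(drop=True)
        if self.mode == "signal" and len(cand):
            self.candidates, self.profiles = score_candidates(
                cand,
                self.index,
                self.regions,
                self.tracks,
                halfwidth=config.profile_halfwidth,
                bin_width=config.bin_width,
                keep_frac=config.smooth_keep_frac,
            )
        else:
            self.candidates, self.profiles = cand, {}

    def rank_and_build(self, betas: tuple[float, float, float] | None = None) -> DiscoveryResult:
        cfg = self.config
        if betas is None:
            betas = (cfg.beta_I, cfg.beta_K, cfg.beta_A)
        if self.mode == "signal":
            scored = combined_score(
                self.candidates, [t.name for t in self.tracks], *betas
            )
        else:
            scored = self.candidates.copy()
            scored["S"] = scored["S_W"]
            scored = scored.sort_values("S", ascending=False, kind="stable").reset_index(drop=True)
        top = scored.head(cfg.top_seeds)
        primaries: list[Motif] = []
        for _, row in top.iterrows():
            m = generalize_seed(row["word"], self.index)
            m.score = float(row["S"])
            for t in self.tracks:
                key = (row["word"], t.name)
                if key in self.profiles:
                    m.mark_distributions[t.name] = self.profiles[key]
            primaries.append(m)
        use_marks = self.mode == "signal"
        merged: list[Motif] = []
        if primaries:
            D, _ = build_distance_matrix(
                primaries, use_marks=use_marks, beta_cluster=cfg.beta_cluster, pseudocount=cfg.pseudocount
            )
            clusters = cluster_motifs(
                primaries,
                D,
                use_marks=use_marks,
                beta_cluster=cfg.beta_cluster,
                distance_threshold=cfg.cluster_threshold,
                seed=np.random.default_rng(cfg.seed + 1),
            )
            for cl in clusters:
                m = merge_cluster(
                    [primaries[i] for i in cl],
                    use_marks=use_marks,
                    beta_cluster=cfg.beta_cluster,
                    pseudocount=cfg.pseudocount,
                )
                merged.append(
                    trim_motif(m, cfg.min_info, cfg.min_support_frac, cfg.pseudocount)
                )
        ranked = rank_motifs(merged)
        for i, m in enumerate(ranked):
            m.name = f"motif_{i + 1}"
        report = {
            "mode": self.mode,
            "K": cfg.K,
            "n_regions": len(self.regions),
            "n_distinct_words": len(self.index),
            "n_candidates": int(self.n_candidates_total),
            "n_scored_candidates": int(len(self.candidates)),
            "n_primary_motifs": len(primaries),
            "n_motifs": len(ranked),
            "betas": {"beta_I": betas[0], "beta_K": betas[1], "beta_A": betas[2]},
        }
        return DiscoveryResult(
            motifs=ranked,
            seed_scores=scored,
            background=self.background,
            index=self.index,
            mode=self.mode,
            report=report,
        )


def discover(
    regions: Sequence[Region],
    tracks: Sequence[SignalTrack] | None = None,
    config: RunConfig | None = None,
) -> DiscoveryResult:
    """Run the full discovery pipeline; see the module docstring."""
    config = config or RunConfig()
    return DiscoveryCache(regions, tracks, config).rank_and_build()
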