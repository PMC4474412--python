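"""Synthetic fixture generator.

Emulates the statistical structure of ChIP-seq motif-discovery inputs with
no external data: background sequence from a 0th/1st-order Markov chain,
motif instances sampled column-wise from a known PFM and planted at a
controlled per-region rate, summits at the planted instance midpoints
(optionally jittered), and per-track signal with a controlled shape —
Gaussian-like peaks centred on instances, flat or noisy baselines, or
one-sided (asymmetric) decay profiles.  A decoy variant plants a tandem
repeat word at a frequency matched to the motif but with no signal peak,
so ranking tests can check that shape scores demote it.

Everything is deterministic under the spec seed, and fixtures are written
to disk in the standard formats (FASTA / bedGraph / BED / TSV) and read
back through the normal readers so the I/O paths are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .background import MarkovBackground, simulate_background
from .index import code_to_word
from .io import Region, SignalTrack, write_fasta

__all__ = [
    "GaussianShape",
    "FlatShape",
    "NoisyShape",
    "AsymmetricShape",
    "FixtureSpec",
    "FixtureBundle",
    "default_planted_pfm",
    "uniform_background",
    "make_fixture",
    "make_spurious_word_fixture",
]

CHROM = "chrS"


@dataclass
class GaussianShape:
    """Kurtotic peak: amplitude·exp(−(x−c)²/2σ²) on top of a noisy baseline."""

    sigma: float = 75.0
    amplitude: float = 10.0
    baseline: float = 0.5
    noise_sd: float = 0.1


@dataclass
class FlatShape:
    level: float = 1.0


@dataclass
class NoisyShape:
    level: float = 1.0
    noise_sd: float = 0.5


@dataclass
class AsymmetricShape:
    """One-sided exponential decay to the right of the instance centre."""

    tau: float = 100.0
    amplitude: float = 10.0
    baseline: float = 0.5
    noise_sd: float = 0.1


Shape = GaussianShape | FlatShape | NoisyShape | AsymmetricShape


def default_planted_pfm(dominant: float = 0.85, consensus: str = "TCAAGGTCA") -> np.ndarray:
    """A realistic 9-bp TF-like PFM: one dominant base per column."""
    base_index = {b: i for i, b in enumerate("ACGT")}
    L = len(consensus)
    pfm = np.full((L, 4), (1 - dominant) / 3)
    for i, c in enumerate(consensus):
        pfm[i, base_index[c]] = dominant
    return pfm


def uniform_background() -> MarkovBackground:
    return MarkovBackground(0, np.full(4, 0.25))


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark: 2000 regions of 200 bp from a
    uniform order-0 background, one 9-bp PFM planted in 40% of regions, a
    DNase-like Gaussian peak track (σ = 75 bp) plus a flat-noise decoy
    track.
    """

    n_regions: int = 2000
    region_length: int = 200
    background: MarkovBackground = field(default_factory=uniform_background)
    planted_pfm: np.ndarray = field(default_factory=default_planted_pfm)
    plant_rate: float = 0.4
    signal_shapes: dict[str, Shape] = field(
        default_factory=lambda: {
            "dnase": GaussianShape(sigma=75.0),
            "noise": NoisyShape(level=1.0, noise_sd=0.5),
        }
    )
    summit_jitter: int = 0
    region_gap: int = 1300  # inter-peak spacing; keeps ±650 bp evaluation flanks disjoint
    pad: int = 2000
    signal_step: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plant_rate <= 1.0:
            raise ValueError("plant_rate must be in [0, 1]")
        if self.planted_pfm.shape[0] > self.region_length:
            raise ValueError("planted motif longer than the region")


@dataclass
class FixtureBundle:
    regions: list[Region]
    tracks: list[SignalTrack]
    summits: list[tuple[str, int]]
    truth: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def _self_extension_rate(word: str, bg: MarkovBackground) -> float:
    """Expected extra occurrences per planted copy of a self-overlapping
    word, from random flanking bases completing a shifted copy."""
    base_index = {b: i for i, b in enumerate("ACGT")}
    rate = 0.0
    K = len(word)
    for s in range(1, K):
        if word[s:] == word[:-s]:  # word is compatible with a shift of s
            left = float(np.prod([bg.initial_probs[base_index[c]] for c in word[:s]]))
            right = float(np.prod([bg.initial_probs[base_index[c]] for c in word[-s:]]))
            rate += left + right
    return rate


def _sample_pfm_instance(pfm: np.ndarray, rng: np.random.Generator) -> str:
    bases = "ACGT"
    cum = np.cumsum(pfm, axis=1)
    u = rng.random(pfm.shape[0])
    return "".join(bases[int(np.searchsorted(cum[i], u[i], side="right"))] for i in range(pfm.shape[0]))


def _codes_to_seq(codes: np.ndarray) -> str:
    return "".join("ACGT"[c] for c in codes)


def _lay_peaks(shape: Shape, span: int, centres: Sequence[int]) -> np.ndarray:
    """Peak contributions only (no baseline/noise) of ``shape`` at ``centres``."""
    values = np.zeros(span)
    x = np.arange(span, dtype=float)
    if isinstance(shape, GaussianShape):
        for c in centres:
            lo = max(0, int(c - 6 * shape.sigma))
            hi = min(span, int(c + 6 * shape.sigma) + 1)
            values[lo:hi] += shape.amplitude * np.exp(
                -((x[lo:hi] - c) ** 2) / (2 * shape.sigma**2)
            )
    elif isinstance(shape, AsymmetricShape):
        for c in centres:
            lo = max(0, int(c))
            hi = min(span, int(c + 8 * shape.tau) + 1)
            if hi > lo:
                values[lo:hi] += shape.amplitude * np.exp(-(x[lo:hi] - c) / shape.tau)
    return values


def _lay_signal(
    shape: Shape,
    span: int,
    centres: Sequence[int],
    step: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-bp values over [0, span); noise is piecewise-constant at ``step``
    resolution so the bedGraph stays compact."""
    n_steps = int(np.ceil(span / step))
    if isinstance(shape, FlatShape):
        coarse = np.full(n_steps, shape.level)
    elif isinstance(shape, NoisyShape):
        coarse = shape.level + rng.normal(0, shape.noise_sd, n_steps)
    else:
        coarse = shape.baseline + rng.normal(0, shape.noise_sd, n_steps)
    values = np.repeat(coarse, step)[:span]
    values += _lay_peaks(shape, span, centres)
    return np.maximum(values, 0.0)


def _build(
    spec: FixtureSpec,
    rng: np.random.Generator,
    decoy_word: str | None = None,
    decoy_shape: Shape | None = None,
) -> FixtureBundle:
    L = spec.region_length
    Lm = spec.planted_pfm.shape[0]
    stride = L + spec.region_gap
    span = 2 * spec.pad + spec.n_regions * stride
    seqs = simulate_background(spec.background, [L] * spec.n_regions, 1, rng)[0]
    planted = rng.random(spec.n_regions) < spec.plant_rate
    if decoy_word is not None:
        # plant the decoy word at the expected count of the motif consensus
        # word (instances only match the consensus when every column draws
        # its dominant base), so the two words reach matched frequency;
        # repeat words self-extend into random flanks, so discount that
        p_consensus = float(np.prod(spec.planted_pfm.max(axis=1)))
        ext = _self_extension_rate(decoy_word, spec.background)
        free = np.flatnonzero(~planted)
        n_decoy = min(max(1, int(round(planted.sum() * p_consensus / (1 + ext)))), len(free))
        decoy_regions = set(rng.choice(free, size=n_decoy, replace=False).tolist())
    else:
        decoy_regions = set()
    centre_offset = (L - Lm) // 2
    regions: list[Region] = []
    truth_rows = []
    motif_centres: list[int] = []
    decoy_centres: list[int] = []
    for i in range(spec.n_regions):
        seq = _codes_to_seq(seqs[i])
        start = spec.pad + i * stride
        if planted[i]:
            inst = _sample_pfm_instance(spec.planted_pfm, rng)
            seq = seq[:centre_offset] + inst + seq[centre_offset + Lm :]
            centre = start + centre_offset + Lm // 2
            motif_centres.append(centre)
            truth_rows.append(
                {"region_index": i, "region_id": f"r{i}", "offset": centre_offset,
                 "word": inst, "centre": centre, "label": "motif"}
            )
        elif i in decoy_regions:
            seq = seq[:centre_offset] + decoy_word + seq[centre_offset + len(decoy_word) :]
            d_centre = start + centre_offset + len(decoy_word) // 2
            decoy_centres.append(d_centre)
            truth_rows.append(
                {"region_index": i, "region_id": f"r{i}", "offset": centre_offset,
                 "word": decoy_word, "centre": d_centre, "label": "decoy"}
            )
        regions.append(Region(id=f"r{i}", sequence=seq, chrom=CHROM, start=start, end=start + L))
    tracks = []
    for name, shape in spec.signal_shapes.items():
        values = _lay_signal(shape, span, motif_centres, spec.signal_step, rng)
        if decoy_shape is not None and decoy_centres:
            values = np.maximum(values + _lay_peaks(decoy_shape, span, decoy_centres), 0.0)
        track = SignalTrack(name)
        track.set_chrom(CHROM, 0, values)
        tracks.append(track)
    summits = []
    for c in motif_centres:
        jit = int(rng.integers(-spec.summit_jitter, spec.summit_jitter + 1)) if spec.summit_jitter else 0
        summits.append((CHROM, c + jit))
    truth = pd.DataFrame(
        truth_rows, columns=["region_index", "region_id", "offset", "word", "centre", "label"]
    )
    return FixtureBundle(regions=regions, tracks=tracks, summits=summits, truth=truth)


def _write(bundle: FixtureBundle, outdir: str | Path) -> FixtureBundle:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "regions.fa"
    write_fasta(bundle.regions, fasta)
    bundle.paths["fasta"] = fasta
    for track in bundle.tracks:
        p = outdir / f"{track.name}.bedgraph"
        track.to_bedgraph(p)
        bundle.paths[f"track_{track.name}"] = p
    summits = outdir / "summits.bed"
    with open(summits, "w") as fh:
        for j, (chrom, pos) in enumerate(bundle.summits):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tsummit_{j}\n")
    bundle.paths["summits"] = summits
    truth = outdir / "truth.tsv"
    bundle.truth.to_csv(truth, sep="\t", index=False)
    bundle.paths["truth"] = truth
    return bundle


def make_fixture(spec: FixtureSpec, outdir: str | Path | None = None) -> FixtureBundle:
    """Generate a planted-motif fixture; optionally write it to ``outdir``."""
    rng = np.random.default_rng(spec.seed)
    bundle = _build(spec, rng)
    if outdir is not None:
        _write(bundle, outdir)
    return bundle


def make_spurious_word_fixture(
    spec: FixtureSpec,
    decoy_word: str = "CTCTCTCTC",
    decoy_shape: Shape | None = None,
    outdir: str | Path | None = None,
) -> FixtureBundle:
    """Planted motif plus a frequency-matched tandem-repeat decoy.

    The decoy word is planted (in regions disjoint from the motif's) at the
    expected count of the motif's consensus word.  By default decoy
    positions receive no signal peak, so the decoy's profile is the track's
    flat/noisy baseline while the motif's is shaped; passing an
    :class:`AsymmetricShape` as ``decoy_shape`` instead lays a skewed peak
    at each decoy position.
    """
    rng = np.random.default_rng(spec.seed)
    bundle = _build(spec, rng, decoy_word=decoy_word, decoy_shape=decoy_shape)
    if outdir is not None:
        _write(bundle, outdir)
    return bundle
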