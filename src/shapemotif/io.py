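"""Readers and writers for the external file formats.

Sequences come in as FASTA (one record per target region, e.g. a ChIP-seq
peak); genome-wide signal comes in as bedGraph (or optionally bigWig);
summits and predicted sites travel as BED; motifs leave as MEME minimal
format plus a TSV sidecar of per-seed scores.  All genomic coordinates are
0-based half-open.  Region FASTA headers may carry genomic coordinates in
the form ``id::chrom:start-end`` so that occurrences can be mapped onto
signal tracks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "Region",
    "SignalTrack",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "read_bigwig",
    "read_bed",
    "read_summits",
    "write_meme_motifs",
    "read_meme_motifs",
    "write_score_sidecar",
]

_HEADER_COORDS = re.compile(r"^(?P<id>.+?)::(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")
_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass
class Region:
    """A target sequence, optionally anchored to genomic coordinates."""

    id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if self.end <= self.start:
                raise ValueError(f"region {self.id}: end must exceed start")
            if len(self.sequence) != self.end - self.start:
                raise ValueError(
                    f"region {self.id}: sequence length {len(self.sequence)} "
                    f"!= coordinate span {self.end - self.start}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, mask_lowercase: bool = False) -> list[Region]:
    """Read target regions from a FASTA file.

    Lowercase (soft-masked) bases are uppercased by default; with
    ``mask_lowercase=True`` they become ``N`` and are excluded from k-mer
    counting downstream.  Headers of the form ``id::chrom:start-end``
    attach genomic coordinates to the region.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected FASTA header, got {first.strip()!r}")
    regions: list[Region] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if mask_lowercase:
            seq = "".join("N" if c.islower() else c for c in raw)
        else:
            seq = raw.upper()
        seq = seq.upper()
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"{path}: record {rec.id}: invalid characters {bad}")
        m = _HEADER_COORDS.match(rec.description.split()[0] if rec.description else rec.id)
        if m:
            regions.append(
                Region(
                    id=m.group("id"),
                    sequence=seq,
                    chrom=m.group("chrom"),
                    start=int(m.group("start")),
                    end=int(m.group("end")),
                )
            )
        else:
            regions.append(Region(id=rec.id, sequence=seq))
    if not regions:
        raise ValueError(f"{path}: no FASTA records found")
    return regions


def write_fasta(regions: Sequence[Region], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.chrom is not None and r.start is not None:
                fh.write(f">{r.id}::{r.chrom}:{r.start}-{r.end}\n")
            else:
                fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


class SignalTrack:
    """A genome-wide signal (histone mark, DNase I, ...) queryable per-bp.

    Stored densely per chromosome over the covered span; queries outside
    covered intervals return 0.0 (sparse-coverage convention: absence of
    signal is zero signal).
    """

    def __init__(self, name: str, step: int = 1):
        if step < 1:
            raise ValueError("step must be >= 1")
        self.name = name
        self.step = step
        # chrom -> (offset, values) where values[i] covers [offset+i, offset+i+1)
        self._data: dict[str, tuple[int, np.ndarray]] = {}

    def set_chrom(self, chrom: str, offset: int, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"track {self.name}: non-finite values on {chrom}")
        self._data[chrom] = (offset, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def query(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp values over [start, end); uncovered positions are 0.0."""
        if end < start:
            raise ValueError("end < start in track query")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        offset, values = self._data[chrom]
        lo = max(start, offset)
        hi = min(end, offset + len(values))
        if hi > lo:
            out[lo - start : hi - start] = values[lo - offset : hi - offset]
        return out

    def to_bedgraph(self, path: str | Path, fmt: str = "%.4f") -> None:
        """Write the track run-length-encoded as 4-column bedGraph."""
        with open(path, "w") as fh:
            for chrom, (offset, values) in self._data.items():
                if len(values) == 0:
                    continue
                change = np.flatnonzero(np.diff(values)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(values)]))
                rows = [
                    f"{chrom}\t{offset + s}\t{offset + e}\t{fmt % values[s]}"
                    for s, e in zip(starts, ends)
                ]
                fh.write("\n".join(rows) + "\n")


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a dense :class:`SignalTrack`.

    Overlapping intervals or non-numeric values are errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    for col in ("start", "end", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = df.loc[coerced.isna()].index[0] + 1
            raise ValueError(f"{path}: non-numeric {col} at data line {bad}")
        df[col] = coerced
    track = SignalTrack(name or path.stem)
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=int)
        ends = sub["end"].to_numpy(dtype=int)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        offset = int(starts[0])
        values = np.zeros(int(ends[-1]) - offset, dtype=float)
        for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
            values[s - offset : e - offset] = v
        track.set_chrom(str(chrom), offset, values)
    return track


def read_bigwig(path: str | Path, name: str | None = None) -> SignalTrack:
    """Optional bigWig reader with the same query contract as bedGraph."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("pyBigWig is required for bigWig input") from exc
    bw = pyBigWig.open(str(path))
    track = SignalTrack(name or Path(path).stem)
    for chrom, length in bw.chroms().items():
        vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, length), dtype=float))
        track.set_chrom(chrom, 0, vals)
    bw.close()
    return track


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, ...])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    return df


def read_summits(path: str | Path) -> list[tuple[str, int]]:
    """Read ChIP-seq summits from BED; a 1 bp interval's start is the summit,
    wider intervals use their midpoint."""
    df = read_bed(path)
    out = []
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        pos = int(start) if end - start <= 1 else int((start + end) // 2)
        out.append((str(chrom), pos))
    return out


# ---------------------------------------------------------------------------
# MEME minimal motif format (v4)
# ---------------------------------------------------------------------------

def write_meme_motifs(motifs, path: str | Path, background=None) -> None:
    """Write motifs in MEME minimal format v4.

    Each motif's count matrix is row-normalised (with its pseudocount); a
    zero-support motif cannot be normalised and is an error.
    """
    bg = background if background is not None else [0.25, 0.25, 0.25, 0.25]
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A %.6f C %.6f G %.6f T %.6f" % tuple(bg),
        "",
    ]
    for i, motif in enumerate(motifs):
        if motif.counts.sum() <= 0:
            raise ValueError(f"motif {i}: zero support, cannot be written")
        row_sums = motif.counts.sum(axis=1)
        # raw count normalisation; rows that are all zero need the pseudocount
        probs = motif.probs(0.0) if np.all(row_sums > 0) else motif.probs()
        name = getattr(motif, "name", None) or f"motif_{i + 1}"
        lines.append(f"MOTIF {name} {motif.consensus}")
        lines.append(
            "letter-probability matrix: alength= 4 w= %d nsites= %d E= 0"
            % (probs.shape[0], max(1, int(round(motif.support))))
        )
        for row in probs:
            lines.append(" ".join("%.6f" % v for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_meme_motifs(path: str | Path) -> list[tuple[str, np.ndarray, int]]:
    """Round-trip reader: returns (name, probability matrix, nsites) tuples."""
    text = Path(path).read_text().splitlines()
    out = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(text) and not text[i].strip().startswith("letter-probability"):
                i += 1
            header = text[i].strip()
            w = int(re.search(r"w=\s*(\d+)", header).group(1))
            m = re.search(r"nsites=\s*(\d+)", header)
            nsites = int(m.group(1)) if m else 0
            rows = []
            for j in range(w):
                rows.append([float(x) for x in text[i + 1 + j].split()])
            probs = np.asarray(rows, dtype=float)
            if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
                raise ValueError(f"{path}: motif {name}: rows do not sum to 1")
            out.append((name, probs, nsites))
            i += w
        i += 1
    return out


def write_score_sidecar(scores: pd.DataFrame, path: str | Path) -> None:
    """TSV sidecar with per-seed sub-scores and (optional) profile vectors."""
    scores.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunable parameters of a discovery run.

    ``mode`` is ``"sequence"`` (rank purely by the over-representation odds
    ratio) or ``"signal"`` (add intensity / kurtosis / asymmetry scores from
    the supplied tracks); ``"auto"`` picks ``signal`` when tracks are given.
    """

    K: int = 9
    mode: str = "auto"  # sequence | signal | auto
    background_order: int = 1
    n_simulations: int = 5
    pvalue_threshold: float = 1e-6
    beta_I: float = 0.3
    beta_K: float = 0.5
    beta_A: float = 0.5
    beta_cluster: float = 0.2
    bin_width: int = 25
    profile_halfwidth: int = 1000
    cluster_threshold: float = 0.0  # >0: cut dendrogram at this distance instead of gap statistic
    pseudocount: float = 0.25
    seed: int = 0
    strand_mode: str = "both"  # both | forward
    top_seeds: int = 30
    max_scored_candidates: int = 300
    smooth_keep_frac: float = 0.375  # fraction of non-negative DFT frequencies kept
    min_info: float = 0.3  # bits; motif-end trimming
    min_support_frac: float = 0.1
    scan_threshold_frac: float = 0.7
    n_motifs_out: int = 3

    def __post_init__(self) -> None:
        if self.K < 4:
            raise ValueError("K must be >= 4")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        if min(self.beta_I, self.beta_K, self.beta_A, self.beta_cluster) < 0:
            raise ValueError("beta weights must be >= 0")
        if self.background_order not in (0, 1):
            raise ValueError("background_order must be 0 or 1")
        if self.mode not in ("sequence", "signal", "auto"):
            raise ValueError("mode must be sequence, signal or auto")
        if self.profile_halfwidth % self.bin_width != 0:
            raise ValueError("profile_halfwidth must be a multiple of bin_width")

    @property
    def n_bins(self) -> int:
        return 2 * self.profile_halfwidth // self.bin_width

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))
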