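"""Readers and writers for the formats the pipeline touches.

BED3+/narrowPeak for peaks, bedGraph and wiggle (fixedStep/variableStep) for
signal, GFF3 for gene models, TSV for tables, YAML for the run manifest and
config.  Internally everything is 0-based half-open; 1-based formats (GFF3,
fixedStep/variableStep wiggle) are converted at the boundary and restored on
write.  Each reader/writer pair round-trips: write(read(x)) is semantically
identical to x.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pyranges as pr
import yaml

from .annotation import GeneModel

__all__ = [
    "Peak",
    "SignalTrack",
    "PipelineConfig",
    "MARKS",
    "TISSUES",
    "read_peaks",
    "write_peaks",
    "read_signal",
    "write_signal",
    "read_gff3",
    "write_gff3",
    "read_manifest",
]

MARKS = ("H3K27me3", "H3K4me3", "DHS")
TISSUES = ("callus", "seedling")


class ParseError(ValueError):
    """Malformed line in an input file; message names the file and line."""


@dataclass(frozen=True)
class Peak:
    """A called enrichment interval (0-based half-open) with its provenance labels."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    mark: str | None = None
    tissue: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if self.start < 0:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: negative start")

    @property
    def length(self) -> int:
        return self.end - self.start


class SignalTrack:
    """Piecewise-constant nonnegative signal over a genome.

    Stored per chromosome as sorted, non-overlapping (start, end, value) runs;
    bases covered by no run have value 0.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.runs = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e[:-1] > s[1:]):
                raise ValueError(f"{chrom}: overlapping runs")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: values must be finite and nonnegative")
            self.runs[chrom] = (s, e, v)

    @classmethod
    def from_intervals(cls, intervals) -> "SignalTrack":
        """Build from an iterable of (chrom, start, end, value)."""
        per_chrom: dict[str, list] = {}
        for chrom, s, e, v in intervals:
            per_chrom.setdefault(chrom, []).append((s, e, v))
        runs = {}
        for chrom, rows in per_chrom.items():
            arr = np.array(rows, dtype=np.float64)
            runs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(runs)

    def total(self) -> float:
        """Genome-wide integral: sum of value x run length."""
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self.runs.values())
        )

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self.runs.items()}
        )

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal over [start, end); 0 outside any run."""
        if chrom not in self.runs or start >= end:
            return 0.0
        s, e, v = self.runs[chrom]
        i = np.searchsorted(e, start, side="right")
        j = np.searchsorted(s, end, side="left")
        if i >= j:
            return 0.0
        ss = np.maximum(s[i:j], start)
        ee = np.minimum(e[i:j], end)
        return float(np.sum((ee - ss) * v[i:j]))

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        if start >= end:
            raise ValueError("empty window")
        return self.window_sum(chrom, start, end) / (end - start)

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); bases outside runs (or outside
        the chromosome) are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.runs:
            return out
        s, e, v = self.runs[chrom]
        i = np.searchsorted(e, start, side="right")
        j = np.searchsorted(s, end, side="left")
        for k in range(i, j):
            lo = max(s[k], start) - start
            hi = min(e[k], end) - start
            out[lo:hi] = v[k]
        return out


def read_peaks(path, mark: str | None = None, tissue: str | None = None) -> list[Peak]:
    """Read a BED3+ / narrowPeak file into labelled peaks.

    Coordinates are taken verbatim (BED is already 0-based half-open); input
    order is preserved.  Column 5 (the BED score) is used as the peak score
    when present.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {cols[1]!r}, {cols[2]!r}"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            score = None
            if len(cols) >= 5:
                try:
                    score = float(cols[4])
                except ValueError:
                    score = None
            peaks.append(Peak(cols[0], start, end, score=score, mark=mark, tissue=tissue))
    return peaks


def write_peaks(peaks, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            name = f"{p.mark or '.'}_{p.tissue or '.'}"
            score = "0" if p.score is None else format(p.score, "g")
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\n")


def _finish_signal(path, per_chrom) -> SignalTrack:
    """Sort runs, merge equal-value abutting/overlapping runs, reject conflicts."""
    runs = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        merged: list[list] = []
        for s, e, v in rows:
            if merged and s < merged[-1][1]:
                if v != merged[-1][2]:
                    raise ParseError(
                        f"{path}: {chrom}:{s}-{e}: overlapping runs with "
                        f"conflicting values ({merged[-1][2]} vs {v})"
                    )
                merged[-1][1] = max(merged[-1][1], e)
            elif merged and s == merged[-1][1] and v == merged[-1][2]:
                merged[-1][1] = e
            else:
                merged.append([s, e, v])
        arr = np.array(merged, dtype=np.float64)
        runs[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return SignalTrack(runs)


def read_signal(path) -> SignalTrack:
    """Read a bedGraph or wiggle (fixedStep / variableStep) signal track.

    Wiggle dialects are 1-based and converted to 0-based half-open on read.
    Overlapping runs with conflicting values raise; equal values are merged.
    """
    per_chrom: dict[str, list] = {}
    mode = "bedgraph"
    chrom = None
    pos = step = span = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            first = line.split(None, 1)[0]
            if first in ("fixedStep", "variableStep"):
                mode = first
                kv = dict(f.split("=", 1) for f in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if mode == "fixedStep":
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", span))
                continue
            fields = line.split()
            try:
                if mode == "bedgraph":
                    if len(fields) != 4:
                        raise ValueError
                    c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    if s >= e:
                        raise ValueError
                    per_chrom.setdefault(c, []).append((s, e, v))
                elif mode == "fixedStep":
                    v = float(fields[0])
                    per_chrom.setdefault(chrom, []).append((pos, pos + span, v))
                    pos += step
                else:  # variableStep
                    s, v = int(fields[0]) - 1, float(fields[1])
                    per_chrom.setdefault(chrom, []).append((s, s + span, v))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed signal line {line!r}") from None
    return _finish_signal(path, per_chrom)


def write_signal(track: SignalTrack, path) -> None:
    """Write as bedGraph with full-precision values (repr round-trip)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            s, e, v = track.runs[chrom]
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{float(v[i])!r}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> tuple[dict[str, int], list[GeneModel]]:
    """Read gene models and chromosome sizes from GFF3.

    Chromosome lengths come from ``##sequence-region`` pragmas.  One
    representative transcript is kept per gene: the longest, first on ties.
    pyranges performs the 1-based -> 0-based conversion.
    """
    genome: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, start, end = line.split()[:4]
                genome[chrom] = int(end)
            elif not line.startswith("#"):
                break
    df = pr.read_gff3(str(path)).df
    genes: list[GeneModel] = []
    gene_rows = df[df.Feature == "gene"]
    mrna = df[df.Feature == "mRNA"]
    parts = df[df.Feature.isin(["exon", "five_prime_UTR", "three_prime_UTR"])]
    for row in gene_rows.itertuples():
        children = mrna[mrna.Parent == row.ID]
        if len(children):
            lengths = children.End - children.Start
            tx = children.iloc[int(np.argmax(lengths.values))]
            tx_id, tx_start, tx_end = tx.ID, int(tx.Start), int(tx.End)
        else:
            tx_id, tx_start, tx_end = row.ID, int(row.Start), int(row.End)
        sub = parts[parts.Parent == tx_id]
        exons = [
            (int(r.Start), int(r.End))
            for r in sub[sub.Feature == "exon"].itertuples()
        ]
        utr5 = [
            (int(r.Start), int(r.End))
            for r in sub[sub.Feature == "five_prime_UTR"].itertuples()
        ]
        utr3 = [
            (int(r.Start), int(r.End))
            for r in sub[sub.Feature == "three_prime_UTR"].itertuples()
        ]
        genes.append(
            GeneModel(
                gene_id=row.ID,
                chrom=row.Chromosome,
                strand=row.Strand,
                start=tx_start,
                end=tx_end,
                exons=exons or [(tx_start, tx_end)],
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genome, genes


def write_gff3(genome: dict[str, int], genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (restoring 1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome):
            fh.write(f"##sequence-region {chrom} 1 {genome[chrom]}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            a = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tchromtrans\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{a}\n"
            )
            tx = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tchromtrans\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tx};Parent={g.gene_id}\n"
            )
            for feat, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivs:
                    fh.write(
                        f"{g.chrom}\tchromtrans\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tx}\n"
                    )


# ---------------------------------------------------------------------------
# Configuration and manifest


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, with the published defaults.

    upstream_bp: upstream extension of the gene window used for mark
        assignment and as the promoter length of the region partition (2 kb).
    fold_change_cutoff: strict fold-change threshold for two-condition
        differential expression (>2).
    preferential_p_cutoff: p-value cutoff for tissue-preferential expression
        calls on the multi-tissue panel (0.05).
    min_fold: signal-fold threshold for differential mark deposition between
        tissues when a gene carries the mark in both.
    pseudocount: added to expression values and windowed mark signal before
        ratios, so fold changes are defined at zero.
    """

    upstream_bp: int = 2000
    fold_change_cutoff: float = 2.0
    preferential_p_cutoff: float = 0.05
    kmeans_k: int = 5
    kmeans_restarts: int = 10
    metagene_flank_bp: int = 1000
    metagene_flank_bins: int = 20
    metagene_body_bins: int = 60
    tss_flank_bp: int = 3000
    tss_bin_bp: int = 100
    heatmap_flank_bp: int = 5000
    cluster_flank_bp: int = 1000
    pseudocount: float = 1.0
    min_fold: float = 2.0
    min_overlap_fraction: float = 0.0
    seed: int = 42
    marks: tuple[str, ...] = MARKS
    tissues: tuple[str, ...] = TISSUES

    def __post_init__(self):
        for name in (
            "upstream_bp",
            "fold_change_cutoff",
            "preferential_p_cutoff",
            "kmeans_k",
            "min_fold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        self.marks = tuple(self.marks)
        self.tissues = tuple(self.tissues)
        if len(self.tissues) != 2:
            raise ValueError("exactly two tissues are compared")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marks"] = list(d["marks"])
        d["tissues"] = list(d["tissues"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class ManifestError(ValueError):
    """A required input slot is missing from the run manifest."""


_REQUIRED_SINGLE = ("genes", "expression", "panel", "panel_samples", "tf_families")


def read_manifest(path, config: PipelineConfig) -> dict:
    """Read and validate the YAML manifest mapping input slots to paths.

    Required slots: ``genes``, ``expression``, ``panel``, ``panel_samples``,
    ``tf_families``, and ``peaks``/``signal`` entries for every configured
    (mark, tissue) pair.  Missing slots raise before any computation.
    """
    base = Path(path).parent
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ManifestError(f"{path}: manifest is not a mapping")

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    out: dict = {}
    missing = []
    for key in _REQUIRED_SINGLE:
        if key not in data:
            missing.append(key)
        else:
            out[key] = resolve(data[key])
    for section in ("peaks", "signal"):
        out[section] = {}
        for mark in config.marks:
            for tissue in config.tissues:
                try:
                    out[section][(mark, tissue)] = resolve(data[section][mark][tissue])
                except (KeyError, TypeError):
                    missing.append(f"{section}/{mark}/{tissue}")
    if missing:
        raise ManifestError(f"{path}: missing manifest entries: {', '.join(missing)}")
    absent = [str(p) for p in out["peaks"].values() if not p.exists()]
    absent += [str(p) for p in out["signal"].values() if not p.exists()]
    absent += [str(out[k]) for k in _REQUIRED_SINGLE if not out[k].exists()]
    if absent:
        raise ManifestError(f"{path}: input files not found: {', '.join(absent)}")
    return out
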