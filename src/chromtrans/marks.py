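"""Peak-to-gene mark assignment and tissue-differential deposition.

A gene carries a mark when its window — gene body plus 2 kb upstream of the
TSS, strand-aware — overlaps at least one peak of that mark.  Differential
deposition between two tissues combines presence/absence with a windowed
mean-signal fold ratio (pseudocounted), an explicit stand-in for the
peak-caller-internal comparison that published two-condition analyses leave
unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel
from .io import Peak, SignalTrack

__all__ = [
    "MarkTable",
    "DifferentialMarkResult",
    "assign_marks",
    "differential_deposition",
    "normalize_tracks",
]


@dataclass
class MarkTable:
    """Gene x (mark, tissue) presence flags plus windowed mean signal.

    ``presence`` and ``mean_signal`` share the same index (gene ids) and
    MultiIndex columns (mark, tissue); mean signal is NaN when no track was
    supplied for that slot.
    """

    presence: pd.DataFrame
    mean_signal: pd.DataFrame

    def flags(self, mark: str, tissue: str) -> pd.Series:
        return self.presence[(mark, tissue)]

    def genes_with(self, mark: str, tissue: str) -> set[str]:
        col = self.presence[(mark, tissue)]
        return set(col.index[col])

    def to_tsv(self, path) -> None:
        flat = self.presence.astype(int).copy()
        flat.columns = [f"{m}_{t}" for m, t in flat.columns]
        sig = self.mean_signal.copy()
        sig.columns = [f"signal_{m}_{t}" for m, t in sig.columns]
        pd.concat([flat, sig], axis=1).sort_index().to_csv(
            path, sep="\t", index_label="gene_id", float_format="%.6g"
        )


@dataclass
class DifferentialMarkResult:
    """Preferentially deposited gene sets for one mark between two tissues."""

    mark: str
    tissue_a: str
    tissue_b: str
    a_preferential: set[str]
    b_preferential: set[str]
    fold: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self):
        if self.a_preferential & self.b_preferential:
            raise ValueError("preferential sets must be disjoint")

    def swapped(self) -> "DifferentialMarkResult":
        return DifferentialMarkResult(
            self.mark,
            self.tissue_b,
            self.tissue_a,
            set(self.b_preferential),
            set(self.a_preferential),
            1.0 / self.fold if len(self.fold) else self.fold,
        )

    def to_tsv(self, path) -> None:
        rows = []
        for g in sorted(self.a_preferential):
            rows.append((g, self.tissue_a, self.fold.get(g, np.nan)))
        for g in sorted(self.b_preferential):
            rows.append((g, self.tissue_b, self.fold.get(g, np.nan)))
        pd.DataFrame(rows, columns=["gene_id", "preferential_in", "fold_a_over_b"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def _window_overlap(tree: IntervalTree, lo: int, hi: int) -> int:
    """Total bases of [lo, hi) covered by the union of tree intervals."""
    hits = sorted((max(iv.begin, lo), min(iv.end, hi)) for iv in tree.overlap(lo, hi))
    covered = 0
    cur_end = lo
    for s, e in hits:
        if e <= cur_end:
            continue
        covered += e - max(s, cur_end)
        cur_end = e
    return covered


def assign_marks(
    peaks: list[Peak],
    genes: list[GeneModel],
    upstream_bp: int = 2000,
    genome: dict[str, int] | None = None,
    tracks: dict[tuple[str, str], SignalTrack] | None = None,
    min_overlap_fraction: float = 0.0,
) -> MarkTable:
    """Flag each gene as carrying each (mark, tissue) it overlaps peaks of.

    The gene window is the gene body plus ``upstream_bp`` upstream of the TSS
    (strand-aware, clipped to the chromosome).  By default one overlapping
    base suffices; ``min_overlap_fraction`` > 0 instead requires that fraction
    of the window to be covered by peaks.  When signal ``tracks`` are given
    (keyed by (mark, tissue)), the windowed mean signal is recorded alongside.
    """
    if upstream_bp < 0:
        raise ValueError("upstream_bp must be >= 0")
    slots = sorted({(p.mark, p.tissue) for p in peaks})
    if any(m is None or t is None for m, t in slots):
        raise ValueError("all peaks must carry mark and tissue labels")
    if tracks:
        slots = sorted(set(slots) | set(tracks))
    trees: dict[tuple[str, str, str], IntervalTree] = {}
    for p in peaks:
        trees.setdefault((p.mark, p.tissue, p.chrom), IntervalTree()).addi(p.start, p.end)

    gene_ids = [g.gene_id for g in genes]
    cols = pd.MultiIndex.from_tuples(slots, names=["mark", "tissue"])
    presence = pd.DataFrame(False, index=gene_ids, columns=cols)
    signal = pd.DataFrame(np.nan, index=gene_ids, columns=cols)
    for g in genes:
        chrom_len = genome.get(g.chrom) if genome else None
        lo, hi = g.window(upstream_bp, chrom_len)
        for mark, tissue in slots:
            tree = trees.get((mark, tissue, g.chrom))
            if tree is not None:
                if min_overlap_fraction > 0:
                    need = min_overlap_fraction * (hi - lo)
                    hit = _window_overlap(tree, lo, hi) >= need
                else:
                    hit = bool(tree.overlap(lo, hi))
                presence.loc[g.gene_id, (mark, tissue)] = hit
            if tracks and (mark, tissue) in tracks:
                signal.loc[g.gene_id, (mark, tissue)] = tracks[(mark, tissue)].window_mean(
                    g.chrom, lo, hi
                )
    return MarkTable(presence=presence, mean_signal=signal)


def normalize_tracks(
    track_a: SignalTrack, track_b: SignalTrack
) -> tuple[SignalTrack, SignalTrack]:
    """Depth-normalize two tracks by scaling each down to the smaller total.

    Mirrors scaling a deeper library to the shallower one; after this the
    genome-wide integrals are equal and fold ratios are comparable.
    """
    ta, tb = track_a.total(), track_b.total()
    if ta == 0 or tb == 0:
        raise ValueError("cannot normalize an all-zero track")
    target = min(ta, tb)
    return track_a.scaled(target / ta), track_b.scaled(target / tb)


def differential_deposition(
    table: MarkTable,
    mark: str,
    tissue_a: str,
    tissue_b: str,
    signal_a: SignalTrack,
    signal_b: SignalTrack,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> DifferentialMarkResult:
    """Call genes preferentially deposited with ``mark`` in one tissue.

    A gene is A-preferential iff it carries the mark in A but not B, or
    carries it in both and (mean_A + c) / (mean_B + c) >= min_fold, where the
    means are windowed mean signals recorded in the table (tracks must be
    depth-normalized first; totals differing by more than 1% raise).
    Symmetric for B.  Fold ratios for all double-carriers are reported.
    """
    ta, tb = signal_a.total(), signal_b.total()
    if ta == 0 or tb == 0 or abs(ta - tb) / max(ta, tb) > 0.01:
        raise ValueError(
            f"signals not depth-normalized: totals {ta:.6g} vs {tb:.6g} differ by >1%"
        )
    fa = table.flags(mark, tissue_a)
    fb = table.flags(mark, tissue_b)
    ma = table.mean_signal[(mark, tissue_a)]
    mb = table.mean_signal[(mark, tissue_b)]
    if ma.isna().any() or mb.isna().any():
        raise ValueError("mean signal missing; assign_marks must be run with tracks")

    both = fa & fb
    ratio = (ma[both] + pseudocount) / (mb[both] + pseudocount)
    a_pref = set(fa.index[fa & ~fb]) | set(ratio.index[ratio >= min_fold])
    b_pref = set(fb.index[fb & ~fa]) | set(ratio.index[ratio <= 1.0 / min_fold])
    return DifferentialMarkResult(
        mark=mark,
        tissue_a=tissue_a,
        tissue_b=tissue_b,
        a_preferential=a_pref,
        b_preferential=b_pref,
        fold=ratio,
    )
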