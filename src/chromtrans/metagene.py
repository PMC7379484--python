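"""Meta-gene signal profiles and TSS-centred signal matrices.

The scaled meta-gene profile maps every gene onto a common coordinate
system — fixed-width flank bins upstream of the TSS and downstream of the
TTS, and a gene body rescaled into a fixed number of equal-fraction bins —
then averages across genes.  TSS matrices keep genes as rows for heatmaps.
Bin values are mean per-base signal, so flank and scaled-body bins are on
the same scale.  Minus-strand genes are reversed so bin 0 is always the
5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .io import SignalTrack

__all__ = ["MetageneProfile", "HeatmapMatrix", "metagene_profile", "tss_matrix"]


@dataclass
class MetageneProfile:
    """Mean signal per scaled-coordinate bin, averaged over genes."""

    bin_labels: list[str]
    means: np.ndarray
    n_genes: int
    n_skipped: int
    flank_bins: int
    body_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bin_labels, "mean_signal": self.means})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class HeatmapMatrix:
    """Gene x fixed-width-bin signal matrix centred on the TSS."""

    values: pd.DataFrame  # index: gene ids; columns: bin start offsets
    clipped: pd.Series  # True where the window ran off a chromosome edge

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out["clipped"] = self.clipped.astype(int)
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean per-base value in ``n_bins`` equal-fraction bins of ``values``."""
    edges = np.floor(np.arange(n_bins + 1) * len(values) / n_bins).astype(int)
    sums = np.add.reduceat(values, edges[:-1])
    return sums / np.diff(edges)


def _gene_window_values(
    track: SignalTrack, gene: GeneModel, flank_bp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-base signal over (upstream flank, body, downstream flank), 5'->3'."""
    up = track.values_array(gene.chrom, gene.start - flank_bp, gene.start)
    body = track.values_array(gene.chrom, gene.start, gene.end)
    down = track.values_array(gene.chrom, gene.end, gene.end + flank_bp)
    if gene.strand == "-":
        up, body, down = down[::-1], body[::-1], up[::-1]
    return up, body, down


def metagene_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    flank_bp: int = 1000,
    flank_bins: int = 20,
    body_bins: int = 60,
) -> MetageneProfile:
    """Scaled TSS->TTS profile with fixed-width flanks, averaged over genes.

    Genes with bodies shorter than ``body_bins`` bases are skipped (counted in
    ``n_skipped``) rather than padded.  The profile is the unweighted mean of
    the per-gene bin vectors.
    """
    if flank_bins < 1 or body_bins < 1:
        raise ValueError("flank_bins and body_bins must be >= 1")
    rows = []
    skipped = 0
    for gene in genes:
        if gene.length < body_bins:
            skipped += 1
            continue
        up, body, down = _gene_window_values(track, gene, flank_bp)
        rows.append(
            np.concatenate(
                [
                    _bin_means(up, flank_bins),
                    _bin_means(body, body_bins),
                    _bin_means(down, flank_bins),
                ]
            )
        )
    if not rows:
        raise ValueError("no gene long enough to profile")
    means = np.mean(rows, axis=0)
    labels = (
        [f"u{i}" for i in range(flank_bins)]
        + [f"b{i}" for i in range(body_bins)]
        + [f"d{i}" for i in range(flank_bins)]
    )
    return MetageneProfile(
        bin_labels=labels,
        means=means,
        n_genes=len(rows),
        n_skipped=skipped,
        flank_bins=flank_bins,
        body_bins=body_bins,
    )


def tss_matrix(
    track: SignalTrack,
    genes: list[GeneModel],
    gene_ids: list[str],
    flank_bp: int = 3000,
    bin_bp: int = 100,
    genome: dict[str, int] | None = None,
) -> HeatmapMatrix:
    """Per-gene binned signal in [TSS - flank_bp, TSS + flank_bp), 5'->3'.

    ``bin_bp`` must divide 2 * flank_bp.  Windows clipped at chromosome edges
    contribute zeros for the missing bases and are flagged in ``clipped``.
    """
    if (2 * flank_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*flank_bp")
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in gene_ids if gid not in by_id]
    if missing:
        raise ValueError(f"gene ids absent from annotation: {', '.join(missing[:5])}")
    n_bins = 2 * flank_bp // bin_bp
    mat = np.empty((len(gene_ids), n_bins))
    clipped = []
    for i, gid in enumerate(gene_ids):
        g = by_id[gid]
        # window centred on the first transcribed base, upstream on the left
        lo, hi = g.tss - flank_bp, g.tss + flank_bp
        if g.strand == "-":
            lo, hi = g.tss + 1 - flank_bp, g.tss + 1 + flank_bp
        vals = track.values_array(g.chrom, lo, hi)
        if g.strand == "-":
            vals = vals[::-1]
        mat[i] = vals.reshape(n_bins, bin_bp).mean(axis=1)
        off_end = genome is not None and hi > genome.get(g.chrom, hi)
        clipped.append(lo < 0 or off_end)
    offsets = [(-flank_bp + j * bin_bp) for j in range(n_bins)]
    return HeatmapMatrix(
        values=pd.DataFrame(mat, index=list(gene_ids), columns=offsets),
        clipped=pd.Series(clipped, index=list(gene_ids)),
    )
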