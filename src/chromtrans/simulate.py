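"""Synthetic two-tissue epigenome generator with planted, machine-readable truth.

Emits a toy genome (GFF3), per-mark per-tissue peak sets (BED) and signal
tracks (bedGraph), a two-condition FPKM table, a multi-tissue expression
panel emulating a 45-array / 13-tissue compendium, a TF family catalog, and
a truth table — everything the pipeline reads, in the formats it reads.

Construction guarantees: genes sit in disjoint slots so each gene's
assignment window (body + 2 kb upstream) never touches a neighbour's; peaks
are placed fully inside their gene's window with a safety margin, so the
overlap rule recovers the planted mark flags exactly; a gene carrying a mark
in both tissues reuses the same peak interval with tissue-specific
amplitude, so windowed fold ratios equal the planted fold.  With zero noise
every downstream call (marks, states, transitions, differential sets, DEGs)
is exactly recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from .annotation import GeneModel
from .io import (
    MARKS,
    TISSUES,
    Peak,
    SignalTrack,
    write_gff3,
    write_peaks,
    write_signal,
)
from .states import TRANSITION_LABELS, UNCLASSIFIED

__all__ = ["SimConfig", "SyntheticTruth", "simulate", "truth_scorecard"]

# Default distribution over (callus state, seedling state) pairs.  Skewed the
# way the biology runs: the pluripotent callus is richer in active/bivalent
# genes, the differentiated seedling carries more H3K27me3.
DEFAULT_STATE_PAIR_WEIGHTS: dict[tuple[str, str], float] = {
    ("active", "active"): 0.14,
    ("repressed", "repressed"): 0.12,
    ("none", "none"): 0.10,
    ("bivalent", "bivalent"): 0.10,
    ("active", "bivalent"): 0.09,
    ("bivalent", "active"): 0.06,
    ("active", "repressed"): 0.08,
    ("repressed", "active"): 0.05,
    ("bivalent", "repressed"): 0.06,
    ("repressed", "bivalent"): 0.05,
    ("active", "none"): 0.05,
    ("none", "active"): 0.04,
    ("repressed", "none"): 0.03,
    ("none", "repressed"): 0.03,
}

PANEL_TISSUES = (
    "callus",
    "root",
    "shoot",
    "young_leaf",
    "mature_leaf",
    "stem",
    "panicle",
    "anther",
    "pistil",
    "seed_5dap",
    "seed_10dap",
    "embryo",
    "endosperm",
)
# 3 callus replicates + 42 across the other 12 tissues = 45 arrays.
PANEL_REPLICATES = (3, 4, 4, 4, 4, 3, 3, 4, 3, 4, 3, 3, 3)

TF_FAMILIES = (
    "AP2/EREBP",
    "NAC",
    "HB",
    "MADS",
    "WRKY",
    "bHLH",
    "GRAS",
    "C2C2-Dof",
    "ARF",
    "AUX/IAA",
    "GRF",
    "LOB",
)


@dataclass
class SimConfig:
    """Design of one synthetic study; the defaults are the study conditions.

    noise_level scales multiplicative signal-amplitude noise (truncated
    Gaussian) and log-expression noise; the multi-tissue panel always has
    unit per-sample variation, which is the scale of
    ``preferential_effect_sd``.
    """

    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_genes: int = 500
    peak_width_median: float = 1000.0
    peak_width_sigma: float = 0.5
    state_pair_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_PAIR_WEIGHTS)
    )
    dhs_prob: dict = field(default_factory=lambda: {"callus": 0.5, "seedling": 0.3})
    base_amplitude: float = 50.0
    diff_fraction: float = 0.1
    diff_fold: float = 4.0
    n_deg: int = 100
    deg_fold: float = 4.0
    anti_corr_fraction: float = 0.7
    n_preferential: int = 150
    preferential_effect_sd: float = 4.0
    tf_fraction: float = 0.4
    noise_level: float = 0.0
    upstream_bp: int = 2000
    seed: int = 42

    def __post_init__(self):
        for name in ("diff_fraction", "anti_corr_fraction", "tf_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.state_pair_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("state_pair_weights must sum to 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if 2 * self.n_deg > self.n_genes or self.n_preferential > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.seed is None:
            raise ValueError("seed is mandatory")


_STATE_FLAGS = {
    "active": (True, False),
    "repressed": (False, True),
    "bivalent": (True, True),
    "none": (False, False),
}

_MIN_SLOT = 3700  # bp per gene slot needed for body + upstream window + margins


class SyntheticTruth:
    """Planted per-gene truth: flags, states, transitions, set memberships."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def mark_flags(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_product(
            [MARKS, TISSUES], names=["mark", "tissue"]
        )
        out = pd.DataFrame(index=self.table.index, columns=cols, dtype=bool)
        short = {"H3K27me3": "k27", "H3K4me3": "k4", "DHS": "dhs"}
        for mark in MARKS:
            for tissue in TISSUES:
                out[(mark, tissue)] = self.table[f"{short[mark]}_{tissue}"].astype(bool)
        return out

    def diff_sets(self, mark: str) -> tuple[set[str], set[str]]:
        short = {"H3K27me3": "k27", "H3K4me3": "k4", "DHS": "dhs"}[mark]
        col = self.table[f"{short}_pref"]
        return set(col.index[col == "callus"]), set(col.index[col == "seedling"])

    def deg_sets(self) -> tuple[set[str], set[str]]:
        col = self.table["deg"]
        return set(col.index[col == "callus"]), set(col.index[col == "seedling"])

    def preferential_set(self) -> set[str]:
        col = self.table["preferential"].astype(bool)
        return set(col.index[col])

    def states(self, tissue: str) -> pd.Series:
        return self.table[f"state_{tissue}"]

    def transitions(self) -> pd.Series:
        return self.table["transition"]

    def archetypes(self) -> pd.Series:
        return self.table["archetype"].astype(int)

    def to_tsv(self, path) -> None:
        self.table.sort_index().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        for col in df.columns:
            if col.split("_")[0] in ("k4", "k27", "dhs") and not col.endswith("pref"):
                df[col] = df[col].astype(bool)
        df["preferential"] = df["preferential"].astype(bool)
        return cls(df)


def _place_genes(cfg: SimConfig, rng) -> tuple[dict[str, int], list[GeneModel]]:
    genome = {f"Chr{i + 1}": int(l) for i, l in enumerate(cfg.chrom_lengths)}
    total = sum(genome.values())
    genes: list[GeneModel] = []
    # largest-remainder apportionment of genes to chromosomes
    quotas = {c: cfg.n_genes * l / total for c, l in genome.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True):
        if sum(counts.values()) >= cfg.n_genes:
            break
        counts[c] += 1
    idx = 0
    for chrom in sorted(genome):
        n = counts[chrom]
        if n == 0:
            continue
        slot = genome[chrom] // n
        if slot < _MIN_SLOT:
            raise ValueError(
                f"infeasible design: {n} genes on {chrom} leaves {slot} bp per "
                f"gene; need >= {_MIN_SLOT}"
            )
        for j in range(n):
            idx += 1
            s0 = j * slot
            length = int(rng.integers(600, 1501))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start = s0 + cfg.upstream_bp + 100
                end = start + length
            else:
                end = s0 + slot - cfg.upstream_bp - 100
                start = end - length
            if length >= 900:
                e1 = (start, start + int(0.4 * length))
                e2 = (start + int(0.6 * length), end)
                exons = [e1, e2]
            else:
                exons = [(start, end)]
            ul = min(max(30, length // 10), exons[0][1] - exons[0][0] - 10)
            if strand == "+":
                utr5 = [(start, start + ul)]
                utr3 = [(end - ul, end)]
            else:
                utr5 = [(end - ul, end)]
                utr3 = [(start, start + ul)]
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return genome, genes


def _truncnorm_factor(rng, sigma: float, size: int) -> np.ndarray:
    """Multiplicative noise factors 1 + e, e ~ N(0, sigma) truncated at 2 sigma."""
    if sigma == 0:
        return np.ones(size)
    e = np.clip(rng.normal(0.0, sigma, size), -2 * sigma, 2 * sigma)
    return np.maximum(1.0 + e, 0.05)


def simulate(cfg: SimConfig, outdir) -> SyntheticTruth:
    """Generate one synthetic study into ``outdir`` and return its truth.

    Writes genes.gff3, peaks/signal per (mark, tissue), expression_fpkm.tsv,
    panel_expression.tsv + panel_samples.tsv, tf_families.tsv, truth.tsv and
    manifest.yaml.  Identical config (including seed) reproduces identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genome, genes = _place_genes(cfg, rng)
    gene_ids = [g.gene_id for g in genes]
    n = len(genes)
    by_id = {g.gene_id: g for g in genes}

    # --- states and mark flags -------------------------------------------
    pairs = list(DEFAULT_STATE_PAIR_WEIGHTS)
    pairs = sorted(cfg.state_pair_weights, key=lambda p: pairs.index(p) if p in pairs else 99)
    probs = np.array([cfg.state_pair_weights[p] for p in pairs])
    pick = rng.choice(len(pairs), size=n, p=probs / probs.sum()) if n else np.array([], int)
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    truth["state_callus"] = [pairs[i][0] for i in pick]
    truth["state_seedling"] = [pairs[i][1] for i in pick]
    truth["transition"] = [
        t if (t := f"{a}-{b}") in TRANSITION_LABELS else UNCLASSIFIED
        for a, b in zip(truth["state_callus"], truth["state_seedling"])
    ]
    for tissue in TISSUES:
        st = truth[f"state_{tissue}"]
        truth[f"k4_{tissue}"] = [_STATE_FLAGS[s][0] for s in st]
        truth[f"k27_{tissue}"] = [_STATE_FLAGS[s][1] for s in st]
        truth[f"dhs_{tissue}"] = rng.random(n) < cfg.dhs_prob[tissue]

    short = {"H3K27me3": "k27", "H3K4me3": "k4", "DHS": "dhs"}

    # --- differential-deposition planting --------------------------------
    # Genes carrying a mark in both tissues share one peak interval; planted
    # differential genes get amplitudes base*sqrt(fold) vs base/sqrt(fold).
    amp = {}  # (gene_id, mark, tissue) -> amplitude
    for mark in MARKS:
        s = short[mark]
        fc = truth[f"{s}_callus"].values
        fs = truth[f"{s}_seedling"].values
        both = [gid for gid, a, b in zip(gene_ids, fc, fs) if a and b]
        n_dir = int(round(cfg.diff_fraction * len(both) / 2))
        chosen = list(rng.permutation(both))
        up_c = set(chosen[:n_dir])
        up_s = set(chosen[n_dir: 2 * n_dir])
        hi = cfg.base_amplitude * math.sqrt(cfg.diff_fold)
        lo = cfg.base_amplitude / math.sqrt(cfg.diff_fold)
        pref = []
        for gid, a, b in zip(gene_ids, fc, fs):
            if a and not b:
                pref.append("callus")
            elif b and not a:
                pref.append("seedling")
            elif a and b and gid in up_c:
                pref.append("callus")
            elif a and b and gid in up_s:
                pref.append("seedling")
            else:
                pref.append("none")
            ac = as_ = cfg.base_amplitude
            if gid in up_c:
                ac, as_ = hi, lo
            elif gid in up_s:
                ac, as_ = lo, hi
            if a:
                amp[(gid, mark, "callus")] = ac
            if b:
                amp[(gid, mark, "seedling")] = as_
        truth[f"{s}_pref"] = pref

    # --- peaks and signal tracks ------------------------------------------
    def draw_peak(g: GeneModel, mark: str) -> tuple[int, int]:
        # Peaks sit fully inside the assignment window with a safety margin.
        # H3K27me3 forms broad domains blanketing the silenced gene and its
        # promoter; H3K4me3 and DHS are sharp and TSS-anchored.
        lo, hi = g.window(cfg.upstream_bp, genome[g.chrom])
        if mark == "H3K27me3":
            start = lo + 10 + int(rng.integers(0, 90))
            end = hi - 10 - int(rng.integers(0, 90))
            return start, end
        width = int(
            np.clip(
                rng.lognormal(math.log(cfg.peak_width_median), cfg.peak_width_sigma),
                300,
                hi - lo - 20,
            )
        )
        center = g.tss + rng.normal(0.0, 200.0)
        start = int(np.clip(center - width / 2, lo + 10, hi - 10 - width))
        return start, start + width

    peaks: dict[tuple[str, str], list[Peak]] = {
        (m, t): [] for m in MARKS for t in TISSUES
    }
    for g in genes:
        for mark in MARKS:
            s = short[mark]
            has = {t: bool(truth.loc[g.gene_id, f"{s}_{t}"]) for t in TISSUES}
            if not any(has.values()):
                continue
            shared = draw_peak(g, mark) if all(has.values()) else None
            for tissue in TISSUES:
                if not has[tissue]:
                    continue
                ps, pe = shared if shared else draw_peak(g, mark)
                a = amp[(g.gene_id, mark, tissue)]
                a *= float(_truncnorm_factor(rng, cfg.noise_level, 1)[0])
                peaks[(mark, tissue)].append(
                    Peak(g.chrom, ps, pe, score=a, mark=mark, tissue=tissue)
                )

    tracks = {
        key: SignalTrack.from_intervals(
            (p.chrom, p.start, p.end, p.score) for p in plist
        )
        if plist
        else SignalTrack({})
        for key, plist in peaks.items()
    }

    # --- two-condition expression with planted DEGs ------------------------
    # Callus-up DEGs are drawn preferentially from genes with seedling-higher
    # H3K27me3 (and vice versa): the planted anti-correlation between the
    # repressive mark and transcription.
    k27_c, k27_s = (
        set(truth.index[truth["k27_pref"] == "callus"]),
        set(truth.index[truth["k27_pref"] == "seedling"]),
    )

    def pick_deg(pool: set[str], forbid: set[str], taken: set[str]) -> list[str]:
        n_anti = int(round(cfg.anti_corr_fraction * cfg.n_deg))
        pool_l = sorted(pool - taken)
        n_anti = min(n_anti, len(pool_l))
        sel = list(rng.choice(pool_l, size=n_anti, replace=False)) if n_anti else []
        rest_pool = sorted(set(gene_ids) - pool - forbid - taken - set(sel))
        n_rest = cfg.n_deg - n_anti
        if n_rest > len(rest_pool):
            raise ValueError("infeasible DEG design")
        sel += list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        return sel

    taken: set[str] = set()
    deg_callus = pick_deg(k27_s, k27_c, taken) if n else []
    taken |= set(deg_callus)
    deg_seedling = pick_deg(k27_c, k27_s, taken) if n else []
    truth["deg"] = "none"
    truth.loc[deg_callus, "deg"] = "callus"
    truth.loc[deg_seedling, "deg"] = "seedling"

    base = 2.0 + rng.lognormal(2.0, 1.0, n)
    expr = pd.DataFrame({"callus": base.copy(), "seedling": base.copy()},
                        index=truth.index)
    expr.loc[deg_callus, "callus"] *= cfg.deg_fold
    expr.loc[deg_seedling, "seedling"] *= cfg.deg_fold
    if cfg.noise_level > 0:
        expr *= np.exp(rng.normal(0.0, cfg.noise_level, expr.shape))

    # --- multi-tissue panel with planted preferential genes ----------------
    samples, sample_tissue = [], []
    for tissue, reps in zip(PANEL_TISSUES, PANEL_REPLICATES):
        for r in range(1, reps + 1):
            samples.append(f"{tissue}_{r}")
            sample_tissue.append(tissue)
    planted_pref = sorted(rng.choice(gene_ids, size=cfg.n_preferential, replace=False)) if n else []
    baseline = rng.normal(8.0, 1.0, n)
    panel = baseline[:, None] + rng.normal(0.0, 1.0, (n, len(samples)))
    is_callus = np.array([t == "callus" for t in sample_tissue])
    pref_idx = truth.index.get_indexer(planted_pref)
    if len(pref_idx):
        panel[np.ix_(pref_idx, np.flatnonzero(is_callus))] += cfg.preferential_effect_sd
    panel = np.maximum(panel, 0.01)
    panel_df = pd.DataFrame(panel, index=truth.index, columns=samples)
    truth["preferential"] = truth.index.isin(planted_pref)

    # --- TF catalog ---------------------------------------------------------
    n_tf = int(round(cfg.tf_fraction * n))
    tf_genes = sorted(rng.choice(gene_ids, size=n_tf, replace=False)) if n else []
    fam_of = rng.choice(len(TF_FAMILIES), size=n_tf)
    tf_rows = [(g, TF_FAMILIES[f]) for g, f in zip(tf_genes, fam_of)]

    # --- cluster archetypes -------------------------------------------------
    # Two signal archetypes around the TSS: genes carrying H3K27me3 in callus
    # (broad high signal) vs. genes without it (flat zero).
    truth["archetype"] = truth["k27_callus"].astype(int)

    # --- write everything ---------------------------------------------------
    write_gff3(genome, genes, outdir / "genes.gff3")
    manifest = {
        "genes": "genes.gff3",
        "expression": "expression_fpkm.tsv",
        "panel": "panel_expression.tsv",
        "panel_samples": "panel_samples.tsv",
        "tf_families": "tf_families.tsv",
        "peaks": {},
        "signal": {},
    }
    for mark in MARKS:
        manifest["peaks"][mark] = {}
        manifest["signal"][mark] = {}
        for tissue in TISSUES:
            pf = f"peaks_{mark.replace('/', '_')}_{tissue}.bed"
            sf = f"signal_{mark.replace('/', '_')}_{tissue}.bedgraph"
            write_peaks(sorted(peaks[(mark, tissue)], key=lambda p: (p.chrom, p.start)),
                        outdir / pf)
            write_signal(tracks[(mark, tissue)], outdir / sf)
            manifest["peaks"][mark][tissue] = pf
            manifest["signal"][mark][tissue] = sf
    expr.sort_index().to_csv(outdir / "expression_fpkm.tsv", sep="\t",
                             index_label="gene_id", float_format="%.8g")
    panel_df.sort_index().to_csv(outdir / "panel_expression.tsv", sep="\t",
                                 index_label="gene_id", float_format="%.8g")
    pd.DataFrame(
        {
            "sample": samples,
            "tissue": sample_tissue,
            "stage": [f"S{(i % 17) + 1}" for i in range(len(samples))],
        }
    ).to_csv(outdir / "panel_samples.tsv", sep="\t", index=False)
    pd.DataFrame(tf_rows, columns=["gene_id", "family"]).to_csv(
        outdir / "tf_families.tsv", sep="\t", index=False
    )
    truth_obj = SyntheticTruth(truth)
    truth_obj.to_tsv(outdir / "truth.tsv")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(outdir / "sim_config.yaml", "w") as fh:
        cfgd = asdict(cfg)
        cfgd["chrom_lengths"] = list(cfgd["chrom_lengths"])
        cfgd["state_pair_weights"] = {
            f"{a}-{b}": w for (a, b), w in cfgd["state_pair_weights"].items()
        }
        yaml.safe_dump(cfgd, fh, sort_keys=True)
    return truth_obj


# ---------------------------------------------------------------------------
# Scorecard


def _set_metrics(pred: set, true: set) -> tuple[float, float]:
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 1.0
    recall = tp / len(true) if true else 1.0
    return precision, recall


def truth_scorecard(truth: SyntheticTruth, outputs: dict) -> pd.DataFrame:
    """Score pipeline outputs against the planted truth.

    ``outputs`` may contain: ``mark_table`` (MarkTable), ``differential``
    ({mark: DifferentialMarkResult}), ``states`` ({tissue: Series}),
    ``transitions`` (DataFrame), ``deg`` ((set, set) as (callus, seedling)),
    ``preferential`` (DataFrame with a ``preferential`` column), ``clusters``
    (Series of labels).  One row per recoverable quantity.
    """
    rows = []

    def add(quantity, n, precision=np.nan, recall=np.nan, accuracy=np.nan, ari=np.nan):
        rows.append((quantity, n, precision, recall, accuracy, ari))

    gene_index = truth.table.index

    if "mark_table" in outputs:
        mt = outputs["mark_table"]
        if set(mt.presence.index) != set(gene_index):
            raise ValueError("mark table gene universe differs from truth")
        tf = truth.mark_flags().reindex(mt.presence.index)
        pred = mt.presence[tf.columns].values.ravel()
        true = tf.values.ravel()
        tp = int(np.sum(pred & true))
        add(
            "mark_flags",
            pred.size,
            precision=tp / pred.sum() if pred.sum() else 1.0,
            recall=tp / true.sum() if true.sum() else 1.0,
            accuracy=float(np.mean(pred == true)),
        )

    for mark, res in outputs.get("differential", {}).items():
        ta, tb = truth.diff_sets(mark)
        pa, rb = _set_metrics(res.a_preferential, ta)
        pb, rbb = _set_metrics(res.b_preferential, tb)
        pred_pairs = {(g, "a") for g in res.a_preferential} | {
            (g, "b") for g in res.b_preferential
        }
        true_pairs = {(g, "a") for g in ta} | {(g, "b") for g in tb}
        p, r = _set_metrics(pred_pairs, true_pairs)
        add(f"differential_{mark}", len(true_pairs), precision=p, recall=r)

    for tissue, called in outputs.get("states", {}).items():
        ts = truth.states(tissue).reindex(called.index)
        add(f"states_{tissue}", len(called), accuracy=float((called == ts).mean()))

    if "transitions" in outputs:
        tt = outputs["transitions"]
        ts = truth.transitions().reindex(tt.index)
        add("transitions", len(tt), accuracy=float((tt["transition"] == ts).mean()))

    if "deg" in outputs:
        deg_a, deg_b = outputs["deg"]
        ta, tb = truth.deg_sets()
        pred = {(g, "a") for g in deg_a} | {(g, "b") for g in deg_b}
        true = {(g, "a") for g in ta} | {(g, "b") for g in tb}
        p, r = _set_metrics(pred, true)
        add("deg", len(true), precision=p, recall=r)

    if "preferential" in outputs:
        calls = outputs["preferential"]
        pred = set(calls.index[calls["preferential"]])
        p, r = _set_metrics(pred, truth.preferential_set())
        add("preferential", len(calls), precision=p, recall=r)

    if "clusters" in outputs:
        labels = outputs["clusters"]
        arch = truth.archetypes().reindex(labels.index)
        add(
            "clusters",
            len(labels),
            ari=float(adjusted_rand_score(arch.values, labels.values)),
        )

    return pd.DataFrame(
        rows, columns=["quantity", "n", "precision", "recall", "accuracy", "ari"]
    )
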