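"""Chromatin state calling and state-transition classification.

A gene's state in a tissue is a pure function of its two histone-mark flags:
H3K4me3 only -> "active", H3K27me3 only -> "repressed", both -> "bivalent"
(the hallmark of poised developmental regulators), neither -> "none".
Between two tissues (here callus -> seedling) seven transitions are defined:
the six directional changes among {active, bivalent, repressed} plus the
stable bivalent-bivalent; pairs involving "none", and the stable
active-active / repressed-repressed pairs, are left unclassified.
"""

from __future__ import annotations

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import hypergeometric_test
from .marks import MarkTable

__all__ = [
    "STATES",
    "TRANSITION_LABELS",
    "call_state",
    "call_states",
    "classify_transitions",
    "transition_counts",
    "transition_enrichment",
]

STATES = ("active", "bivalent", "repressed", "none")

#: The seven classified callus->seedling transitions.
TRANSITION_LABELS = (
    "bivalent-active",
    "active-bivalent",
    "repressed-bivalent",
    "bivalent-repressed",
    "active-repressed",
    "repressed-active",
    "bivalent-bivalent",
)

UNCLASSIFIED = "unclassified"


def call_state(h3k4me3: bool, h3k27me3: bool) -> str:
    """Map the two mark flags to the gene's chromatin state."""
    if h3k4me3 and h3k27me3:
        return "bivalent"
    if h3k4me3:
        return "active"
    if h3k27me3:
        return "repressed"
    return "none"


def call_states(table: MarkTable, tissue: str) -> pd.Series:
    """Per-gene state in one tissue from the mark table's flags."""
    k4 = table.flags("H3K4me3", tissue)
    k27 = table.flags("H3K27me3", tissue)
    return pd.Series(
        [call_state(a, b) for a, b in zip(k4, k27)], index=k4.index, name=tissue
    )


def classify_transitions(
    states_a: pd.Series, states_b: pd.Series
) -> pd.DataFrame:
    """Label each gene's (state in A, state in B) pair.

    Both inputs must cover the same gene universe.  Pairs among the seven
    transition labels get that label; everything else (pairs involving
    "none", and stable active-active / repressed-repressed) is
    "unclassified".
    """
    if set(states_a.index) != set(states_b.index):
        only_a = set(states_a.index) ^ set(states_b.index)
        raise ValueError(
            f"gene universes differ between tissues ({len(only_a)} mismatched)"
        )
    states_b = states_b.reindex(states_a.index)
    labels = []
    for a, b in zip(states_a, states_b):
        lab = f"{a}-{b}"
        labels.append(lab if lab in TRANSITION_LABELS else UNCLASSIFIED)
    return pd.DataFrame(
        {
            "state_a": states_a.values,
            "state_b": states_b.values,
            "transition": labels,
        },
        index=states_a.index,
    )


def transition_counts(table: pd.DataFrame) -> pd.Series:
    """Genes per transition label (all seven labels always present)."""
    counts = table["transition"].value_counts()
    return counts.reindex(list(TRANSITION_LABELS) + [UNCLASSIFIED], fill_value=0)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "*"
    return ""


def transition_enrichment(
    gene_set: set[str],
    table: pd.DataFrame,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` in each transition class.

    The universe defaults to all genes with a classified transition.  For
    each of the seven labels the upper-tail p of the overlap is reported,
    with significance stars at p < 0.01 (*) and p < 0.001 (***) and
    BH-adjusted q alongside.
    """
    if universe is None:
        universe = set(table.index[table["transition"] != UNCLASSIFIED])
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & universe
    N, n = len(universe), len(gene_set)
    rows = []
    for label in TRANSITION_LABELS:
        members = set(table.index[table["transition"] == label]) & universe
        K = len(members)
        k = len(gene_set & members)
        p = hypergeometric_test(N, K, n, k) if K else 1.0
        rows.append((label, N, K, n, k, p))
    df = pd.DataFrame(rows, columns=["transition", "N", "K", "n", "k", "p"])
    df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    df["stars"] = [_stars(p) for p in df["p"]]
    return df
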