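"""Hypergeometric over-representation tests for gene-set partitions.

Used for transcription-factor family enrichment (e.g., a catalog of ~2,700
TFs partitioned into families such as AP2/EREBP, NAC, HB, MADS) and for
cluster/transition memberships.  The test is the exact one-sided
(enrichment-only) hypergeometric upper tail; Benjamini-Hochberg q-values are
reported alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["FamilyCatalog", "hypergeometric_test", "family_enrichment"]


def hypergeometric_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: category size, n: draws (query size), k: overlap.
    Computed through the survival function, which works in log space and is
    exact to double precision for the sizes used here.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class FamilyCatalog:
    """Gene-family membership map (family label -> member gene ids)."""

    families: dict[str, set[str]]

    def __post_init__(self):
        self.families = {f: set(m) for f, m in self.families.items()}

    @property
    def size(self) -> int:
        return len(self.all_members())

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.families.values():
            out |= members
        return out

    @classmethod
    def from_tsv(cls, path) -> "FamilyCatalog":
        """Read a two-column (gene, family) TSV, header optional."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.iloc[0, 0].lower() in ("gene", "gene_id"):
            df = df.iloc[1:]
        fams: dict[str, set[str]] = {}
        for gene, family in zip(df.iloc[:, 0], df.iloc[:, 1]):
            fams.setdefault(family, set()).add(gene)
        return cls(fams)

    def to_tsv(self, path) -> None:
        rows = [
            (g, f) for f in sorted(self.families) for g in sorted(self.families[f])
        ]
        pd.DataFrame(rows, columns=["gene_id", "family"]).to_csv(
            path, sep="\t", index=False
        )


def family_enrichment(
    query: set[str],
    catalog: FamilyCatalog,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Test each family for over-representation in ``query``.

    The universe defaults to the catalog membership (the natural choice when
    the query is itself a TF subset); families are intersected with the
    universe before testing and families absent from it are dropped.  Results
    carry raw p, BH-adjusted q, and fold enrichment (k/n)/(K/N), sorted by
    (p, family).
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if universe is None:
        universe = catalog.all_members()
    universe = set(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe: {', '.join(extra)}")
    N, n = len(universe), len(query)
    rows = []
    for family in sorted(catalog.families):
        members = catalog.families[family] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = hypergeometric_test(N, K, n, k)
        fold = (k / n) / (K / N)
        rows.append((family, N, K, n, k, p, fold))
    df = pd.DataFrame(
        rows, columns=["family", "N", "K", "n", "k", "p", "fold_enrichment"]
    )
    if len(df):
        df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "family"], kind="stable").reset_index(drop=True)
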