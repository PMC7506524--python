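"""Gene-level over-representation of the SNPs inside a PRS.

SNPs are mapped to genes by position against a user-supplied gene-interval
table (BED-like input, held 1-based inclusive internally), and the resulting
gene list is tested for over-representation in user-supplied gene sets (GMT)
with a one-sided Fisher exact test, optionally the EASE variant (one overlap
gene subtracted before testing), and Bonferroni correction over the number
of sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneIntervalTable:
    """Gene bodies as 1-based inclusive intervals."""

    table: pd.DataFrame  # columns gene, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(t.columns):
            raise ValueError(f"gene intervals need columns {sorted(required)}")
        if (t["start"] > t["end"]).any():
            raise ValueError("interval start must be <= end")
        if t.duplicated(["gene", "chrom", "start", "end"]).any():
            raise ValueError("duplicate gene intervals")
        self.table = t.reset_index(drop=True)

    @classmethod
    def read_bed(cls, path, flank_kb: float = 0.0) -> "GeneIntervalTable":
        """Read a BED-like file (chrom, start, end, gene); BED half-open
        0-based coordinates are converted to 1-based inclusive.  An optional
        symmetric flank widens every interval."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "gene"],
                         usecols=[0, 1, 2, 3])
        flank = int(flank_kb * 1000)
        out = pd.DataFrame({
            "gene": df["gene"].astype(str),
            "chrom": df["chrom"].astype(str),
            "start": np.maximum(1, df["start"].astype(int) + 1 - flank),
            "end": df["end"].astype(int) + flank,
        })
        return cls(out)

    def all_genes(self) -> set[str]:
        return set(self.table["gene"])


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = {g for g in genes if g}
            if not genes:
                raise ValueError(f"empty gene set {name!r}")
            sets[name] = genes
    return sets


def snps_to_genes(positions: pd.DataFrame,
                  intervals: GeneIntervalTable) -> set[str]:
    """Genes containing at least one query SNP (bounds inclusive).

    ``positions`` needs columns ``CHR`` and ``BP`` (1-based).
    """
    genes: set[str] = set()
    t = intervals.table
    for chrom, grp in positions.groupby(positions["CHR"].astype(str)):
        sub = t[t["chrom"] == chrom]
        if sub.empty:
            continue
        bp = grp["BP"].to_numpy(dtype=np.int64)
        for gene, start, end in zip(sub["gene"], sub["start"], sub["end"]):
            if np.any((bp >= start) & (bp <= end)):
                genes.add(gene)
    return genes


def overrepresent(query: set[str], sets: dict[str, set[str]],
                  background: set[str], ease: bool = False) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each gene set.

    Each set is intersected with the background first.  Fold enrichment is
    (k/n)/(K/N) for overlap k, query size n, set size K, background N.
    With ``ease`` one overlap gene is subtracted before the test (the EASE
    score used by DAVID), which is conservative.  Adjusted P is Bonferroni
    over the number of sets tested; rows are sorted by P.
    """
    if not background:
        raise ValueError("empty background gene set")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    n_bg = len(background)
    n_query = len(query)
    rows = []
    m = 0
    for name, genes in sets.items():
        genes = genes & background
        if not genes:
            continue
        m += 1
        k = len(query & genes)
        big_k = len(genes)
        fold = (k / n_query) / (big_k / n_bg) if n_query and big_k else 0.0
        k_test = max(k - 1, 0) if ease else k
        table = [[k_test, n_query - k_test],
                 [big_k - k_test, n_bg - n_query - big_k + k_test]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append((name, k, fold, float(p)))
    out = pd.DataFrame(rows, columns=["set", "gene_count", "fold_enrichment", "p"])
    out["p_adjusted"] = np.minimum(1.0, out["p"] * m)
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
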