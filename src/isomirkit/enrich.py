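"""Hypergeometric pathway over-representation with BH-FDR correction.

Given a target-gene set (e.g. the union of predicted targets of a group of
differentially expressed miRNAs) and pathway memberships, each pathway is
tested for over-representation with the upper-tail hypergeometric
probability P(X >= k), where k is the overlap, K the pathway size, n the
target-set size and N the gene universe. Benjamini-Hochberg q-values are
computed across all tested pathways.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts pathway genes in a size-``n`` draw without replacement from a
    universe of ``N`` genes of which ``K`` are in the pathway.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent sizes N={N} K={K} n={n} k={k}")
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Parse a GMT file: ``pathway_id <tab> description <tab> gene ...``."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pid, desc, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            if pid in pathways:
                raise ValueError(f"duplicate pathway id {pid!r} in {path}")
            pathways[pid] = (desc, genes)
    return pathways


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a newline-delimited gene-symbol list (blank lines ignored)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def target_union(gene_lists: Iterable[Iterable[str]]) -> frozenset[str]:
    """Union of per-miRNA target-gene lists."""
    out: set[str] = set()
    for gl in gene_lists:
        out.update(gl)
    return frozenset(out)


def enrich_targets(
    target_genes: Iterable[str],
    pathways: Mapping[str, tuple[str, frozenset[str]]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Test every pathway for over-representation of the target genes.

    The universe defaults to all genes appearing in at least one pathway;
    an explicit universe further restricts it. Targets outside the universe
    are dropped before testing. Results are sorted by p-value and carry
    Benjamini-Hochberg q-values over all tested pathways.
    """
    gmt_universe: set[str] = set()
    for _, genes in pathways.values():
        gmt_universe |= genes
    uni = gmt_universe if universe is None else gmt_universe & set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    targets = set(target_genes) & uni
    N, n = len(uni), len(targets)
    rows = []
    for pid, (desc, genes) in pathways.items():
        members = genes & uni
        K = len(members)
        k = len(members & targets)
        rows.append(
            {"pathway_id": pid, "description": desc, "K": K, "n": n, "k": k,
             "N": N, "p": hypergeom_test(N, K, n, k)}
        )
    df = pd.DataFrame(rows).sort_values(["p", "pathway_id"], ignore_index=True)
    df["q"] = bh_qvalues(df["p"].tolist())
    return df


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return list(stats.false_discovery_control(pvalues, method="bh"))


def write_enrichment_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
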