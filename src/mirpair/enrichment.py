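"""Gene-set over-representation of the final target genes.

Hypergeometric (or EASE) p per term, fold enrichment, BH FDR reported in
percent, and Bonferroni over the tested family. EASE is the conservative
DAVID-style variant: the upper tail is computed with one gene removed
from the overlap. The universe defaults, at the pipeline level, to the
genes measured on the platform after flag filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = ["hypergeom_p", "fold_enrichment", "enrich", "read_gmt", "write_gmt"]


def hypergeom_p(m: int, n: int, M: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric P(X >= m); EASE uses P(X >= m-1).

    m: overlap, n: study-set size, M: term size in universe, N: universe.
    """
    if not (0 <= m <= min(n, M) and n <= N and M <= N):
        raise ValueError(f"inconsistent counts m={m}, n={n}, M={M}, N={N}")
    if m == 0:
        return 1.0
    k = m - 1 if ease else m
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def fold_enrichment(m: int, n: int, M: int, N: int) -> float:
    """(m/n) / (M/N)."""
    if n <= 0 or M <= 0 or N <= 0:
        raise ValueError("n, M, N must be positive")
    return (m / n) / (M / N)


def read_gmt(path) -> list:
    """GMT: term_id <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            sets.append((fields[0], fields[1], [g for g in fields[2:] if g]))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for term_id, desc, genes in sets:
            fh.write("\t".join([term_id, desc, *genes]) + "\n")


def enrich(
    study_genes,
    gene_sets,
    universe,
    ease: bool = True,
    regulators: dict | None = None,
) -> pd.DataFrame:
    """One result row per term overlapping the study set, sorted by p.

    ``regulators`` optionally maps gene -> set of miRNA ids (from the
    final regulatory pairs) to fill the per-term miRNA column.
    """
    universe = set(universe)
    study = set(study_genes)
    if not universe:
        raise ValueError("empty universe")
    if not study:
        raise ValueError("empty study set")
    if not study <= universe:
        extra = sorted(study - universe)[0]
        raise ValueError(f"study gene {extra!r} not in universe")
    N = len(universe)
    n = len(study)
    rows = []
    for term_id, name, genes in gene_sets:
        members = set(genes) & universe
        overlap = sorted(members & study)
        m, M = len(overlap), len(members)
        if m == 0 or M == 0:
            continue
        mirnas = sorted({mi for g in overlap for mi in (regulators or {}).get(g, ())})
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "m": m,
                "n": n,
                "M": M,
                "N": N,
                "fold_enrichment": fold_enrichment(m, n, M, N),
                "p_value": hypergeom_p(m, n, M, N, ease=ease),
                "overlap_genes": ",".join(overlap),
                "regulator_mirnas": ",".join(mirnas),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "name", "m", "n", "M", "N", "fold_enrichment",
            "p_value", "overlap_genes", "regulator_mirnas",
        ],
    )
    if len(out):
        out["fdr_percent"] = bh_adjust(out["p_value"].to_numpy()) * 100.0
        out["bonferroni"] = (out["p_value"] * len(out)).clip(upper=1.0)
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr_percent"] = pd.Series(dtype=float)
        out["bonferroni"] = pd.Series(dtype=float)
    return out


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
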