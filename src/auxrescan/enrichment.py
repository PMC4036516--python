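"""DE-list intersection and hypergeometric functional-category enrichment.

Two differential-expression comparisons are intersected at adjusted P <
alpha (strictly less; both comparisons must pass).  Each functional
category (MapMan-BIN-style gene sets) is then tested for over-representation
in a DE gene set with an upper-tail hypergeometric test — the probability of
drawing at least the observed number of category genes when sampling the DE
set size from the universe — and the per-set P values are corrected with
Benjamini-Hochberg.  Several gene sets (e.g. all / common / unique DE genes)
can be tested against the same category map, each with its own correction.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DE table TSV with columns gene_id, padj, direction."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "padj"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    if "direction" not in df.columns:
        df["direction"] = "up"
    return df.set_index("gene_id")


def intersect_de(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Genes with adjusted P strictly below alpha in BOTH comparisons.

    Returns a frame indexed by gene_id with the direction taken from
    ``table_a`` and a ``direction_conflict`` flag where the two comparisons
    disagree.
    """
    sig_a = table_a.index[table_a["padj"] < alpha]
    sig_b = table_b.index[table_b["padj"] < alpha]
    shared = sig_a.intersection(sig_b)
    out = pd.DataFrame(index=shared.sort_values())
    out["direction"] = table_a.loc[out.index, "direction"]
    if "direction" in table_b.columns:
        out["direction_conflict"] = (
            table_b.loc[out.index, "direction"] != out["direction"]
        )
    else:
        out["direction_conflict"] = False
    out.index.name = "gene_id"
    return out


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts category genes among ``n`` draws without replacement from a
    universe of ``N`` genes of which ``K`` are in the category.  Computed by
    exact summation of the hypergeometric pmf (scipy's survival function),
    never a normal approximation.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"impossible hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    de_sets: Mapping[str, Iterable[str]] | Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    category_labels: Optional[Mapping[str, str]] = None,
    directions: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of one or more DE gene sets per category.

    ``de_sets`` may be a single gene collection or a mapping of set name ->
    genes (each set is tested and BH-corrected independently).  Category
    genes outside the universe are logged and dropped from K.  Returns a
    long-format frame with one row per (gene_set, category).
    """
    if not isinstance(de_sets, Mapping):
        de_sets = {"de": de_sets}
    universe = set(universe)
    N = len(universe)

    cat_genes: dict[str, set] = {}
    for cid, genes in category_map.items():
        genes = set(genes)
        outside = genes - universe
        if outside:
            logger.warning(
                "category %s: %d genes outside the universe dropped", cid, len(outside)
            )
        kept = genes & universe
        if kept:
            cat_genes[cid] = kept

    frames = []
    for set_name, genes in de_sets.items():
        de = set(genes)
        if not de <= universe:
            raise ValueError(
                f"gene set {set_name!r} contains genes outside the universe"
            )
        n = len(de)
        rows = []
        for cid, cg in cat_genes.items():
            K = len(cg)
            hit = de & cg
            k = len(hit)
            n_down = (
                sum(1 for g in hit if directions.get(g) == "down")
                if directions
                else None
            )
            rows.append(
                {
                    "gene_set": set_name,
                    "category_id": cid,
                    "category_label": (category_labels or {}).get(cid, ""),
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "de_frequency": k / n if n else 0.0,
                    "genome_frequency": K / N if N else 0.0,
                    "p_raw": hypergeom_upper(k, K, n, N),
                    "n_down": n_down,
                }
            )
        frame = pd.DataFrame(rows)
        if len(frame):
            frame["p_adj"] = bh_adjust(frame["p_raw"].to_numpy())
        else:
            frame["p_adj"] = pd.Series(dtype=float)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    cols = [
        "gene_set", "category_id", "category_label", "k", "K", "n", "N",
        "de_frequency", "genome_frequency", "p_raw", "p_adj", "n_down",
    ]
    return out[cols] if len(out) else out


def read_category_map(
    path: str | os.PathLike,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a category map TSV (category_id, gene_id[, label])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"category_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: category map needs category_id and gene_id")
    cmap: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        cmap.setdefault(row["category_id"], set()).add(row["gene_id"])
        if "label" in df.columns and pd.notna(row.get("label")):
            labels[row["category_id"]] = row["label"]
    return cmap, labels


def write_category_map(
    category_map: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    labels: Optional[Mapping[str, str]] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("category_id\tgene_id\tlabel\n")
        for cid in sorted(category_map):
            for g in sorted(category_map[cid]):
                fh.write(f"{cid}\t{g}\t{(labels or {}).get(cid, '')}\n")
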