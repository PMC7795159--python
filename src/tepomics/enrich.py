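"""Gene-set enrichment and cross-layer term integration.

Gene, intron and protein layers are analyzed by preranked GSEA: features
are ranked by ``-log10(p) * sign(log2FC)`` and a weighted Kolmogorov-
Smirnov-style enrichment score (weight exponent w = 1) is compared against
a gene-label permutation null.  The miRNA layer uses over-representation
(hypergeometric) instead — miRNAs have no natural ranked universe here —
and its significant results enter the integration with a fixed
NES of 1.5 times the direction sign.  Terms significant in every provided
layer form the cross-layer overlap, each annotated with its per-layer
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tepomics.enrich")

P_FLOOR = 1e-300
ORA_NES = 1.5  # fixed NES magnitude assigned to ORA-derived results


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset
    collection: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    layer: str
    es: float
    nes: float
    p_value: float
    significant: bool
    direction: int  # sign of NES


def rank_stat(p_value: float, log2fc: float) -> float:
    """Ranking statistic ``-log10(p) * sign(FC)`` with a 1e-300 p floor."""
    p = max(float(p_value), P_FLOOR)
    sign = 0.0 if log2fc == 0 else (1.0 if log2fc > 0 else -1.0)
    return float(-np.log10(p) * sign)


def rank_table(de_table: pd.DataFrame) -> pd.Series:
    """Ranked statistic per feature from a DE table, descending order."""
    stats_ = de_table.apply(lambda row: rank_stat(row["p_value"], row["log2fc"]), axis=1)
    out = pd.Series(stats_.to_numpy(), index=de_table["feature"].to_numpy())
    return out.sort_values(ascending=False, kind="mergesort")


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_core(stats_sorted: np.ndarray, member_pos: np.ndarray, w: float) -> float:
    """Signed ES for member positions within a descending-sorted stat vector.

    The running sum rises by the member's normalized |stat|^w and falls by
    1/(N - n_set) per non-member; only values at member positions (just
    after the rise, and just before the next rise) can be extremes, so the
    scan is O(n_set) given the positions.
    """
    n = stats_sorted.size
    k = member_pos.size
    if k == 0 or k >= n:
        raise ValueError("gene set must be a non-empty proper subset of the ranked universe")
    pos = np.sort(member_pos)
    wts = np.abs(stats_sorted[pos]) ** w
    total = wts.sum()
    if total == 0:
        wts = np.full(k, 1.0 / k)
    else:
        wts = wts / total
    dec = 1.0 / (n - k)
    cum_w = np.cumsum(wts)
    j = np.arange(k)
    drop_before = (pos - j) * dec          # non-members passed before member j
    upper = cum_w - drop_before            # value just after member j's rise
    lower = np.concatenate(([0.0], cum_w[:-1])) - drop_before  # just before
    hi = upper.max()
    lo = lower.min()
    return float(hi if hi >= -lo else lo)


def gsea_es(ranked: pd.Series, gene_set: GeneSet, w: float = 1.0) -> float:
    """Enrichment score of a set against a ranked (feature -> stat) series.

    ``ranked`` must be sorted in descending statistic order.  Raises if the
    set is disjoint from, or covers, the whole universe.
    """
    idx = ranked.index
    member_mask = idx.isin(gene_set.members)
    k = int(member_mask.sum())
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} disjoint from the ranked universe")
    if k == len(idx):
        raise ValueError(f"gene set {gene_set.name!r} equals the ranked universe")
    return _es_core(ranked.to_numpy(dtype=float), np.flatnonzero(member_mask), w)


def gsea_preranked(
    ranked: pd.Series,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    w: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation GSEA over a collection of sets.

    The null redraws each set's positions uniformly from the ranked universe
    (gene-label permutation preserving set size).  For observed ES of sign s,
    ``p = (1 + #{|ES_perm| >= |ES|, sign s}) / (1 + #{perms of sign s})`` and
    ``NES = ES / mean(|ES_perm| of sign s)``.  Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    stats_arr = ranked.to_numpy(dtype=float)
    n = stats_arr.size
    rows = []
    for gs in gene_sets:
        es = gsea_es(ranked, gs, w)
        k = int(ranked.index.isin(gs.members).sum())
        null = np.empty(n_perm)
        for b in range(n_perm):
            pos = rng.choice(n, size=k, replace=False)
            null[b] = _es_core(stats_arr, pos, w)
        same = null > 0 if es > 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            p, nes = 1.0, np.nan
        else:
            p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / np.abs(null[same]).mean()
        rows.append(
            {
                "set_name": gs.name, "es": es, "nes": nes, "p_value": p,
                "significant": p < alpha, "direction": 1 if es > 0 else -1,
                "n_members": k,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# over-representation (miRNA layer)
# ---------------------------------------------------------------------------

def ora_hypergeom(hits: set, universe: set, gene_set: GeneSet) -> float:
    """Upper-tail hypergeometric p for the overlap of hits with a set."""
    hits = set(hits)
    universe = set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    members = gene_set.members & universe
    if not members:
        raise ValueError(f"gene set {gene_set.name!r} disjoint from the universe")
    overlap = len(hits & members)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(hits)))


def mirna_ora(
    hits: set,
    universe: set,
    gene_sets: list[GeneSet],
    directions: dict[str, int] | None = None,
    alpha: float = 0.05,
    layer: str = "mirna",
) -> pd.DataFrame:
    """ORA over miRNA sets; significant terms get NES = +/-1.5.

    ``directions`` maps set name to +1/-1 (e.g. the sign of the mean log2FC
    of the hit miRNAs in the set); default +1.  The fixed 1.5 magnitude is
    the convention for injecting rank-free ORA results into an
    NES-based integration.
    """
    rows = []
    for gs in gene_sets:
        try:
            p = ora_hypergeom(hits, universe, gs)
        except ValueError:
            logger.warning("set %s disjoint from the miRNA universe; skipped", gs.name)
            continue
        d = (directions or {}).get(gs.name, 1)
        sig = p < alpha
        rows.append(
            {
                "set_name": gs.name, "layer": layer, "es": np.nan,
                "nes": ORA_NES * d if sig else np.nan,
                "p_value": p, "significant": sig, "direction": d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def cross_layer_overlap(
    results_by_layer: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Terms significant in every provided layer, with per-layer direction.

    Expects per-layer frames with ``set_name``, ``p_value`` (optionally
    ``padj``), ``nes`` and ``direction`` columns; at least two layers.
    """
    if len(results_by_layer) < 2:
        raise ValueError("need results from at least two layers")
    col = "padj" if use_adjusted else "p_value"
    sig_sets = []
    for layer, df in results_by_layer.items():
        sig_sets.append(set(df.loc[df[col] < alpha, "set_name"]))
    common = set.intersection(*sig_sets)
    rows = []
    for term in sorted(common):
        for layer, df in results_by_layer.items():
            row = df[df["set_name"] == term].iloc[0]
            rows.append(
                {
                    "term": term, "layer": layer,
                    "nes": float(row["nes"]) if pd.notna(row["nes"]) else np.nan,
                    "direction": int(row["direction"]),
                    "p_value": float(row[col]),
                }
            )
    return pd.DataFrame(rows, columns=["term", "layer", "nes", "direction", "p_value"])
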