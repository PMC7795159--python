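"""Sign-constrained "expected correlation" multi-omics networks.

For each patient group, miRNA-layer features (canonical miRNAs or isomiRs)
are linked to gene-layer features (mRNAs or intron-spanning reads) by
*negative* sample-wise correlations, and gene-layer features to proteins by
*positive* correlations — the sign pattern expected from miRNA repression
and from translation.  Edges additionally require p < alpha (0.05 default).
Two groups x two miRNA layers x two gene layers gives eight networks; the
transcripts present in all four same-group networks form that group's
cross-network core, and node degree identifies hubs (the SPARC-style
analysis).

Candidate features default to the differentially expressed set of each
layer; a config switch admits all filtered features instead (used e.g. for
null-calibration runs where nothing is differentially expressed).
IsomiR nodes can be collapsed to their parent miRNA for display while edges
stay per-isomiR, so parallel connections between one miRNA and one gene
represent distinct isomiR classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("tepomics.xnet")

MIRNA_LAYERS = ("canonical", "isomir")
GENE_LAYERS = ("mrna", "intron")

NODE_MIRNA = "mirna"
NODE_TRANSCRIPT = "transcript"
NODE_PROTEIN = "protein"


@dataclass(frozen=True)
class Edge:
    source: str
    source_type: str
    target: str
    target_type: str
    r: float
    p: float
    relation: str  # mirna_gene | gene_protein


@dataclass
class OmicsNetwork:
    """One (group, miRNA layer, gene layer) expected-correlation network."""

    group: str
    mirna_layer: str
    gene_layer: str
    edges: list[Edge] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.group}_{self.mirna_layer}_{self.gene_layer}"

    def nodes_of_type(self, node_type: str) -> set[str]:
        out = set()
        for e in self.edges:
            if e.source_type == node_type:
                out.add(e.source)
            if e.target_type == node_type:
                out.add(e.target)
        return out

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(group=self.group, mirna_layer=self.mirna_layer, gene_layer=self.gene_layer)
        for e in self.edges:
            g.add_node(e.source, node_type=e.source_type)
            g.add_node(e.target, node_type=e.target_type)
            g.add_edge(e.source, e.target, r=e.r, p=e.p, relation=e.relation)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": e.source, "source_type": e.source_type,
                    "target": e.target, "target_type": e.target_type,
                    "r": e.r, "p": e.p, "relation": e.relation,
                    "network": self.label,
                }
                for e in self.edges
            ],
            columns=["source", "source_type", "target", "target_type", "r", "p", "relation", "network"],
        )


def correlate_pair(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    """Correlation and two-sided p-value for one pair of per-sample vectors.

    Pearson by default (the cor.test default); the p-value comes from
    ``t = r sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def _corr_matrix(a: np.ndarray, b: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs correlations between rows of a and rows of b (same columns)."""
    n = a.shape[1]
    if method == "spearman":
        a = np.apply_along_axis(stats.rankdata, 1, a)
        b = np.apply_along_axis(stats.rankdata, 1, b)
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az ** 2).sum(axis=1))
    bsd = np.sqrt((bz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t), np.where(np.abs(r) >= 1.0, 0.0, np.nan), p)
    return r, p


def _drop_constant(mat: pd.DataFrame, what: str) -> pd.DataFrame:
    sd = mat.std(axis=1)
    const = sd[sd == 0].index
    if len(const):
        logger.warning("skipping %d zero-variance %s feature(s)", len(const), what)
    return mat.loc[sd > 0]


def build_expected_network(
    group: str,
    mirna_layer: str,
    gene_layer: str,
    mirna_matrix: pd.DataFrame,
    gene_matrix: pd.DataFrame,
    protein_matrix: pd.DataFrame,
    de_sets: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    method: str = "pearson",
) -> OmicsNetwork:
    """Build one expected-correlation network.

    Matrices are normalized expression (features x samples) already
    restricted to one group's samples; the protein matrix may cover a sample
    subset and gene-protein correlations use only samples present in both
    layers.  ``de_sets`` (keys ``mirna``, ``gene``, ``protein``) restricts
    candidate features; None uses every row.  Edge rules: miRNA->gene
    requires r < 0, gene->protein r > 0, both at p < alpha; isolated nodes
    are dropped (only nodes with an edge appear).
    """
    if mirna_layer not in MIRNA_LAYERS or gene_layer not in GENE_LAYERS:
        raise ValueError(f"unknown layer combination ({mirna_layer}, {gene_layer})")
    shared_mg = [s for s in mirna_matrix.columns if s in set(gene_matrix.columns)]
    if len(shared_mg) < 4:
        raise ValueError("fewer than 4 shared samples between miRNA and gene layers")
    shared_gp = [s for s in gene_matrix.columns if s in set(protein_matrix.columns)]
    if len(shared_gp) < 4:
        raise ValueError("fewer than 4 shared samples between gene and protein layers")

    def restrict(mat: pd.DataFrame, key: str) -> pd.DataFrame:
        if de_sets is None or de_sets.get(key) is None:
            return mat
        keep = [f for f in mat.index if f in set(de_sets[key])]
        return mat.loc[keep]

    mm = _drop_constant(restrict(mirna_matrix[shared_mg], "mirna"), "miRNA")
    gm_full = restrict(gene_matrix, "gene")
    pm_full = restrict(protein_matrix, "protein")

    edges: list[Edge] = []
    gm = _drop_constant(gm_full[shared_mg], "gene")
    if len(mm) and len(gm):
        r, p = _corr_matrix(mm.to_numpy(float), gm.to_numpy(float), method)
        ii, jj = np.where((r < 0) & (p < alpha))
        for i, j in zip(ii, jj):
            edges.append(
                Edge(str(mm.index[i]), NODE_MIRNA, str(gm.index[j]), NODE_TRANSCRIPT,
                     float(r[i, j]), float(p[i, j]), "mirna_gene")
            )
    gm2 = _drop_constant(gm_full[shared_gp], "gene")
    pm = _drop_constant(pm_full[shared_gp], "protein")
    if len(gm2) and len(pm):
        r, p = _corr_matrix(gm2.to_numpy(float), pm.to_numpy(float), method)
        ii, jj = np.where((r > 0) & (p < alpha))
        for i, j in zip(ii, jj):
            edges.append(
                Edge(str(gm2.index[i]), NODE_TRANSCRIPT, str(pm.index[j]), NODE_PROTEIN,
                     float(r[i, j]), float(p[i, j]), "gene_protein")
            )
    return OmicsNetwork(group=group, mirna_layer=mirna_layer, gene_layer=gene_layer, edges=edges)


def build_all_networks(
    matrices_by_group: dict[str, dict[str, pd.DataFrame]],
    de_sets_by_layer: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    method: str = "pearson",
) -> list[OmicsNetwork]:
    """All eight networks: groups x {canonical, isomir} x {mrna, intron}.

    ``matrices_by_group[group]`` maps layer name (``mirna``, ``isomir``,
    ``mrna``, ``intron``, ``protein``) to that group's normalized matrix.
    ``de_sets_by_layer`` uses the same layer keys.
    """
    nets = []
    for group in ("A", "B"):
        mats = matrices_by_group[group]
        for mlayer, glayer in itertools.product(MIRNA_LAYERS, GENE_LAYERS):
            src = "mirna" if mlayer == "canonical" else "isomir"
            de = None
            if de_sets_by_layer is not None:
                de = {
                    "mirna": de_sets_by_layer.get(src),
                    "gene": de_sets_by_layer.get(glayer),
                    "protein": de_sets_by_layer.get("protein"),
                }
            nets.append(
                build_expected_network(
                    group, mlayer, glayer,
                    mats[src], mats[glayer], mats["protein"],
                    de_sets=de, alpha=alpha, method=method,
                )
            )
    return nets


def node_degrees(net: OmicsNetwork) -> list[tuple[str, str, int]]:
    """(node, node_type, degree) sorted by descending degree, ties by id."""
    deg: dict[tuple[str, str], int] = {}
    for e in net.edges:
        deg[(e.source, e.source_type)] = deg.get((e.source, e.source_type), 0) + 1
        deg[(e.target, e.target_type)] = deg.get((e.target, e.target_type), 0) + 1
    return sorted(
        [(n, t, d) for (n, t), d in deg.items()],
        key=lambda x: (-x[2], x[0]),
    )


def top_transcript(net: OmicsNetwork) -> str | None:
    """Highest-degree transcript node; None for an empty network.

    Equal degrees are broken by total incident correlation strength
    (sum of |r|) — a genuine hub carries stronger edges than a node that
    reaches the same degree through marginal correlations — then by id.
    """
    deg: dict[str, float] = {}
    strength: dict[str, float] = {}
    for e in net.edges:
        for node, typ in ((e.source, e.source_type), (e.target, e.target_type)):
            if typ == NODE_TRANSCRIPT:
                deg[node] = deg.get(node, 0) + 1
                strength[node] = strength.get(node, 0.0) + abs(e.r)
    if not deg:
        return None
    return min(deg, key=lambda t: (-deg[t], -strength[t], t))


def top_transcript_pooled(networks: list[OmicsNetwork]) -> str | None:
    """Top transcript by degree pooled over several networks.

    Used for the hub question in the isomiR networks of one group: the
    hub's regulators connect to it through both gene layers, so pooling
    degree over the two isomiR networks asks which transcript is the most
    connected overall.  Ties resolve by total |r| then id, as in
    :func:`top_transcript`.
    """
    deg: dict[str, float] = {}
    strength: dict[str, float] = {}
    for net in networks:
        for e in net.edges:
            for node, typ in ((e.source, e.source_type), (e.target, e.target_type)):
                if typ == NODE_TRANSCRIPT:
                    deg[node] = deg.get(node, 0) + 1
                    strength[node] = strength.get(node, 0.0) + abs(e.r)
    if not deg:
        return None
    return min(deg, key=lambda t: (-deg[t], -strength[t], t))


def cross_network_core(networks: list[OmicsNetwork]) -> set[str]:
    """Transcripts present in all four same-group networks."""
    if len(networks) != 4:
        raise ValueError("expected exactly four networks")
    groups = {n.group for n in networks}
    if len(groups) != 1:
        raise ValueError("networks must belong to one group")
    combos = {(n.mirna_layer, n.gene_layer) for n in networks}
    if len(combos) != 4:
        raise ValueError("expected all four miRNA x gene layer combinations")
    sets = [n.nodes_of_type(NODE_TRANSCRIPT) for n in networks]
    return set.intersection(*sets)
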