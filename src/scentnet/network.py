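"""Volatile-transcript correlation-network inference.

Profiles are condition means (replicates averaged first): volatile contents
in ug/g and gene expression in FPKM over the shared genotype x stage
conditions (nine when three genotypes and three stages overlap). For each
node pair the Pearson correlation r is computed across conditions, with the
two-sided p-value from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.

Mutual rank: rank_a(b) is the 1-based position of b when a's candidate
partners are sorted by |r| descending (average ranks on ties), and
MR(a,b) = sqrt(rank_a(b) * rank_b(a)), symmetric and >= 1. By default every
node is ranked among all other nodes (genes and volatiles alike); the
bipartite option ranks each node only among the opposite class.

An edge passes when |r| >= pcc_min (0.7), p <= p_max (0.05) and
MR <= mr_max (10), all inclusive. Only volatile-gene and volatile-volatile
pairs become edges; gene-gene pairs take part in the ranking universe only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .registry_io import SampleKey

PCC_MIN = 0.7
P_MAX = 0.05
MR_MAX = 10.0


@dataclass
class ProfileMatrix:
    """Condition-mean profiles for one node class (``volatile`` or ``gene``)."""

    values: pd.DataFrame
    node_class: str

    def __post_init__(self) -> None:
        if self.node_class not in ("volatile", "gene"):
            raise ValueError(f"unknown node class {self.node_class!r}")
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            raise ValueError("duplicate node ids in profile matrix")


def condition_means(samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns (GENOTYPE_STAGE[_ORGAN]_REP) per condition."""
    conds = [SampleKey.parse(c).condition for c in samples.columns]
    out = samples.T.groupby(pd.Index(conds, name="condition")).mean().T
    return out[sorted(set(conds))]


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p over paired finite values.

    Constant input returns (nan, nan) — the undefined-correlation marker,
    excluded from ranking. Fewer than 3 paired finite values is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired finite values, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return (float("nan"), float("nan"))
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    return r, _pvalue_from_r(np.array([r]), n)[0]


def _pvalue_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform of r with n-2 df (vectorized)."""
    r = np.asarray(r, dtype=float)
    p = np.full(r.shape, np.nan)
    ok = np.isfinite(r)
    rr = np.clip(r[ok], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(rr) * np.sqrt(n - 2) / np.sqrt(1.0 - rr * rr)
    p[ok] = 2.0 * stats.t.sf(t, df=n - 2)
    p[ok] = np.minimum(p[ok], 1.0)
    return p


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Pearson correlations across columns (nodes in rows).

    Constant rows yield NaN against every partner.
    """
    values = profiles.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(values)
    c = np.clip(c, -1.0, 1.0)
    sd = values.std(axis=1)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return pd.DataFrame(c, index=profiles.index, columns=profiles.index)


def rank_matrix(c: pd.DataFrame, universe_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-row 1-based partner ranks by |r| descending, average ranks on ties.

    Self pairs, undefined correlations, and entries outside ``universe_mask``
    rank behind every real candidate (they tie for the worst ranks, which
    keeps genuine partner ranks correct and 1-based).
    """
    a = np.abs(c.to_numpy(dtype=float))
    np.fill_diagonal(a, -np.inf)
    a[~np.isfinite(a)] = -np.inf
    if universe_mask is not None:
        a = np.where(universe_mask, a, -np.inf)
    neg = -a  # rank descending: rankdata ascends, so negate
    # fast ordinal ranks by double argsort; exact tie-averaging applied only
    # to rows that actually contain ties
    order = np.argsort(neg, axis=1, kind="stable")
    ranks = np.empty(neg.shape, dtype=float)
    rows = np.arange(neg.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, neg.shape[1] + 1, dtype=float)[None, :]
    srt = np.take_along_axis(neg, order, axis=1)
    tied_rows = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
    for i in tied_rows:
        ranks[i] = stats.rankdata(neg[i], method="average")
    return ranks


def mutual_rank_matrix(c: pd.DataFrame, universe_mask: np.ndarray | None = None) -> pd.DataFrame:
    """MR(a,b) = sqrt(rank_a(b) * rank_b(a)); NaN where the PCC is undefined."""
    ranks = rank_matrix(c, universe_mask)
    mr = np.sqrt(ranks * ranks.T)
    undef = ~np.isfinite(c.to_numpy(dtype=float))
    if universe_mask is not None:
        undef |= ~universe_mask
    mr[undef] = np.nan
    np.fill_diagonal(mr, np.nan)
    return pd.DataFrame(mr, index=c.index, columns=c.columns)


def mutual_rank(c: pd.DataFrame, a: str, b: str) -> float:
    """Mutual rank of one node pair from an all-pairs PCC matrix."""
    return float(mutual_rank_matrix(c).at[a, b])


@dataclass
class EdgeSet:
    """Undirected volatile-gene / volatile-volatile edges with filter flags.

    ``edges`` columns: node_a, node_b (canonical node_a < node_b), class_a,
    class_b, pcc, pvalue, mutual_rank, sign, passes.
    """

    edges: pd.DataFrame
    n_conditions: int
    thresholds: dict = field(default_factory=dict)

    def passing(self) -> pd.DataFrame:
        return self.edges[self.edges["passes"]].reset_index(drop=True)


def build_network(
    volatiles: ProfileMatrix,
    genes: ProfileMatrix,
    guides: list[str] | tuple[str, ...] = (),
    pcc_min: float = PCC_MIN,
    p_max: float = P_MAX,
    mr_max: float = MR_MAX,
    bipartite: bool = False,
    full: bool = False,
) -> EdgeSet:
    """Correlate volatile and gene condition profiles and filter edges.

    Returns the passing edges incident to the guide volatiles; with
    ``full=True`` all passing volatile-gene / volatile-volatile edges are
    returned. With no guides and ``full=False`` the edge set is empty.
    """
    if volatiles.node_class != "volatile" or genes.node_class != "gene":
        raise ValueError("expected (volatile, gene) profile matrices")
    shared = [c for c in volatiles.values.columns if c in set(genes.values.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared conditions, got {len(shared)}")
    missing_guides = [g for g in guides if g not in volatiles.values.index]
    if missing_guides:
        raise KeyError(f"guide code(s) not in volatile profiles: {missing_guides}")

    stacked = pd.concat([volatiles.values[shared], genes.values[shared]])
    if stacked.index.duplicated().any():
        raise ValueError("volatile and gene node ids overlap")
    is_volatile = np.r_[
        np.ones(len(volatiles.values), dtype=bool),
        np.zeros(len(genes.values), dtype=bool),
    ]
    n = len(shared)

    c = correlation_matrix(stacked)
    universe = None
    if bipartite:
        universe = is_volatile[:, None] != is_volatile[None, :]
    mr = mutual_rank_matrix(c, universe)

    cm = c.to_numpy()
    mrm = mr.to_numpy()

    # candidate pairs: at least one volatile, upper triangle
    iu, ju = np.triu_indices(len(stacked), k=1)
    cand = is_volatile[iu] | is_volatile[ju]
    if bipartite:
        cand &= is_volatile[iu] != is_volatile[ju]
    iu, ju = iu[cand], ju[cand]

    ids = stacked.index.to_numpy()
    pcc = cm[iu, ju]
    pval = _pvalue_from_r(pcc, n)
    mrv = mrm[iu, ju]
    defined = np.isfinite(pcc)
    passes = (
        defined
        & (np.abs(pcc) >= pcc_min)
        & (pval <= p_max)
        & np.isfinite(mrv)
        & (mrv <= mr_max)
    )

    a_ids, b_ids = ids[iu], ids[ju]
    swap = a_ids > b_ids
    a_ids, b_ids = np.where(swap, b_ids, a_ids), np.where(swap, a_ids, b_ids)
    cls = np.where(is_volatile, "volatile", "gene")
    a_cls, b_cls = cls[iu], cls[ju]
    a_cls, b_cls = np.where(swap, b_cls, a_cls), np.where(swap, a_cls, b_cls)

    edges = pd.DataFrame(
        {
            "node_a": a_ids,
            "node_b": b_ids,
            "class_a": a_cls,
            "class_b": b_cls,
            "pcc": pcc,
            "pvalue": pval,
            "mutual_rank": mrv,
            "sign": np.where(pcc >= 0, "positive", "negative"),
            "passes": passes,
        }
    )
    edges = edges[defined]

    guide_set = set(guides)
    keep = edges["passes"] & (
        np.ones(len(edges), dtype=bool)
        if full
        else (edges["node_a"].isin(guide_set) | edges["node_b"].isin(guide_set))
    )
    result = edges[keep].sort_values(["node_a", "node_b"]).reset_index(drop=True)
    return EdgeSet(
        edges=result,
        n_conditions=n,
        thresholds={"pcc_min": pcc_min, "p_max": p_max, "mr_max": mr_max,
                    "bipartite": bipartite},
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def _as_graph(edges: EdgeSet) -> nx.Graph:
    g = nx.Graph()
    df = edges.edges.sort_values(["node_a", "node_b"])
    for _, row in df.iterrows():
        for node, cls in ((row["node_a"], row["class_a"]), (row["node_b"], row["class_b"])):
            if node not in g:
                g.add_node(node, node_class=cls)
        g.add_edge(
            row["node_a"],
            row["node_b"],
            pcc=float(row["pcc"]),
            pvalue=float(row["pvalue"]),
            mutual_rank=float(row["mutual_rank"]),
            sign=str(row["sign"]),
        )
    return g


def export_network(edges: EdgeSet, path, fmt: str = "tsv") -> None:
    """Write an edge set as ``tsv``, ``sif`` (node_a pcc_edge node_b), or GraphML."""
    df = edges.edges.sort_values(["node_a", "node_b"])
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in df.iterrows():
                fh.write(f"{row['node_a']}\tpcc_edge\t{row['node_b']}\n")
    elif fmt == "graphml":
        nx.write_graphml(_as_graph(edges), path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use tsv, sif or graphml")


def read_network_graphml(path) -> pd.DataFrame:
    """Read back a GraphML export as a canonical edge table."""
    g = nx.read_graphml(path)
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((u, v))
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                "class_a": g.nodes[a].get("node_class"),
                "class_b": g.nodes[b].get("node_class"),
                "pcc": float(data["pcc"]),
                "pvalue": float(data["pvalue"]),
                "mutual_rank": float(data["mutual_rank"]),
                "sign": data["sign"],
            }
        )
    cols = ["node_a", "node_b", "class_a", "class_b", "pcc", "pvalue", "mutual_rank", "sign"]
    return pd.DataFrame(rows, columns=cols).sort_values(["node_a", "node_b"]).reset_index(drop=True)
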