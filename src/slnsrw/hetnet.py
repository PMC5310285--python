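"""Heterogeneous biomedical network: data model, edge-list I/O, initial weights.

The network integrates entities of several kinds — genes, diseases and
ontology terms — joined by undirected, typed edges.  Each edge carries

* an **edge type index** in ``[0, K)``.  For networks read from an edge
  list the type is determined by the unordered pair of endpoint node
  types (a gene–gene interaction and an HPO-term–gene annotation are
  different types), enumerated in sorted order.  Synthetic networks may
  label edge types arbitrarily.
* a scalar **initial weight** ``t0`` in ``[0, 1]``, taken either from a
  source confidence score or from annotation evidence codes (the maximum
  weight over an edge's codes, so an experimentally verified relation
  dominates a computational prediction on the same pair).

The one-hot **edge feature vector** ``t(u, v)`` — zero everywhere except
``t0`` at the edge's type index — is the input to the learnable edge
strength model (see :mod:`slnsrw.edge_model`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODE_TYPES = ("disease", "do_term", "gene", "go_term", "hpo_term")

EDGE_LIST_COLUMNS = (
    "source_id",
    "source_type",
    "target_id",
    "target_type",
    "evidence",
    "confidence",
)


class NetworkError(ValueError):
    """Raised on malformed or inconsistent network input."""


def edge_type_name(type_a: str, type_b: str) -> str:
    """Canonical name of the edge type joining two node types."""
    a, b = sorted((type_a, type_b))
    return f"{a}-{b}"


@dataclass
class HeteroNetwork:
    """Undirected heterogeneous network with typed nodes and typed edges.

    Nodes are stored as parallel lists of opaque string ids and node
    types; edges as parallel arrays of endpoint indices, type indices,
    initial weights ``t0`` and (possibly empty) evidence-code lists.
    Self-loops and parallel edges are rejected.
    """

    node_ids: list[str]
    node_types: list[str]
    edge_u: np.ndarray
    edge_v: np.ndarray
    edge_type: np.ndarray
    t0: np.ndarray
    evidence: list[list[str]]
    edge_type_names: list[str]
    confidence: np.ndarray | None = None  # NaN where the source had none

    _node_index: dict[str, int] = field(init=False, repr=False)
    _edge_index: dict[tuple[int, int], int] = field(init=False, repr=False)
    _adjacency: list[np.ndarray] | None = field(
        init=False, repr=False, default=None
    )

    def __post_init__(self) -> None:
        self.edge_u = np.asarray(self.edge_u, dtype=np.intp)
        self.edge_v = np.asarray(self.edge_v, dtype=np.intp)
        self.edge_type = np.asarray(self.edge_type, dtype=np.intp)
        self.t0 = np.asarray(self.t0, dtype=float)
        if self.confidence is None:
            self.confidence = np.full(self.n_edges, np.nan)
        self._node_index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(self._node_index) != len(self.node_ids):
            raise NetworkError("duplicate node ids")
        self._edge_index = {}
        for e in range(self.n_edges):
            key = self._edge_key(self.edge_u[e], self.edge_v[e])
            if key in self._edge_index:
                raise NetworkError(f"parallel edge for node pair {key}")
            self._edge_index[key] = e
        self.validate()

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_u)

    @property
    def K(self) -> int:
        """Number of edge types."""
        return len(self.edge_type_names)

    @staticmethod
    def _edge_key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    def node_index(self, node_id: str) -> int:
        try:
            return self._node_index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def has_edge(self, u: str | int, v: str | int) -> bool:
        ui = u if isinstance(u, (int, np.integer)) else self.node_index(u)
        vi = v if isinstance(v, (int, np.integer)) else self.node_index(v)
        return self._edge_key(ui, vi) in self._edge_index

    def edge_id(self, u: str | int, v: str | int) -> int:
        """Index of the undirected edge (u, v); KeyError if absent."""
        ui = u if isinstance(u, (int, np.integer)) else self.node_index(u)
        vi = v if isinstance(v, (int, np.integer)) else self.node_index(v)
        try:
            return self._edge_index[self._edge_key(ui, vi)]
        except KeyError:
            raise KeyError(f"no edge between {u!r} and {v!r}") from None

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.intp)
        np.add.at(deg, self.edge_u, 1)
        np.add.at(deg, self.edge_v, 1)
        return deg

    def neighbors(self, node: str | int) -> np.ndarray:
        """Sorted array of neighbor node indices."""
        ni = node if isinstance(node, (int, np.integer)) else self.node_index(node)
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for u, v in zip(self.edge_u, self.edge_v):
                adj[u].append(v)
                adj[v].append(u)
            self._adjacency = [np.array(sorted(a), dtype=np.intp) for a in adj]
        return self._adjacency[ni]

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both orientations of every edge: (tail, head, undirected edge id)."""
        tails = np.concatenate([self.edge_u, self.edge_v])
        heads = np.concatenate([self.edge_v, self.edge_u])
        eids = np.concatenate([np.arange(self.n_edges)] * 2)
        return tails, heads, eids

    def edge_feature(self, u: str | int, v: str | int) -> np.ndarray:
        """One-hot feature vector t(u, v): t0 at the edge's type index.

        Symmetric in (u, v) because the edge is undirected.
        """
        e = self.edge_id(u, v)
        t = np.zeros(self.K)
        t[self.edge_type[e]] = self.t0[e]
        return t

    def edge_features(self) -> np.ndarray:
        """Dense |E| x K matrix of one-hot edge features."""
        T = np.zeros((self.n_edges, self.K))
        T[np.arange(self.n_edges), self.edge_type] = self.t0
        return T

    # -- validation ------------------------------------------------------

    def validate(self, check_t0: bool = False) -> None:
        if len(self.node_types) != len(self.node_ids):
            raise NetworkError("node_ids and node_types length mismatch")
        for t in self.node_types:
            if t not in NODE_TYPES:
                raise NetworkError(f"unknown node type {t!r}")
        if not (
            len(self.edge_v)
            == len(self.edge_type)
            == len(self.t0)
            == len(self.evidence)
            == len(self.edge_u)
        ):
            raise NetworkError("edge array length mismatch")
        if np.any(self.edge_u == self.edge_v):
            raise NetworkError("self-loop present")
        if self.n_edges and (
            self.edge_type.min() < 0 or self.edge_type.max() >= self.K
        ):
            raise NetworkError("edge type index out of range")
        if check_t0 and self.n_edges:
            if np.any(~np.isfinite(self.t0)) or np.any(
                (self.t0 < 0) | (self.t0 > 1)
            ):
                raise NetworkError("t0 outside [0, 1]")

    def copy(self) -> "HeteroNetwork":
        return HeteroNetwork(
            node_ids=list(self.node_ids),
            node_types=list(self.node_types),
            edge_u=self.edge_u.copy(),
            edge_v=self.edge_v.copy(),
            edge_type=self.edge_type.copy(),
            t0=self.t0.copy(),
            evidence=[list(ev) for ev in self.evidence],
            edge_type_names=list(self.edge_type_names),
            confidence=None if self.confidence is None else self.confidence.copy(),
        )

    def without_edges(self, pairs: set[tuple[int, int]]) -> "HeteroNetwork":
        """Copy of the network with the given unordered node-index pairs removed."""
        keys = {self._edge_key(u, v) for u, v in pairs}
        keep = np.array(
            [
                self._edge_key(self.edge_u[e], self.edge_v[e]) not in keys
                for e in range(self.n_edges)
            ],
            dtype=bool,
        )
        return HeteroNetwork(
            node_ids=list(self.node_ids),
            node_types=list(self.node_types),
            edge_u=self.edge_u[keep],
            edge_v=self.edge_v[keep],
            edge_type=self.edge_type[keep],
            t0=self.t0[keep],
            evidence=[ev for ev, k in zip(self.evidence, keep) if k],
            edge_type_names=list(self.edge_type_names),
            confidence=self.confidence[keep] if self.confidence is not None else None,
        )


# -- edge-list I/O -------------------------------------------------------


def read_edge_list(path) -> HeteroNetwork:
    """Read a TSV edge list into a validated :class:`HeteroNetwork`.

    Expected header columns: ``source_id  source_type  target_id
    target_type  evidence  confidence`` (the last two optional; evidence
    codes are semicolon-separated).  Duplicate rows for the same node
    pair are merged: evidence codes are unioned and confidences maxed.
    Edge types are enumerated from the observed unordered node-type
    pairs in sorted order; an optional ``edge_type`` column overrides
    the derived labels (used by synthetic networks, whose types are
    not functions of the endpoint node types).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_LIST_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise NetworkError(f"edge list missing columns: {missing}")
    has_type_col = "edge_type" in df.columns

    node_type_of: dict[str, str] = {}
    type_label: dict[tuple[str, str], str] = {}
    # merged[key] = [u_id, v_id, evidence_set, confidence]
    merged: dict[tuple[str, str], list] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        src, st = row.source_id.strip(), row.source_type.strip()
        tgt, tt = row.target_id.strip(), row.target_type.strip()
        if not src or not tgt:
            raise NetworkError(f"line {row_no}: empty node id")
        if src == tgt:
            raise NetworkError(f"line {row_no}: self-loop on {src!r}")
        for nid, ntype in ((src, st), (tgt, tt)):
            if ntype not in NODE_TYPES:
                raise NetworkError(
                    f"line {row_no}: unknown node type {ntype!r} for {nid!r}"
                )
            prev = node_type_of.setdefault(nid, ntype)
            if prev != ntype:
                raise NetworkError(
                    f"line {row_no}: node {nid!r} typed both {prev!r} and {ntype!r}"
                )
        codes = set()
        if "evidence" in df.columns and getattr(row, "evidence", "").strip():
            codes = {c.strip() for c in row.evidence.split(";") if c.strip()}
        conf = np.nan
        if "confidence" in df.columns and getattr(row, "confidence", "").strip():
            try:
                conf = float(row.confidence)
            except ValueError:
                raise NetworkError(
                    f"line {row_no}: malformed confidence {row.confidence!r}"
                ) from None
            if not 0.0 <= conf <= 1.0:
                raise NetworkError(f"line {row_no}: confidence outside [0, 1]")
        key = tuple(sorted((src, tgt)))
        if has_type_col and getattr(row, "edge_type", "").strip():
            label = row.edge_type.strip()
            prev = type_label.setdefault(key, label)
            if prev != label:
                raise NetworkError(
                    f"line {row_no}: edge {key} typed both {prev!r} and {label!r}"
                )
        if key in merged:
            entry = merged[key]
            entry[2] |= codes
            if not np.isnan(conf):
                entry[3] = conf if np.isnan(entry[3]) else max(entry[3], conf)
        else:
            merged[key] = [src, tgt, codes, conf]

    node_ids = sorted(node_type_of)
    node_types = [node_type_of[n] for n in node_ids]
    index = {n: i for i, n in enumerate(node_ids)}

    def label_of(key: tuple[str, str]) -> str:
        if key in type_label:
            return type_label[key]
        return edge_type_name(node_type_of[key[0]], node_type_of[key[1]])

    type_pairs = sorted({label_of(key) for key in merged})
    type_index = {name: k for k, name in enumerate(type_pairs)}

    keys = sorted(merged)
    eu, ev, etype, conf_arr, evidence = [], [], [], [], []
    for key in keys:
        src, tgt, codes, conf = merged[key]
        eu.append(index[src])
        ev.append(index[tgt])
        etype.append(type_index[label_of(key)])
        conf_arr.append(conf)
        evidence.append(sorted(codes))
    conf_arr = np.array(conf_arr, dtype=float) if keys else np.empty(0)
    t0 = np.where(np.isnan(conf_arr), 0.0, conf_arr)
    return HeteroNetwork(
        node_ids=node_ids,
        node_types=node_types,
        edge_u=np.array(eu, dtype=np.intp),
        edge_v=np.array(ev, dtype=np.intp),
        edge_type=np.array(etype, dtype=np.intp),
        t0=t0,
        evidence=evidence,
        edge_type_names=type_pairs,
        confidence=conf_arr,
    )


def write_edge_list(net: HeteroNetwork, path) -> None:
    """Write a network as a TSV edge list (current t0 in the confidence column)."""
    rows = []
    for e in range(net.n_edges):
        u, v = net.edge_u[e], net.edge_v[e]
        rows.append(
            {
                "source_id": net.node_ids[u],
                "source_type": net.node_types[u],
                "target_id": net.node_ids[v],
                "target_type": net.node_types[v],
                "evidence": ";".join(net.evidence[e]),
                "confidence": repr(float(net.t0[e])),
                "edge_type": net.edge_type_names[net.edge_type[e]],
            }
        )
    pd.DataFrame(rows, columns=[*EDGE_LIST_COLUMNS, "edge_type"]).to_csv(
        path, sep="\t", index=False
    )


# -- evidence weights ----------------------------------------------------


@dataclass(frozen=True)
class EvidenceWeightTable:
    """Mapping evidence code -> initial weight in [0, 1].

    Experimental codes carry high weight (EXP -> 1.0) and purely
    computational ones low weight (IEA -> 0.4); an edge annotated with
    several codes takes the maximum weight among them.
    """

    weights: dict[str, float]

    def __post_init__(self) -> None:
        for code, w in self.weights.items():
            if not 0.0 <= w <= 1.0:
                raise NetworkError(f"evidence weight for {code!r} outside [0, 1]")

    def __getitem__(self, code: str) -> float:
        return self.weights[code]

    def __contains__(self, code: str) -> bool:
        return code in self.weights


def read_evidence_table(path) -> EvidenceWeightTable:
    """Read a two-column TSV ``code  weight``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise NetworkError("evidence table needs two columns: code, weight")
    code_col, weight_col = df.columns[:2]
    return EvidenceWeightTable(
        {str(c): float(w) for c, w in zip(df[code_col], df[weight_col])}
    )


def assign_initial_weights(
    net: HeteroNetwork,
    table: EvidenceWeightTable,
    default: float | None = None,
) -> HeteroNetwork:
    """Set each edge's t0 from its confidence or its evidence codes.

    An edge keeps its source confidence when one was given; otherwise
    t0 is the maximal table weight over the edge's valid evidence codes.
    Edges with neither raise unless ``default`` is supplied.
    """
    out = net.copy()
    for e in range(out.n_edges):
        conf = out.confidence[e] if out.confidence is not None else np.nan
        if not np.isnan(conf):
            out.t0[e] = conf
            continue
        weights = [table[c] for c in out.evidence[e] if c in table]
        if weights:
            out.t0[e] = max(weights)
        elif default is not None:
            out.t0[e] = default
        else:
            u, v = out.node_ids[out.edge_u[e]], out.node_ids[out.edge_v[e]]
            raise NetworkError(
                f"edge ({u!r}, {v!r}) has no confidence and no known evidence code"
            )
    out.validate(check_t0=True)
    return out


# -- training instances --------------------------------------------------


@dataclass(frozen=True)
class TrainingInstance:
    """Ranking supervision for one disease: known genes vs sampled non-genes."""

    disease: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise NetworkError("positive and negative sets overlap")
        if self.disease in self.positives or self.disease in self.negatives:
            raise NetworkError("disease node inside its own gene sets")

    def check_against(self, net: HeteroNetwork) -> None:
        for nid in (self.disease, *self.positives, *self.negatives):
            net.node_index(nid)


def write_instances(instances: list[TrainingInstance], path) -> None:
    rows = []
    for inst in instances:
        for g in inst.positives:
            rows.append({"disease_id": inst.disease, "gene_id": g, "label": "pos"})
        for g in inst.negatives:
            rows.append({"disease_id": inst.disease, "gene_id": g, "label": "neg"})
    pd.DataFrame(rows, columns=["disease_id", "gene_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_instances(path) -> list[TrainingInstance]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for disease, grp in df.groupby("disease_id", sort=True):
        pos = tuple(grp.loc[grp["label"] == "pos", "gene_id"])
        neg = tuple(grp.loc[grp["label"] == "neg", "gene_id"])
        bad = set(grp["label"]) - {"pos", "neg"}
        if bad:
            raise NetworkError(f"unknown instance labels: {sorted(bad)}")
        out.append(TrainingInstance(disease, pos, neg))
    return out


# -- benchmark construction ----------------------------------------------


def build_benchmark_sets(
    net: HeteroNetwork,
    min_positives: int = 5,
    seed: int | None = None,
    disease_types: tuple[str, ...] = ("disease",),
) -> tuple[list[TrainingInstance], list[TrainingInstance], HeteroNetwork]:
    """Construct per-disease train/test instances and the pruned network.

    Every disease node with at least ``min_positives`` gene neighbors
    contributes an instance: its gene neighbors are the positives, and
    an equal number of genes *not* adjacent to it are sampled uniformly
    without replacement as negatives.  Positives and negatives are each
    split 50/50 at random into a training and a testing half.  The
    returned pruned network has all selected disease-gene positive edges
    removed, so evaluation cannot read the answer off a direct edge.
    """
    rng = np.random.default_rng(seed)
    gene_idx = np.array(
        [i for i, t in enumerate(net.node_types) if t == "gene"], dtype=np.intp
    )
    gene_set = set(gene_idx.tolist())
    train, test = [], []
    removed: set[tuple[int, int]] = set()
    for d in range(net.n_nodes):
        if net.node_types[d] not in disease_types:
            continue
        pos = [v for v in net.neighbors(d).tolist() if v in gene_set]
        if len(pos) < min_positives:
            continue
        candidates = sorted(gene_set - set(pos) - {d})
        if len(candidates) < len(pos):
            raise NetworkError(
                f"disease {net.node_ids[d]!r}: only {len(candidates)} "
                f"non-adjacent genes for {len(pos)} negatives"
            )
        neg = rng.choice(np.array(candidates), size=len(pos), replace=False).tolist()
        pos_perm = rng.permutation(pos).tolist()
        neg_perm = rng.permutation(neg).tolist()
        half_p = (len(pos_perm) + 1) // 2
        half_n = (len(neg_perm) + 1) // 2
        did = net.node_ids[d]
        as_ids = lambda idxs: tuple(net.node_ids[i] for i in idxs)
        train.append(
            TrainingInstance(did, as_ids(pos_perm[:half_p]), as_ids(neg_perm[:half_n]))
        )
        test.append(
            TrainingInstance(did, as_ids(pos_perm[half_p:]), as_ids(neg_perm[half_n:]))
        )
        removed.update((d, p) for p in pos)
    if not train:
        raise NetworkError(
            f"no disease node has >= {min_positives} gene neighbors"
        )
    pruned = net.without_edges(removed)
    return train, test, pruned
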