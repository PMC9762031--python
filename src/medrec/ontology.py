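"""Medical-code ontologies and knowledge-enhanced leaf embeddings.

Diagnosis (ICD-10-style) and drug (14-digit NDC-style) codes live at the
leaves of rooted classification trees.  A leaf code's embedding is computed
by multi-head graph attention over the leaf and its ancestors on the root
path, so that codes sharing classification ancestry share representation --
the mechanism by which the hierarchy's domain knowledge enters the model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, softmax


class OntologyError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class CodeOntology:
    """A rooted tree of code nodes; the observable codes are the leaves.

    Parameters
    ----------
    kind : str
        ``"diagnosis"`` or ``"drug"``.
    parent : mapping of node label -> parent label
        Every node except the root appears as a key.
    """

    kind: str
    parent: Mapping[str, str]

    def __post_init__(self):
        children: dict[str, list[str]] = {}
        nodes = set(self.parent)
        for child, par in self.parent.items():
            nodes.add(par)
            children.setdefault(par, []).append(child)
        roots = [n for n in nodes if n not in self.parent]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {sorted(roots)!r}")
        # cycle / reachability check by walking up from every node
        for node in nodes:
            seen = set()
            cur = node
            while cur in self.parent:
                if cur in seen:
                    raise OntologyError(f"cycle through node {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
            if cur != roots[0]:
                raise OntologyError(f"node {node!r} not reachable from root")
        object.__setattr__(self, "_root", roots[0])
        object.__setattr__(self, "_children", children)
        leaves = tuple(sorted(n for n in nodes if n not in children))
        object.__setattr__(self, "_leaves", leaves)
        object.__setattr__(self, "_nodes", tuple(sorted(nodes)))
        object.__setattr__(self, "_node_index", {n: i for i, n in enumerate(self._nodes)})
        object.__setattr__(self, "_leaf_set", frozenset(leaves))

    @property
    def root(self) -> str:
        return self._root

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node labels, sorted (stable node indexing)."""
        return self._nodes

    @property
    def leaves(self) -> tuple[str, ...]:
        return self._leaves

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def is_leaf(self, node: str) -> bool:
        return node in self._leaf_set

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(self._children.get(node, ()))

    def node_index(self, node: str) -> int:
        try:
            return self._node_index[node]
        except KeyError:
            raise OntologyError(f"unknown node {node!r}") from None

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_edges(cls, kind: str, edges: Iterable[tuple[str, str]]) -> "CodeOntology":
        parent = {}
        for par, child in edges:
            if child in parent and parent[child] != par:
                raise OntologyError(f"node {child!r} has two parents")
            parent[child] = par
        return cls(kind=kind, parent=parent)

    @classmethod
    def read_edge_list(cls, path: str | Path, kind: str) -> "CodeOntology":
        """Read a two-column parent-child edge list (tab or comma separated)."""
        edges = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) != 2:
                raise OntologyError(f"bad edge line: {line!r}")
            edges.append((parts[0], parts[1]))
        return cls.from_edges(kind, edges)

    def write_edge_list(self, path: str | Path, sep: str = "\t") -> None:
        lines = [f"{par}{sep}{child}" for child, par in sorted(self.parent.items())]
        Path(path).write_text("\n".join(lines) + "\n")


def ancestor_set(ontology: CodeOntology, leaf: str) -> list[str]:
    """The attention neighborhood of a leaf: itself plus all ancestors.

    Returned in leaf-to-root order.  Raises for unknown or internal nodes.
    """
    if not ontology.is_leaf(leaf):
        raise OntologyError(f"{leaf!r} is not a leaf of the {ontology.kind} ontology")
    out = [leaf]
    cur = leaf
    while cur in ontology.parent:
        cur = ontology.parent[cur]
        out.append(cur)
    return out


class GraphAttentionEmbedding:
    """Multi-head graph-attention embedding of ontology leaves.

    Each head k transforms node vectors with W^k and scores a (leaf,
    neighbor) pair with a leaky-ReLU of a learned linear form on the
    concatenated transformed vectors (the standard GAT scorer); softmax over
    the leaf's neighborhood (the leaf plus its root-path ancestors) gives
    attention coefficients, and the head output is the ELU of the
    attention-weighted sum of transformed neighbor vectors.  Heads are
    concatenated, so the leaf embedding has length ``n_heads * head_dim``.
    """

    def __init__(self, ontology: CodeOntology, embed_dim: int = 64,
                 n_heads: int = 4, node_dim: int | None = None,
                 rng: np.random.Generator | None = None,
                 leaky_slope: float = 0.2):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        rng = rng or np.random.default_rng()
        self.ontology = ontology
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.embed_dim = embed_dim
        self.node_dim = node_dim or embed_dim
        self.leaky_slope = leaky_slope
        n = ontology.n_nodes
        scale = 1.0 / np.sqrt(self.node_dim)
        self.node_table = Parameter(rng.normal(0.0, scale, size=(n, self.node_dim)),
                                    name=f"{ontology.kind}.node_table")
        self.W = [Parameter(rng.normal(0.0, scale, size=(self.node_dim, self.head_dim)),
                            name=f"{ontology.kind}.W{k}") for k in range(n_heads)]
        a_scale = 1.0 / np.sqrt(self.head_dim)
        self.a_src = [Parameter(rng.normal(0.0, a_scale, size=self.head_dim))
                      for _ in range(n_heads)]
        self.a_dst = [Parameter(rng.normal(0.0, a_scale, size=self.head_dim))
                      for _ in range(n_heads)]
        # precompute the padded neighborhood index matrix over all leaves
        paths = [ [ontology.node_index(n_) for n_ in ancestor_set(ontology, leaf)]
                  for leaf in ontology.leaves]
        depth = max(len(p) for p in paths)
        self._nbr_idx = np.zeros((len(paths), depth), dtype=np.intp)
        self._nbr_mask = np.zeros((len(paths), depth), dtype=bool)
        for i, p in enumerate(paths):
            self._nbr_idx[i, :len(p)] = p
            self._nbr_mask[i, :len(p)] = True
        self._leaf_pos = {leaf: i for i, leaf in enumerate(ontology.leaves)}

    @property
    def parameters(self) -> list[Parameter]:
        return [self.node_table, *self.W, *self.a_src, *self.a_dst]

    # -- forward --------------------------------------------------------------

    def _head_scores(self, k: int) -> tuple[Tensor, Tensor]:
        """Transformed node vectors and raw pair scores for head k."""
        Wh = self.node_table @ self.W[k]                       # (N, d)
        src = Wh @ self.a_src[k]                               # (N,)
        dst = Wh @ self.a_dst[k]                               # (N,)
        leaf_ids = self._nbr_idx[:, 0]
        scores = src.take(leaf_ids).reshape(-1, 1) + dst.take(self._nbr_idx)
        return Wh, scores.leaky_relu(self.leaky_slope)         # (L, A)

    def attention_coefficients(self, center: str, head: int) -> dict[str, float]:
        """Normalized attention weights of one leaf's neighborhood for one head.

        Weights are non-negative and sum to 1 over the leaf-plus-ancestors
        neighborhood.
        """
        if not 0 <= head < self.n_heads:
            raise ValueError(f"head {head} out of range")
        if center not in self._leaf_pos:
            raise OntologyError(f"{center!r} is not a leaf")
        neighbors = ancestor_set(self.ontology, center)
        _, scores = self._head_scores(head)
        i = self._leaf_pos[center]
        alpha = softmax(scores[i:i + 1], axis=-1, mask=self._nbr_mask[i:i + 1])
        return {n_: float(alpha.data[0, j]) for j, n_ in enumerate(neighbors)}

    def embed_all_leaves(self) -> Tensor:
        """Embeddings for every leaf, rows ordered like ``ontology.leaves``."""
        heads = []
        for k in range(self.n_heads):
            Wh, scores = self._head_scores(k)
            alpha = softmax(scores, axis=-1, mask=self._nbr_mask)      # (L, A)
            nbr_vecs = Wh.take(self._nbr_idx)                          # (L, A, d)
            agg = (alpha.reshape(*alpha.shape, 1) * nbr_vecs).sum(axis=1)
            heads.append(agg.elu())
        return concatenate(heads, axis=-1)                             # (L, K*d)

    def embed_code(self, code: str) -> Tensor:
        """Embedding of a single leaf code (length ``embed_dim``)."""
        if code not in self._leaf_pos:
            raise OntologyError(f"{code!r} is not a leaf of the "
                                f"{self.ontology.kind} ontology")
        return self.embed_all_leaves()[self._leaf_pos[code]:self._leaf_pos[code] + 1].reshape(self.embed_dim)

    def leaf_row(self, code: str) -> int:
        return self._leaf_pos[code]
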