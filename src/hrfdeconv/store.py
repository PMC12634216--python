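"""Hybrid spatial + context store for HRF estimates.

Estimated HRFs are kept in a k-d tree over 3-D optode coordinates
(millimetres) so that nearest-neighbour and radius searches prune whole
branches instead of scanning every node, and simultaneously indexed in a
context hash table (see :mod:`hrfdeconv.context`) so a contextually relevant
sub-tree can be branched off cheaply. One tree node carries both chromophore
payloads (HbO and HbR kernels share a location), and serves both chromophore
views of the store.

Two kinds of special node exist. Global (location-free) HRFs are placed at
random coordinates in [359, 361]³ — far outside head space — so they cluster
into their own subtree instead of degrading the tree into a linear tail. The
canonical double-gamma HRF is pinned at exactly (359, 359, 359) and is the
universal fallback whenever a search finds nothing within its distance
threshold.

The whole store round-trips through a deterministic JSON document (keyed by
``doi|channel`` to prevent clashes) so montage-specific HRF sets can be
saved, shared and merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from .canonical import DoubleGammaParams, double_gamma_hrf
from .context import (
    ContextHashTable,
    ContextQuery,
    bin_size_for,
    bin_numeric_context,
    context_key,
    context_similarity,
    keys_for_context_value,
)
from .errors import (
    DuplicateEntryError,
    FormatError,
    MergeConflictError,
    ValidationError,
)
from .types import HRFEstimate

__all__ = [
    "HRNode",
    "HRStore",
    "place_global_hrf",
    "store_to_json",
    "store_from_json",
    "merge_stores",
]

SCHEMA_VERSION = "1.0"
CANONICAL_LOCATION = (359.0, 359.0, 359.0)
GLOBAL_CENTER = 360.0
GLOBAL_MAX_DEVIATION = 1.0


@dataclass(eq=False)
class HRNode:
    """A k-d tree node holding the paired chromophore payloads for one
    (doi, channel) key."""

    location: np.ndarray
    doi: str
    channel_id: str
    hbo: Optional[HRFEstimate] = None
    hbr: Optional[HRFEstimate] = None
    context: dict = field(default_factory=dict)
    is_global: bool = False
    left: Optional["HRNode"] = None
    right: Optional["HRNode"] = None
    split_axis: int = 0

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        if self.location.shape != (3,) or not np.all(np.isfinite(self.location)):
            raise ValidationError("node location must be a finite 3-vector (mm)")
        if self.hbo is None and self.hbr is None:
            raise ValidationError("node must carry at least one chromophore payload")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.doi, self.channel_id)

    def payload(self, chromophore: str) -> Optional[HRFEstimate]:
        return self.hbo if str(chromophore).lower() == "hbo" else self.hbr

    def detached_copy(self) -> "HRNode":
        """Copy sharing payloads but with fresh tree linkage."""
        return HRNode(
            location=self.location.copy(),
            doi=self.doi,
            channel_id=self.channel_id,
            hbo=self.hbo,
            hbr=self.hbr,
            context=dict(self.context),
            is_global=self.is_global,
        )


def place_global_hrf(rng: np.random.Generator) -> np.ndarray:
    """Random coordinates for a location-free (global) HRF: uniform in
    [359, 361]³, centred on (360, 360, 360) with max deviation 1."""
    return rng.uniform(
        GLOBAL_CENTER - GLOBAL_MAX_DEVIATION,
        GLOBAL_CENTER + GLOBAL_MAX_DEVIATION,
        size=3,
    )


class HRStore:
    """Two k-d tree chromophore views over shared nodes, plus a context hash
    table of node references and the pinned canonical fallback."""

    def __init__(
        self,
        frame: str = "head-mm",
        canonical_params: Optional[DoubleGammaParams] = None,
    ) -> None:
        self.frame = frame
        self.version = SCHEMA_VERSION
        self.canonical_params = canonical_params or DoubleGammaParams()
        self.root: Optional[HRNode] = None
        self.table = ContextHashTable()
        self.nodes: dict = {}  # (doi, channel_id) -> HRNode, canonical excluded
        self.canonical = HRNode(
            location=np.array(CANONICAL_LOCATION),
            doi="canonical",
            channel_id="canonical",
            hbo=double_gamma_hrf(self.canonical_params, "hbo"),
            hbr=double_gamma_hrf(self.canonical_params, "hbr"),
            context={"model": "canonical-double-gamma"},
            is_global=True,
        )
        self._tree_insert(self.canonical)

    # -- tree views -----------------------------------------------------
    @property
    def hbo_tree(self) -> Optional[HRNode]:
        return self.root

    @property
    def hbr_tree(self) -> Optional[HRNode]:
        return self.root

    def __len__(self) -> int:
        return len(self.nodes)

    def all_nodes(self, include_canonical: bool = False) -> List[HRNode]:
        out = list(self.nodes.values())
        if include_canonical:
            out.append(self.canonical)
        return out

    # -- insertion ------------------------------------------------------
    def _tree_insert(self, node: HRNode) -> None:
        node.left = node.right = None
        if self.root is None:
            node.split_axis = 0
            self.root = node
            return
        current = self.root
        depth = 0
        while True:
            axis = depth % 3
            if node.location[axis] < current.location[axis]:
                if current.left is None:
                    node.split_axis = (depth + 1) % 3
                    current.left = node
                    return
                current = current.left
            else:
                if current.right is None:
                    node.split_axis = (depth + 1) % 3
                    current.right = node
                    return
                current = current.right
            depth += 1

    def _register_context(self, node: HRNode) -> None:
        for group, value in node.context.items():
            for key in keys_for_context_value(group, value):
                self.table.insert(key, node)

    def insert_node(self, node: HRNode, force: bool = False) -> "HRStore":
        """Insert a node; duplicate (doi, channel_id) keys raise unless
        ``force`` overwrites (the replacement triggers a tree rebuild)."""
        if node.key in self.nodes:
            if not force:
                raise DuplicateEntryError(
                    f"node with key (doi={node.doi!r}, channel={node.channel_id!r}) "
                    "already present"
                )
            self.nodes.pop(node.key)
            self.nodes[node.key] = node
            self.rebuild()
            return self
        self.nodes[node.key] = node
        self._tree_insert(node)
        self._register_context(node)
        return self

    def add_estimate(
        self,
        hbo: Optional[HRFEstimate] = None,
        hbr: Optional[HRFEstimate] = None,
        location=None,
        doi: str = "unpublished",
        channel_id: str = "",
        context: Optional[dict] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> HRNode:
        """Convenience wrapper: build a node (placing it globally when no
        location is given) and insert it."""
        is_global = location is None
        if is_global:
            if rng is None:
                raise ValidationError("a seeded rng is required to place a global HRF")
            location = place_global_hrf(rng)
        node = HRNode(
            location=np.asarray(location, dtype=float),
            doi=doi,
            channel_id=channel_id,
            hbo=hbo,
            hbr=hbr,
            context=dict(context or {}),
            is_global=is_global,
        )
        self.insert_node(node)
        return node

    def rebuild(self) -> None:
        """Rebalance: batch median-split build over all nodes, canonical
        included."""
        nodes = self.all_nodes(include_canonical=True)
        for n in nodes:
            n.left = n.right = None
        self.root = self._build_median(nodes, depth=0)
        self.table = ContextHashTable()
        for n in self.nodes.values():
            self._register_context(n)

    def _build_median(self, nodes: List[HRNode], depth: int) -> Optional[HRNode]:
        if not nodes:
            return None
        axis = depth % 3
        nodes = sorted(nodes, key=lambda n: n.location[axis])
        mid = len(nodes) // 2
        node = nodes[mid]
        node.split_axis = axis
        node.left = self._build_median(nodes[:mid], depth + 1)
        node.right = self._build_median(nodes[mid + 1 :], depth + 1)
        return node

    # -- search ---------------------------------------------------------
    def nearest_hrf(
        self,
        point,
        max_dist: float = 1.0,
        query: Optional[ContextQuery] = None,
        chromophore: Optional[str] = None,
    ) -> HRNode:
        """Nearest node to ``point`` (Euclidean, pruned k-d recursion) among
        nodes passing the context filter and carrying the requested
        chromophore payload, if within ``max_dist`` (default 1 mm); otherwise
        the canonical fallback node."""
        if max_dist < 0:
            raise ValidationError(f"max_dist must be >= 0, got {max_dist}")
        point = np.asarray(point, dtype=float)

        def accept(node: HRNode) -> bool:
            if node is self.canonical:
                return False
            if chromophore is not None and node.payload(chromophore) is None:
                return False
            if query is not None:
                return context_similarity(query, node.context) >= query.threshold
            return True

        best_node, best_dist = self._nn_search(self.root, point, 0, None, np.inf, accept)
        if best_node is not None and best_dist <= max_dist:
            return best_node
        return self.canonical

    def _nn_search(
        self,
        node: Optional[HRNode],
        point: np.ndarray,
        depth: int,
        best: Optional[HRNode],
        best_dist: float,
        accept: Callable[[HRNode], bool],
    ) -> Tuple[Optional[HRNode], float]:
        if node is None:
            return best, best_dist
        dist = float(np.linalg.norm(node.location - point))
        if accept(node) and dist < best_dist:
            best, best_dist = node, dist
        axis = depth % 3
        diff = point[axis] - node.location[axis]
        near, far = (node.left, node.right) if diff < 0 else (node.right, node.left)
        best, best_dist = self._nn_search(near, point, depth + 1, best, best_dist, accept)
        if abs(diff) <= best_dist:  # far branch can still hold a closer node
            best, best_dist = self._nn_search(far, point, depth + 1, best, best_dist, accept)
        return best, best_dist

    def radius_hrfs(self, point, radius: float) -> List[HRNode]:
        """All nodes with Euclidean distance <= radius from ``point``
        (canonical excluded unless the sphere reaches it)."""
        if radius < 0:
            raise ValidationError(f"radius must be >= 0, got {radius}")
        point = np.asarray(point, dtype=float)
        out: List[HRNode] = []

        def recurse(node: Optional[HRNode], depth: int) -> None:
            if node is None:
                return
            if float(np.linalg.norm(node.location - point)) <= radius:
                out.append(node)
            axis = depth % 3
            diff = point[axis] - node.location[axis]
            near, far = (node.left, node.right) if diff < 0 else (node.right, node.left)
            recurse(near, depth + 1)
            if abs(diff) <= radius:
                recurse(far, depth + 1)

        recurse(self.root, 0)
        return out

    def branch(self, query: ContextQuery) -> "HRStore":
        """Context-filtered sub-store.

        Candidates are gathered through hash-table lookups on each query item
        (numeric items expand centre-out over their bins); candidates whose
        weighted context similarity reaches the query threshold are inserted
        into a fresh store. The canonical node is always present in the
        result.
        """
        candidates: List[HRNode] = []
        seen = set()
        for item in query.items:
            rng_item = item.numeric_range
            if rng_item is not None:
                keys = [
                    context_key(item.group, b)
                    for b in bin_numeric_context(*rng_item, bin_size_for(item.group))
                ]
            else:
                keys = [context_key(item.group, item.value)]
            for key in keys:
                for node in self.table.lookup(key):
                    if id(node) not in seen:
                        seen.add(id(node))
                        candidates.append(node)
        sub = HRStore(frame=self.frame, canonical_params=self.canonical_params)
        for node in candidates:
            if context_similarity(query, node.context) >= query.threshold:
                sub.insert_node(node.detached_copy())
        return sub


# -- JSON persistence ---------------------------------------------------

_REQUIRED_NODE_FIELDS = ("location", "duration_s", "sfreq", "doi", "channel_id")


def _payload_to_json(h: Optional[HRFEstimate]) -> Optional[dict]:
    if h is None:
        return None
    return {
        "kernel": [float(v) for v in h.kernel],
        "spread": None if h.spread is None else [float(v) for v in h.spread],
        "subjects": None
        if h.subject_kernels is None
        else [[float(v) for v in k] for k in h.subject_kernels],
    }


def _node_to_json(node: HRNode) -> dict:
    ref = node.hbo or node.hbr
    return {
        "location": [float(v) for v in node.location],
        "duration_s": float(ref.duration_s),
        "sfreq": float(ref.sfreq),
        "doi": node.doi,
        "channel_id": node.channel_id,
        "is_global": bool(node.is_global),
        "context": _context_to_json(node.context),
        "hbo": _payload_to_json(node.hbo),
        "hbr": _payload_to_json(node.hbr),
    }


def _context_to_json(context: dict) -> dict:
    out = {}
    for group, value in context.items():
        if isinstance(value, tuple):
            value = list(value)
        if isinstance(value, (np.integer, np.floating)):
            value = float(value)
        out[str(group)] = value
    return out


def store_to_json(store: HRStore) -> str:
    """Serialize with sorted keys and fixed indentation so a second
    serialization of the parsed document is byte-identical."""
    doc = {
        "metadata": {
            "version": store.version,
            "frame": store.frame,
            "canonical": {
                "duration_s": float(store.canonical_params.duration_s),
                "sfreq": float(store.canonical_params.sfreq),
            },
        },
        "nodes": {
            f"{node.doi}|{node.channel_id}": _node_to_json(node)
            for node in store.nodes.values()
        },
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def _require(mapping: dict, field_name: str, path: str):
    if field_name not in mapping or mapping[field_name] is None:
        raise FormatError(f"{path}.{field_name}: missing required field")
    return mapping[field_name]


def _payload_from_json(
    data: Optional[dict], duration_s: float, sfreq: float, chromophore: str, path: str
) -> Optional[HRFEstimate]:
    if data is None:
        return None
    kernel = _require(data, "kernel", path)
    try:
        return HRFEstimate(
            kernel=np.asarray(kernel, dtype=float),
            duration_s=duration_s,
            sfreq=sfreq,
            chromophore=chromophore,
            spread=None if data.get("spread") is None else np.asarray(data["spread"]),
            subject_kernels=None
            if data.get("subjects") is None
            else [np.asarray(k, dtype=float) for k in data["subjects"]],
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def store_from_json(text: str) -> HRStore:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError("$: top level must be an object")
    meta = _require(doc, "metadata", "$")
    nodes = doc.get("nodes", {})
    canon = meta.get("canonical", {})
    params = DoubleGammaParams(
        duration_s=canon.get("duration_s", 30.0), sfreq=canon.get("sfreq", 10.0)
    )
    store = HRStore(frame=meta.get("frame", "head-mm"), canonical_params=params)
    for key in sorted(nodes):
        path = f"$.nodes['{key}']"
        data = nodes[key]
        for field_name in _REQUIRED_NODE_FIELDS:
            _require(data, field_name, path)
        duration_s, sfreq = float(data["duration_s"]), float(data["sfreq"])
        hbo = _payload_from_json(data.get("hbo"), duration_s, sfreq, "hbo", path + ".hbo")
        hbr = _payload_from_json(data.get("hbr"), duration_s, sfreq, "hbr", path + ".hbr")
        if hbo is None and hbr is None:
            raise FormatError(f"{path}: node has neither hbo nor hbr payload")
        context = {
            g: tuple(v) if isinstance(v, list) and len(v) == 2 else v
            for g, v in data.get("context", {}).items()
        }
        store.insert_node(
            HRNode(
                location=np.asarray(data["location"], dtype=float),
                doi=str(data["doi"]),
                channel_id=str(data["channel_id"]),
                hbo=hbo,
                hbr=hbr,
                context=context,
                is_global=bool(data.get("is_global", False)),
            )
        )
    return store


def merge_stores(a: HRStore, b: HRStore, policy: str = "error") -> HRStore:
    """Union of two stores' nodes under a key-collision policy.

    ``error`` (default) raises :class:`MergeConflictError` listing the
    colliding (doi, channel) keys; ``keep_a`` / ``keep_b`` keep the named
    side's node. The spatial tree and hash table are rebuilt over the union.
    """
    if policy not in ("error", "keep_a", "keep_b"):
        raise ValidationError(f"unknown merge policy {policy!r}")
    if a.version != b.version:
        raise ValidationError(
            f"incompatible schema versions: {a.version} vs {b.version}"
        )
    collisions = sorted(set(a.nodes) & set(b.nodes))
    if collisions and policy == "error":
        raise MergeConflictError(collisions)
    merged = HRStore(frame=a.frame, canonical_params=a.canonical_params)
    for node in a.nodes.values():
        if policy == "keep_b" and node.key in b.nodes:
            continue
        merged.insert_node(node.detached_copy())
    for node in b.nodes.values():
        if node.key in merged.nodes:
            continue
        merged.insert_node(node.detached_copy())
    merged.rebuild()
    return merged
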