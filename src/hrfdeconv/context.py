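"""Experimental-context hashing, binning and similarity.

Context items (task, study, age range, stimulus duration/intensity, DOI …)
attached to stored HRFs are indexed in a hash table so that a sub-tree of
contextually relevant estimates can be pulled out without walking the whole
spatial tree. Keys are the lower-cased group and value joined with a hyphen
("task-flanker", "study-care") to keep similar-looking values from different
groups apart. The table uses SHA3-256 with open addressing and a quadratic
probe; numeric values and ranges are discretized into fixed-width bins
(1 year for age, 1.0 s for duration, 0.1 for stimulus intensity) and every
covering bin is registered, so a later range query can enumerate bins from
the centre of its range outwards and stop at the first hits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import HrfError, ValidationError

__all__ = [
    "DEFAULT_BIN_SIZES",
    "context_key",
    "hash_context_key",
    "probe_sequence",
    "ContextHashTable",
    "bin_numeric_context",
    "ContextQuery",
    "context_similarity",
]

#: Bin widths per context group for numeric values; anything unlisted uses 1.0.
DEFAULT_BIN_SIZES = {"age": 1.0, "duration": 1.0, "intensity": 0.1}

ContextValue = Union[str, float, int, Tuple[float, float]]


def bin_size_for(group: str) -> float:
    return DEFAULT_BIN_SIZES.get(group.strip().lower(), 1.0)


def _render_value(value: ContextValue) -> str:
    if isinstance(value, str):
        return value.strip().lower()
    if isinstance(value, (int, float, np.integer, np.floating)):
        return f"{float(value):.1f}"  # fixed 1-decimal rendering keeps bins stable
    raise ValidationError(f"cannot render context value {value!r} as a key")


def context_key(group: str, value: ContextValue) -> str:
    """Hyphenated, normalized key string, e.g. ``task-flanker`` or ``age-5.0``."""
    group = str(group).strip().lower()
    rendered = _render_value(value)
    if not group or not rendered:
        raise ValidationError("context group and value must be nonempty")
    return f"{group}-{rendered}"


def hash_context_key(key: str, m: int) -> int:
    """Base slot: first 8 bytes of SHA3-256(key) as an unsigned integer mod m."""
    digest = hashlib.sha3_256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % m


def probe_sequence(base: int, m: int) -> Iterator[int]:
    """Quadratic probe: visit (base + i²) mod m for i = 0, 1, 2, …, m-1."""
    for i in range(m):
        yield (base + i * i) % m


def _next_prime(n: int) -> int:
    def is_prime(k: int) -> bool:
        if k < 2:
            return False
        if k % 2 == 0:
            return k == 2
        f = 3
        while f * f <= k:
            if k % f == 0:
                return False
            f += 2
        return True

    while not is_prime(n):
        n += 1
    return n


class ContextHashTable:
    """Open-addressing hash table mapping context keys to lists of node
    references.

    Prime table sizes; resize doubles to the next prime when the load factor
    exceeds 0.7 (quadratic probing is only guaranteed to find a free slot at
    moderate load). Appending a node under an existing key does not create a
    new slot.
    """

    _INITIAL_SIZE = 53
    MAX_LOAD = 0.7

    def __init__(self, size: Optional[int] = None) -> None:
        self.m = _next_prime(size or self._INITIAL_SIZE)
        self._keys: List[Optional[str]] = [None] * self.m
        self._values: List[Optional[list]] = [None] * self.m
        self.n_keys = 0

    @property
    def load_factor(self) -> float:
        return self.n_keys / self.m

    def _find_slot(self, key: str) -> int:
        base = hash_context_key(key, self.m)
        for slot in probe_sequence(base, self.m):
            if self._keys[slot] is None or self._keys[slot] == key:
                return slot
        raise HrfError("probe sequence exhausted")  # pragma: no cover - resize prevents

    def _resize(self) -> None:
        old = [(k, v) for k, v in zip(self._keys, self._values) if k is not None]
        self.m = _next_prime(2 * self.m)
        self._keys = [None] * self.m
        self._values = [None] * self.m
        self.n_keys = 0
        for key, nodes in old:
            slot = self._find_slot(key)
            self._keys[slot] = key
            self._values[slot] = nodes
            self.n_keys += 1

    def insert(self, key: str, node) -> None:
        slot = self._find_slot(key)
        if self._keys[slot] is None:
            self._keys[slot] = key
            self._values[slot] = []
            self.n_keys += 1
            if self.load_factor > self.MAX_LOAD:
                self._resize()
                slot = self._find_slot(key)
        if node not in self._values[slot]:
            self._values[slot].append(node)

    def lookup(self, key: str) -> list:
        base = hash_context_key(key, self.m)
        for slot in probe_sequence(base, self.m):
            if self._keys[slot] is None:
                return []
            if self._keys[slot] == key:
                return list(self._values[slot])
        return []

    def keys(self) -> List[str]:
        return [k for k in self._keys if k is not None]


def bin_numeric_context(lo: float, hi: float, bin_size: float) -> List[float]:
    """Fixed-width bins covering [lo, hi], ordered centre-out.

    Bins start at ``lo`` and step by ``bin_size``; they are emitted in order
    of closeness to the range midpoint, starting with the bin at or just
    below it and alternating below/above (ages 4–7 with 1-year bins give
    5, 6, 4, 7). A degenerate range (lo == hi) yields the single bin [lo].
    """
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    if lo > hi:
        raise ValidationError(f"lo must be <= hi, got {lo} > {hi}")
    span = hi - lo
    n_bins = int(np.floor(span / bin_size + 1e-9)) + 1
    bins = [lo + i * bin_size for i in range(n_bins)]
    if bins[-1] < hi - 1e-9:  # remainder shorter than one bin still covered
        bins.append(lo + n_bins * bin_size)
    mid = (lo + hi) / 2.0
    # closest to midpoint first; equidistant pairs emit the lower bin first
    return sorted(bins, key=lambda b: (abs(b - mid), b))


@dataclass
class QueryItem:
    group: str
    value: ContextValue
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.group = str(self.group).strip().lower()
        if self.weight <= 0:
            raise ValidationError("query item weights must be positive")

    @property
    def numeric_range(self) -> Optional[Tuple[float, float]]:
        if isinstance(self.value, (tuple, list)) and len(self.value) == 2:
            lo, hi = float(self.value[0]), float(self.value[1])
            if lo > hi:
                raise ValidationError(f"range lo {lo} > hi {hi}")
            return lo, hi
        if isinstance(self.value, (int, float, np.integer, np.floating)):
            v = float(self.value)
            return v, v
        return None


@dataclass
class ContextQuery:
    """A weighted list of context items with a similarity threshold
    (defaulting to 95%)."""

    items: List[QueryItem] = field(default_factory=list)
    threshold: float = 0.95

    def __post_init__(self) -> None:
        self.items = [
            it if isinstance(it, QueryItem) else QueryItem(*it) for it in self.items
        ]
        if not (0 < self.threshold <= 1):
            raise ValidationError(f"threshold must be in (0, 1], got {self.threshold}")

    @classmethod
    def from_strings(cls, pairs: Iterable[str], threshold: float = 0.95) -> "ContextQuery":
        """Parse ``group=value`` strings; ``lo-hi`` numeric values become
        ranges (e.g. ``age=4-7``)."""
        items = []
        for pair in pairs:
            if "=" not in pair:
                raise ValidationError(f"expected group=value, got {pair!r}")
            group, raw = pair.split("=", 1)
            value: ContextValue = raw.strip()
            parts = raw.strip().split("-")
            try:
                if len(parts) == 2 and all(parts):
                    value = (float(parts[0]), float(parts[1]))
                else:
                    value = float(raw)
            except ValueError:
                pass
            items.append(QueryItem(group=group, value=value))
        return cls(items=items, threshold=threshold)


def _ranges_overlap(a: Tuple[float, float], b: Tuple[float, float]) -> bool:
    return a[0] <= b[1] + 1e-12 and b[0] <= a[1] + 1e-12


def _node_numeric_range(value) -> Optional[Tuple[float, float]]:
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return float(value[0]), float(value[1])
    if isinstance(value, (int, float, np.integer, np.floating)) and not isinstance(value, bool):
        return float(value), float(value)
    return None


def item_matches(item: QueryItem, node_context: dict) -> bool:
    """Case-insensitive text equality, or numeric range overlap."""
    node_value = None
    for group, value in node_context.items():
        if str(group).strip().lower() == item.group:
            node_value = value
            break
    else:
        return False
    q_range = item.numeric_range
    if q_range is not None:
        n_range = _node_numeric_range(node_value)
        if n_range is None:
            return False
        return _ranges_overlap(q_range, n_range)
    if not isinstance(node_value, str):
        return False
    return node_value.strip().lower() == str(item.value).strip().lower()


def context_similarity(query: ContextQuery, node_context: dict) -> float:
    """Weighted proportion of query items matched by the node's context.

    Query-side coverage only: extra context on the node that the query did
    not ask about does not lower the score.
    """
    if not query.items:
        raise ValidationError("context query must contain at least one item")
    total = sum(it.weight for it in query.items)
    matched = sum(it.weight for it in query.items if item_matches(it, node_context))
    return matched / total


def keys_for_context_value(group: str, value: ContextValue) -> List[str]:
    """All hash keys a node's context entry registers under (one per covering
    bin for numeric values/ranges; a single key for text)."""
    rng = _node_numeric_range(value)
    if rng is None:
        return [context_key(group, value)]
    bins = bin_numeric_context(rng[0], rng[1], bin_size_for(group))
    return [context_key(group, b) for b in bins]
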