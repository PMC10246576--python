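"""Persistent red-black interval trees and the genomic interval set algebra.

The engine behind all interval operations is an immutable (persistent)
red-black tree per sequence, augmented with the maximum interval end of each
subtree (``max_end``) so that overlap queries can prune whole subtrees.
Insertion uses the functional four-case rebalance of Okasaki: the tree is
never modified in place, every operation returns a new version and old
versions remain valid.  There is no deletion; derived sets (merge,
intersect, subtract, complement) are rebuilt from scratch.

Duplicate intervals are retained on insert (multiset semantics) so that a
parsed file with repeated records survives a round-trip; :func:`merge`
collapses duplicates along with all other overlaps.  Abutting intervals
(``end == next.start``) coalesce under merge, which makes the set operations
exact complements of one another at the covered-base level.

Strand is ignored by the algebra; it travels with the intervals as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .errors import AssemblyMismatchError
from .genome import GenomeAssembly, GenomicInterval, validate_interval

RED = "R"
BLACK = "B"


@dataclass(frozen=True)
class RbNode:
    """One node of a persistent red-black interval tree.

    ``max_end`` is the maximum interval end over the node's entire subtree;
    it is recomputed on construction, never patched.
    """

    color: str
    interval: GenomicInterval
    left: Optional["RbNode"]
    right: Optional["RbNode"]
    max_end: int = 0

    def __post_init__(self) -> None:
        m = self.interval.end
        if self.left is not None and self.left.max_end > m:
            m = self.left.max_end
        if self.right is not None and self.right.max_end > m:
            m = self.right.max_end
        object.__setattr__(self, "max_end", m)


def _key(iv: GenomicInterval) -> tuple[int, int]:
    return (iv.start, iv.end)


def _balance(
    color: str,
    iv: GenomicInterval,
    left: Optional[RbNode],
    right: Optional[RbNode],
) -> RbNode:
    """Okasaki's four-case rebalance: rewrite any black node with a red
    child that itself has a red child into a red node with two black
    children."""
    if color == BLACK:
        if left is not None and left.color == RED:
            ll, lr = left.left, left.right
            if ll is not None and ll.color == RED:
                return RbNode(
                    RED,
                    left.interval,
                    RbNode(BLACK, ll.interval, ll.left, ll.right),
                    RbNode(BLACK, iv, lr, right),
                )
            if lr is not None and lr.color == RED:
                return RbNode(
                    RED,
                    lr.interval,
                    RbNode(BLACK, left.interval, ll, lr.left),
                    RbNode(BLACK, iv, lr.right, right),
                )
        if right is not None and right.color == RED:
            rl, rr = right.left, right.right
            if rl is not None and rl.color == RED:
                return RbNode(
                    RED,
                    rl.interval,
                    RbNode(BLACK, iv, left, rl.left),
                    RbNode(BLACK, right.interval, rl.right, rr),
                )
            if rr is not None and rr.color == RED:
                return RbNode(
                    RED,
                    right.interval,
                    RbNode(BLACK, iv, left, rl),
                    RbNode(BLACK, rr.interval, rr.left, rr.right),
                )
    return RbNode(color, iv, left, right)


def tree_insert(root: Optional[RbNode], iv: GenomicInterval) -> RbNode:
    """Insert *iv*, returning the root of a new tree; *root* is unchanged.

    Equal keys go to the right subtree, so duplicates are retained and
    in-order traversal is stable for them.
    """

    def ins(node: Optional[RbNode]) -> RbNode:
        if node is None:
            return RbNode(RED, iv, None, None)
        if _key(iv) < _key(node.interval):
            return _balance(node.color, node.interval, ins(node.left), node.right)
        return _balance(node.color, node.interval, node.left, ins(node.right))

    r = ins(root)
    if r.color == RED:
        r = RbNode(BLACK, r.interval, r.left, r.right)
    return r


def tree_iter(root: Optional[RbNode]) -> Iterator[GenomicInterval]:
    """In-order traversal: intervals sorted by (start, end)."""
    stack: list[RbNode] = []
    node = root
    while stack or node is not None:
        while node is not None:
            stack.append(node)
            node = node.left
        node = stack.pop()
        yield node.interval
        node = node.right


def tree_search(
    root: Optional[RbNode], qstart: int, qend: int
) -> list[GenomicInterval]:
    """All stored intervals overlapping [qstart, qend), sorted by (start, end).

    Subtrees with ``max_end <= qstart`` cannot contain an overlap and are
    skipped; right subtrees of nodes with ``start >= qend`` likewise.
    """
    out: list[GenomicInterval] = []

    def walk(node: Optional[RbNode]) -> None:
        if node is None or node.max_end <= qstart:
            return
        walk(node.left)
        iv = node.interval
        if iv.start < qend:
            if qstart < iv.end:
                out.append(iv)
            walk(node.right)

    walk(root)
    return out


class IntervalSet:
    """An immutable multiset of genomic intervals bounded by an assembly.

    One red-black tree per sequence; every stored interval has been
    validated against the assembly.  All operations return new sets and
    leave their operands observably unchanged.
    """

    __slots__ = ("assembly", "_roots")

    def __init__(
        self,
        assembly: GenomeAssembly,
        _roots: dict[str, RbNode] | None = None,
    ) -> None:
        self.assembly = assembly
        self._roots: dict[str, RbNode] = dict(_roots) if _roots else {}

    @classmethod
    def from_intervals(
        cls, assembly: GenomeAssembly, intervals: Iterable[GenomicInterval]
    ) -> "IntervalSet":
        roots: dict[str, RbNode] = {}
        for iv in intervals:
            validate_interval(iv, assembly)
            roots[iv.seq_name] = tree_insert(roots.get(iv.seq_name), iv)
        return cls(assembly, roots)

    # -- introspection -------------------------------------------------

    def root(self, seq_name: str) -> Optional[RbNode]:
        return self._roots.get(seq_name)

    def __len__(self) -> int:
        return sum(1 for _ in self)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for name in self.assembly.names:
            yield from tree_iter(self._roots.get(name))

    def to_list(self) -> list[GenomicInterval]:
        return list(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.assembly == other.assembly and self.to_list() == other.to_list()

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals over {len(self.assembly)} sequences)"

    def _check_same_assembly(self, other: "IntervalSet") -> None:
        if self.assembly != other.assembly:
            raise AssemblyMismatchError(
                "interval sets are bound to different assemblies"
            )

    # -- the five operations -------------------------------------------

    def insert(self, iv: GenomicInterval) -> "IntervalSet":
        """A new set containing all prior intervals plus *iv*."""
        validate_interval(iv, self.assembly)
        roots = dict(self._roots)
        roots[iv.seq_name] = tree_insert(roots.get(iv.seq_name), iv)
        return IntervalSet(self.assembly, roots)

    def search_overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """Stored intervals overlapping *query*, sorted by (start, end)."""
        validate_interval(query, self.assembly)
        return tree_search(self._roots.get(query.seq_name), query.start, query.end)

    def _merged_runs(self, seq_name: str) -> list[tuple[int, int]]:
        """Maximal runs of overlapping-or-abutting intervals on one sequence."""
        runs: list[tuple[int, int]] = []
        for iv in tree_iter(self._roots.get(seq_name)):
            if runs and iv.start <= runs[-1][1]:
                if iv.end > runs[-1][1]:
                    runs[-1] = (runs[-1][0], iv.end)
            else:
                runs.append((iv.start, iv.end))
        return runs

    def merge(self) -> "IntervalSet":
        """Collapse the set to pairwise disjoint, non-abutting intervals
        covering exactly the same bases."""
        out: list[GenomicInterval] = []
        for name in self.assembly.names:
            out.extend(
                GenomicInterval(name, s, e) for s, e in self._merged_runs(name)
            )
        return IntervalSet.from_intervals(self.assembly, out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Bases covered by both sets, as disjoint intervals."""
        self._check_same_assembly(other)
        out: list[GenomicInterval] = []
        for name in self.assembly.names:
            a = self._merged_runs(name)
            b = other._merged_runs(name)
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.append(GenomicInterval(name, s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet.from_intervals(self.assembly, out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases covered by this set but not by *other*."""
        self._check_same_assembly(other)
        out: list[GenomicInterval] = []
        for name in self.assembly.names:
            b = other._merged_runs(name)
            for s, e in self._merged_runs(name):
                cur = s
                for bs, be in b:
                    if be <= cur:
                        continue
                    if bs >= e:
                        break
                    if bs > cur:
                        out.append(GenomicInterval(name, cur, bs))
                    cur = max(cur, be)
                    if cur >= e:
                        break
                if cur < e:
                    out.append(GenomicInterval(name, cur, e))
        return IntervalSet.from_intervals(self.assembly, out)

    def complement(self) -> "IntervalSet":
        """Bases of the whole assembly not covered by this set.

        Sequences with no stored intervals contribute their full span.
        """
        out: list[GenomicInterval] = []
        for name, length in self.assembly:
            cur = 0
            for s, e in self._merged_runs(name):
                if s > cur:
                    out.append(GenomicInterval(name, cur, s))
                cur = max(cur, e)
            if cur < length:
                out.append(GenomicInterval(name, cur, length))
        return IntervalSet.from_intervals(self.assembly, out)

    def covered_bases(self) -> int:
        """Total number of distinct bases covered by the set."""
        return sum(
            e - s
            for name in self.assembly.names
            for s, e in self._merged_runs(name)
        )


# -- structural audit (used by tests and the acceptance run) ------------


def audit_tree(root: Optional[RbNode]) -> tuple[int, int, int]:
    """Verify every red-black and augmentation invariant of a tree.

    Returns ``(black_height, n_nodes, height)``.  Raises AssertionError on
    any violation: a red node with a red child, unequal black heights,
    unsorted in-order traversal, or a stale ``max_end``.
    """

    def walk(node: Optional[RbNode]) -> tuple[int, int, int, int]:
        if node is None:
            return (1, 0, 0, 0)  # black height counts the nil leaf
        lbh, ln, lh, lmax = walk(node.left)
        rbh, rn, rh, rmax = walk(node.right)
        assert lbh == rbh, "unequal black heights"
        if node.color == RED:
            assert node.left is None or node.left.color == BLACK, "red-red"
            assert node.right is None or node.right.color == BLACK, "red-red"
        expected_max = max(node.interval.end, lmax, rmax)
        assert node.max_end == expected_max, "stale max_end"
        if node.left is not None:
            assert _key(node.left.interval) <= _key(node.interval), "order"
        if node.right is not None:
            assert _key(node.interval) <= _key(node.right.interval), "order"
        bh = lbh + (1 if node.color == BLACK else 0)
        return (bh, ln + rn + 1, max(lh, rh) + 1, expected_max)

    if root is not None:
        assert root.color == BLACK, "root must be black"
    bh, n, h, _ = walk(root)
    prev = None
    for iv in tree_iter(root):
        if prev is not None:
            assert _key(prev) <= _key(iv), "in-order traversal unsorted"
        prev = iv
    return bh, n, h
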