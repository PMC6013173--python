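"""Regression tree for BoE by binary recursive partitioning.

At every node each (variable, threshold) candidate is scored by the
reduction in deviance (sum of squares about the node mean) it achieves;
thresholds are midpoints between consecutive observed values, so on
presence/absence predictors every chosen cutoff is 0.5.  Partitioning
stops when fewer than ``min_to_split`` observations remain, the node
deviance is zero, no split reduces deviance, or the depth cap is reached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CountMatrix

_TIE_EPS = 1e-12


@dataclass
class TreeNode:
    """One node of the partition: split (variable, threshold) or leaf."""

    n: int
    deviance: float
    mean: float
    split_var: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None  # rows with x < threshold
    right: "TreeNode | None" = None  # rows with x >= threshold

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def node_count(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.node_count() + self.right.node_count()

    def predict_row(self, row: pd.Series) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.split_var] < node.threshold else node.right
        return node.mean


def _deviance(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum()) if len(y) else 0.0


def _best_split(X: np.ndarray, y: np.ndarray, columns: list[str]):
    """Exhaustive (variable, threshold) search maximizing deviance
    reduction; ties resolved to the lowest column index, then the lowest
    threshold (guaranteed by ascending scan order with strict improvement)."""
    n = len(y)
    parent_dev = _deviance(y)
    best = None  # (reduction, col_idx, threshold)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        cum = np.cumsum(ys)
        cum2 = np.cumsum(ys**2)
        total, total2 = cum[-1], cum2[-1]
        # split after position i-1 (left size i) wherever the value changes
        change = np.nonzero(np.diff(xs))[0] + 1
        for i in change:
            nl, nr = i, n - i
            sl, sl2 = cum[i - 1], cum2[i - 1]
            dev_l = sl2 - sl**2 / nl
            dev_r = (total2 - sl2) - (total - sl) ** 2 / nr
            reduction = parent_dev - dev_l - dev_r
            if reduction > _TIE_EPS and (best is None or reduction > best[0] + _TIE_EPS):
                threshold = (xs[i - 1] + xs[i]) / 2.0
                best = (reduction, j, threshold)
    if best is None:
        return None
    return best[1], best[2]


def _grow(X, y, columns, min_to_split, max_depth, depth) -> TreeNode:
    node = TreeNode(n=len(y), deviance=_deviance(y), mean=float(y.mean()))
    if len(y) < min_to_split or node.deviance <= _TIE_EPS or depth >= max_depth:
        return node
    found = _best_split(X, y, columns)
    if found is None:
        return node
    j, threshold = found
    mask = X[:, j] < threshold
    node.split_var = columns[j]
    node.threshold = float(threshold)
    node.left = _grow(X[mask], y[mask], columns, min_to_split, max_depth, depth + 1)
    node.right = _grow(X[~mask], y[~mask], columns, min_to_split, max_depth, depth + 1)
    return node


def fit_tree(
    P: CountMatrix,
    boe: np.ndarray,
    min_to_split: int = 6,
    max_depth: int = 6,
) -> TreeNode:
    """Greedy deviance-partitioning regression tree of BoE on TF counts."""
    y = np.asarray(boe, dtype=float)
    if len(P) != len(y):
        raise ValueError("matrix rows and response length differ")
    X = P.to_numpy(dtype=float)
    return _grow(X, y, list(P.columns), min_to_split, max_depth, 0)


def predict_tree(tree: TreeNode, P: CountMatrix) -> np.ndarray:
    """Leaf-mean prediction per row."""
    X = P.to_numpy(dtype=float)
    col = {c: j for j, c in enumerate(P.columns)}
    out = np.empty(len(P))
    for i in range(len(P)):
        node = tree
        while not node.is_leaf:
            node = (node.left if X[i, col[node.split_var]] < node.threshold
                    else node.right)
        out[i] = node.mean
    return out


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def render_tree(tree: TreeNode) -> str:
    """Deterministic indented text: condition, n, deviance (4 significant
    digits) and mean BoE for every node."""
    lines: list[str] = []

    def walk(node: TreeNode, label: str, depth: int) -> None:
        lines.append(
            f"{'|  ' * depth}{label}: n={node.n} "
            f"deviance={_fmt(node.deviance)} mean={_fmt(node.mean)}"
        )
        if not node.is_leaf:
            walk(node.left, f"{node.split_var} < {_fmt(node.threshold)}", depth + 1)
            walk(node.right, f"{node.split_var} >= {_fmt(node.threshold)}", depth + 1)

    walk(tree, "root", 0)
    return "\n".join(lines) + "\n"


_LINE_RE = re.compile(
    r"^(?P<indent>(\|  )*)(?P<label>.+?): "
    r"n=(?P<n>\d+) deviance=(?P<dev>[^ ]+) mean=(?P<mean>[^ ]+)$"
)


def parse_tree(text: str) -> TreeNode:
    """Rebuild the node statistics and structure from rendered text."""
    entries = []
    for line in text.strip().splitlines():
        m = _LINE_RE.match(line)
        if not m:
            raise ValueError(f"unparseable tree line: {line!r}")
        depth = len(m.group("indent")) // 3
        entries.append((depth, m.group("label"), int(m.group("n")),
                        float(m.group("dev")), float(m.group("mean"))))

    pos = 0

    def build(depth: int) -> TreeNode:
        nonlocal pos
        d, label, n, dev, mean = entries[pos]
        if d != depth:
            raise ValueError("inconsistent indentation")
        pos += 1
        node = TreeNode(n=n, deviance=dev, mean=mean)
        if pos < len(entries) and entries[pos][0] == depth + 1:
            left_label = entries[pos][1]
            var, _, rest = left_label.partition(" < ")
            if not rest:
                raise ValueError("malformed split label")
            node.left = build(depth + 1)
            node.right = build(depth + 1)
            node.split_var = var
            node.threshold = float(rest)
        return node

    root = build(0)
    if pos != len(entries):
        raise ValueError("trailing tree lines")
    return root
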