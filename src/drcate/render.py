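"""Deterministic text and DOT renderings of causal and policy trees.

Convention (stated in every rendering header): the left branch is taken
when the split condition ``feature <= threshold`` is TRUE.  Causal-tree
leaves show the leaf effect, its standard error and the honest estimation
count; policy-tree leaves show the assigned action and, when available,
the routed count.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Tuple, Union

from .policy import PolicyTreeNode
from .tree import CausalTreeModel, TreeNode

LevelMaps = Dict[str, Dict[int, str]]


def _leaf_label(node: Union[TreeNode, PolicyTreeNode]) -> str:
    if isinstance(node, PolicyTreeNode):
        return f"action={node.action}"
    return (
        f"tau={node.tau_hat:.4g} (se={node.se:.3g}) n={node.n_est}"
        f" [treated={node.n_treat_est}, control={node.n_control_est}]"
    )


def _split_label(node, level_maps: Optional[LevelMaps]) -> str:
    return f"{node.feature} <= {node.threshold:g}"


def render_tree_text(
    tree: Union[CausalTreeModel, TreeNode, PolicyTreeNode],
    level_maps: Optional[LevelMaps] = None,
) -> str:
    root = tree.root if isinstance(tree, CausalTreeModel) else tree
    lines = ["# left branch = condition TRUE"]

    def walk(node, indent: int) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(f"{pad}* {_leaf_label(node)}")
            return
        lines.append(f"{pad}{_split_label(node, level_maps)}")
        walk(node.left, indent + 1)
        walk(node.right, indent + 1)

    walk(root, 0)
    return "\n".join(lines) + "\n"


def render_dot(
    tree: Union[CausalTreeModel, TreeNode, PolicyTreeNode],
    level_maps: Optional[LevelMaps] = None,
    name: str = "tree",
) -> str:
    root = tree.root if isinstance(tree, CausalTreeModel) else tree
    lines = [f"digraph {name} {{", '  // left branch = condition TRUE']
    counter = [0]

    def walk(node) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            lines.append(f'  n{nid} [shape=box, label="{_leaf_label(node)}"];')
            return nid
        lines.append(f'  n{nid} [label="{_split_label(node, level_maps)}"];')
        left = walk(node.left)
        right = walk(node.right)
        lines.append(f'  n{nid} -> n{left} [label="true"];')
        lines.append(f'  n{nid} -> n{right} [label="false"];')
        return nid

    walk(root)
    lines.append("}")
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(r'^\s*n(\d+) \[(?:shape=box, )?label="([^"]*)"\];', re.MULTILINE)
_EDGE_RE = re.compile(r'^\s*n(\d+) -> n(\d+) \[label="(true|false)"\];', re.MULTILINE)
_SPLIT_RE = re.compile(r"^(?P<feature>\S+) <= (?P<threshold>[-0-9.eE+]+)$")


def parse_dot(dot: str) -> dict:
    """Parse a rendering produced by :func:`render_dot` back to a nested
    dict ``{"feature":..., "threshold":..., "left":..., "right":...}`` (or
    ``{"leaf": label}``).  Used to verify renderings round-trip."""
    labels: Dict[int, str] = {}
    for m in _NODE_RE.finditer(dot):
        labels[int(m.group(1))] = m.group(2)
    children: Dict[int, Dict[str, int]] = {}
    for m in _EDGE_RE.finditer(dot):
        children.setdefault(int(m.group(1)), {})[m.group(3)] = int(m.group(2))

    def build(nid: int) -> dict:
        label = labels[nid]
        split = _SPLIT_RE.match(label)
        if nid in children and split:
            return {
                "feature": split.group("feature"),
                "threshold": float(split.group("threshold")),
                "left": build(children[nid]["true"]),
                "right": build(children[nid]["false"]),
            }
        return {"leaf": label}

    if not labels:
        raise ValueError("no nodes found in DOT input")
    return build(min(labels))


def structure_of(tree: Union[CausalTreeModel, TreeNode, PolicyTreeNode]) -> dict:
    """The same nested-dict view of a live tree, for round-trip checks."""
    root = tree.root if isinstance(tree, CausalTreeModel) else tree

    def walk(node) -> dict:
        if node.is_leaf:
            return {"leaf": _leaf_label(node)}
        return {
            "feature": node.feature,
            "threshold": float(node.threshold),
            "left": walk(node.left),
            "right": walk(node.right),
        }

    return walk(root)
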