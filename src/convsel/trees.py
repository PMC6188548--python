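"""Rooted phylogenetic trees with branch tags.

A small, explicit tree structure tuned for likelihood work: nodes are
stored in a flat list with parent/child indices, every non-root node owns
the branch above it (so "branch i" always means the edge between node i
and its parent), and branches may carry a tag.  Tags use the codon-model
community's Newick convention of a ``#`` suffix (``(A,B)#1:0.1``), with
``#1`` conventionally marking the foreground branch of a branch-site test;
arbitrary tags such as ``#B`` label clade identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the error."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass
class Node:
    index: int
    name: str | None = None
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    length: float = 0.0
    tag: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


class RootedTree:
    """Rooted tree; node 0..n-1 in a flat list, branches identified by child node."""

    def __init__(self, nodes: list[Node], root: int):
        self.nodes = nodes
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        names = [n.name for n in self.nodes if n.is_tip]
        if any(n is None or n == "" for n in names):
            raise ValueError("every tip must be named")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate tip names: {dup}")
        if self.nodes[self.root].parent is not None:
            raise ValueError("root must have no parent")
        for n in self.nodes:
            if not (n.length >= 0.0):  # also catches NaN
                raise ValueError(
                    f"branch length of node {n.index} must be finite and >= 0"
                )

    # -- basic queries ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes if n.is_tip)

    def tip_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.is_tip]

    def tip_index(self) -> dict[str, int]:
        return {n.name: n.index for n in self.nodes if n.is_tip}

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def branch_nodes(self) -> list[int]:
        """All nodes owning a branch (everything but the root), postorder."""
        return [i for i in self.postorder() if i != self.root]

    def node_by_tag(self, tag: str) -> int:
        hits = [n.index for n in self.nodes if n.tag == tag]
        if not hits:
            raise KeyError(f"no branch tagged {tag!r}")
        if len(hits) > 1:
            raise KeyError(f"tag {tag!r} is not unique: nodes {hits}")
        return hits[0]

    def has_tag(self, tag: str) -> bool:
        return any(n.tag == tag for n in self.nodes)

    def subtree_tips(self, index: int) -> list[str]:
        out = []
        stack = [index]
        while stack:
            i = stack.pop()
            node = self.nodes[i]
            if node.is_tip:
                out.append(node.name)
            stack.extend(node.children)
        return out

    def mrca(self, names: list[str]) -> int:
        tips = self.tip_index()
        paths = []
        for name in names:
            if name not in tips:
                raise KeyError(f"tip {name!r} not in tree")
            path = []
            i: int | None = tips[name]
            while i is not None:
                path.append(i)
                i = self.nodes[i].parent
            paths.append(list(reversed(path)))
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if node a lies on the path from b to the root (a != b allowed)."""
        i: int | None = b
        while i is not None:
            if i == a:
                return True
            i = self.nodes[i].parent
        return False

    def path_length(self, name_a: str, name_b: str) -> float:
        tips = self.tip_index()
        anc = self.mrca([name_a, name_b])
        total = 0.0
        for name in (name_a, name_b):
            i = tips[name]
            while i != anc:
                total += self.nodes[i].length
                i = self.nodes[i].parent
        return total

    # -- editing ---------------------------------------------------------
    def copy(self) -> "RootedTree":
        nodes = [
            Node(n.index, n.name, n.parent, list(n.children), n.length, n.tag)
            for n in self.nodes
        ]
        return RootedTree(nodes, self.root)

    def prune_to(self, taxa: set[str] | list[str]) -> "RootedTree":
        """Restrict to the given tips, collapsing unary nodes additively.

        Path lengths between retained tips are preserved exactly; a tag on a
        collapsed-away node is inherited by the surviving branch below it
        (unless that branch already carries its own tag).
        """
        keep_names = set(taxa)
        missing = keep_names - set(self.tip_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        keep = {i for i, n in enumerate(self.nodes) if n.is_tip and n.name in keep_names}
        if len(keep) < 1:
            raise ValueError("cannot prune to an empty taxon set")
        # mark internal nodes with >=1 kept descendant
        needed = set(keep)
        for i in self.postorder():
            node = self.nodes[i]
            if node.children and any(c in needed for c in node.children):
                needed.add(i)

        new_nodes: list[Node] = []
        mapping: dict[int, int] = {}

        def build(old: int) -> int:
            """Return new index for old node, collapsing unary chains."""
            node = self.nodes[old]
            kept_children = [c for c in node.children if c in needed]
            if node.is_tip or len(kept_children) >= 2 or old == self.root:
                idx = len(new_nodes)
                new_nodes.append(Node(idx, node.name, None, [], node.length, node.tag))
                mapping[old] = idx
                for c in kept_children:
                    ci = build(c)
                    new_nodes[ci].parent = idx
                    new_nodes[idx].children.append(ci)
                return idx
            # unary internal node: splice out, child absorbs the length
            ci = build(kept_children[0])
            new_nodes[ci].length += node.length
            if new_nodes[ci].tag is None:
                new_nodes[ci].tag = node.tag
            return ci

        root_new = build(self.root)
        # drop a unary root stub
        while len(new_nodes[root_new].children) == 1:
            child = new_nodes[root_new].children[0]
            new_nodes[child].parent = None
            new_nodes[child].length = 0.0
            root_new = child
        tree = RootedTree.__new__(RootedTree)
        tree.nodes = new_nodes
        tree.root = root_new
        tree._validate()
        return tree._reindexed()

    def _reindexed(self) -> "RootedTree":
        """Compact node indices to 0..n-1 over reachable nodes."""
        order = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.nodes[i].children)
        remap = {old: new for new, old in enumerate(order)}
        nodes = []
        for old in order:
            n = self.nodes[old]
            nodes.append(
                Node(
                    remap[old],
                    n.name,
                    None if n.parent is None else remap[n.parent],
                    [remap[c] for c in n.children],
                    n.length,
                    n.tag,
                )
            )
        return RootedTree(nodes, remap[self.root])

    def with_branch_lengths(self, lengths: dict[int, float]) -> "RootedTree":
        t = self.copy()
        for i, v in lengths.items():
            t.nodes[i].length = float(v)
        return t


# ---------------------------------------------------------------------------
# Newick parsing / writing
# ---------------------------------------------------------------------------

_NAME_END = set("(),:;#")


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string into a RootedTree.

    Supports branch lengths (default 0 when absent) and ``#tag`` branch
    labels on tips and internal nodes.  Malformed input raises
    :class:`NewickError` with the character offset.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick string must end with ';'", len(text))
    nodes: list[Node] = []
    pos = 0

    def new_node() -> int:
        nodes.append(Node(len(nodes)))
        return len(nodes) - 1

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def parse_name() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _NAME_END and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def parse_clade() -> int:
        nonlocal pos
        skip_ws()
        idx = new_node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                nodes[child].parent = idx
                nodes[idx].children.append(child)
                skip_ws()
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses", pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r}", pos)
        name = parse_name()
        if name:
            nodes[idx].name = name
        if pos < len(s) and s[pos] == "#":
            pos += 1
            tag = parse_name()
            if not tag:
                raise NewickError("empty branch tag after '#'", pos)
            nodes[idx].tag = tag
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                nodes[idx].length = float(s[start:pos])
            except ValueError:
                raise NewickError("invalid branch length", start) from None
        if not nodes[idx].children and not nodes[idx].name:
            raise NewickError("unnamed tip", pos)
        return idx

    root = parse_clade()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise NewickError("trailing content before ';'", pos)
    return RootedTree(nodes, root)


def _fmt_length(x: float) -> str:
    return f"{x:.12g}"


def write_newick(tree: RootedTree, lengths: bool = True) -> str:
    """Serialize a RootedTree to Newick, preserving ``#`` branch tags."""

    def render(i: int) -> str:
        node = tree.nodes[i]
        if node.children:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            body += node.name or ""
        else:
            body = node.name
        if node.tag is not None:
            body += f"#{node.tag}"
        if lengths and i != tree.root:
            body += ":" + _fmt_length(node.length)
        return body

    return render(tree.root) + ";"
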