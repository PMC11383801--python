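"""Rooted trees with cross-brace labels and node-age calibrations.

A *braced* tree is a rooted binary tree in which internal nodes may carry

* a brace label ``#k`` marking nodes in different paralogue subtrees that
  represent the same species divergence and must therefore share one age, and
* an age calibration (uniform window with soft or hard bounds, or a
  one-sided minimum/maximum).

The serialized form extends Newick, e.g.::

    (((A1, A2) #1, A3) #2, ((B1, B2) [#1 B{0.2, 0.4}], B3) #2) 'B(0.9,1.1)';

``B{min,max}`` is a two-sided calibration, ``L{min}`` a minimum, ``U{max}``
a maximum; a bracketed group ``[#k B{..}]`` attaches both a label and a
calibration; the root calibration may be quoted in parenthesis form.
Optional third/fourth arguments of ``B`` give the tail probabilities of the
lower/upper bound (0 makes the bound hard); ``L``/``U`` accept one optional
tail probability. Ages are in Ga (1 unit = 10**9 years).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Calibration",
    "Node",
    "BracedTree",
    "BraceMap",
    "BracedNewickError",
    "CalibrationConflictError",
    "parse_braced_newick",
    "write_braced_newick",
    "assign_driver_mirrors",
    "ma_to_ga",
    "ga_to_ma",
]

DEFAULT_TAIL_PROB = 0.025


def ma_to_ga(age_ma: float) -> float:
    """Convert an age in Ma to the internal Ga unit."""
    return age_ma / 1000.0


def ga_to_ma(age_ga: float) -> float:
    return age_ga * 1000.0


class BracedNewickError(ValueError):
    """Malformed braced-Newick input; carries the character position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


class CalibrationConflictError(ValueError):
    """Two braced nodes with one label carry different calibrations."""


@dataclass(frozen=True)
class Calibration:
    """A node-age calibration in Ga.

    ``t_min``/``t_max`` bound the age; either may be absent for a pure
    maximum/minimum.  A *soft* bound lets ``tail_prob`` of the prior mass
    escape beyond it; a *hard* bound allows none.
    """

    t_min: Optional[float] = None
    t_max: Optional[float] = None
    left_soft: bool = True
    right_soft: bool = True
    tail_prob: float = DEFAULT_TAIL_PROB

    def __post_init__(self) -> None:
        if self.t_min is None and self.t_max is None:
            raise ValueError("calibration needs at least one bound")
        if self.t_min is not None and self.t_min < 0:
            raise ValueError(f"t_min must be >= 0, got {self.t_min}")
        if self.t_min is not None and self.t_max is not None:
            if not self.t_min < self.t_max:
                raise ValueError(
                    f"t_min must be < t_max, got ({self.t_min}, {self.t_max})"
                )
        if not 0.0 < self.tail_prob < 0.5:
            raise ValueError(f"tail_prob must be in (0, 0.5), got {self.tail_prob}")

    @property
    def has_min(self) -> bool:
        return self.t_min is not None

    @property
    def has_max(self) -> bool:
        return self.t_max is not None

    def to_token(self, style: str = "brace") -> str:
        """Serialize as ``B{..}``/``L{..}``/``U{..}`` (or parenthesised)."""
        op, cl = ("{", "}") if style == "brace" else ("(", ")")
        lp = self.tail_prob if self.left_soft else 0.0
        rp = self.tail_prob if self.right_soft else 0.0
        if self.has_min and self.has_max:
            args = [self.t_min, self.t_max]
            if (lp, rp) != (DEFAULT_TAIL_PROB, DEFAULT_TAIL_PROB):
                args += [lp, rp]
            return "B" + op + ", ".join(_fmt(a) for a in args) + cl
        if self.has_min:
            args = [self.t_min] + ([lp] if lp != DEFAULT_TAIL_PROB else [])
            return "L" + op + ", ".join(_fmt(a) for a in args) + cl
        args = [self.t_max] + ([rp] if rp != DEFAULT_TAIL_PROB else [])
        return "U" + op + ", ".join(_fmt(a) for a in args) + cl


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest string that round-trips exactly


@dataclass(eq=False)
class Node:
    """One node of a braced tree (tip or internal)."""

    name: Optional[str] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    brace_label: Optional[int] = None
    calibration: Optional[Calibration] = None
    index: int = -1  # postorder index, assigned by BracedTree

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal[{len(self.children)}]"
        return f"<Node {self.name or self.index} {kind}>"


@dataclass
class BraceMap:
    """label -> (driver node, mirror nodes); mirrors alias the driver's age."""

    groups: dict[int, tuple[Node, list[Node]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, label: int) -> bool:
        return label in self.groups

    def driver(self, label: int) -> Node:
        return self.groups[label][0]

    def mirrors(self, label: int) -> list[Node]:
        return self.groups[label][1]

    def driver_of(self, node: Node) -> Node:
        """The node whose age parameter ``node`` aliases (itself if unbraced)."""
        if node.brace_label is None or node.brace_label not in self.groups:
            return node
        return self.groups[node.brace_label][0]

    def items(self):
        return self.groups.items()


class BracedTree:
    """A rooted tree with brace labels, calibrations and a tip->species map.

    Node indices are assigned in postorder (tips first within each clade,
    root last); they are the canonical coordinates used by age vectors,
    priors and trace columns.
    """

    def __init__(
        self,
        root: Node,
        paralogue_of: Optional[dict[str, str]] = None,
    ):
        self.root = root
        self._assign_indices()
        self.paralogue_of = paralogue_of or {}
        self._validate()

    # -- construction ------------------------------------------------

    def _assign_indices(self) -> None:
        self._postorder = list(self.root.postorder())
        for i, node in enumerate(self._postorder):
            node.index = i
            if node.name is None:
                node.name = f"n{i}"

    def _validate(self) -> None:
        for node in self._postorder:
            if len(node.children) == 1:
                raise ValueError(f"unary node {node.name!r} not allowed")
        names = [n.name for n in self.tips()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip names")
        # brace labels: calibrations on one label must agree; singletons warn
        by_label: dict[int, list[Node]] = {}
        for node in self._postorder:
            if node.brace_label is not None:
                by_label.setdefault(node.brace_label, []).append(node)
        for label, nodes in by_label.items():
            calibs = {n.calibration for n in nodes if n.calibration is not None}
            if len(calibs) > 1:
                raise CalibrationConflictError(
                    f"brace label #{label} carries conflicting calibrations; "
                    "that information has to be the same on every braced node"
                )
            if len(nodes) == 1:
                warnings.warn(
                    f"brace label #{label} is attached to a single node; "
                    "treated as unbraced",
                    stacklevel=3,
                )

    # -- traversal ---------------------------------------------------

    def postorder(self) -> list[Node]:
        return list(self._postorder)

    def preorder(self) -> list[Node]:
        return list(self.root.preorder())

    def tips(self) -> list[Node]:
        return [n for n in self._postorder if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self._postorder if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def n_nodes(self) -> int:
        return len(self._postorder)

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def node_by_name(self, name: str) -> Node:
        for n in self._postorder:
            if n.name == name:
                return n
        raise KeyError(name)

    def mrca(self, tip_names: list[str]) -> Node:
        """Most recent common ancestor of a set of tips."""
        want = set(tip_names)
        below: dict[Node, set[str]] = {}
        for n in self._postorder:
            if n.is_tip:
                below[n] = {n.name}
            else:
                below[n] = set().union(*(below[c] for c in n.children))
            if want <= below[n]:
                return n
        raise ValueError(f"tips {tip_names} not all present")

    def brace_labels(self) -> dict[int, list[Node]]:
        out: dict[int, list[Node]] = {}
        for node in self._postorder:
            if node.brace_label is not None:
                out.setdefault(node.brace_label, []).append(node)
        return out

    def copy(self) -> "BracedTree":
        def clone(node: Node) -> Node:
            c = Node(
                name=node.name,
                brace_label=node.brace_label,
                calibration=node.calibration,
            )
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return BracedTree(clone(self.root), dict(self.paralogue_of))

    # -- comparison --------------------------------------------------

    def same_as(self, other: "BracedTree") -> bool:
        """Structural equality: topology, tip names, labels, calibrations."""

        def key(node: Node):
            if node.is_tip:
                return (node.name, node.brace_label, node.calibration)
            child_keys = tuple(sorted((key(c) for c in node.children), key=repr))
            return (child_keys, node.brace_label, node.calibration)

        return key(self.root) == key(other.root)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[A-Za-z0-9_.\-|/]+")
_NUM_RE = re.compile(r"[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?")


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str) -> BracedNewickError:
        return BracedNewickError(message, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, ch: str) -> None:
        self.skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != ch:
            raise self.error(f"expected {ch!r}")
        self.pos += 1

    def match(self, ch: str) -> bool:
        if self.peek() == ch:
            self.pos += 1
            return True
        return False

    def name(self) -> str:
        self.skip_ws()
        m = _NAME_RE.match(self.text, self.pos)
        if not m:
            raise self.error("expected a name")
        self.pos = m.end()
        return m.group()

    def number(self) -> float:
        self.skip_ws()
        m = _NUM_RE.match(self.text, self.pos)
        if not m:
            raise self.error("expected a number")
        self.pos = m.end()
        return float(m.group())


def _parse_calib_args(
    sc: _Scanner, kind: str, open_ch: str, close_ch: str
) -> Calibration:
    sc.take(open_ch)
    args = [sc.number()]
    while sc.match(","):
        args.append(sc.number())
    sc.take(close_ch)
    if kind == "B":
        if len(args) < 2 or len(args) > 4:
            raise sc.error("B calibration takes 2-4 arguments")
        lp = args[2] if len(args) > 2 else DEFAULT_TAIL_PROB
        rp = args[3] if len(args) > 3 else DEFAULT_TAIL_PROB
        tail = max(lp, rp)
        if tail == 0.0:
            tail = DEFAULT_TAIL_PROB  # placeholder; both bounds hard
        return Calibration(
            t_min=args[0],
            t_max=args[1],
            left_soft=lp > 0,
            right_soft=rp > 0,
            tail_prob=tail,
        )
    if len(args) > 2:
        raise sc.error(f"{kind} calibration takes 1-2 arguments")
    p = args[1] if len(args) > 1 else DEFAULT_TAIL_PROB
    soft = p > 0
    if not soft:
        p = DEFAULT_TAIL_PROB
    if kind == "L":
        return Calibration(t_min=args[0], left_soft=soft, tail_prob=p)
    return Calibration(t_max=args[0], right_soft=soft, tail_prob=p)


def _parse_annotations(sc: _Scanner, node: Node) -> None:
    """Consume any sequence of ``#k``, ``B{..}``-style tokens and ``[..]``
    or quoted groups following a clade."""

    def set_label(label: int) -> None:
        if node.brace_label is not None and node.brace_label != label:
            raise sc.error(
                f"node carries two brace labels (#{node.brace_label}, #{label}); "
                "one node cannot have two or more labels"
            )
        node.brace_label = label

    def set_calib(c: Calibration) -> None:
        if node.calibration is not None and node.calibration != c:
            raise sc.error("node carries two different calibrations")
        node.calibration = c

    while True:
        ch = sc.peek()
        if ch == "#":
            sc.take("#")
            set_label(int(sc.number()))
        elif ch in "BLU" and sc.text[sc.pos + 1 : sc.pos + 2] == "{":
            kind = ch
            sc.pos += 1
            set_calib(_parse_calib_args(sc, kind, "{", "}"))
        elif ch == "[":
            sc.take("[")
            while sc.peek() != "]":
                inner = sc.peek()
                if inner == "#":
                    sc.take("#")
                    set_label(int(sc.number()))
                elif inner in "BLU":
                    kind = inner
                    sc.pos += 1
                    open_ch = sc.peek()
                    if open_ch not in "{(":
                        raise sc.error("expected '{' or '(' after calibration type")
                    close_ch = "}" if open_ch == "{" else ")"
                    set_calib(_parse_calib_args(sc, kind, open_ch, close_ch))
                else:
                    raise sc.error(f"unexpected token {inner!r} in bracket group")
            sc.take("]")
        elif ch == "'":
            sc.take("'")
            kind = sc.peek()
            if kind not in "BLU":
                raise sc.error("expected B/L/U calibration inside quotes")
            sc.pos += 1
            open_ch = sc.peek()
            if open_ch not in "{(":
                raise sc.error("expected '{' or '(' after calibration type")
            close_ch = "}" if open_ch == "{" else ")"
            set_calib(_parse_calib_args(sc, kind, open_ch, close_ch))
            sc.take("'")
        else:
            return


def _parse_clade(sc: _Scanner) -> Node:
    if sc.peek() == "(":
        sc.take("(")
        node = Node()
        node.add_child(_parse_clade(sc))
        while sc.match(","):
            node.add_child(_parse_clade(sc))
        sc.take(")")
        if len(node.children) < 2:
            raise sc.error("internal node needs >= 2 children")
        if sc.peek() and _NAME_RE.match(sc.text, sc.pos) and sc.peek() not in "BLU":
            node.name = sc.name()
    else:
        node = Node(name=sc.name())
    _parse_annotations(sc, node)
    return node


def parse_braced_newick(
    text: str,
    paralogue_of: Optional[dict[str, str]] = None,
    time_unit: str = "Ga",
) -> BracedTree:
    """Parse a braced-Newick string into a :class:`BracedTree`.

    ``time_unit`` declares the unit of calibration ages in the input
    (``"Ga"`` or ``"Ma"``); ages are converted to Ga internally.
    """
    if time_unit not in ("Ga", "Ma"):
        raise ValueError(f"time_unit must be 'Ga' or 'Ma', got {time_unit!r}")
    sc = _Scanner(text)
    root = _parse_clade(sc)
    sc.match(";")
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise sc.error("trailing characters after tree")
    tree = BracedTree(root, paralogue_of)
    if time_unit == "Ma":
        for node in tree.postorder():
            c = node.calibration
            if c is not None:
                node.calibration = Calibration(
                    t_min=None if c.t_min is None else ma_to_ga(c.t_min),
                    t_max=None if c.t_max is None else ma_to_ga(c.t_max),
                    left_soft=c.left_soft,
                    right_soft=c.right_soft,
                    tail_prob=c.tail_prob,
                )
    return tree


def write_braced_newick(tree: BracedTree, include_names: bool = False) -> str:
    """Serialize a braced tree back to the extended Newick form."""

    def render(node: Node) -> str:
        if node.is_tip:
            s = node.name
        else:
            s = "(" + ", ".join(render(c) for c in node.children) + ")"
            if include_names:
                s += node.name
        ann = []
        if node is tree.root and node.calibration is not None:
            ann.append("'" + node.calibration.to_token("paren") + "'")
            if node.brace_label is not None:
                ann.insert(0, f"#{node.brace_label}")
        elif node.brace_label is not None and node.calibration is not None:
            ann.append(
                f"[#{node.brace_label} {node.calibration.to_token('brace')}]"
            )
        elif node.brace_label is not None:
            ann.append(f"#{node.brace_label}")
        elif node.calibration is not None:
            ann.append(node.calibration.to_token("brace"))
        if ann:
            s += " " + " ".join(ann)
        return s

    return render(tree.root) + ";"


def assign_driver_mirrors(tree: BracedTree) -> BraceMap:
    """Choose a driver node per brace label; all others become mirrors.

    The driver is the first node carrying the label in preorder.  Any
    calibration attached to a braced node is propagated to the driver (the
    tree validator has already enforced that calibrations on one label
    agree).  Labels attached to a single node yield no group.
    """
    groups: dict[int, tuple[Node, list[Node]]] = {}
    seen: dict[int, list[Node]] = {}
    for node in tree.preorder():
        if node.brace_label is not None:
            seen.setdefault(node.brace_label, []).append(node)
    for label, nodes in seen.items():
        if len(nodes) < 2:
            continue  # validated with a warning upstream; treated as unbraced
        driver, mirrors = nodes[0], nodes[1:]
        calib = next((n.calibration for n in nodes if n.calibration is not None), None)
        if calib is not None and driver.calibration is None:
            driver.calibration = calib
        groups[label] = (driver, mirrors)
    return BraceMap(groups)
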