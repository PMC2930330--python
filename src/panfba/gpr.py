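"""Gene-protein-reaction (GPR) boolean rules.

A GPR is a boolean tree over gene identifiers.  AND nodes model enzyme
complexes (every subunit required), OR nodes model isozymes (any one
suffices).  An empty rule means the reaction is not gene-associated and is
always active.

Rules are parsed from the usual infix notation, e.g.::

    (cbdb_0123 and cbdb_0124) or det_0456

``and``/``or`` are case-insensitive; parentheses group.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GPRParseError(ValueError):
    """Raised for malformed GPR rule strings."""


@dataclass(frozen=True)
class GPRNode:
    """One node of a GPR tree: an AND/OR operator or a gene leaf."""

    op: str  # "and", "or", or "gene"
    gene: str | None = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def is_active(self, knocked_out: frozenset[str] | set[str]) -> bool:
        if self.op == "gene":
            return self.gene not in knocked_out
        if self.op == "and":
            return all(c.is_active(knocked_out) for c in self.children)
        return any(c.is_active(knocked_out) for c in self.children)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


@dataclass(frozen=True)
class GPR:
    """A full GPR association; ``root is None`` means non-gene-associated."""

    root: GPRNode | None = None

    @classmethod
    def from_string(cls, rule: str | None) -> "GPR":
        if rule is None or not rule.strip():
            return cls(None)
        tokens = _tokenize(rule)
        node, pos = _parse_or(tokens, 0)
        if pos != len(tokens):
            raise GPRParseError(f"trailing tokens in GPR rule: {rule!r}")
        return cls(node)

    @property
    def empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def is_active(self, knocked_out: set[str] | frozenset[str]) -> bool:
        """Evaluate the rule with the given genes removed.

        AND = all children active, OR = any child active; an empty rule is
        always active.
        """
        if self.root is None:
            return True
        return self.root.is_active(frozenset(knocked_out))

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    cur = ""
    for ch in rule:
        if ch in "()":
            if cur:
                tokens.append(cur)
                cur = ""
            tokens.append(ch)
        elif ch.isspace():
            if cur:
                tokens.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    return tokens


def _parse_or(tokens: list[str], pos: int) -> tuple[GPRNode, int]:
    node, pos = _parse_and(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "or":
        nxt, pos = _parse_and(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return GPRNode("or", children=tuple(children)), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[GPRNode, int]:
    node, pos = _parse_atom(tokens, pos)
    children = [node]
    while pos < len(tokens) and tokens[pos].lower() == "and":
        nxt, pos = _parse_atom(tokens, pos + 1)
        children.append(nxt)
    if len(children) == 1:
        return node, pos
    return GPRNode("and", children=tuple(children)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GPRNode, int]:
    if pos >= len(tokens):
        raise GPRParseError("unexpected end of GPR rule")
    tok = tokens[pos]
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GPRParseError("unbalanced parentheses in GPR rule")
        return node, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRParseError(f"unexpected token {tok!r} in GPR rule")
    return GPRNode("gene", gene=tok), pos + 1


def evaluate_gpr(gpr: GPR | str | None, knocked_out: set[str]) -> bool:
    """Convenience wrapper: is the reaction active under these knockouts?"""
    if not isinstance(gpr, GPR):
        gpr = GPR.from_string(gpr)
    return gpr.is_active(knocked_out)
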