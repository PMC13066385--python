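"""Gene-protein-reaction (GPR) boolean rules and reaction expression scoring.

A GPR rule is a boolean expression over gene identifiers (e.g.
``(HADHA and HADHB) or ACAA2``) describing which gene products enable a
metabolic reaction.  Reaction expression is estimated by substituting
``OR -> max`` and ``AND -> min`` over the genes' expression values, here
taken from deconvoluted compartment profiles so reactions can be scored
separately for cancer and stroma in each cohort.

Genes absent from the expression map are dropped from their parent
operator's operand list (for min as well as max); a node whose operands are
all missing evaluates to NA and propagates.  A strict mode instead lets a
missing operand poison AND to NA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .datatypes import CompartmentProfile

# Expression tree: a leaf is a gene id string; an internal node is
# ("and"|"or", (child, child, ...)) with same-operator children flattened,
# so equal rules compare equal regardless of associativity grouping.
Node = Union[str, tuple]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GPRSyntaxError(ValueError):
    """Malformed GPR rule text, with the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRRule:
    reaction_id: str
    tree: Node
    subsystem: str = ""

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(_iter_leaves(self.tree))

    def canonical(self) -> str:
        return _to_string(self.tree)


def _iter_leaves(node: Node):
    if isinstance(node, str):
        yield node
    else:
        for child in node[1]:
            yield from _iter_leaves(child)


def _to_string(node: Node, parent_op: str | None = None) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    joined = f" {op} ".join(_to_string(c, op) for c in children)
    # an OR under an AND must keep its parentheses (AND binds tighter)
    if parent_op == "and" and op == "or":
        return f"({joined})"
    return joined


def _flatten(op: str, children: list[Node]) -> Node:
    if len(children) == 1:
        return children[0]
    flat: list[Node] = []
    for c in children:
        if isinstance(c, tuple) and c[0] == op:
            flat.extend(c[1])
        else:
            flat.append(c)
    return (op, tuple(flat))


def parse_gpr(rule_text: str, reaction_id: str = "", subsystem: str = "") -> GPRRule:
    """Parse GPR rule text into a :class:`GPRRule`.

    Grammar: ``expr := term ("or" term)*``, ``term := factor ("and" factor)*``,
    ``factor := GENE | "(" expr ")"``.  AND binds tighter than OR; operator
    keywords are case-insensitive; any other token is a gene identifier.
    """
    tokens = [(m.group(), m.start()) for m in _TOKEN_RE.finditer(rule_text)]
    if not tokens:
        raise GPRSyntaxError("empty rule", 0)
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> Node:
        terms = [parse_term()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            advance()
            terms.append(parse_term())
        return _flatten("or", terms)

    def parse_term() -> Node:
        factors = [parse_factor()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            advance()
            factors.append(parse_factor())
        return _flatten("and", factors)

    def parse_factor() -> Node:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError("dangling operator: expected gene or '('",
                                 len(rule_text))
        text, at = advance()
        if text == "(":
            inner = parse_expr()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRSyntaxError("unbalanced parentheses: missing ')'", at)
            advance()
            return inner
        if text == ")":
            raise GPRSyntaxError("unbalanced parentheses: unexpected ')'", at)
        if text.lower() in ("and", "or"):
            raise GPRSyntaxError(f"dangling operator {text!r}", at)
        return text

    tree = parse_expr()
    if (tok := peek()) is not None:
        raise GPRSyntaxError(f"unexpected token {tok[0]!r}", tok[1])
    return GPRRule(reaction_id=reaction_id, tree=tree, subsystem=subsystem)


def evaluate_gpr(
    rule: GPRRule, expr_of: Mapping[str, float], strict_and: bool = False
) -> float:
    """Evaluate a rule with OR -> max and AND -> min over gene expression.

    Missing genes are dropped from their parent's operand list; a node with
    all operands missing yields NaN and is dropped in turn.  With
    ``strict_and`` a single missing AND operand makes the node NaN.
    """
    def ev(node: Node) -> float | None:
        if isinstance(node, str):
            v = expr_of.get(node)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
        op, children = node
        vals = [ev(c) for c in children]
        if strict_and and op == "and" and any(v is None for v in vals):
            return None
        present = [v for v in vals if v is not None]
        if not present:
            return None
        return max(present) if op == "or" else min(present)

    result = ev(rule.tree)
    return float("nan") if result is None else result


def missing_leaf_count(rule: GPRRule, expr_of: Mapping[str, float]) -> int:
    return sum(
        1 for g in rule.leaves
        if g not in expr_of or (isinstance(expr_of[g], float) and np.isnan(expr_of[g]))
    )


def rules_from_table(table: pd.DataFrame) -> list[GPRRule]:
    """Parse a reaction_id / subsystem / rule table into GPRRule objects."""
    return [
        parse_gpr(row["rule"], reaction_id=str(row["reaction_id"]),
                  subsystem=str(row.get("subsystem", "") or ""))
        for _, row in table.iterrows()
    ]


def score_reactions(
    rules: list[GPRRule],
    profile: CompartmentProfile,
    groups: tuple[str, str] | None = None,
    strict_and: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score every reaction per (group, compartment) from a compartment profile.

    Returns the long-format score table (reaction x group x compartment,
    with the count of missing genes per reaction) and, when ``groups``
    names two profile groups, a differential table of group2 - group1
    scores per compartment.  Scores are on the profile's stored scale,
    recorded in the table's ``scale`` attribute.
    """
    if not rules:
        raise ValueError("empty rule set")
    rows = []
    for group_name in profile.groups:
        grp = profile.group(group_name)
        for compartment, col in (("cancer", "e_c"), ("stroma", "e_s")):
            expr_of = grp[col].to_dict()
            for rule in rules:
                rows.append({
                    "reaction_id": rule.reaction_id,
                    "subsystem": rule.subsystem,
                    "group": group_name,
                    "compartment": compartment,
                    "score": evaluate_gpr(rule, expr_of, strict_and=strict_and),
                    "n_missing_genes": missing_leaf_count(rule, expr_of),
                })
    scores = pd.DataFrame(rows)
    scores.attrs["scale"] = profile.scale

    diff = None
    if groups is not None:
        g1, g2 = groups
        wide = scores.pivot_table(
            index=["reaction_id", "subsystem", "compartment"],
            columns="group", values="score", aggfunc="first", dropna=False,
        )
        diff = (wide[g2] - wide[g1]).rename("score_diff").reset_index()
        diff.attrs["scale"] = profile.scale
    return scores, diff
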