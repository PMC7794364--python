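"""Gene-protein-reaction (GPR) rule parsing and evaluation.

Grammar: infix boolean over bare gene symbols with ``and`` / ``or``
(case-insensitive) and parentheses.  ``and`` binds tighter than ``or``.
Under the usual semantics, ``and`` joins subunits of one complex (all
required) and ``or`` joins isozymes (any suffices), so a reaction is
available iff its rule evaluates true when functional genes are true.
"""

from __future__ import annotations

import re
from typing import Iterable

__all__ = ["genes_in_rule", "evaluate_gpr", "GPRSyntaxError"]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GPRSyntaxError(ValueError):
    """Malformed GPR expression."""


def _tokenize(rule: str) -> list[str]:
    return _TOKEN.findall(rule)


def genes_in_rule(rule: str) -> set[str]:
    """All gene symbols appearing in a rule (empty rule -> empty set)."""
    return {
        tok for tok in _tokenize(rule)
        if tok not in "()" and tok.lower() not in ("and", "or")
    }


def evaluate_gpr(rule: str, inactive_genes: Iterable[str]) -> bool:
    """Evaluate a GPR with the given genes switched off.

    Every gene not listed in ``inactive_genes`` is treated as functional
    (true).  An empty rule evaluates true: a reaction without gene
    association cannot be impaired by a mutation.

    Returns True if the reaction remains catalyzed, False if the gene
    losses disable it.
    """
    rule = rule.strip()
    if not rule:
        return True
    inactive = set(inactive_genes)
    tokens = _tokenize(rule)
    result, pos = _parse_or(tokens, 0, inactive)
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR {rule!r}")
    return result


def _parse_or(tokens: list[str], pos: int, inactive: set[str]) -> tuple[bool, int]:
    value, pos = _parse_and(tokens, pos, inactive)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        rhs, pos = _parse_and(tokens, pos + 1, inactive)
        value = value or rhs
    return value, pos


def _parse_and(tokens: list[str], pos: int, inactive: set[str]) -> tuple[bool, int]:
    value, pos = _parse_atom(tokens, pos, inactive)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        rhs, pos = _parse_atom(tokens, pos + 1, inactive)
        value = value and rhs
    return value, pos


def _parse_atom(tokens: list[str], pos: int, inactive: set[str]) -> tuple[bool, int]:
    if pos >= len(tokens):
        raise GPRSyntaxError("unexpected end of GPR expression")
    tok = tokens[pos]
    if tok == "(":
        value, pos = _parse_or(tokens, pos + 1, inactive)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GPRSyntaxError("unbalanced parentheses in GPR")
        return value, pos + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GPRSyntaxError(f"unexpected token {tok!r} in GPR")
    return tok not in inactive, pos + 1
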