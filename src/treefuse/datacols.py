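"""Expression-based computed columns, filtering, and column management.

Expressions are evaluated independently per branch over that branch's own
annotation values — there are no parent/child references, so evaluation
order over the tree can never matter.  Missing is contagious: any missing
operand makes the result missing, except inside ``isMissing`` (which tests
for it) and ``if`` (which selects lazily once its condition is known).
Division by zero, ``log``/``log10`` of a non-positive number and ``sqrt``
of a negative one yield missing rather than an error, so a single bad cell
cannot abort a whole-tree calculation.

Grammar (infix, ``^`` right-associative, ``round`` half-away-from-zero)::

    expr    := cmp
    cmp     := add (("<"|"<="|">"|">="|"=="|"!=") add)?
    add     := mul (("+"|"-") mul)*
    mul     := unary (("*"|"/") unary)*
    unary   := "-" unary | pow
    pow     := atom ("^" unary)?
    atom    := NUMBER | "pi" | "e" | col("id") | FUNC "(" args ")" | "(" expr ")"

Functions: ``min``, ``max``, ``abs``, ``round``, ``sqrt``, ``log`` (natural),
``log10``, ``exp``, ``if(cond, a, b)``, ``isMissing(x)``.
Text columns are not valid operands; only ``isMissing`` accepts them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Union

from .model import HIDDEN, NUMERIC, ColumnError, Node, Tree

__all__ = [
    "ExpressionError",
    "Expression",
    "parse",
    "evaluate_column",
    "filter_branches",
    "copy_column",
    "delete_column",
    "set_visibility",
]


class ExpressionError(ValueError):
    """Parse or validation failure, with character position where known."""

    def __init__(self, message: str, pos: Optional[int] = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


# -- AST --------------------------------------------------------------------

@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Const:
    name: str  # "pi" | "e"


@dataclass(frozen=True)
class Col:
    id: str


@dataclass(frozen=True)
class Unary:
    op: str
    operand: "Expression"


@dataclass(frozen=True)
class Bin:
    op: str
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class Call:
    name: str
    args: tuple


Expression = Union[Num, Const, Col, Unary, Bin, Call]

_CONSTANTS = {"pi": math.pi, "e": math.e}
_FUNCTIONS = {"min": (2, None), "max": (2, None), "abs": (1, 1),
              "round": (1, 2), "sqrt": (1, 1), "log": (1, 1),
              "log10": (1, 1), "exp": (1, 1), "if": (3, 3),
              "isMissing": (1, 1)}

_TOKEN_RE = re.compile(r"""
    (?P<num>\d+\.?\d*([eE][+-]?\d+)?|\.\d+([eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z_0-9]*)
  | (?P<str>"[^"]*")
  | (?P<op><=|>=|==|!=|[-+*/^<>(),])
  | (?P<ws>\s+)
""", re.VERBOSE)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            tokens.append((m.lastgroup, m.group(), pos))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, text, pos = self.next()
        if text != value:
            raise ExpressionError(f"expected {value!r}, found {text or 'end'!r}",
                                  pos)

    def parse(self) -> Expression:
        node = self.cmp()
        kind, text, pos = self.peek()
        if kind != "end":
            raise ExpressionError(f"unexpected trailing {text!r}", pos)
        return node

    def cmp(self) -> Expression:
        left = self.add()
        kind, text, _ = self.peek()
        if text in ("<", "<=", ">", ">=", "==", "!="):
            self.next()
            return Bin(text, left, self.add())
        return left

    def add(self) -> Expression:
        node = self.mul()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = Bin(op, node, self.mul())
        return node

    def mul(self) -> Expression:
        node = self.unary()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = Bin(op, node, self.unary())
        return node

    def unary(self) -> Expression:
        if self.peek()[1] == "-":
            self.next()
            return Unary("-", self.unary())
        return self.power()

    def power(self) -> Expression:
        base = self.atom()
        if self.peek()[1] == "^":
            self.next()
            return Bin("^", base, self.unary())  # right-associative
        return base

    def atom(self) -> Expression:
        kind, text, pos = self.next()
        if kind == "num":
            return Num(float(text))
        if text == "(":
            node = self.cmp()
            self.expect(")")
            return node
        if kind == "name":
            if text in _CONSTANTS:
                return Const(text)
            if text == "col":
                self.expect("(")
                skind, stext, spos = self.next()
                if skind != "str":
                    raise ExpressionError(
                        'col() takes a double-quoted column id', spos)
                self.expect(")")
                return Col(stext[1:-1])
            if text in _FUNCTIONS:
                lo, hi = _FUNCTIONS[text]
                self.expect("(")
                args = [self.cmp()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.cmp())
                self.expect(")")
                if len(args) < lo or (hi is not None and len(args) > hi):
                    raise ExpressionError(
                        f"{text}() takes {lo}"
                        + ("" if hi == lo else f"..{hi if hi else 'n'}")
                        + f" arguments, got {len(args)}", pos)
                return Call(text, tuple(args))
            raise ExpressionError(f"unknown name {text!r}", pos)
        raise ExpressionError(f"unexpected {text or 'end of expression'!r}", pos)


def parse(text: str) -> Expression:
    """Parse an expression string into its syntax tree."""
    return _Parser(text).parse()


def format_expression(node: Expression) -> str:
    """Canonical (fully parenthesized) text; reparses to an identical tree."""
    if isinstance(node, Num):
        v = node.value
        return str(int(v)) if v.is_integer() else repr(v)
    if isinstance(node, Const):
        return node.name
    if isinstance(node, Col):
        return f'col("{node.id}")'
    if isinstance(node, Unary):
        return f"(-{format_expression(node.operand)})"
    if isinstance(node, Bin):
        return (f"({format_expression(node.left)} {node.op} "
                f"{format_expression(node.right)})")
    if isinstance(node, Call):
        return (node.name + "("
                + ", ".join(format_expression(a) for a in node.args) + ")")
    raise TypeError(f"not an expression node: {node!r}")


def column_references(node: Expression) -> set:
    """All column ids referenced anywhere in the expression."""
    if isinstance(node, Col):
        return {node.id}
    if isinstance(node, Unary):
        return column_references(node.operand)
    if isinstance(node, Bin):
        return column_references(node.left) | column_references(node.right)
    if isinstance(node, Call):
        out: set = set()
        for a in node.args:
            out |= column_references(a)
        return out
    return set()


def _validate(tree: Tree, node: Expression, inside_is_missing=False) -> None:
    if isinstance(node, Col):
        col = tree.column(node.id)  # undeclared -> ColumnError
        if col.value_type != NUMERIC and not inside_is_missing:
            raise ColumnError(
                f"column {node.id!r} is text; only isMissing accepts it")
    elif isinstance(node, Unary):
        _validate(tree, node.operand)
    elif isinstance(node, Bin):
        _validate(tree, node.left)
        _validate(tree, node.right)
    elif isinstance(node, Call):
        if node.name == "isMissing":
            _validate(tree, node.args[0], inside_is_missing=True)
        else:
            for a in node.args:
                _validate(tree, a)


def _truthy(v) -> bool:
    return bool(v) if isinstance(v, bool) else v != 0


def _round_half_away(x: float, digits: float = 0.0) -> float:
    d = int(digits)
    scale = 10.0 ** d
    y = x * scale
    y = math.floor(y + 0.5) if y >= 0 else math.ceil(y - 0.5)
    return y / scale


def _eval(node: Expression, annotations: dict):
    """Evaluate against one branch's annotation map; None means missing."""
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Const):
        return _CONSTANTS[node.name]
    if isinstance(node, Col):
        return annotations.get(node.id)
    if isinstance(node, Unary):
        v = _eval(node.operand, annotations)
        return None if v is None else -v
    if isinstance(node, Bin):
        left = _eval(node.left, annotations)
        right = _eval(node.right, annotations)
        if left is None or right is None:
            return None
        op = node.op
        if op == "+":
            return left + right
        if op == "-":
            return left - right
        if op == "*":
            return left * right
        if op == "/":
            return None if right == 0 else left / right
        if op == "^":
            try:
                r = left ** right
            except (OverflowError, ValueError, ZeroDivisionError):
                return None
            return None if isinstance(r, complex) else r
        if op == "<":
            return left < right
        if op == "<=":
            return left <= right
        if op == ">":
            return left > right
        if op == ">=":
            return left >= right
        if op == "==":
            return left == right
        if op == "!=":
            return left != right
    if isinstance(node, Call):
        name = node.name
        if name == "isMissing":
            return _eval(node.args[0], annotations) is None
        if name == "if":
            cond = _eval(node.args[0], annotations)
            if cond is None:
                return None
            chosen = node.args[1] if _truthy(cond) else node.args[2]
            return _eval(chosen, annotations)
        vals = [_eval(a, annotations) for a in node.args]
        if any(v is None for v in vals):
            return None
        if name == "min":
            return min(vals)
        if name == "max":
            return max(vals)
        if name == "abs":
            return abs(vals[0])
        if name == "round":
            return _round_half_away(*vals)
        if name == "sqrt":
            return math.sqrt(vals[0]) if vals[0] >= 0 else None
        if name == "log":
            return math.log(vals[0]) if vals[0] > 0 else None
        if name == "log10":
            return math.log10(vals[0]) if vals[0] > 0 else None
        if name == "exp":
            try:
                return math.exp(vals[0])
            except OverflowError:
                return None
    raise TypeError(f"not an expression node: {node!r}")


def _as_ast(expr) -> Expression:
    return parse(expr) if isinstance(expr, str) else expr


def evaluate_column(tree: Tree, target_id: str,
                    expr: Union[str, Expression]) -> Tree:
    """Evaluate ``expr`` on every branch, storing results in ``target_id``.

    The target is auto-declared as a hidden numeric column if absent.  All
    referenced columns are checked before any value is written."""
    ast = _as_ast(expr)
    _validate(tree, ast)
    if target_id not in tree.columns:
        tree.declare_column(target_id, HIDDEN, NUMERIC)
    elif tree.columns[target_id].value_type != NUMERIC:
        raise ColumnError(f"target column {target_id!r} is not numeric")
    results = []
    for nd in tree.nodes():
        v = _eval(ast, nd.branch.annotations)
        if isinstance(v, bool):
            v = float(v)
        results.append((nd, v))
    for nd, v in results:
        tree.set_annotation(nd, target_id, v)
    return tree


def filter_branches(tree: Tree, predicate: Union[str, Expression]) -> list:
    """Nodes whose branch satisfies the predicate; a missing predicate value
    excludes the branch."""
    ast = _as_ast(predicate)
    _validate(tree, ast)
    out = []
    for nd in tree.nodes():
        v = _eval(ast, nd.branch.annotations)
        if v is not None and _truthy(v):
            out.append(nd)
    return out


def copy_column(tree: Tree, src_id: str, dst_id: str,
                kind: Optional[str] = None) -> Tree:
    """Duplicate values and type of ``src_id`` into a new column ``dst_id``."""
    src = tree.column(src_id)
    tree.declare_column(dst_id, kind or src.kind, src.value_type)
    for nd in tree.nodes():
        v = nd.branch.annotations.get(src_id)
        if v is not None:
            nd.branch.annotations[dst_id] = v
    return tree


def delete_column(tree: Tree, column_id: str) -> Tree:
    """Remove the declaration and every stored value of the column."""
    tree.column(column_id)
    del tree.columns[column_id]
    for nd in tree.nodes():
        nd.branch.annotations.pop(column_id, None)
    return tree


def set_visibility(tree: Tree, column_id: str, visible: bool) -> Tree:
    tree.column(column_id).kind = "visible" if visible else "hidden"
    return tree
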