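"""Safe compilation of user-written model equations.

Expressions are parsed with the Python ``ast`` module and evaluated against
a whitelist of symbols and operators, so arbitrary code can never run.
Symbols: ``f1..fm`` (mixing fractions), ``S1..Sm`` (source signatures,
per-signature vectors), declared auxiliary parameter names, declared
auxiliary variable names.  Functions: ``ln``/``log`` (natural), ``exp``,
``sqrt``.  Operators: ``+ - * / **`` and unary minus.
"""

from __future__ import annotations

import ast

import numpy as np

from .model_core import ModelEquation

_FUNCTIONS = {"ln": np.log, "log": np.log, "exp": np.exp, "sqrt": np.sqrt}

_BINOPS = {
    ast.Add: np.add,
    ast.Sub: np.subtract,
    ast.Mult: np.multiply,
    ast.Div: np.true_divide,
    ast.Pow: np.power,
}


class ExpressionError(ValueError):
    """Raised when a model expression cannot be parsed or references
    unknown symbols; the message names the offending token."""


class ExpressionEquation(ModelEquation):
    """Model equation compiled from an arithmetic expression string."""

    def __init__(self, expr: str, m: int, param_names=(), var_names=()):
        self.expr = expr
        self.m = int(m)
        self.param_names = tuple(param_names)
        self.var_names = tuple(var_names)
        self.name = f"expression({expr})"
        try:
            tree = ast.parse(expr, mode="eval")
        except SyntaxError as e:
            raise ExpressionError(f"syntax error in model expression at {e.text!r}") from None
        self._validate(tree.body)
        self._tree = tree.body

    # -- validation -----------------------------------------------------------

    def _known_symbols(self) -> set[str]:
        syms = {f"f{j + 1}" for j in range(self.m)} | {f"S{j + 1}" for j in range(self.m)}
        return syms | set(self.param_names) | set(self.var_names) | set(_FUNCTIONS)

    def _validate(self, node: ast.AST) -> None:
        known = self._known_symbols()
        for sub in ast.walk(node):
            if isinstance(sub, ast.Name):
                if sub.id not in known:
                    raise ExpressionError(f"unknown symbol {sub.id!r} in model expression")
            elif isinstance(sub, ast.Call):
                if not isinstance(sub.func, ast.Name) or sub.func.id not in _FUNCTIONS:
                    raise ExpressionError("only ln/log/exp/sqrt function calls are allowed")
                if sub.keywords or len(sub.args) != 1:
                    raise ExpressionError(
                        f"function {getattr(sub.func, 'id', '?')!r} takes one positional argument"
                    )
            elif isinstance(sub, ast.Constant):
                if not isinstance(sub.value, (int, float)):
                    raise ExpressionError(f"unsafe literal {sub.value!r} in model expression")
            elif isinstance(sub, ast.BinOp):
                if type(sub.op) not in _BINOPS:
                    raise ExpressionError(
                        f"operator {type(sub.op).__name__!r} is not allowed"
                    )
            elif isinstance(sub, ast.UnaryOp):
                if not isinstance(sub.op, (ast.USub, ast.UAdd)):
                    raise ExpressionError(
                        f"operator {type(sub.op).__name__!r} is not allowed"
                    )
            elif not isinstance(sub, (ast.Expression, ast.Load, ast.operator, ast.unaryop)):
                raise ExpressionError(
                    f"construct {type(sub).__name__!r} is not allowed in model expressions"
                )

    # -- evaluation -----------------------------------------------------------

    def mu(self, f, r, S, params):
        f = np.asarray(f, dtype=float)
        S = np.asarray(S, dtype=float)
        env: dict[str, np.ndarray] = {}
        for j in range(self.m):
            env[f"f{j + 1}"] = f[:, j, None]  # (N, 1)
            env[f"S{j + 1}"] = S[j][None, :]  # (1, n)
        for name in self.param_names:
            env[name] = np.asarray(params[name], dtype=float)
        for name in self.var_names:
            env[name] = np.asarray(r[name], dtype=float)[:, None]
        out = self._eval(self._tree, env)
        return np.broadcast_to(out, (f.shape[0], S.shape[1])).copy()

    def _eval(self, node, env):
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            return env[node.id]
        if isinstance(node, ast.BinOp):
            return _BINOPS[type(node.op)](self._eval(node.left, env),
                                          self._eval(node.right, env))
        if isinstance(node, ast.UnaryOp):
            val = self._eval(node.operand, env)
            return -val if isinstance(node.op, ast.USub) else +val
        if isinstance(node, ast.Call):
            return _FUNCTIONS[node.func.id](self._eval(node.args[0], env))
        raise ExpressionError(f"construct {type(node).__name__!r} is not allowed")
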