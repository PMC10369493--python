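"""A small textual language for equilibrium-constant expressions.

Grammar (whitespace-free):

==========================  ==================================================
``K[1+2]``                  elementary association of an i-mer and a j-mer
``K[1+1+2]``                concerted higher-order-body association
``K[1+1]*K[1+2]``           reaction path: product of elementary constants
``Kprime[3]``               uncorrelated (mean-concentration) constant K'_m
``Ktrans[1+3=2+2]``         transfer reaction, correlated (direct) form
``KtransRatio[1+3=2+2]``    transfer as a ratio of two binding constants
``KtransPrime[1+3=2+2]``    transfer from uncorrelated means
``Kprob[4]``                probability-ratio form (needs n_total == m)
==========================  ==================================================

These strings name columns in scan reports and rows in model summaries.
"""

from __future__ import annotations

import re
from typing import Sequence

from . import estimators as est

__all__ = ["evaluate_expression", "default_expressions", "parse_expression"]

_TOKEN = re.compile(r"^(K|Kprime|Ktrans|KtransRatio|KtransPrime|Kprob)\[([0-9+=]+)\]$")


def _parse_sizes(text: str) -> tuple[int, ...]:
    try:
        return tuple(int(x) for x in text.split("+"))
    except ValueError as exc:
        raise ValueError(f"bad size list {text!r}") from exc


def parse_expression(expr: str):
    """Parse an expression string into (kind, payload).

    kind is one of ``elementary``, ``path``, ``uncorrelated``,
    ``transfer_direct``, ``transfer_ratio``, ``transfer_uncorrelated``,
    ``prob_ratio``.
    """
    expr = expr.replace(" ", "")
    parts = expr.split("*")
    if len(parts) > 1:
        steps = []
        for p in parts:
            m = _TOKEN.match(p)
            if not m or m.group(1) != "K":
                raise ValueError(
                    f"only elementary K[...] factors may be multiplied, got {p!r}"
                )
            steps.append(est.ReactionSpec(_parse_sizes(m.group(2))))
        return "path", tuple(steps)
    m = _TOKEN.match(expr)
    if not m:
        raise ValueError(f"cannot parse expression {expr!r}")
    head, body = m.group(1), m.group(2)
    if head == "K":
        return "elementary", _parse_sizes(body)
    if head == "Kprime":
        return "uncorrelated", int(body)
    if head == "Kprob":
        return "prob_ratio", int(body)
    # transfer family: reactants=products
    if "=" not in body:
        raise ValueError(f"transfer expression needs '=': {expr!r}")
    lhs, rhs = body.split("=", 1)
    rxn = est.ReactionSpec(_parse_sizes(lhs), _parse_sizes(rhs))
    kind = {
        "Ktrans": "transfer_direct",
        "KtransRatio": "transfer_ratio",
        "KtransPrime": "transfer_uncorrelated",
    }[head]
    return kind, rxn


def evaluate_expression(data, expr: str, n_blocks: int = est.DEFAULT_N_BLOCKS) -> est.KEstimate:
    """Evaluate an expression string on a series or exact ensemble."""
    kind, payload = parse_expression(expr)
    if kind == "elementary":
        return est.elementary_K(data, payload, n_blocks)
    if kind == "path":
        return est.path_K(data, payload, n_blocks)
    if kind == "uncorrelated":
        return est.uncorrelated_K(data, payload, n_blocks)
    if kind == "prob_ratio":
        _, _, _, _, n_total, _ = est._unpack(data)
        if payload != n_total:
            raise ValueError(
                f"Kprob[{payload}] requires n_total == {payload}, have {n_total}"
            )
        return est.prob_ratio_K(data, n_blocks)
    if kind == "transfer_direct":
        return est.transfer_K_direct(data, payload, n_blocks)
    if kind == "transfer_ratio":
        return est.transfer_K_ratio(data, payload, n_blocks)
    if kind == "transfer_uncorrelated":
        return est.transfer_K_uncorrelated(data, payload, n_blocks)
    raise AssertionError(kind)


def default_expressions(n_total: int) -> list[str]:
    """Standard expression inventory for a system of ``n_total`` particles.

    All two-body binding constants, the gradual-monomer-addition path and
    the concerted m-body constant for the full multimer, the uncorrelated
    comparison constants, the probability-ratio form, and the
    monomer-transfer reactions.
    """
    n = int(n_total)
    out: list[str] = []
    for i in range(1, n // 2 + 1):
        for j in range(i, n - i + 1):
            out.append(f"K[{i}+{j}]")
    if n >= 3:
        out.append("*".join(f"K[1+{j}]" for j in range(1, n)))
        out.append("K[" + "+".join(["1"] * n) + "]")
    for m in range(2, n + 1):
        out.append(f"Kprime[{m}]")
    out.append(f"Kprob[{n}]")
    for b in range(3, n):
        out.append(f"Ktrans[1+{b}=2+{b - 1}]")
        out.append(f"KtransRatio[1+{b}=2+{b - 1}]")
    return out


def canonical_label(expr: str) -> str:
    """Normalized form of an expression string (used as report key)."""
    kind, payload = parse_expression(expr)
    if kind == "path":
        return "*".join(f"K[{r.label()}]" for r in payload)
    return expr.replace(" ", "")
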