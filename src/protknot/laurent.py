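"""Sparse integer Laurent polynomials in one or two variables.

Knot invariants live in Laurent rings — Z[t, t^-1] for the Alexander
polynomial, Z[a^±1, z^±1] for HOMFLY-PT, Z[A^±1, u^±1] for the Turaev
loop bracket — so exponents may be negative and coefficients must stay
exact integers.  Keys are exponent tuples, values nonzero ints.
"""

from __future__ import annotations

from fractions import Fraction

__all__ = ["Laurent"]


class Laurent:
    """Immutable sparse Laurent polynomial with integer coefficients."""

    __slots__ = ("terms", "arity")

    def __init__(self, terms: dict | None = None, arity: int = 1):
        clean: dict[tuple[int, ...], int] = {}
        if terms:
            for k, c in terms.items():
                if c == 0:
                    continue
                key = (k,) if isinstance(k, int) else tuple(k)
                clean[key] = clean.get(key, 0) + int(c)
                if clean[key] == 0:
                    del clean[key]
        if clean:
            arity = len(next(iter(clean)))
        object.__setattr__(self, "terms", clean)
        object.__setattr__(self, "arity", arity)

    def __setattr__(self, *a):  # immutability
        raise AttributeError("Laurent is immutable")

    # -- constructors ------------------------------------------------------
    @classmethod
    def const(cls, c: int, arity: int = 1) -> "Laurent":
        return cls({(0,) * arity: c}, arity=arity)

    @classmethod
    def monomial(cls, c: int, *exps: int) -> "Laurent":
        return cls({tuple(exps): c}, arity=len(exps))

    # -- ring operations ---------------------------------------------------
    def __add__(self, other: "Laurent") -> "Laurent":
        out = dict(self.terms)
        for k, c in other.terms.items():
            out[k] = out.get(k, 0) + c
        return Laurent(out, arity=self.arity)

    def __sub__(self, other: "Laurent") -> "Laurent":
        out = dict(self.terms)
        for k, c in other.terms.items():
            out[k] = out.get(k, 0) - c
        return Laurent(out, arity=self.arity)

    def __neg__(self) -> "Laurent":
        return Laurent({k: -c for k, c in self.terms.items()}, arity=self.arity)

    def __mul__(self, other) -> "Laurent":
        if isinstance(other, int):
            return Laurent({k: c * other for k, c in self.terms.items()}, arity=self.arity)
        out: dict[tuple[int, ...], int] = {}
        for k1, c1 in self.terms.items():
            for k2, c2 in other.terms.items():
                k = tuple(a + b for a, b in zip(k1, k2))
                out[k] = out.get(k, 0) + c1 * c2
        return Laurent(out, arity=self.arity)

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "Laurent":
        if n < 0:
            if len(self.terms) != 1:
                raise ValueError("can only invert monomials")
            (k, c), = self.terms.items()
            if abs(c) != 1:
                raise ValueError("can only invert unit monomials")
            base = Laurent({tuple(-e for e in k): c}, arity=self.arity)
            return base ** (-n)
        out = Laurent.const(1, arity=self.arity)
        for _ in range(n):
            out = out * self
        return out

    def __eq__(self, other) -> bool:
        if isinstance(other, int):
            other = Laurent.const(other, arity=self.arity)
        return isinstance(other, Laurent) and self.terms == other.terms

    def __hash__(self):
        return hash(frozenset(self.terms.items()))

    def __bool__(self) -> bool:
        return bool(self.terms)

    # -- queries -----------------------------------------------------------
    def substitute(self, var: int, value: Fraction | int) -> Fraction:
        """Evaluate variable ``var`` (all others must be absent)."""
        total = Fraction(0)
        for k, c in self.terms.items():
            for i, e in enumerate(k):
                if i != var and e != 0:
                    raise ValueError("polynomial has other variables")
            total += Fraction(c) * Fraction(value) ** k[var]
        return total

    def invert_variable(self, var: int = 0) -> "Laurent":
        """Substitute x -> x^-1 for variable ``var``."""
        out = {}
        for k, c in self.terms.items():
            kk = list(k)
            kk[var] = -kk[var]
            out[tuple(kk)] = c
        return Laurent(out, arity=self.arity)

    def degree_span(self, var: int = 0) -> tuple[int, int]:
        exps = [k[var] for k in self.terms]
        return (min(exps), max(exps)) if exps else (0, 0)

    def shift(self, var: int, amount: int) -> "Laurent":
        out = {}
        for k, c in self.terms.items():
            kk = list(k)
            kk[var] += amount
            out[tuple(kk)] = c
        return Laurent(out, arity=self.arity)

    def coeffs_1d(self) -> tuple[int, ...]:
        """Dense coefficient tuple (lowest degree first) for 1-variable polys."""
        if self.arity != 1:
            raise ValueError("coeffs_1d requires a 1-variable polynomial")
        if not self.terms:
            return (0,)
        lo, hi = self.degree_span(0)
        out = [0] * (hi - lo + 1)
        for (e,), c in self.terms.items():
            out[e - lo] = c
        return tuple(out)

    def __repr__(self) -> str:
        if not self.terms:
            return "0"
        names = "tzu"
        if self.arity == 2:
            names = "az"
        bits = []
        for k in sorted(self.terms):
            c = self.terms[k]
            mono = "".join(
                f"{names[i]}^{e}" for i, e in enumerate(k) if e != 0
            )
            bits.append(f"{c:+d}{mono}")
        return " ".join(bits)
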