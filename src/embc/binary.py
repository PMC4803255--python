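"""Binary codes, delimiters and binary-region membership.

With m variables the mixture has at most k = 2^m components, one per
combination of low (L) / high (H) values.  Codes are ordered
lexicographically with L < H and variable 1 as the leading symbol
(bivariate order: LL, LH, HL, HH).

A *delimiter* r_Z is a splitting value of one variable conditional on the
L/H context of the remaining variables; Z is the code with a dot at the
splitting variable (e.g. r_.L, r_H.).  With all clusters active there are
m * 2^(m-1) delimiters.  The binary region R_j of cluster j is the
intersection of the axis-aligned half-spaces its delimiters define; the
cluster mean is constrained to lie inside R_j.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

L, H = "L", "H"


def codes(m: int) -> list[str]:
    """All 2^m binary codes in lexicographic (L < H) order."""
    return ["".join(p) for p in itertools.product(L + H, repeat=m)]


def code_index(code: str) -> int:
    return int(code.replace(L, "0").replace(H, "1"), 2)


def delimiter_key(code: str, split_var: int) -> str:
    """The dotted context key of ``code``'s delimiter at ``split_var``."""
    return code[:split_var] + "." + code[split_var + 1:]


def delimiter_keys(m: int) -> list[str]:
    """All m * 2^(m-1) delimiter keys."""
    out = []
    for l in range(m):
        for ctx in itertools.product(L + H, repeat=m - 1):
            out.append("".join(ctx[:l]) + "." + "".join(ctx[l:]))
    return out


def adjacent_pair(key: str) -> tuple[str, str]:
    """(low, high) cluster codes separated by the delimiter ``key``."""
    l = key.index(".")
    return key[:l] + L + key[l + 1:], key[:l] + H + key[l + 1:]


class DelimiterSet(dict):
    """Mapping dotted-context key -> splitting value (None when undefined,
    e.g. because an adjacent cluster was absorbed)."""

    def __init__(self, m: int, values: dict | None = None):
        super().__init__({k: None for k in delimiter_keys(m)})
        self.m = m
        if values:
            self.update(values)

    @property
    def expected_count(self) -> int:
        return self.m * 2 ** (self.m - 1)

    @property
    def defined_count(self) -> int:
        return sum(v is not None for v in self.values())

    def pairs(self) -> Iterator[tuple[str, str, str, int]]:
        """Yield (key, low_code, high_code, split_var) for every delimiter."""
        for key in self:
            a, b = adjacent_pair(key)
            yield key, a, b, key.index(".")

    def bounds(self, code: str) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned (lower, upper) bounds of region R_code.

        Undefined delimiters leave the corresponding side unbounded.
        """
        m = len(code)
        lo = np.full(m, -np.inf)
        hi = np.full(m, np.inf)
        for l in range(m):
            r = self.get(delimiter_key(code, l))
            if r is None:
                continue
            if code[l] == L:
                hi[l] = r
            else:
                lo[l] = r
        return lo, hi


def region_membership(
    X: np.ndarray,
    delimiters: DelimiterSet,
    code_list: list[str],
    active: np.ndarray,
    W: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean (n, k) membership of each point in each binary region.

    A point belongs to R_j iff, for every variable l, it lies on cluster
    j's side of the delimiter in j's own context (boundary inclusive);
    constraints with undefined delimiters are skipped.  Regions may
    overlap, so multiple memberships are possible.  A point in no region
    is assigned to the region of its current maximum-posterior cluster
    (requires ``W``); this fallback is how ambiguous mid-gap points keep
    contributing to the mean of the cluster that claims them.
    """
    n = X.shape[0]
    k = len(code_list)
    member = np.zeros((n, k), dtype=bool)
    for j, code in enumerate(code_list):
        if not active[j]:
            continue
        lo, hi = delimiters.bounds(code)
        member[:, j] = np.all((X >= lo) & (X <= hi), axis=1)
    orphan = ~member.any(axis=1)
    if np.any(orphan) and W is not None:
        Wm = np.where(active, W[orphan], -np.inf)
        member[np.flatnonzero(orphan), np.argmax(Wm, axis=1)] = True
    return member
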