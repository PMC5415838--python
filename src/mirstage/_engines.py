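"""RNA secondary-structure folding engines.

The built-in reference engine minimises a deliberately small, fixed energy
model over pseudoknot-free structures:

* base-pair terms: GC −3.0, AU −2.0, GU −1.0 kcal/mol per pair;
* loop terms charged to the pair closing the loop: hairpin loop +4.0,
  bulge/internal loop +3.0, multibranch loop +4.0 kcal/mol;
* hairpin loops span at least 3 unpaired bases; bulge/internal loops are
  searched up to 30 unpaired bases total; external bases are free.

The model is documented and frozen so that screening thresholds, the
synthetic-data generator and the tests all see identical energies.  A
thermodynamic engine (ViennaRNA, when its python bindings are importable)
can be plugged in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_BIG = 1e9
_MIN_HAIRPIN = 3
_MAXLOOP = 30

_HAIRPIN_PENALTY = 4.0
_INTERNAL_PENALTY = 3.0
_MULTI_PENALTY = 4.0

# A=0 C=1 G=2 U=3
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

_PAIR_ENERGY = np.full((4, 4), _BIG)
_PAIR_ENERGY[0, 3] = _PAIR_ENERGY[3, 0] = -2.0  # A:U
_PAIR_ENERGY[1, 2] = _PAIR_ENERGY[2, 1] = -3.0  # C:G
_PAIR_ENERGY[2, 3] = _PAIR_ENERGY[3, 2] = -1.0  # G:U


def encode_rna(sequence: str) -> np.ndarray:
    """Encode an RNA/DNA string (T treated as U) as integer codes."""
    try:
        return np.array([_CODE[c] for c in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA character {exc.args[0]!r}") from None


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases ``a``:``b``; +inf-like for non-pairs."""
    e = _PAIR_ENERGY[_CODE[a.upper()], _CODE[b.upper()]]
    return float(e)


def can_pair(a: str, b: str) -> bool:
    return pair_energy(a, b) < _BIG / 2


@njit(cache=True)
def _fill(enc, pe, maxloop, hp, ip, mp):  # pragma: no cover - numba kernel
    n = enc.size
    V = np.full((n, n), _BIG)
    M = np.full((n, n), _BIG)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if span >= _MIN_HAIRPIN + 1:
                e = pe[enc[i], enc[j]]
                if e < _BIG / 2.0:
                    best = hp
                    # stack / bulge / internal loop
                    pmax = min(i + 1 + maxloop, j - _MIN_HAIRPIN - 2)
                    for p in range(i + 1, pmax + 1):
                        left = p - i - 1
                        qmin = j - 1 - (maxloop - left)
                        if qmin < p + _MIN_HAIRPIN + 1:
                            qmin = p + _MIN_HAIRPIN + 1
                        for q in range(j - 1, qmin - 1, -1):
                            if V[p, q] < _BIG / 2.0:
                                pen = 0.0 if (p == i + 1 and q == j - 1) else ip
                                t = V[p, q] + pen
                                if t < best:
                                    best = t
                    # multibranch loop (>=2 branches)
                    for k in range(i + 1, j - 1):
                        if M[i + 1, k] < _BIG / 2.0 and M[k + 1, j - 1] < _BIG / 2.0:
                            t = M[i + 1, k] + M[k + 1, j - 1] + mp
                            if t < best:
                                best = t
                    V[i, j] = e + best
            m = V[i, j]
            if M[i + 1, j] < m:
                m = M[i + 1, j]
            if M[i, j - 1] < m:
                m = M[i, j - 1]
            for k in range(i + 1, j):
                if M[i, k] < _BIG / 2.0 and M[k + 1, j] < _BIG / 2.0:
                    t = M[i, k] + M[k + 1, j]
                    if t < m:
                        m = t
            M[i, j] = m
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j + 1):
            if V[i, j] < _BIG / 2.0:
                t = W[i] + V[i, j]
                if t < best:
                    best = t
        W[j + 1] = best
    return V, M, W


_TOL = 1e-6


def _trace_V(i, j, enc, V, M, pairs):
    pairs.append((i, j))
    e = _PAIR_ENERGY[enc[i], enc[j]]
    rem = V[i, j] - e
    pmax = min(i + 1 + _MAXLOOP, j - _MIN_HAIRPIN - 2)
    for p in range(i + 1, pmax + 1):
        left = p - i - 1
        qmin = max(j - 1 - (_MAXLOOP - left), p + _MIN_HAIRPIN + 1)
        for q in range(j - 1, qmin - 1, -1):
            pen = 0.0 if (p == i + 1 and q == j - 1) else _INTERNAL_PENALTY
            if V[p, q] < _BIG / 2 and abs(V[p, q] + pen - rem) < _TOL:
                _trace_V(p, q, enc, V, M, pairs)
                return
    if abs(rem - _HAIRPIN_PENALTY) < _TOL:
        return
    for k in range(i + 1, j - 1):
        if (
            M[i + 1, k] < _BIG / 2
            and M[k + 1, j - 1] < _BIG / 2
            and abs(M[i + 1, k] + M[k + 1, j - 1] + _MULTI_PENALTY - rem) < _TOL
        ):
            _trace_M(i + 1, k, enc, V, M, pairs)
            _trace_M(k + 1, j - 1, enc, V, M, pairs)
            return
    raise AssertionError("traceback failed: inconsistent DP tables")


def _trace_M(i, j, enc, V, M, pairs):
    while True:
        if abs(M[i, j] - V[i, j]) < _TOL:
            _trace_V(i, j, enc, V, M, pairs)
            return
        if i + 1 <= j and abs(M[i, j] - M[i + 1, j]) < _TOL:
            i += 1
            continue
        if j - 1 >= i and abs(M[i, j] - M[i, j - 1]) < _TOL:
            j -= 1
            continue
        for k in range(i + 1, j):
            if (
                M[i, k] < _BIG / 2
                and M[k + 1, j] < _BIG / 2
                and abs(M[i, k] + M[k + 1, j] - M[i, j]) < _TOL
            ):
                _trace_M(i, k, enc, V, M, pairs)
                _trace_M(k + 1, j, enc, V, M, pairs)
                return
        raise AssertionError("traceback failed in multiloop table")


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure and its energy (kcal/mol)."""

    sequence: str
    structure: str
    mfe: float

    def pair_table(self) -> list[int]:
        return pair_table(self.structure)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket text."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def structure_energy(sequence: str, structure: str) -> float:
    """Direct energy of a given structure under the reference model.

    Classifies, for each base pair, the loop it closes (hairpin, stack,
    bulge/internal, or multibranch) from the dot-bracket alone.  Used as the
    independent evaluator backing the exhaustive-enumeration checks of the
    DP engine.
    """
    enc = encode_rna(sequence)
    pt = pair_table(structure)
    total = 0.0
    for i, j in [(i, pt[i]) for i in range(len(pt)) if pt[i] > i]:
        e = _PAIR_ENERGY[enc[i], enc[j]]
        if e > _BIG / 2:
            raise ValueError(f"non-pairable bases at {i},{j}")
        total += e
        # walk the loop closed by (i, j)
        branches = 0
        unpaired = 0
        k = i + 1
        while k < j:
            if pt[k] == -1:
                unpaired += 1
                k += 1
            else:
                branches += 1
                k = pt[k] + 1
        if branches == 0:
            if unpaired < _MIN_HAIRPIN:
                raise ValueError("hairpin loop shorter than 3")
            total += _HAIRPIN_PENALTY
        elif branches == 1:
            total += 0.0 if unpaired == 0 else _INTERNAL_PENALTY
        else:
            total += _MULTI_PENALTY
    return total


class BuiltinEngine:
    """Dynamic-programming minimiser over the fixed reference energy model."""

    name = "builtin"

    def __init__(self, max_length: int = 400):
        self.max_length = max_length
        self._cache: dict[str, FoldResult] = {}

    def fold(self, sequence: str) -> FoldResult:
        seq = sequence.upper().replace("T", "U")
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        if len(seq) > self.max_length:
            raise ValueError(
                f"sequence length {len(seq)} exceeds engine limit {self.max_length}"
            )
        enc = encode_rna(seq)
        n = enc.size
        if n == 0:
            return FoldResult(seq, "", 0.0)
        V, M, W = _fill(
            enc.astype(np.int64),
            _PAIR_ENERGY,
            _MAXLOOP,
            _HAIRPIN_PENALTY,
            _INTERNAL_PENALTY,
            _MULTI_PENALTY,
        )
        mfe = float(W[n])
        pairs: list[tuple[int, int]] = []
        # trace the external-loop decisions
        k = n
        while k > 0:
            if abs(W[k] - W[k - 1]) < _TOL:
                k -= 1
                continue
            found = False
            for i in range(k):
                if V[i, k - 1] < _BIG / 2 and abs(W[i] + V[i, k - 1] - W[k]) < _TOL:
                    _trace_V(i, k - 1, enc, V, M, pairs)
                    k = i
                    found = True
                    break
            if not found:  # pragma: no cover
                raise AssertionError("traceback failed in external loop")
        db = ["."] * n
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        result = FoldResult(seq, "".join(db), round(mfe, 6))
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[seq] = result
        return result


class ViennaEngine:
    """Thermodynamic engine backed by the ViennaRNA python bindings."""

    name = "vienna"

    def __init__(self):
        import RNA  # noqa: F401  (import error surfaces to the caller)

        self._rna = RNA

    def fold(self, sequence: str) -> FoldResult:
        seq = sequence.upper().replace("T", "U")
        structure, mfe = self._rna.fold(seq)
        return FoldResult(seq, structure, float(mfe))


_DEFAULT: BuiltinEngine | None = None


def get_engine(name: str = "builtin"):
    """Return a folding engine by name (``builtin`` or ``vienna``)."""
    global _DEFAULT
    if name == "builtin":
        if _DEFAULT is None:
            _DEFAULT = BuiltinEngine()
        return _DEFAULT
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown folding engine {name!r}")
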