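"""Single-sequence RNA secondary structure prediction and stability classes.

Two folding routes are provided:

* ``fold_nussinov`` - exact base-pair maximization (AU/GC/GU, hairpin loops of
  at least ``min_loop`` bases), the oracle-testable core;
* ``fold_energy`` - minimum free energy under a reduced nearest-neighbour
  model (16-entry Watson-Crick/wobble stacking table plus logarithmic
  hairpin/interior penalties and an affine multiloop term).  The model is a
  deliberate simplification: absolute kcal/mol values are on the right scale
  but will not match full Turner-parameter folders such as RNAfold; an
  external engine can be plugged in through ``external_fold_adapter`` when
  RNAfold-scale energies are required.

Stability classes follow two distinct conventions used for different
questions: a miRNA-precursor hairpin is called stable when its MFE lies in
[-80, -30] kcal/mol, while a long ncRNA structure is called stable only below
-80 kcal/mol.  Both are kept verbatim as separate contexts.
"""
from __future__ import annotations

import math
import subprocess
from dataclasses import dataclass, field

import numpy as np

from ._kernels import INF, zuker_fill

_RNA_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

DEFAULT_MAX_FOLD_LENGTH = 5000

# approximate Watson-Crick / wobble stacking energies, kcal/mol:
# key (XY, WZ) = pair (i,j)=X-Y stacked on pair (i+1,j-1)=W-Z
_STACK_TABLE = {
    ("CG", "CG"): -3.3, ("CG", "GC"): -2.4, ("CG", "GU"): -2.1,
    ("CG", "UG"): -1.4, ("CG", "AU"): -2.1, ("CG", "UA"): -2.1,
    ("GC", "CG"): -3.4, ("GC", "GC"): -3.3, ("GC", "GU"): -2.5,
    ("GC", "UG"): -1.5, ("GC", "AU"): -2.2, ("GC", "UA"): -2.4,
    ("GU", "CG"): -2.5, ("GU", "GC"): -2.1, ("GU", "GU"): -1.4,
    ("GU", "UG"): 0.3, ("GU", "AU"): -1.4, ("GU", "UA"): -1.3,
    ("UG", "CG"): -2.1, ("UG", "GC"): -1.4, ("UG", "GU"): 0.6,
    ("UG", "UG"): -0.5, ("UG", "AU"): -1.0, ("UG", "UA"): -0.6,
    ("AU", "CG"): -2.4, ("AU", "GC"): -2.2, ("AU", "GU"): -1.3,
    ("AU", "UG"): -1.0, ("AU", "AU"): -1.1, ("AU", "UA"): -0.9,
    ("UA", "CG"): -2.1, ("UA", "GC"): -2.1, ("UA", "GU"): -1.0,
    ("UA", "UG"): -0.8, ("UA", "AU"): -1.3, ("UA", "UA"): -0.6,
}


@dataclass
class EnergyParams:
    """Reduced nearest-neighbour parameter set (kcal/mol)."""

    stack: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_STACK_TABLE))
    hairpin_a: float = 5.6
    hairpin_b: float = 1.6  # * ln(size/3)
    interior_a: float = 3.2
    interior_b: float = 1.1  # * ln(size)
    ml_close: float = 3.4
    ml_branch: float = 0.4
    ml_unpaired: float = 0.1
    min_hairpin_loop: int = 3
    max_interior: int = 30

    def hairpin(self, size: int) -> float:
        return self.hairpin_a + self.hairpin_b * math.log(size / 3.0) \
            if size > 3 else self.hairpin_a

    def interior(self, size: int) -> float:
        return self.interior_a + self.interior_b * math.log(size)

    def tables(self, n: int):
        stack = np.zeros((4, 4, 4, 4))
        for (p1, p2), e in self.stack.items():
            stack[_RNA_CODE[p1[0]], _RNA_CODE[p1[1]],
                  _RNA_CODE[p2[0]], _RNA_CODE[p2[1]]] = e
        can = np.zeros((4, 4), dtype=np.bool_)
        for a, b in _PAIRS:
            can[_RNA_CODE[a], _RNA_CODE[b]] = True
        hp = np.full(max(n + 1, 5), INF)
        for sz in range(self.min_hairpin_loop, max(n + 1, 5)):
            hp[sz] = self.hairpin(sz)
        inter = np.full(self.max_interior + 1, INF)
        for sz in range(1, self.max_interior + 1):
            inter[sz] = self.interior(sz)
        return can, stack, hp, inter


@dataclass
class FoldResult:
    sequence_id: str
    structure: str
    mfe_kcal_mol: float
    pair_count: int
    stability_class: str = ""


def _normalize(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(b not in "ACGU" for b in s):
        raise ValueError("RNA sequence contains characters outside ACGU/T")
    return s


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def pairs_to_dotbracket(n: int, pairs: list[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dotbracket_to_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def fold_nussinov(seq: str, min_loop: int = 3) -> tuple[int, str]:
    """Maximum non-crossing AU/GC/GU pairing with hairpin loops >= min_loop.

    Deterministic traceback prefers pairing (i, j) over bifurcation on ties.
    """
    s = _normalize(seq)
    n = len(s)
    if n == 0:
        return 0, ""
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            if can_pair(s[i], s[j]) and (j - i - 1) >= min_loop:
                inner = dp[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i, j):
                if can_pair(s[k], s[j]) and (j - k - 1) >= min_loop:
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        # prefer pairing (i, j) itself on ties, then earliest pairing partner
        if can_pair(s[i], s[j]) and (j - i - 1) >= min_loop:
            inner = dp[i + 1][j - 1] if i + 1 <= j - 1 else 0
            if dp[i][j] == inner + 1:
                pairs.append((i, j))
                stack.append((i + 1, j - 1))
                continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if can_pair(s[k], s[j]) and (j - k - 1) >= min_loop:
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if dp[i][j] == left + inner + 1:
                    pairs.append((k, j))
                    stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    pairs.sort()
    return sum(1 for _ in pairs), pairs_to_dotbracket(n, pairs)


def score_structure(seq: str, pairs: list[tuple[int, int]],
                    params: EnergyParams | None = None) -> float:
    """Independent free-energy evaluation of a given structure by loop
    decomposition under the same reduced model (used for self-consistency
    checks and brute-force oracles)."""
    params = params or EnergyParams()
    s = _normalize(seq)
    pairs = sorted(pairs)
    pair_set = set(pairs)
    for i, j in pair_set:
        if not can_pair(s[i], s[j]):
            raise ValueError(f"non-pairable bases at ({i},{j})")
        if j - i - 1 < params.min_hairpin_loop:
            raise ValueError(f"hairpin loop below minimum at ({i},{j})")
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int] | None] = [None]
    for p in pairs:
        while stack[-1] is not None and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        children.setdefault(stack[-1], []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    energy = 0.0
    for closing, kids in children.items():
        if closing is None:
            continue  # external bases are free
        i, j = closing
        if not kids:
            energy += params.hairpin(j - i - 1)
        elif len(kids) == 1:
            (k, l1) = kids[0]
            n1, n2 = k - i - 1, j - l1 - 1
            if n1 == 0 and n2 == 0:
                energy += params.stack[(s[i] + s[j], s[k] + s[l1])]
            else:
                energy += params.interior(n1 + n2)
        else:
            unpaired = (j - i - 1) - sum(l1 - k + 1 for k, l1 in kids)
            energy += (params.ml_close + params.ml_branch * (len(kids) + 1)
                       + params.ml_unpaired * unpaired)
    return energy


def fold_energy(seq: str, params: EnergyParams | None = None,
                sequence_id: str = "seq",
                max_length: int = DEFAULT_MAX_FOLD_LENGTH) -> FoldResult:
    """Minimum-free-energy structure under the reduced model (Zuker-style
    recursion with interior loops capped at ``params.max_interior``)."""
    params = params or EnergyParams()
    s = _normalize(seq)
    n = len(s)
    if n > max_length:
        raise ValueError(f"sequence {sequence_id!r} longer than {max_length} nt")
    if n == 0:
        return FoldResult(sequence_id, "", 0.0, 0)
    codes = np.array([_RNA_CODE[b] for b in s], dtype=np.int64)
    can, stackE, hp, inter = params.tables(n)
    V, WM, WM2, W = zuker_fill(codes, can, stackE, hp, inter,
                               params.ml_close, params.ml_branch,
                               params.ml_unpaired, params.min_hairpin_loop,
                               params.max_interior)
    mfe = min(0.0, float(W[n]))
    pairs = _traceback_energy(s, codes, V, WM, WM2, W, params, stackE)
    structure = pairs_to_dotbracket(n, pairs)
    return FoldResult(sequence_id, structure, round(mfe, 6), len(pairs))


_EPS = 1e-7


def _traceback_energy(s, codes, V, WM, WM2, W, params: EnergyParams, stackE):
    n = len(s)
    pairs: list[tuple[int, int]] = []
    if W[n] >= -_EPS:
        return pairs
    # external loop
    work: list[tuple[str, int, int]] = []
    j = n
    while j > 0:
        if abs(W[j] - W[j - 1]) < _EPS:
            j -= 1
            continue
        found = False
        for i in range(j):
            if V[i, j - 1] < INF / 2 and abs(W[j] - (W[i] + V[i, j - 1])) < _EPS:
                work.append(("V", i, j - 1))
                j = i
                found = True
                break
        if not found:  # pragma: no cover - defensive
            j -= 1
    while work:
        kind, i, j = work.pop()
        if kind == "V":
            pairs.append((i, j))
            span = j - i
            # hairpin?
            if abs(V[i, j] - params.hairpin(span - 1)) < _EPS:
                continue
            # stack?
            if span - 2 > params.min_hairpin_loop and V[i + 1, j - 1] < INF / 2:
                e = stackE[codes[i], codes[j], codes[i + 1], codes[j - 1]]
                if can_pair(s[i + 1], s[j - 1]) and \
                        abs(V[i, j] - (e + V[i + 1, j - 1])) < _EPS:
                    work.append(("V", i + 1, j - 1))
                    continue
            # interior / bulge?
            done = False
            for k in range(i + 1, j):
                n1 = k - i - 1
                if n1 > params.max_interior:
                    break
                for l1 in range(j - 1, k, -1):
                    n2 = j - l1 - 1
                    sz = n1 + n2
                    if sz > params.max_interior:
                        break
                    if sz == 0 or V[k, l1] >= INF / 2:
                        continue
                    if abs(V[i, j] - (params.interior(sz) + V[k, l1])) < _EPS:
                        work.append(("V", k, l1))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            # multiloop
            work.append(("WM2", i + 1, j - 1))
        elif kind == "WM2":
            for k in range(i + 1, j):
                if WM[i, k] < INF / 2 and WM[k + 1, j] < INF / 2 and \
                        abs(WM2[i, j] - (WM[i, k] + WM[k + 1, j])) < _EPS:
                    work.append(("WM", i, k))
                    work.append(("WM", k + 1, j))
                    break
        elif kind == "WM":
            if V[i, j] < INF / 2 and abs(WM[i, j] - (V[i, j] + params.ml_branch)) < _EPS:
                work.append(("V", i, j))
            elif abs(WM[i, j] - (WM[i + 1, j] + params.ml_unpaired)) < _EPS:
                work.append(("WM", i + 1, j))
            elif abs(WM[i, j] - (WM[i, j - 1] + params.ml_unpaired)) < _EPS:
                work.append(("WM", i, j - 1))
            else:
                work.append(("WM2", i, j))
    pairs.sort()
    return pairs


def classify_stability(mfe_kcal_mol: float, context: str) -> str:
    """Stability call for an MFE value under one of two contexts:
    ``mirna_precursor`` (stable iff -80 <= mfe <= -30) or
    ``lncrna_structure`` (stable iff mfe < -80)."""
    if context == "mirna_precursor":
        return "stable" if -80.0 <= mfe_kcal_mol <= -30.0 else "unstable"
    if context == "lncrna_structure":
        return "stable" if mfe_kcal_mol < -80.0 else "unstable"
    raise ValueError(f"unknown stability context {context!r}")


def external_fold_adapter(seq: str, sequence_id: str = "seq",
                          command: str = "RNAfold") -> FoldResult:
    """Optional hook folding through an external engine (RNAfold-compatible
    stdin/stdout).  Energies returned on the external engine's scale."""
    proc = subprocess.run([command, "--noPS"], input=f">{sequence_id}\n{seq}\n",
                          capture_output=True, text=True, check=True)
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    structure_line = lines[-1]
    structure, _, energy = structure_line.partition(" ")
    mfe = float(energy.strip().strip("()"))
    pairs = dotbracket_to_pairs(structure)
    return FoldResult(sequence_id, structure, mfe, len(pairs))
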