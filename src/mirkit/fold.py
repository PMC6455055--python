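"""Minimum-energy RNA secondary structure by base-pair dynamic programming.

The default provider scores each admissible base pair with a fixed energy
(G:C -3, A:U -2, G:U -1 kcal/mol), forbids hairpin loops shorter than three
unpaired bases, and returns one optimal nested structure in dot-bracket
notation.  It is deliberately simpler than nearest-neighbour thermodynamics:
every energy-based rule in this package is a threshold or a ratio evaluated
under a single consistent provider, so only relative energies matter.  A
different callable with the same ``(sequence) -> (structure, energy)``
signature may be substituted anywhere a ``fold_provider`` argument is
accepted, as long as one provider is used for a whole run.
"""

from __future__ import annotations

from typing import Callable, Dict, Tuple

import numpy as np

#: energy (kcal/mol) of each admissible pair; absent keys do not pair
PAIR_ENERGY: Dict[frozenset, float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_LOOP = 3

RNA_ALPHABET = frozenset("ACGU")

FoldProvider = Callable[[str], Tuple[str, float]]


def pair_energy(a: str, b: str) -> float:
    """Energy of pairing bases ``a`` and ``b``; 0.0 if they cannot pair."""
    return PAIR_ENERGY.get(frozenset((a, b)), 0.0)


def can_pair(a: str, b: str) -> bool:
    return frozenset((a, b)) in PAIR_ENERGY


def _validate(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_ENERGY_MATRIX = np.zeros((4, 4))
for _pair, _e in PAIR_ENERGY.items():
    _a, _b = tuple(_pair)
    _ENERGY_MATRIX[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _e
    _ENERGY_MATRIX[_BASE_INDEX[_b], _BASE_INDEX[_a]] = _e


def fold(sequence: str, min_loop: int = MIN_LOOP) -> Tuple[str, float]:
    """Fold ``sequence`` and return ``(dot_bracket, energy)``.

    Energy is the sum of pair energies over the optimal nested structure and
    is therefore never positive.  Ties between optimal structures are broken
    by pairing the 5'-most base whenever doing so is optimal, with the
    5'-most admissible partner.
    """
    seq = _validate(sequence)
    n = len(seq)
    if n == 0:
        return "", 0.0
    codes = np.array([_BASE_INDEX[c] for c in seq])
    # pe[i, k] = energy of pairing positions i and k; +inf where inadmissible
    pe = _ENERGY_MATRIX[codes[:, None], codes[None, :]].copy()
    pe[pe == 0.0] = np.inf
    # E[i, j] = minimum energy of subsequence i..j inclusive; the padded
    # lower triangle stays 0 so empty intervals contribute nothing.
    E = np.zeros((n + 2, n + 2))
    for i in range(n - min_loop - 2, -1, -1):
        row_next = E[i + 1]
        if not np.isfinite(pe[i, i + min_loop + 1 :]).any():
            E[i, i + min_loop + 1 : n] = row_next[i + min_loop + 1 : n]
            continue
        for j in range(i + min_loop + 1, n):
            ks = np.arange(i + min_loop + 1, j + 1)
            cand = pe[i, ks] + row_next[ks - 1] + E[ks + 1, j]
            best = cand.min(initial=row_next[j])
            E[i, j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1 or E[i, j] == 0.0:
            continue
        target = E[i, j]
        paired = False
        # prefer pairing i (5'-most base) with its 5'-most optimal partner
        for k in range(i + min_loop + 1, j + 1):
            if pe[i, k] == np.inf:
                continue
            if pe[i, k] + E[i + 1, k - 1] + E[k + 1, j] == target:
                structure[i], structure[k] = "(", ")"
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure), float(E[0, n - 1])


def structure_energy(sequence: str, structure: str, min_loop: int = MIN_LOOP) -> float:
    """Energy of an explicit dot-bracket ``structure`` on ``sequence``."""
    seq = _validate(sequence)
    if len(structure) != len(seq):
        raise ValueError("structure length != sequence length")
    total = 0.0
    stack = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if idx - i <= min_loop:
                raise ValueError(f"loop shorter than {min_loop} at pair ({i},{idx})")
            if not can_pair(seq[i], seq[idx]):
                raise ValueError(f"inadmissible pair {seq[i]}:{seq[idx]} at ({i},{idx})")
            total += pair_energy(seq[i], seq[idx])
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return total


def pairs_from_dotbracket(structure: str) -> Dict[int, int]:
    """Map each paired position to its partner (both directions, 0-based)."""
    partner: Dict[int, int] = {}
    stack = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            partner[i] = idx
            partner[idx] = i
    return partner
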