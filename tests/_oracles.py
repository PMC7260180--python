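"""Independent brute-force oracles the implementation is checked against.

These deliberately use the dumbest correct algorithms (substring scans,
quadratic dynamic programming, exhaustive permutation enumeration) and share
no code with the package's own audit/design paths.
"""

from __future__ import annotations

from itertools import permutations


def naive_missing_kmers(
    parent_protein: str, construct_protein: str, k: int
) -> list[tuple[str, int]]:
    """All (peptide, parent position) pairs not found by a plain substring scan."""
    out = []
    for i in range(len(parent_protein) - k + 1):
        pep = parent_protein[i:i + k]
        if pep not in construct_protein:
            out.append((pep, i))
    return out


def naive_junctional(
    parent_proteins: list[str], construct_protein: str, k: int
) -> set[str]:
    """Construct k-mers absent from every parent, by direct enumeration."""
    construct_kmers = {
        construct_protein[i:i + k]
        for i in range(len(construct_protein) - k + 1)
    }
    parental = set()
    for prot in parent_proteins:
        parental |= {prot[i:i + k] for i in range(len(prot) - k + 1)}
    return construct_kmers - parental


def dp_longest_common_substring(s: str, t: str) -> int:
    """Quadratic dynamic-programming longest common substring length."""
    best = 0
    prev = [0] * (len(t) + 1)
    for i in range(1, len(s) + 1):
        cur = [0] * (len(t) + 1)
        for j in range(1, len(t) + 1):
            if s[i - 1] == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def valid_orders_by_enumeration(parent_ids: list) -> list[tuple[int, ...]]:
    """Indices of all permutations with no two adjacent equal parent ids."""
    valid = []
    for perm in permutations(range(len(parent_ids))):
        if all(
            parent_ids[a] != parent_ids[b]
            for a, b in zip(perm, perm[1:])
        ):
            valid.append(perm)
    return valid
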