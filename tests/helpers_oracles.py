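"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations, kept free of any import from the
package's corresponding code paths, so that agreement is evidence and
not tautology.
"""

from __future__ import annotations

_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def brute_force_orfs(seq: str, min_len: int) -> set[tuple[int, int, int]]:
    """Enumerate every stop-free codon stretch ≥ min_len in six frames.

    Returns {(frame, start, end)} with forward-strand 0-based half-open
    coordinates, frames 1-3 forward and 4-6 reverse.
    """
    seq = seq.upper()
    n = len(seq)
    found: set[tuple[int, int, int]] = set()
    for strand in "+-":
        s = seq if strand == "+" else oracle_revcomp(seq)
        for off in range(3):
            codon_idx_runs: list[list[int]] = [[]]
            for ci in range((n - off) // 3):
                codon = s[off + 3 * ci : off + 3 * ci + 3]
                if codon in _STOPS:
                    codon_idx_runs.append([])
                else:
                    codon_idx_runs[-1].append(ci)
            for run in codon_idx_runs:
                if run and 3 * len(run) >= min_len:
                    a = off + 3 * run[0]
                    b = off + 3 * (run[-1] + 1)
                    if strand == "-":
                        a, b = n - b, n - a
                    frame = off + 1 if strand == "+" else off + 4
                    found.add((frame, a, b))
    return found


def ancestor_set_lca(lineages: list[tuple[str, ...]]) -> tuple[str, ...]:
    """LCA of rank-ordered name paths by ancestor-set intersection.

    Each lineage's ancestor set is its set of prefixes; the LCA is the
    longest prefix common to all lineages (empty tuple = root).
    """
    def prefixes(lin: tuple[str, ...]) -> set[tuple[str, ...]]:
        return {lin[: i + 1] for i in range(len(lin))} | {()}

    common = prefixes(lineages[0])
    for lin in lineages[1:]:
        common &= prefixes(lin)
    return max(common, key=len)


def count_q_bases(quals: list[str], threshold: int) -> int:
    return sum(1 for q in quals for ch in q if ord(ch) - 33 >= threshold)
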