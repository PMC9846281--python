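"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force, structured differently
from the library code they check: the Ka/Ks oracle classifies mutation
pathways by depth-first recursion over raw strings, and the monophyly
oracle works on a nested-tuple tree representation without any tree
library.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Nei–Gojobori brute-force oracle
# ---------------------------------------------------------------------------

def oracle_codon_sites(codon: str, code_id: int = 2) -> float:
    """Synonymous site count of one codon by direct enumeration."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    aa = table.forward_table
    stops = set(table.stop_codons)
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            m = codon[:pos] + b + codon[pos + 1 :]
            if m in stops:
                continue
            valid += 1
            syn += aa[m] == aa[codon]
        if valid:
            total += syn / valid
    return total


def _oracle_paths(cur: str, target: str, aa, stops) -> list[tuple[int, int]]:
    """All (syn, nonsyn) step counts over stop-free mutation pathways,
    found by depth-first recursion (one path per ordering of changes)."""
    if cur == target:
        return [(0, 0)]
    out: list[tuple[int, int]] = []
    for pos in range(3):
        if cur[pos] == target[pos]:
            continue
        nxt = cur[:pos] + target[pos] + cur[pos + 1 :]
        if nxt in stops:
            continue
        step_syn = 1 if aa[nxt] == aa[cur] else 0
        for s, n in _oracle_paths(nxt, target, aa, stops):
            out.append((s + step_syn, n + (1 - step_syn)))
    return out


def oracle_pairwise(seq_a: str, seq_b: str, code_id: int = 2):
    """Brute-force NG86 with Jukes–Cantor correction.

    Returns (S, N, Sd, Nd, Ka, Ks); Ka/Ks are None when saturated. Codon
    pairs with stops or fully blocked pathways are skipped, mirroring the
    documented estimator conventions.
    """
    import math

    table = CodonTable.unambiguous_dna_by_id[code_id]
    aa = table.forward_table
    stops = set(table.stop_codons)
    s_a = s_b = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if ca in stops or cb in stops:
            continue
        paths = _oracle_paths(ca, cb, aa, stops)
        if not paths:
            continue
        sd += sum(p[0] for p in paths) / len(paths)
        nd += sum(p[1] for p in paths) / len(paths)
        s_a += oracle_codon_sites(ca, code_id)
        s_b += oracle_codon_sites(cb, code_id)
        n_codons += 1
    S = (s_a + s_b) / 2
    N = 3 * n_codons - S
    pS = sd / S if S else 0.0
    pN = nd / N if N else 0.0
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)  # noqa: E731
    return S, N, sd, nd, jc(pN), jc(pS)


def random_sense_codons(rng, n: int, code_id: int = 2) -> str:
    """Uniform random stop-free codon string of n codons."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    sense = sorted(table.forward_table)
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n))


# ---------------------------------------------------------------------------
# Random trees as nested tuples + monophyly oracle
# ---------------------------------------------------------------------------

def random_tuple_tree(rng, labels: list[str]):
    """Random binary topology over ``labels`` by repeated random joins."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def tuple_tree_to_newick(node) -> str:
    def render(n):
        if isinstance(n, tuple):
            return "(" + ",".join(render(c) for c in n) + ")"
        return n

    return render(node) + ";"


def _subtree_leafsets(node, acc: list[frozenset]) -> frozenset:
    if not isinstance(node, tuple):
        s = frozenset({node})
    else:
        s = frozenset()
        for child in node:
            s |= _subtree_leafsets(child, acc)
    acc.append(s)
    return s


def oracle_monophyletic(tuple_tree, tipset: set[str]) -> bool:
    """Edge-bipartition monophyly by enumerating every subtree leaf set."""
    sides: list[frozenset] = []
    all_tips = _subtree_leafsets(tuple_tree, sides)
    if tipset == set(all_tips):
        return True
    target = frozenset(tipset)
    comp = all_tips - target
    return any(s == target or s == comp for s in sides)
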