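"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (small-n exhaustive or textbook DP)
and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith–Waterman local score, Gotoh affine-gap DP.

    A gap of length k costs gap_open + k * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def union_find_components(nodes, edges) -> dict:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    roots = {}
    comp = {}
    for n in sorted(nodes, key=str):
        r = find(n)
        if r not in roots:
            roots[r] = None
    # number components by smallest member id
    members = {}
    for n in nodes:
        members.setdefault(find(n), []).append(n)
    ordered = sorted(members.values(), key=lambda ms: min(map(str, ms)))
    for cid, ms in enumerate(ordered):
        for n in ms:
            comp[n] = cid
    return comp


def conductance_by_edge_count(edges, origin, domain) -> float:
    """Classify every edge of one component as internal/external to a domain."""
    internal = external = 0
    for u, v in edges:
        u_in, v_in = origin[u] == domain, origin[v] == domain
        if u_in and v_in:
            internal += 1
        elif u_in or v_in:
            external += 1
    if external == 0:
        return 0.0
    if internal == 0:
        return float("inf")
    return external / internal


def bfs_distances(nodes, edges, sources) -> dict:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {s: 0 for s in sources if s in adj}
    frontier = list(dist)
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return {n: dist.get(n, float("inf")) for n in nodes}


def all_maximal_cliques(nodes, edges, min_size) -> list:
    """Exhaustive subset enumeration (only usable for ~12 nodes)."""
    nodes = sorted(nodes, key=str)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(frozenset(p) in edge_set for p in combinations(subset, 2))

    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if not is_clique(subset):
                continue
            others = [n for n in nodes if n not in subset]
            if any(is_clique(subset + (n,)) for n in others):
                continue
            cliques.append(tuple(sorted(subset, key=str)))
    return sorted(cliques)


def ecdf_sweep_ks(a, b):
    """(D+, D-, D) by evaluating both ECDFs at every pooled point."""
    pooled = sorted(list(a) + list(b))
    dplus = dminus = 0.0
    for x in pooled:
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        dplus = max(dplus, fa - fb)
        dminus = max(dminus, fb - fa)
    return dplus, dminus, max(dplus, dminus)


def chi2_by_hand(table):
    """Pearson chi-square for a 2x2 table, no continuity correction."""
    (a, b), (c, d) = table
    n = a + b + c + d
    chi2 = 0.0
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    for i, obs_row in enumerate(table):
        for j, obs in enumerate(obs_row):
            exp = rows[i] * cols[j] / n
            chi2 += (obs - exp) ** 2 / exp
    return chi2


def count_codon_sites(codon) -> tuple[float, float, int]:
    """(syn, nonsyn, n_stop_neighbours) by enumerating all 9 point mutations,
    translating with Biopython."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    s = n = stops = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            maa = str(Seq(mut).translate())
            if maa == "*":
                stops += 1
            elif maa == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n, int(stops)
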