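"""Independent straight-loop oracles for the coupling-analysis pipeline.

Deliberately naive (python loops, no vectorization, no shared code with the
package internals) so the fast implementations can be checked against them
on small inputs.
"""

from __future__ import annotations

import math

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_f1(rows: list[str], q: list[float], lam: float) -> list[list[float]]:
    M, L = len(rows), len(rows[0])
    out = []
    for i in range(L):
        freqs = []
        for a in range(20):
            count = sum(1 for m in range(M) if rows[m][i] == AA[a])
            freqs.append((1.0 - lam) * count / M + lam * q[a])
        out.append(freqs)
    return out


def oracle_f2(rows: list[str], q: list[float], lam: float):
    """f2[i][j][a][b]; diagonal blocks are f1 * delta(a=b)."""
    M, L = len(rows), len(rows[0])
    f1 = oracle_f1(rows, q, lam)
    out = [[[[0.0] * 20 for _ in range(20)] for _ in range(L)] for _ in range(L)]
    for i in range(L):
        for j in range(L):
            for a in range(20):
                for b in range(20):
                    if i == j:
                        out[i][j][a][b] = f1[i][a] if a == b else 0.0
                    else:
                        count = sum(
                            1
                            for m in range(M)
                            if rows[m][i] == AA[a] and rows[m][j] == AA[b]
                        )
                        out[i][j][a][b] = (1.0 - lam) * count / M + lam * q[a] * q[b]
    return out


def oracle_conservation(f1, q):
    """Binary relative entropy per (position, amino acid)."""
    return [
        [
            f * math.log(f / qa) + (1 - f) * math.log((1 - f) / (1 - qa))
            for f, qa in zip(row, q)
        ]
        for row in f1
    ]


def oracle_phi(f1, q):
    return [
        [abs(math.log(f * (1 - qa) / (qa * (1 - f)))) for f, qa in zip(row, q)]
        for row in f1
    ]


def oracle_coupling_tensor(rows, q, lam):
    f1 = oracle_f1(rows, q, lam)
    f2 = oracle_f2(rows, q, lam)
    phi = oracle_phi(f1, q)
    L = len(f1)
    return [
        [
            [
                [
                    phi[i][a] * phi[j][b] * (f2[i][j][a][b] - f1[i][a] * f1[j][b])
                    for b in range(20)
                ]
                for a in range(20)
            ]
            for j in range(L)
        ]
        for i in range(L)
    ]


def oracle_ctilde(rows, q, lam):
    tensor = oracle_coupling_tensor(rows, q, lam)
    L = len(tensor)
    out = [[0.0] * L for _ in range(L)]
    for i in range(L):
        for j in range(L):
            total = 0.0
            for a in range(20):
                for b in range(20):
                    total += tensor[i][j][a][b] ** 2
            out[i][j] = math.sqrt(total)
    return out


def oracle_transitive_clusters(records, id_thr: float, cov_thr: float):
    """Brute-force all-pairs transitive closure at the identity/coverage
    thresholds; returns frozensets of member ids."""
    n = len(records)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    def strip(s):
        return s.residues.replace("-", "")

    for i in range(n):
        for j in range(i + 1, n):
            a, b = strip(records[i]), strip(records[j])
            longer = max(len(a), len(b))
            matches = sum(x == y for x, y in zip(a, b))
            identity = matches / longer
            coverage = min(len(a), len(b)) / longer
            if identity >= id_thr and coverage >= cov_thr:
                union(i, j)
    groups: dict[int, set[str]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(find(i), set()).add(rec.id)
    return {frozenset(g) for g in groups.values()}
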