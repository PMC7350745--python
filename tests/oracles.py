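"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately simple and slow: plain-Python dynamic
programs and enumeration, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def gotoh_score(a: str, b: str, scoring) -> float:
    """Plain-Python affine-gap global alignment score (three-state DP).

    A gap run of length L costs -(open + (L-1) * extend), i.e. the open
    score applies to the first gapped position.
    """
    alpha = scoring.alphabet
    sub = scoring.matrix
    go, ge = scoring.gap_open, scoring.gap_extend
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[alpha.index(a[i - 1])][alpha.index(b[j - 1])]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


_CODON = {}


def _codon_table():
    global _CODON
    if not _CODON:
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        _CODON = {
            b1 + b2 + b3: aa
            for (b1, b2, b3), aa in zip(itertools.product(bases, bases, bases), aas)
        }
    return _CODON


def naive_translate(dna: str) -> str:
    table = _codon_table()
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else table[codon])
    return "".join(out)


def naive_revcomp(dna: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(dna))


def naive_iupac_count(seq: str, iupac: str, both_strands: bool) -> int:
    """Exhaustive per-position IUPAC matching, counting overlaps.

    In both-strand mode a palindromic pattern is counted once per position.
    """
    codes = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A",
            "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
            "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}

    def matches(pattern: str, pos: int) -> bool:
        return all(seq[pos + k] in codes[p] for k, p in enumerate(pattern))

    w = len(iupac)
    rc = "".join(comp[c] for c in reversed(iupac))
    palindromic = rc == iupac
    count = 0
    for pos in range(len(seq) - w + 1):
        fwd = matches(iupac, pos)
        if fwd:
            count += 1
        if both_strands:
            rev = matches(rc, pos)
            if rev and not (palindromic and fwd):
                count += 1
    return count


def triple_loop_tom(a):
    """Unsigned TOM by explicit triple loop over a dense adjacency list."""
    n = len(a)
    k = [sum(a[i][u] for u in range(n)) for i in range(n)]
    t = [[0.0] * n for _ in range(n)]
    for i in range(n):
        t[i][i] = 1.0
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i][u] * a[u][j] for u in range(n) if u != i and u != j)
            t[i][j] = (shared + a[i][j]) / (min(k[i], k[j]) + 1.0 - a[i][j])
    return t


def exhaustive_three_way_sp(seqs, sub, alphabet, gap: float) -> float:
    """Optimal sum-of-pairs score of a 3-sequence alignment (linear gaps).

    Exhaustive DP over the (n1+1, n2+1, n3+1) lattice with 7 move types.
    Gap-vs-residue costs ``gap`` per pair; gap-vs-gap costs nothing.
    """
    s1, s2, s3 = seqs
    n1, n2, n3 = len(s1), len(s2), len(s3)

    def pair(x, y):
        if x is None and y is None:
            return 0.0
        if x is None or y is None:
            return gap
        return sub[alphabet.index(x)][alphabet.index(y)]

    best = {(0, 0, 0): 0.0}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            for k in range(n3 + 1):
                if (i, j, k) == (0, 0, 0):
                    continue
                candidates = []
                for di, dj, dk in itertools.product((0, 1), repeat=3):
                    if (di, dj, dk) == (0, 0, 0):
                        continue
                    pi, pj, pk = i - di, j - dj, k - dk
                    if pi < 0 or pj < 0 or pk < 0:
                        continue
                    c1 = s1[pi] if di else None
                    c2 = s2[pj] if dj else None
                    c3 = s3[pk] if dk else None
                    col = pair(c1, c2) + pair(c1, c3) + pair(c2, c3)
                    candidates.append(best[(pi, pj, pk)] + col)
                best[(i, j, k)] = max(candidates)
    return best[(n1, n2, n3)]


def linear_sp_score(rows, sub, alphabet, gap: float) -> float:
    """Sum-of-pairs score of an alignment under linear gap costs."""
    total = 0.0
    for r1, r2 in itertools.combinations(rows, 2):
        for a, b in zip(r1, r2):
            if a == "-" and b == "-":
                continue
            if a == "-" or b == "-":
                total += gap
            else:
                total += sub[alphabet.index(a)][alphabet.index(b)]
    return total
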