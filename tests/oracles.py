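"""Independent brute-force oracles used by the tests.

These are deliberately naive reimplementations — exhaustive dynamic
programming for global alignment scores and graph connected components for
single-linkage clustering — kept separate from the package so that the
implementation under test and its oracle share no code.
"""

from itertools import combinations

NEG_INF = float("-inf")


def gotoh_global_score(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Affine-gap global alignment score by the three-state Gotoh recursion.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``. Terminal
    gaps are penalised (true global alignment). ``matrix`` maps residue
    pairs to scores.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[(a[i - 1], b[j - 1])]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open,
                          Y[i - 1][j] - gap_open,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open,
                          X[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend)
    return int(max(M[n][m], X[n][m], Y[n][m]))


def blosum62_dict():
    """BLOSUM62 as a plain dict, taken from biotite's matrix data (the
    scores, not the alignment algorithm, are shared with the implementation)."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    mat = balign.SubstitutionMatrix.std_protein_matrix()
    alph = mat.get_alphabet1()
    letters = [str(s) for s in alph]
    arr = mat.score_matrix()
    return {(x, y): int(arr[i][j])
            for i, x in enumerate(letters) for j, y in enumerate(letters)}


def hamming_identity(a: str, b: str) -> int:
    """Percent identity of two 10-mers by direct position count; 'X' never
    matches."""
    assert len(a) == len(b) == 10
    return 10 * sum(1 for x, y in zip(a, b) if x == y and x != "X")


def connected_components(codes, threshold):
    """Single-linkage clusters as connected components of the thresholded
    identity graph, by exhaustive breadth-first search."""
    codes = list(dict.fromkeys(codes))
    adj = {c: set() for c in codes}
    for a, b in combinations(codes, 2):
        if hamming_identity(a, b) >= threshold:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for c in codes:
        if c in seen:
            continue
        comp, queue = set(), [c]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def random_codes(rng, n):
    """n random valid signature codes (D...K anchored, like real ones)."""
    import numpy as np

    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return ["D" + "".join(rng.choice(aas, size=8)) + "K" for _ in range(n)]
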