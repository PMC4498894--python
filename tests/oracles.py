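"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the scanner oracle checks
every window position by position, and the local-alignment oracle enumerates
every possible set of aligned residue pairs.
"""

from itertools import combinations

from classbsurvey.motifs import AMBIGUITY_AA, STANDARD_AA

_RESIDUES = set(STANDARD_AA + AMBIGUITY_AA)
_IDX = {c: i for i, c in enumerate(STANDARD_AA)}


def brute_scan(seq, pattern):
    """All matching windows, as (start, end, text) 1-based tuples."""
    m = len(pattern.positions)
    out = []
    for s in range(len(seq) - m + 1):
        ok = True
        for k, pos in enumerate(pattern.positions):
            c = seq[s + k]
            if pos is None:
                if c not in _RESIDUES:
                    ok = False
                    break
            elif c not in pos:
                ok = False
                break
        if ok:
            out.append((s + 1, s + m, seq[s : s + m]))
    return out


def enumerated_local_score(a, b, scheme):
    """Optimal local-alignment score by enumerating every alignment.

    A local alignment with affine gaps is determined by its ordered set of
    aligned residue pairs; gaps between consecutive pairs cost
    open + length * extend per gapped sequence.  Enumerating all equal-size
    index subsequences of both sequences covers every alignment (terminal
    gaps never help).  Exponential — use only on tiny inputs.
    """
    best = 0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                s = 0
                for t in range(k):
                    s += scheme.matrix[_IDX[a[ia[t]]], _IDX[b[ib[t]]]]
                    if t:
                        ga = ia[t] - ia[t - 1] - 1
                        gb = ib[t] - ib[t - 1] - 1
                        if ga:
                            s -= scheme.gap_open + ga * scheme.gap_extend
                        if gb:
                            s -= scheme.gap_open + gb * scheme.gap_extend
                best = max(best, s)
    return int(best)


def biopython_local_score(a, b, scheme):
    """Independent dynamic-programming route via Bio.Align.PairwiseAligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return int(aligner.score(a, b))
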