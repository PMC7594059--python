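"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own dynamic-programming code:
ORFs come from frame-wise translation splitting, alignments and profile
scores from exhaustive path enumeration.
"""

import math

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from prospector.io_formats import AMINO_ALPHABET, ProfileHMM

B62 = substitution_matrices.load("BLOSUM62")


def random_dna(rng, length):
    return "".join(
        "ACGTN"[i]
        for i in rng.choice(5, size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04])
    )


def oracle_orfs(seq: str, code: int, min_aa: int):
    """Enumerate maximal stop-free regions in all six frames by hand."""
    table = CodonTable.unambiguous_dna_by_id[code]
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            run = []
            run_start = 0
            for idx, codon in enumerate(codons + ["TAA"]):
                is_stop = idx == len(codons) or codon in table.stop_codons
                if is_stop:
                    if len(run) >= min_aa:
                        start = frame + 3 * run_start
                        end = start + 3 * len(run)
                        if strand == "-":
                            start, end = n - end, n - start
                        out.add((strand, start, end, "".join(run)))
                    run = []
                    run_start = idx + 1
                else:
                    run.append(table.forward_table.get(codon, "X"))
    return out


def brute_force_local(q, t, gap_open=11.0, gap_extend=1.0):
    """Every local alignment path; gap of length k costs open + k·extend;
    the empty alignment scores 0."""
    best = 0.0

    def rec(i, j, score, last):
        nonlocal best
        if score > best:
            best = score
        if i < len(q) and j < len(t):
            rec(i + 1, j + 1, score + B62[q[i]][t[j]], "M")
        if i < len(q):
            rec(i + 1, j, score - (gap_extend if last == "I" else gap_open + gap_extend), "I")
        if j < len(t):
            rec(i, j + 1, score - (gap_extend if last == "D" else gap_open + gap_extend), "D")

    for i in range(len(q)):
        for j in range(len(t)):
            rec(i, j, 0.0, None)
    return best


def random_profile(rng, length):
    def dirichlet_log(n):
        return np.log(rng.dirichlet(np.ones(n) * 2.0))

    return ProfileHMM(
        name="rnd",
        length=length,
        match_emissions=np.vstack([dirichlet_log(20) for _ in range(length)]),
        insert_emissions=np.vstack([dirichlet_log(20) for _ in range(length + 1)]),
        transitions=np.vstack([dirichlet_log(7) for _ in range(length + 1)]),
    )


def enumerate_profile_paths(profile, seq):
    """All local state paths of the package's scoring model: uniform entry
    into any match state, free exit from any match state.  Returns
    (viterbi_bits, forward_bits)."""
    L = profile.length
    x = [AMINO_ALPHABET.index(a) for a in seq]
    em = profile.match_emissions - profile.background
    ei = profile.insert_emissions - profile.background
    t = profile.transitions
    entry = -math.log(L)
    ends = []

    def rec(state, k, i, score):
        if state == "M":
            ends.append(score)
        if i < len(x):
            if state == "M" and k < L:
                rec("M", k + 1, i + 1, score + t[k, 0] + em[k, x[i]])
            if state == "M":
                rec("I", k, i + 1, score + t[k, 1] + ei[k, x[i]])
            if state == "I" and k < L:
                rec("M", k + 1, i + 1, score + t[k, 3] + em[k, x[i]])
            if state == "I":
                rec("I", k, i + 1, score + t[k, 4] + ei[k, x[i]])
            if state == "D" and k < L:
                rec("M", k + 1, i + 1, score + t[k, 5] + em[k, x[i]])
        if state == "M" and k < L:
            rec("D", k + 1, i, score + t[k, 2])
        if state == "D" and k < L:
            rec("D", k + 1, i, score + t[k, 6])

    for i in range(len(x)):
        for k in range(1, L + 1):
            rec("M", k, i + 1, entry + em[k - 1, x[i]])
    best = max(ends)
    total = best + math.log(sum(math.exp(s - best) for s in ends))
    return best / math.log(2), total / math.log(2)


def random_additive_tree(rng, n_taxa):
    """A random binary tree with positive branch lengths, returned as its
    exact path-length (additive) distance matrix over the leaves."""
    labels = [f"t{i}" for i in range(n_taxa)]
    index = {lab: i for i, lab in enumerate(labels)}
    d = np.zeros((n_taxa, n_taxa))
    # Each cluster maps leaf -> distance from the cluster root to that leaf.
    clusters = [{lab: 0.0} for lab in labels]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[int(j)]
        la, lb = float(rng.uniform(1, 10)), float(rng.uniform(1, 10))
        for x, dx in a.items():
            for y, dy in b.items():
                d[index[x], index[y]] = d[index[y], index[x]] = dx + la + lb + dy
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, int(j))]
        clusters.append(merged)
    return labels, d
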