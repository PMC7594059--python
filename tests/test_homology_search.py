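"""Alignment and profile-HMM engines vs exhaustive enumeration oracles,
plus catalytic-motif scanning."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from prospector.io_formats import AMINO_ALPHABET, BACKGROUND_LOG, ProfileHMM
from prospector.homology_search import (
    CANONICAL_C,
    local_align,
    forward_score,
    scan_motifs,
    scan_orfs,
    search_reference,
    viterbi_score,
)
from prospector.synthetic_data import random_protein

from oracles import brute_force_local, enumerate_profile_paths, random_profile

B62 = substitution_matrices.load("BLOSUM62")


def test_smith_waterman_matches_enumeration_on_tiny_pairs(rng):
    for _ in range(40):
        q = random_protein(rng, int(rng.integers(1, 7)))
        t = random_protein(rng, int(rng.integers(1, 7)))
        expected = brute_force_local(q, t)
        if expected == 0.0:
            continue  # empty alignment optimal; hit object still returned
        hit = local_align(q, t)
        assert hit.raw_score == pytest.approx(expected)


def test_identical_sequences_score_diagonal_sum(rng):
    seq = random_protein(rng, 50)
    hit = local_align(seq, seq)
    assert hit.raw_score == pytest.approx(sum(B62[a][a] for a in seq))
    assert hit.query_interval == (0, 50)


def test_score_monotone_under_appended_residues(rng):
    base_q = random_protein(rng, 30)
    base_t = random_protein(rng, 30)
    base = local_align(base_q, base_t).raw_score
    for _ in range(10):
        assert local_align(base_q + random_protein(rng, 10), base_t).raw_score >= base


def test_empty_reference_set_yields_no_hits():
    assert search_reference("q", "MKLV" * 10, []) == []


def test_nonpositive_gap_penalties_rejected():
    with pytest.raises(ValueError):
        local_align("MKL", "MKL", gap_open=0)
    with pytest.raises(ValueError):
        local_align("", "MKL")


def test_evalue_scales_with_search_space(rng):
    seq = random_protein(rng, 40)
    small = local_align(seq, seq, search_space=1e3)
    large = local_align(seq, seq, search_space=1e6)
    assert large.e_value == pytest.approx(small.e_value * 1e3)


# ---------------------------------------------------------------------------
# Profile Viterbi/forward vs path enumeration


def test_viterbi_and_forward_match_path_enumeration(rng):
    for _ in range(30):
        L = int(rng.integers(1, 5))
        n = int(rng.integers(1, 7))
        profile = random_profile(rng, L)
        seq = random_protein(rng, n)
        v_expected, f_expected = enumerate_profile_paths(profile, seq)
        v, _ = viterbi_score(profile, seq)
        f = forward_score(profile, seq)
        assert v == pytest.approx(v_expected, abs=1e-9)
        assert f == pytest.approx(f_expected, abs=1e-9)


def test_forward_dominates_viterbi(rng):
    for _ in range(100):
        profile = random_profile(rng, int(rng.integers(1, 8)))
        seq = random_protein(rng, int(rng.integers(1, 25)))
        v, _ = viterbi_score(profile, seq)
        assert forward_score(profile, seq) >= v - 1e-9


def test_consensus_emission_beats_shuffled(profiles):
    profile = profiles[0]
    consensus = profile.consensus
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        letters = np.array(list(consensus))
        rng.shuffle(letters)
        shuffled = "".join(letters)
        if viterbi_score(profile, consensus)[0] > viterbi_score(profile, shuffled)[0]:
            wins += 1
    assert wins == 20


def test_viterbi_interval_covers_planted_domain(profiles, rng):
    """A profile consensus embedded in random flanks is located there."""
    profile = profiles[1]
    flank5, flank3 = random_protein(rng, 40), random_protein(rng, 60)
    seq = flank5 + profile.consensus + flank3
    bits, (lo, hi) = viterbi_score(profile, seq)
    assert bits > 100
    assert abs(lo - 40) <= 5 and abs(hi - (40 + profile.length)) <= 5


def test_scan_orfs_ordering_and_empty_profiles(profiles, library_bundle):
    from prospector.orf_tools import find_orfs

    contig = next(c for c in library_bundle.contigs if "phage" in c.id)
    orfs = find_orfs(contig, min_aa=200)
    assert scan_orfs(orfs, []) == []
    hits = scan_orfs(orfs, profiles)
    bits = [h.bit_score for h in hits]
    assert bits == sorted(bits, reverse=True)
    assert hits[0].profile_class == "decoy"


# ---------------------------------------------------------------------------
# Catalytic motif scanning


def test_canonical_motifs_located_in_order():
    seq = "M" * 30 + "DYSKWD" + "A" * 20 + "GSGLPNT" + "L" * 10 + "AGDDK" + "W" * 20
    ann = scan_motifs(seq)
    assert ann.motifC is not None and ann.motifC_variant == "GDD"
    assert ann.motifC_canonical
    assert ann.motifA is not None and ann.motifB is not None
    assert ann.motifA[0][0] < ann.motifB[0][0] < ann.motifC[0][0]


def test_gfd_variant_reported_noncanonical():
    seq = "M" * 30 + "DYSKWD" + "A" * 20 + "GSGLPNT" + "L" * 10 + "AGFDK" + "W" * 20
    ann = scan_motifs(seq)
    assert ann.motifC_variant == "GFD"
    assert not ann.motifC_canonical
    assert ann.motifA is not None and ann.motifB is not None


def test_motifless_sequence_yields_nulls():
    ann = scan_motifs("MKLV" * 25)
    assert ann.motifC is None and ann.motifA is None and ann.motifB is None


def test_shuffled_rdrp_rarely_keeps_canonical_c():
    from prospector.synthetic_data import RDRP_SEED_A

    rng = np.random.default_rng(7)
    letters = np.array(list(RDRP_SEED_A))
    found = 0
    for _ in range(100):
        rng.shuffle(letters)
        ann = scan_motifs("".join(letters))
        if ann.motifC_canonical:
            found += 1
    # Null behavior recorded: canonical C by chance in under half of shuffles.
    assert found < 50


def test_canonical_tripeptides_are_the_documented_set():
    assert CANONICAL_C == {"GDD", "SDD", "GDN"}
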