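"""Remote-homology detection engines.

Three detectors live here:

* :func:`local_align` — Smith–Waterman local protein alignment with
  affine gaps (delegated to Biopython's ``PairwiseAligner``) and
  Karlin–Altschul bit scores / e-values, used for the reference-set
  similarity tiers.
* :func:`viterbi_score` / :func:`forward_score` — profile-HMM scoring of
  ORFs in fully local mode (uniform entry over match states, free exit),
  with log-odds taken against the profile background.  Implemented
  directly on the parsed emission/transition arrays; the delete-state
  chain is vectorized with a prefix-scan so scoring a domain-length
  profile against a long ORF stays cheap.
* :func:`scan_motifs` — RdRp catalytic motif annotation (motifs A, B and
  C, with the canonical C tripeptides GDD/SDD/GDN and noncanonical
  variants such as GFD reported but flagged).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import AA_INDEX, ProfileHMM
from .orf_tools import OrfRecord

# Karlin–Altschul parameters for gapped BLOSUM62 with gap open 11 /
# extend 1 (the BLASTP defaults this stage stands in for).
KA_LAMBDA = 0.267
KA_K = 0.041

MOTIF_A_PATTERN = re.compile(r"D.{2,4}D")
MOTIF_B_PATTERN = re.compile(r"G.{0,2}G.{0,3}[NT]")
MOTIF_C_PATTERN = re.compile(r"(?=([GS].[DN]))")
CANONICAL_C = frozenset({"GDD", "SDD", "GDN"})


@dataclass
class AlignmentHit:
    """A local alignment of a query against one labeled reference."""

    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    e_value: float
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    target_label: str = "viral"


@dataclass
class ProfileHit:
    """A profile-HMM hit on a translated ORF."""

    orf_id: str
    profile_name: str
    profile_class: str
    bit_score: float
    e_value: Optional[float] = None
    interval: tuple[int, int] = (0, 0)


@dataclass
class MotifAnnotation:
    """Located RdRp catalytic motifs on one ORF (None when absent)."""

    orf_id: str
    motifA: Optional[tuple[tuple[int, int], str]] = None
    motifB: Optional[tuple[tuple[int, int], str]] = None
    motifC: Optional[tuple[tuple[int, int], str]] = None
    motifC_canonical: bool = False
    motifC_variant: str = ""


# ---------------------------------------------------------------------------
# Smith–Waterman stage

_ALIGNER_CACHE: dict[tuple, PairwiseAligner] = {}


def _get_aligner(matrix: str, gap_open: float, gap_extend: float, mode: str):
    key = (matrix, gap_open, gap_extend, mode)
    if key not in _ALIGNER_CACHE:
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        # BLAST convention: a gap of length k costs open + k * extend.
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        aligner.mode = mode
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def bit_score_from_raw(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def evalue_from_raw(raw: float, search_space: float) -> float:
    return KA_K * search_space * math.exp(-KA_LAMBDA * raw)


def local_align(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    target_id: str = "target",
    target_label: str = "viral",
    search_space: Optional[float] = None,
) -> AlignmentHit:
    """Optimal Smith–Waterman local alignment with affine gaps.

    ``search_space`` is the m·n product used for the e-value; it defaults
    to the product of the two sequence lengths but callers searching a
    reference set pass the total reference size.
    """
    if not query or not target:
        raise ValueError("sequences must be nonempty")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive costs")
    aligner = _get_aligner(matrix, gap_open, gap_extend, "local")
    alignments = aligner.align(query, target)
    raw = float(alignments.score)
    best = alignments[0]
    blocks_q, blocks_t = best.aligned
    if len(blocks_q):
        q_iv = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
        t_iv = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    else:  # no positive-scoring alignment
        q_iv = t_iv = (0, 0)
    if search_space is None:
        search_space = float(len(query) * len(target))
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=raw,
        bit_score=bit_score_from_raw(raw),
        e_value=evalue_from_raw(raw, search_space),
        query_interval=q_iv,
        target_interval=t_iv,
        target_label=target_label,
    )


def search_reference(
    query_id: str,
    query: str,
    references: Sequence[tuple[str, str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[AlignmentHit]:
    """Align one query against a labeled reference set.

    E-values use the whole reference set as the search space (m × total
    reference residues).  Hits are sorted by bit score descending with a
    lexicographic tie-break on target id.
    """
    if not references:
        return []
    total = float(sum(len(seq) for _, seq, _ in references))
    hits = [
        local_align(
            query,
            seq,
            matrix,
            gap_open,
            gap_extend,
            query_id=query_id,
            target_id=rid,
            target_label=label,
            search_space=len(query) * total,
        )
        for rid, seq, label in references
    ]
    hits.sort(key=lambda h: (-h.bit_score, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# Profile-HMM stage

_LN2 = math.log(2.0)


def _encode(seq: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, -1) for a in seq.upper()], dtype=int)


def _prepared(profile: ProfileHMM):
    """Per-profile score tables, cached on the profile object."""
    cache = getattr(profile, "_score_cache", None)
    if cache is None:
        # Column 20 holds the score of unknown residues (background odds).
        match_lo = np.zeros((profile.length, 21))
        match_lo[:, :20] = profile.match_emissions - profile.background
        ins_lo = np.zeros((profile.length + 1, 21))
        ins_lo[:, :20] = profile.insert_emissions - profile.background
        cache = (match_lo, ins_lo, profile.transitions)
        profile._score_cache = cache
    return cache


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq.upper()) - set(AA_INDEX) - set("XBZJUO*")
    if bad:
        raise ValueError(f"sequence is not amino acid (offending: {sorted(bad)})")


def viterbi_score(profile: ProfileHMM, seq: str) -> tuple[float, tuple[int, int]]:
    """Max log-odds (bits) over local alignments of ``seq`` to the profile.

    Entry is uniform over match states (cost ``ln L``), exit from any
    match state is free, and residues outside the matched interval score
    zero against the background.  Returns the score and the matched
    query interval (0-based half-open).
    """
    _check_sequence(seq)
    match_lo, ins_lo, trans = _prepared(profile)
    L = profile.length
    x = _encode(seq)
    x[x < 0] = 20
    n = len(x)
    entry = -math.log(L)
    NEG = -np.inf
    # State arrays over k = 1..L stored in index 0..L-1.
    vm_prev = np.full(L, NEG)
    vi_prev = np.full(L, NEG)
    vd_prev = np.full(L, NEG)
    sm_prev = np.zeros(L, dtype=int)
    si_prev = np.zeros(L, dtype=int)
    sd_prev = np.zeros(L, dtype=int)
    mm = trans[1:, 0]  # M_k -> M_{k+1}, k = 1..L
    mi = trans[1:, 1]
    md = trans[1:, 2]
    im = trans[1:, 3]
    ii = trans[1:, 4]
    dm = trans[1:, 5]
    dd = trans[1:, 6]
    best = NEG
    best_iv = (0, 0)
    with np.errstate(invalid="ignore"):
        for i in range(n):
            em = match_lo[:, x[i]]
            # Candidates for M_k: fresh entry, M/I/D at k-1 from the
            # previous row.
            c_entry = np.full(L, entry)
            c_m = np.full(L, NEG)
            c_i = np.full(L, NEG)
            c_d = np.full(L, NEG)
            c_m[1:] = vm_prev[:-1] + mm[:-1]
            c_i[1:] = vi_prev[:-1] + im[:-1]
            c_d[1:] = vd_prev[:-1] + dm[:-1]
            stack = np.vstack([c_entry, c_m, c_i, c_d])
            choice = stack.argmax(axis=0)
            vm = em + stack[choice, np.arange(L)]
            sm = np.full(L, i, dtype=int)
            prev_starts = np.vstack(
                [
                    np.full(L, i, dtype=int),
                    np.concatenate([[0], sm_prev[:-1]]),
                    np.concatenate([[0], si_prev[:-1]]),
                    np.concatenate([[0], sd_prev[:-1]]),
                ]
            )
            sm = prev_starts[choice, np.arange(L)]
            # I_k from M_k / I_k of the previous row.
            a = vm_prev + mi
            b = vi_prev + ii
            vi = ins_lo[1:, x[i]] + np.maximum(a, b)
            si = np.where(a >= b, sm_prev, si_prev)
            # D chain within this row: prefix-scan over k.
            vd = np.full(L, NEG)
            sd = np.zeros(L, dtype=int)
            if L > 1:
                # P[k] accumulates D->D costs; entering D_{j+1} from M_j
                # pays only MD, so the baseline subtracts P up to j.
                p = np.concatenate([[0.0], np.cumsum(dd[:-1])])
                a_enter = vm[:-1] + md[:-1] - p[1:]
                run = np.maximum.accumulate(a_enter)
                idx = np.arange(L - 1)
                arg = np.maximum.accumulate(np.where(a_enter >= run, idx, 0))
                vd[1:] = run + p[1:]
                sd[1:] = sm[arg]
            row_best = vm.max()
            if row_best > best:
                k_best = int(vm.argmax())
                best = row_best
                best_iv = (int(sm[k_best]), i + 1)
            vm_prev, vi_prev, vd_prev = vm, vi, vd
            sm_prev, si_prev, sd_prev = sm, si, sd
    return best / _LN2, best_iv


def forward_score(profile: ProfileHMM, seq: str) -> float:
    """Log-sum (bits) over the same local path ensemble as Viterbi."""
    _check_sequence(seq)
    match_lo, ins_lo, trans = _prepared(profile)
    L = profile.length
    x = _encode(seq)
    x[x < 0] = 20
    n = len(x)
    entry = -math.log(L)
    NEG = -np.inf
    fm_prev = np.full(L, NEG)
    fi_prev = np.full(L, NEG)
    fd_prev = np.full(L, NEG)
    mm = trans[1:, 0]
    mi = trans[1:, 1]
    md = trans[1:, 2]
    im = trans[1:, 3]
    ii = trans[1:, 4]
    dm = trans[1:, 5]
    dd = trans[1:, 6]
    total = NEG
    with np.errstate(invalid="ignore"):
        for i in range(n):
            em = match_lo[:, x[i]]
            c = np.full(L, entry)
            c_m = np.full(L, NEG)
            c_i = np.full(L, NEG)
            c_d = np.full(L, NEG)
            c_m[1:] = fm_prev[:-1] + mm[:-1]
            c_i[1:] = fi_prev[:-1] + im[:-1]
            c_d[1:] = fd_prev[:-1] + dm[:-1]
            fm = em + np.logaddexp(np.logaddexp(c, c_m), np.logaddexp(c_i, c_d))
            fi = ins_lo[1:, x[i]] + np.logaddexp(fm_prev + mi, fi_prev + ii)
            fd = np.full(L, NEG)
            if L > 1:
                p = np.concatenate([[0.0], np.cumsum(dd[:-1])])
                a_enter = fm[:-1] + md[:-1] - p[1:]
                fd[1:] = np.logaddexp.accumulate(a_enter) + p[1:]
            total = np.logaddexp(total, np.logaddexp.reduce(fm))
            fm_prev, fi_prev, fd_prev = fm, fi, fd
    return total / _LN2


def classify_profile(name: str) -> str:
    """Name-convention profile class: decoy profiles carry a ``phage`` or
    ``decoy`` tag in their name, everything else is an RdRp profile."""
    lowered = name.lower()
    if "phage" in lowered or "decoy" in lowered:
        return "decoy"
    return "rdrp_viral"


def profile_evalue_calibrated(
    profile: ProfileHMM, bit_score: float, n_targets: int = 1
) -> Optional[float]:
    """Exponential-tail e-value from the profile's FORWARD calibration."""
    if "FORWARD" not in profile.calibration:
        return None
    tau, lam = profile.calibration["FORWARD"]
    return n_targets * math.exp(-lam * (bit_score - tau))


def profile_evalue_permutation(
    profile: ProfileHMM,
    seq: str,
    observed_bits: float,
    n_shuffles: int = 200,
    seed: int = 0,
) -> float:
    """Rank-based empirical p-value against a residue-shuffled null."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    exceed = 0
    for _ in range(n_shuffles):
        rng.shuffle(letters)
        score, _ = viterbi_score(profile, "".join(letters))
        if score >= observed_bits:
            exceed += 1
    return (1 + exceed) / (n_shuffles + 1)


def score_orf(
    profile: ProfileHMM,
    orf: OrfRecord | str,
    profile_class: Optional[str] = None,
) -> ProfileHit:
    """Viterbi-score one ORF against one profile."""
    seq = orf if isinstance(orf, str) else orf.aa_seq
    orf_id = orf if isinstance(orf, str) else orf.id
    bits, interval = viterbi_score(profile, seq)
    e_value = profile_evalue_calibrated(profile, bits)
    return ProfileHit(
        orf_id=orf_id,
        profile_name=profile.name,
        profile_class=profile_class or classify_profile(profile.name),
        bit_score=bits,
        e_value=e_value,
        interval=interval,
    )


def scan_orfs(
    orfs: Sequence[OrfRecord],
    profiles: Sequence[ProfileHMM],
    profile_classes: Optional[dict[str, str]] = None,
) -> list[ProfileHit]:
    """Score every (ORF, profile) pair; sort by bit score descending with
    lexicographic tie-breaks on profile name then ORF id."""
    hits = []
    for orf in orfs:
        for profile in profiles:
            cls = (
                profile_classes.get(profile.name)
                if profile_classes
                else None
            )
            hits.append(score_orf(profile, orf, profile_class=cls))
    hits.sort(key=lambda h: (-h.bit_score, h.profile_name, h.orf_id))
    return hits


# ---------------------------------------------------------------------------
# Catalytic motif scanning


def scan_motifs(orf: OrfRecord | str, window: int = 200) -> MotifAnnotation:
    """Locate RdRp catalytic motifs A, B and C on an ORF.

    Motif C is the anchor: the best match to ``[GS]-x-[DN]``, canonical
    when the tripeptide is GDD, SDD or GDN.  Motifs A (``D-x(2,4)-D``)
    and B (G-rich then a conserved N/T) are searched upstream of C within
    ``window`` residues, honoring the A < B < C ordering.  Canonical C
    anchors supporting a full A<B<C chain are preferred; noncanonical
    variants (e.g. GFD) are reported with ``motifC_canonical=False``.
    """
    seq = orf if isinstance(orf, str) else orf.aa_seq
    orf_id = orf if isinstance(orf, str) else orf.id
    candidates = [
        (m.start(1), m.group(1)) for m in MOTIF_C_PATTERN.finditer(seq)
    ]
    if not candidates:
        return MotifAnnotation(orf_id=orf_id)
    candidates.sort(key=lambda c: (c[1] not in CANONICAL_C, c[0]))

    def upstream_motifs(c_pos: int):
        lo = max(0, c_pos - window)
        region = seq[lo:c_pos]
        b_hit = a_hit = None
        for mb in MOTIF_B_PATTERN.finditer(region):
            b_start = lo + mb.start()
            ma_best = None
            for ma in MOTIF_A_PATTERN.finditer(region[: mb.start()]):
                ma_best = ma
                break
            if ma_best is not None:
                a_hit = ((lo + ma_best.start(), lo + ma_best.end()), ma_best.group())
                b_hit = ((b_start, lo + mb.end()), mb.group())
                break
            if b_hit is None:
                b_hit = ((b_start, lo + mb.end()), mb.group())
        if a_hit is None:
            ma = MOTIF_A_PATTERN.search(region)
            if ma:
                a_hit = ((lo + ma.start(), lo + ma.end()), ma.group())
        return a_hit, b_hit

    chosen = None
    for c_pos, tri in candidates:
        a_hit, b_hit = upstream_motifs(c_pos)
        full = a_hit is not None and b_hit is not None and a_hit[0][0] < b_hit[0][0]
        if full:
            chosen = (c_pos, tri, a_hit, b_hit)
            break
    if chosen is None:
        c_pos, tri = candidates[0]
        a_hit, b_hit = upstream_motifs(c_pos)
        chosen = (c_pos, tri, a_hit, b_hit)
    c_pos, tri, a_hit, b_hit = chosen
    return MotifAnnotation(
        orf_id=orf_id,
        motifA=a_hit,
        motifB=b_hit,
        motifC=((c_pos, c_pos + 3), tri),
        motifC_canonical=tri in CANONICAL_C,
        motifC_variant=tri,
    )
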