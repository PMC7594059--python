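"""Evidence-tier triage of contigs and candidate arbitration.

Every contig receives exactly one of four tiers:

* ``strong_hit``   — best reference e-value < 1e-05,
* ``weak_hit``     — best e-value in [1e-05, 1e-03),
* ``orphan_long_orf`` — no hit below 1e-03 but at least one ORF ≥ 200 aa,
* ``dark_matter``  — no signal at all.

RdRp candidacy is decided by winner-takes-all arbitration over the union
of reference hits and profile hits: the candidate survives only when the
single best-scoring hit is viral.  A best-scoring phage/decoy hit rejects
the candidate outright — the false-positive control that keeps
bacteriophage-like signals out of the virus tables.  Failing the
catalytic-motif gate never discards a candidate; it only downgrades its
confidence to ``unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .homology_search import AlignmentHit, MotifAnnotation, ProfileHit
from .orf_tools import OrfRecord

TIERS = ("strong_hit", "weak_hit", "orphan_long_orf", "dark_matter")

STRONG_EVALUE = 1e-05
WEAK_EVALUE = 1e-03
MIN_ORPHAN_ORF_AA = 200


@dataclass
class TriageResult:
    contig_id: str
    tier: str
    best_reference_hit: Optional[AlignmentHit] = None
    best_profile_hits: list[ProfileHit] = field(default_factory=list)
    candidate_virus: bool = False
    rejection_reason: Optional[str] = None
    confidence: Optional[str] = None
    route: Optional[str] = None


def classify_contig(
    contig_id: str,
    reference_hits: Sequence[AlignmentHit],
    orfs: Sequence[OrfRecord],
    strong_evalue: float = STRONG_EVALUE,
    weak_evalue: float = WEAK_EVALUE,
    min_orf_aa: int = MIN_ORPHAN_ORF_AA,
) -> str:
    """Assign one evidence tier to a contig."""
    best = min((h.e_value for h in reference_hits), default=float("inf"))
    if best < strong_evalue:
        return "strong_hit"
    if best < weak_evalue:
        return "weak_hit"
    if any(len(o) >= min_orf_aa for o in orfs):
        return "orphan_long_orf"
    return "dark_matter"


def arbitrate_candidate(
    profile_hits: Sequence[ProfileHit],
    reference_hits: Sequence[AlignmentHit] = (),
) -> tuple[bool, Optional[str]]:
    """Winner-takes-all arbitration across profile and reference hits.

    The pooled hits are ranked by bit score (lexicographic name
    tie-break); the contig is a candidate virus iff the winner is viral
    (``rdrp_viral`` profile or ``viral`` reference).  Decoy winners give
    a ``phage-like`` rejection, nonviral reference winners a
    ``nonviral best hit`` rejection.
    """
    pool: list[tuple[float, str, str]] = []
    for h in profile_hits:
        pool.append((h.bit_score, h.profile_name, h.profile_class))
    for h in reference_hits:
        pool.append((h.bit_score, h.target_id, h.target_label))
    if not pool:
        return False, "no hits"
    pool.sort(key=lambda t: (-t[0], t[1]))
    _, name, cls = pool[0]
    if cls in ("rdrp_viral", "viral"):
        return True, None
    if cls == "decoy":
        return False, f"phage-like: best hit is decoy profile {name}"
    return False, f"nonviral best hit: {name}"


def motif_gate(annotation: MotifAnnotation) -> str:
    """``confirmed`` iff motifs A, B and a canonical C are all located in
    order; anything less (including a GFD-style variant C) is
    ``unresolved`` — retained, but not confidently called an RdRp."""
    if (
        annotation.motifA is not None
        and annotation.motifB is not None
        and annotation.motifC is not None
        and annotation.motifC_canonical
        and annotation.motifA[0][0] < annotation.motifB[0][0] < annotation.motifC[0][0]
    ):
        return "confirmed"
    return "unresolved"


def summarize_tiers(results: Iterable[TriageResult]) -> pd.DataFrame:
    """Tier counts and fractions over all triaged contigs."""
    results = list(results)
    rows = []
    total = len(results)
    counts = {tier: 0 for tier in TIERS}
    for r in results:
        counts[r.tier] += 1
    for tier in TIERS:
        rows.append(
            {
                "tier": tier,
                "count": counts[tier],
                "fraction": counts[tier] / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
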