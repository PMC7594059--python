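"""End-to-end orchestration: contigs → ORFs → search → triage → report.

One run takes a set of library FASTAs, a labeled reference protein set,
a profile collection, and optional per-contig read counts, and produces
per-library triage tables, a virus-candidate report, tier summaries,
demarcation outputs and a run log echoing every threshold used.  The
run is deterministic for a fixed configuration and seed.

Candidates arrive by two routes that end in the same arbitration:

* similarity route — the contig's best reference hit is viral at the
  strong/weak tier;
* profile route — the contig is an orphan with a ≥200-aa ORF whose best
  profile hit is an RdRp profile.

Profile hits below ``min_profile_bits`` never enter arbitration; this
keeps chance local alignments of long random ORFs from being promoted
by a winner-takes-all rule that has no other notion of significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .abundance import abundance as read_fraction_percent
from .abundance import classify_abundance, read_counts_tsv
from .demarcation import RankDistributions, demarcate, global_identity, nj_tree
from .homology_search import ProfileHit, scan_orfs, search_reference
from .io_formats import (
    Contig,
    parse_hmmer3_profile,
    read_fasta,
    read_labeled_proteins,
    write_tsv,
)
from .orf_tools import OrfRecord, find_frameshift_candidates, find_orfs
from .triage import (
    TriageResult,
    arbitrate_candidate,
    classify_contig,
    motif_gate,
    summarize_tiers,
)
from .homology_search import scan_motifs

logger = logging.getLogger("prospector")


class ConfigurationError(ValueError):
    """Missing or inconsistent run inputs."""


@dataclass
class RunConfig:
    fasta: list[str]
    profiles: str
    reference: str
    counts: Optional[str] = None
    total_non_rrna: Optional[int] = None
    outdir: str = "prospector_out"
    contig_min_nt: int = 200
    min_orf_aa: int = 200
    min_ref_orf_aa: int = 60
    max_orfs_per_contig: int = 8
    strong_evalue: float = 1e-05
    weak_evalue: float = 1e-03
    min_profile_bits: float = 15.0
    demarcation_thresholds: list[float] = field(default_factory=lambda: [90.0, 50.0])
    genetic_codes: list[int] = field(default_factory=lambda: [1, 4])
    cross_library_floor: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.fasta, str):
            self.fasta = [self.fasta]
        if not self.fasta:
            raise ConfigurationError("at least one contig FASTA is required")
        if not all(0 < t <= 100 for t in self.demarcation_thresholds):
            raise ConfigurationError("demarcation thresholds must be in (0, 100]")
        if not self.strong_evalue < self.weak_evalue:
            raise ConfigurationError("e-value bounds must be ordered strong < weak")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class CandidateRecord:
    name: str
    contig: Contig
    library: str
    route: str
    tier: str
    protein: str
    best_hit: str
    best_hit_class: str
    best_hit_bits: float
    percent_identity: Optional[float]
    motif_confidence: str
    architecture: str
    genetic_code: int
    read_count: Optional[int] = None
    percent_non_rrna: Optional[float] = None
    abundance_class: Optional[str] = None


@dataclass
class LibraryResult:
    library: str
    triage: list[TriageResult]
    candidates: list[CandidateRecord]
    tier_summary: pd.DataFrame


def _dedupe_orfs(orfs: Sequence[OrfRecord]) -> list[OrfRecord]:
    seen = {}
    for orf in sorted(orfs, key=lambda o: (o.start, o.end, o.strand, o.genetic_code)):
        key = (orf.strand, orf.start, orf.end, orf.aa_seq)
        if key not in seen:
            seen[key] = orf
    return list(seen.values())


def _contig_orfs(contig: Contig, config: RunConfig) -> list[OrfRecord]:
    pool: list[OrfRecord] = []
    for code in config.genetic_codes:
        pool.extend(find_orfs(contig, code=code, min_aa=config.min_ref_orf_aa))
    return _dedupe_orfs(pool)


def process_contig(
    contig: Contig,
    references: Sequence[tuple[str, str, str]],
    profiles,
    config: RunConfig,
) -> tuple[TriageResult, Optional[CandidateRecord]]:
    """Triage one contig and, if it survives arbitration, build its
    candidate-report row."""
    orfs = _contig_orfs(contig, config)
    search_orfs = sorted(orfs, key=len, reverse=True)[: config.max_orfs_per_contig]
    ref_hits = []
    for orf in search_orfs:
        ref_hits.extend(search_reference(orf.id, orf.aa_seq, references))
    ref_hits.sort(key=lambda h: (-h.bit_score, h.target_id))
    long_orfs = [o for o in orfs if len(o) >= config.min_orf_aa]
    tier = classify_contig(
        contig.id,
        ref_hits,
        orfs,
        strong_evalue=config.strong_evalue,
        weak_evalue=config.weak_evalue,
        min_orf_aa=config.min_orf_aa,
    )
    result = TriageResult(
        contig_id=contig.id,
        tier=tier,
        best_reference_hit=ref_hits[0] if ref_hits else None,
    )
    profile_hits: list[ProfileHit] = []
    if long_orfs and tier != "dark_matter":
        profile_hits = scan_orfs(long_orfs, profiles)
        result.best_profile_hits = profile_hits[:5]
    if tier == "dark_matter":
        result.candidate_virus = False
        result.rejection_reason = "dark matter: no signal"
        return result, None
    strong_hits = [h for h in profile_hits if h.bit_score >= config.min_profile_bits]
    candidate, reason = arbitrate_candidate(strong_hits, ref_hits)
    result.candidate_virus = candidate
    result.rejection_reason = reason
    if not candidate:
        return result, None

    orf_by_id = {o.id: o for o in orfs}
    if strong_hits and (
        not ref_hits or strong_hits[0].bit_score >= ref_hits[0].bit_score
    ):
        route = "profile"
        best = strong_hits[0]
        cand_orf = orf_by_id[best.orf_id]
        best_hit, best_cls, best_bits = best.profile_name, best.profile_class, best.bit_score
        # %ID against the profile consensus stands in for a pairwise hit.
        ref_seq = next(p.consensus for p in profiles if p.name == best.profile_name)
    else:
        route = "similarity"
        best = ref_hits[0]
        cand_orf = orf_by_id[best.query_id]
        best_hit, best_cls, best_bits = best.target_id, best.target_label, best.bit_score
        ref_seq = next(seq for rid, seq, _ in references if rid == best.target_id)

    protein = cand_orf.aa_seq
    architecture = "single_orf"
    fusions = find_frameshift_candidates(contig, orfs)
    for fusion in sorted(fusions, key=lambda f: -len(f.fused_aa)):
        if fusion.orf2.aa_seq == cand_orf.aa_seq or fusion.orf1.aa_seq == cand_orf.aa_seq:
            protein = fusion.fused_aa
            architecture = f"-1_frameshift@{fusion.slip_pos}"
            break
    pid = global_identity(protein, ref_seq) if ref_seq else None
    annotation = scan_motifs(protein)
    confidence = motif_gate(annotation)
    result.confidence = confidence
    result.route = route
    record = CandidateRecord(
        name=f"cand_{contig.id}",
        contig=contig,
        library=contig.library,
        route=route,
        tier=tier,
        protein=protein,
        best_hit=best_hit,
        best_hit_class=best_cls,
        best_hit_bits=round(best_bits, 2),
        percent_identity=round(pid, 1) if pid is not None else None,
        motif_confidence=confidence,
        architecture=architecture,
        genetic_code=cand_orf.genetic_code,
    )
    return result, record


def run_library(
    contigs: Sequence[Contig],
    references,
    profiles,
    config: RunConfig,
    counts: Optional[dict[str, int]] = None,
    total_non_rrna: Optional[int] = None,
    library: str = "",
) -> LibraryResult:
    triage_results = []
    candidates = []
    for contig in contigs:
        result, record = process_contig(contig, references, profiles, config)
        triage_results.append(result)
        if record is not None:
            candidates.append(record)
    if counts:
        total = total_non_rrna or sum(counts.values())
        for record in candidates:
            count = counts.get(record.contig.id)
            if count is not None:
                record.read_count = count
                record.percent_non_rrna = read_fraction_percent(count, total)
                record.abundance_class = classify_abundance(record.percent_non_rrna)
    return LibraryResult(
        library=library,
        triage=triage_results,
        candidates=candidates,
        tier_summary=summarize_tiers(triage_results),
    )


def cross_library_compare(
    candidates: Sequence[CandidateRecord], floor: float = 25.0
) -> pd.DataFrame:
    """All cross-library candidate pairs with global identity ≥ floor."""
    rows = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            a, b = candidates[i], candidates[j]
            if a.library == b.library:
                continue
            pid = global_identity(a.protein, b.protein)
            if pid >= floor:
                rows.append(
                    {
                        "candidate_a": a.name,
                        "library_a": a.library,
                        "candidate_b": b.name,
                        "library_b": b.library,
                        "percent_identity": round(pid, 1),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_a",
            "library_a",
            "candidate_b",
            "library_b",
            "percent_identity",
        ],
    )


def _triage_frame(results: Sequence[TriageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        best = r.best_reference_hit
        rows.append(
            {
                "contig_id": r.contig_id,
                "tier": r.tier,
                "best_hit": best.target_id if best else "",
                "best_hit_label": best.target_label if best else "",
                "best_hit_evalue": f"{best.e_value:.3g}" if best else "",
                "candidate_virus": r.candidate_virus,
                "confidence": r.confidence or "",
                "route": r.route or "",
                "reason": r.rejection_reason or "",
            }
        )
    return pd.DataFrame(rows)


def _candidate_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "name": c.name,
                "contig_id": c.contig.id,
                "library": c.library,
                "length_nt": len(c.contig.seq),
                "read_count": c.read_count,
                "percent_non_rrna": c.percent_non_rrna,
                "abundance_class": c.abundance_class or "",
                "route": c.route,
                "tier": c.tier,
                "best_hit": c.best_hit,
                "best_hit_class": c.best_hit_class,
                "best_hit_bits": c.best_hit_bits,
                "percent_identity": c.percent_identity,
                "motif_confidence": c.motif_confidence,
                "architecture": c.architecture,
                "genetic_code": c.genetic_code,
                "protein": c.protein,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "contig_id", "library", "length_nt", "read_count",
            "percent_non_rrna", "abundance_class", "route", "tier",
            "best_hit", "best_hit_class", "best_hit_bits",
            "percent_identity", "motif_confidence", "architecture",
            "genetic_code", "protein",
        ],
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full configured run and write all reports.

    Returns a mapping of output names to paths.  Raises
    :class:`ConfigurationError` before any compute if inputs are missing.
    """
    for path in [*config.fasta, config.profiles, config.reference] + (
        [config.counts] if config.counts else []
    ):
        if not Path(path).exists():
            raise ConfigurationError(f"input not found: {path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines = [
        f"seed={config.seed}",
        f"contig_min_nt={config.contig_min_nt}",
        f"min_orf_aa={config.min_orf_aa}",
        f"strong_evalue={config.strong_evalue}",
        f"weak_evalue={config.weak_evalue}",
        f"min_profile_bits={config.min_profile_bits}",
        f"demarcation_thresholds={config.demarcation_thresholds}",
        f"genetic_codes={config.genetic_codes}",
        f"cross_library_floor={config.cross_library_floor}",
    ]
    references = read_labeled_proteins(config.reference)
    profiles = parse_hmmer3_profile(config.profiles)
    counts = read_counts_tsv(config.counts) if config.counts else None

    outputs: dict[str, Path] = {"log": log_path}
    all_candidates: list[CandidateRecord] = []
    for fasta_path in config.fasta:
        library = Path(fasta_path).parent.name or Path(fasta_path).stem
        contigs = read_fasta(fasta_path, library=library, min_length=config.contig_min_nt)
        for contig in contigs:
            contig.library = library
        log_lines.append(f"library {library}: {len(contigs)} contigs from {fasta_path}")
        result = run_library(
            contigs,
            references,
            profiles,
            config,
            counts=counts,
            total_non_rrna=config.total_non_rrna,
            library=library,
        )
        prefix = f"{library}." if len(config.fasta) > 1 else ""
        triage_path = outdir / f"{prefix}triage.tsv"
        write_tsv(_triage_frame(result.triage), triage_path)
        outputs[f"{prefix}triage"] = triage_path
        summary_path = outdir / f"{prefix}tier_summary.tsv"
        write_tsv(result.tier_summary, summary_path)
        outputs[f"{prefix}tier_summary"] = summary_path
        cand_path = outdir / f"{prefix}candidates.tsv"
        write_tsv(_candidate_frame(result.candidates), cand_path)
        outputs[f"{prefix}candidates"] = cand_path
        log_lines.append(
            f"library {library}: {len(result.candidates)} candidate virus(es)"
        )
        all_candidates.extend(result.candidates)

    seqs = [(c.name, c.protein) for c in all_candidates]
    if len(seqs) >= 2:
        for threshold in config.demarcation_thresholds:
            res = demarcate(seqs, threshold)
            part = pd.DataFrame(
                [
                    {"species": f"sp_{i + 1}", "member": member}
                    for i, cluster in enumerate(res.clusters)
                    for member in cluster
                ]
            )
            path = outdir / f"species_t{threshold:g}.tsv"
            write_tsv(part, path)
            outputs[f"species_t{threshold:g}"] = path
            log_lines.append(
                f"demarcation at {threshold:g}%: {len(res.clusters)} species"
            )
        matrix = res.matrix
        mat_df = pd.DataFrame(matrix.values, columns=matrix.labels)
        mat_df.insert(0, "label", matrix.labels)
        mat_path = outdir / "identity_matrix.tsv"
        write_tsv(mat_df, mat_path)
        outputs["identity_matrix"] = mat_path
        if len(seqs) >= 3:
            tree_path = outdir / "candidates.nwk"
            tree_path.write_text(nj_tree(matrix) + "\n")
            outputs["tree"] = tree_path
    if len(config.fasta) > 1:
        pairs = cross_library_compare(all_candidates, config.cross_library_floor)
        pairs_path = outdir / "cross_library_pairs.tsv"
        write_tsv(pairs, pairs_path)
        outputs["cross_library_pairs"] = pairs_path

    log_path.write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return outputs
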