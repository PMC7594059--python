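"""Seeded mock metatranscriptomes with planted divergent RNA viruses.

The generator emulates the composition of a nonaxenic algal culture
library after rRNA depletion and assembly: abundant host-like coding
contigs, rRNA-like repeats, bacteriophage decoy ORFs, and planted viral
contigs whose RdRp diverges from a known seed protein by a controlled
amount.  Every emitted contig carries one row in a machine-readable
truth table, so detection, arbitration and demarcation can all be scored
without any external database.

Divergence is introduced by substitution only (no indels), with
replacement residues drawn from a fixed BLOSUM62-derived exchangeability
table, so the realized identity of a mutant equals its target up to
rounding.  Back-translation picks uniformly among the synonymous codons
of the plan's genetic code; under the protozoan/mold mitochondrial code
(table 4) tryptophan may be encoded by TGA, which truncates
standard-code translation — exactly the ambiguity real mito-like virus
genomes present.

Per-contig read counts are drawn directly from a log-normal (no read
simulation: assembly and quantification are upstream of this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import (
    AA_INDEX,
    AMINO_ALPHABET,
    BACKGROUND_FREQS,
    Contig,
    ProfileHMM,
    build_profile,
    write_fasta,
    write_hmmer3_profile,
    write_labeled_proteins,
    write_tsv,
)
from .orf_tools import SLIPPERY_HEPTAMER, SUPPORTED_CODES, reverse_complement

GENOME_ARCHITECTURES = ("single_orf", "two_orf_frameshift", "two_orf_adjacent")

CONTIG_CLASSES = ("host", "rrna_like", "phage_decoy", "virus")


class GenerationError(ValueError):
    """A plan cannot be realized (e.g. genome too short for its ORFs)."""


# ---------------------------------------------------------------------------
# Plans


@dataclass
class VirusPlan:
    """One planted virus: an RdRp source diverged to a target identity and
    packaged into a genome architecture."""

    name: str
    rdrp_source: str  # amino-acid sequence of the seed RdRp
    target_identity: float
    genome_architecture: str = "single_orf"
    genetic_code: int = 1
    genome_length: int = 0  # 0 = minimal length that fits
    read_count: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.target_identity <= 100:
            raise ValueError("target identity must be in (0, 100]")
        if self.genome_architecture not in GENOME_ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.genome_architecture!r}")
        if self.genetic_code not in SUPPORTED_CODES:
            raise ValueError(f"unsupported genetic code {self.genetic_code}")
        if self.read_count < 0:
            raise ValueError("read count must be nonnegative")


@dataclass
class LibraryPlan:
    """Composition of one synthetic library."""

    n_host_contigs: int = 24
    host_length_range: tuple[int, int] = (600, 2100)
    n_rrna_like: int = 4
    n_decoy_phage: int = 4
    planted_viruses: list[VirusPlan] = field(default_factory=list)
    abundance_lognormal_params: tuple[float, float] = (5.5, 1.5)
    total_non_rrna_reads: int = 1_000_000
    seed: int = 0
    library: str = "SYN_1"
    host_coding_fraction: float = 0.5
    host_long_orf_fraction: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_host_contigs, self.n_rrna_like, self.n_decoy_phage) < 0:
            raise ValueError("contig counts must be nonnegative")
        planted = sum(v.read_count for v in self.planted_viruses)
        if self.total_non_rrna_reads < planted:
            raise ValueError(
                "total non-rRNA reads must cover the planted virus read counts"
            )


@dataclass
class LibraryBundle:
    contigs: list[Contig]
    counts: dict[str, int]
    truth: pd.DataFrame
    plan: LibraryPlan


# ---------------------------------------------------------------------------
# Protein mutation

_B62 = substitution_matrices.load("BLOSUM62")
_BG_NORM = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()


def _exchange_table() -> np.ndarray:
    """P(b | a) for substitutions: background-weighted BLOSUM62 odds with
    the diagonal removed."""
    table = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ALPHABET):
        for j, b in enumerate(AMINO_ALPHABET):
            if i != j:
                table[i, j] = BACKGROUND_FREQS[j] * 2.0 ** (_B62[a][b] / 2.0)
        table[i] /= table[i].sum()
    return table


EXCHANGE = _exchange_table()


def mutate_protein(protein: str, target_identity: float, seed: int) -> str:
    """Substitute residues to reach ``target_identity`` percent identity.

    Exactly ``round(L · (1 − t/100))`` positions are changed, each to a
    different residue drawn from the exchangeability table, so the
    realized identity equals the target up to the rounding granularity
    of one position.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    if len(protein) < 20:
        raise ValueError("protein must be at least 20 residues")
    rng = np.random.default_rng(seed)
    n = len(protein)
    k = round(n * (1.0 - target_identity / 100.0))
    positions = rng.choice(n, size=k, replace=False)
    out = list(protein)
    for pos in positions:
        a = out[pos]
        if a in AA_INDEX:
            out[pos] = AMINO_ALPHABET[rng.choice(20, p=EXCHANGE[AA_INDEX[a]])]
        else:
            out[pos] = AMINO_ALPHABET[rng.choice(20, p=_BG_NORM)]
    return "".join(out)


def percent_identity_ungapped(a: str, b: str) -> float:
    """Position-wise identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# Back-translation

_SYNONYMOUS: dict[int, dict[str, list[str]]] = {}
for _code in SUPPORTED_CODES:
    _table = CodonTable.unambiguous_dna_by_id[_code]
    _syn: dict[str, list[str]] = {}
    for _codon, _aa in sorted(_table.forward_table.items()):
        _syn.setdefault(_aa, []).append(_codon)
    _SYNONYMOUS[_code] = _syn

_T_START: dict[int, dict[str, list[str]]] = {
    code: {
        aa: [c for c in codons if c.startswith("T")]
        for aa, codons in syn.items()
        if any(c.startswith("T") for c in codons)
    }
    for code, syn in _SYNONYMOUS.items()
}

_STOPS: dict[int, list[str]] = {
    code: sorted(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    for code in SUPPORTED_CODES
}


def back_translate(aa_seq: str, code: int, rng: np.random.Generator) -> list[str]:
    """One codon per residue, uniform among the code's synonymous codons."""
    syn = _SYNONYMOUS[code]
    codons = []
    for aa in aa_seq:
        choices = syn.get(aa)
        if choices is None:
            raise GenerationError(f"residue {aa!r} has no codon under code {code}")
        codons.append(choices[rng.integers(len(choices))])
    return codons


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=length))


def _heptamer_free_nt(rng: np.random.Generator, length: int) -> str:
    """Random nucleotides guaranteed not to contain the slippery heptamer
    on either strand (so planted slip positions stay unambiguous)."""
    rc = reverse_complement(SLIPPERY_HEPTAMER)
    for _ in range(100):
        seq = _random_nt(rng, length)
        if SLIPPERY_HEPTAMER not in seq and rc not in seq:
            return seq
    raise GenerationError("could not draw a heptamer-free segment")


def random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=_BG_NORM)
    return "".join(AMINO_ALPHABET[i] for i in idx)


# ---------------------------------------------------------------------------
# Built-in seed proteins (deterministic synthetic stand-ins for real RdRp
# and phage proteins; they carry proper catalytic-motif blocks but are
# otherwise random draws from the background composition)

MOTIF_A_BLOCK = "DYSKWD"
MOTIF_B_BLOCK = "GSGLPNT"
MOTIF_C_BLOCK = "SGDD"


def _make_seed_rdrp(seed: int, length: int = 350) -> str:
    rng = np.random.default_rng(seed)
    protein = list(random_protein(rng, length))
    for pos in (50, 120, 180, 240, 310):
        protein[pos] = "W"
    a_at, b_at, c_at = 200, 258, 290
    protein[a_at : a_at + len(MOTIF_A_BLOCK)] = MOTIF_A_BLOCK
    protein[b_at : b_at + len(MOTIF_B_BLOCK)] = MOTIF_B_BLOCK
    protein[c_at : c_at + len(MOTIF_C_BLOCK)] = MOTIF_C_BLOCK
    return "".join(protein)


RDRP_SEED_A = _make_seed_rdrp(20201019)
RDRP_SEED_B = _make_seed_rdrp(12101180, length=330)
PHAGE_SEED = "".join(random_protein(np.random.default_rng(668187), 320))
HOST_SEEDS = [
    random_protein(np.random.default_rng(86576 + i), int(L))
    for i, L in enumerate((280, 320, 360, 300, 340))
]

RDRP_SOURCES = {"rdrpA": RDRP_SEED_A, "rdrpB": RDRP_SEED_B}


def make_default_profiles() -> list[ProfileHMM]:
    """Profiles for the two RdRp clans plus a bacteriophage decoy, each
    built from a small family of diverged copies of its seed."""
    profiles = []
    for name, seed_protein, base in (
        ("RdRp_clanA", RDRP_SEED_A, 1000),
        ("RdRp_clanB", RDRP_SEED_B, 2000),
        ("phage_capsid_decoy", PHAGE_SEED, 3000),
    ):
        family = [seed_protein] + [
            mutate_protein(seed_protein, 85, seed=base + i) for i in range(7)
        ]
        profiles.append(build_profile(name, family))
    return profiles


def make_default_reference() -> list[tuple[str, str, str]]:
    """Labeled reference proteins: clan-A RdRps (viral) and host proteins
    (nonviral).  Clan B and the phage protein are deliberately absent, so
    clan-B viruses and phage contigs arrive as orphans."""
    refs = [
        ("rdrpA_ref", RDRP_SEED_A, "viral"),
        ("rdrpA_rel90", mutate_protein(RDRP_SEED_A, 90, seed=101), "viral"),
        ("rdrpA_rel70", mutate_protein(RDRP_SEED_A, 70, seed=102), "viral"),
    ]
    refs += [
        (f"host_protein_{i + 1}", seq, "nonviral") for i, seq in enumerate(HOST_SEEDS)
    ]
    return refs


# ---------------------------------------------------------------------------
# Planting viral contigs


def _truth_row(contig_id: str, cls: str, **extra) -> dict:
    row = {
        "contig_id": contig_id,
        "class": cls,
        "virus_name": None,
        "orf_start": -1,
        "orf_end": -1,
        "strand": "+",
        "genetic_code": 1,
        "architecture": "",
        "target_identity": np.nan,
        "realized_identity": np.nan,
        "slip_pos": -1,
        "read_count": 0,
        "protein": "",
    }
    row.update(extra)
    return row


def plant_viral_contig(
    plan: VirusPlan, seed: int, contig_id: Optional[str] = None, library: str = ""
) -> tuple[Contig, dict]:
    """Realize one virus plan as a contig plus its truth-table row."""
    rng = np.random.default_rng(seed)
    contig_id = contig_id or f"virus_{plan.name}"
    source = (
        RDRP_SOURCES[plan.rdrp_source]
        if plan.rdrp_source in RDRP_SOURCES
        else plan.rdrp_source
    )
    mutated = mutate_protein(source, plan.target_identity, seed=int(rng.integers(2**31)))
    code = plan.genetic_code

    if plan.genome_architecture == "single_orf":
        return _plant_single_orf(plan, rng, contig_id, library, source, mutated, code)
    if plan.genome_architecture == "two_orf_adjacent":
        return _plant_two_orf_adjacent(
            plan, rng, contig_id, library, source, mutated, code
        )
    return _plant_frameshift(plan, rng, contig_id, library, source, mutated, code)


def _resolve_length(plan: VirusPlan, needed: int) -> int:
    length = plan.genome_length or needed + 120
    if length < needed:
        raise GenerationError(
            f"{plan.name}: genome length {length} cannot accommodate "
            f"{needed} nt of coding sequence and flanking stops"
        )
    return length


def _split_utrs(rng: np.random.Generator, extra: int) -> tuple[int, int]:
    u5 = int(rng.integers(extra + 1)) if extra > 0 else 0
    return u5, extra - u5


def _plant_single_orf(plan, rng, contig_id, library, source, mutated, code):
    coding = "".join(back_translate(mutated, code, rng))
    stop = _STOPS[code][int(rng.integers(len(_STOPS[code])))]
    needed = len(coding) + 6
    length = _resolve_length(plan, needed)
    u5, u3 = _split_utrs(rng, length - needed)
    seq = _heptamer_free_nt(rng, u5) + "TAA" + coding + stop + _heptamer_free_nt(rng, u3)
    start = u5 + 3
    row = _truth_row(
        contig_id,
        "virus",
        virus_name=plan.name,
        orf_start=start,
        orf_end=start + len(coding),
        genetic_code=code,
        architecture=plan.genome_architecture,
        target_identity=plan.target_identity,
        realized_identity=percent_identity_ungapped(source, mutated),
        read_count=plan.read_count,
        protein=mutated,
    )
    return Contig(id=contig_id, seq=seq, library=library, read_count=plan.read_count), row


def _plant_two_orf_adjacent(plan, rng, contig_id, library, source, mutated, code):
    hyp = random_protein(rng, 60)
    coding1 = "".join(back_translate(hyp, code, rng))
    coding2 = "".join(back_translate(mutated, code, rng))
    mid = _heptamer_free_nt(rng, 3 * int(rng.integers(2, 8)))
    needed = 3 + len(coding1) + 3 + len(mid) + 3 + len(coding2) + 3
    length = _resolve_length(plan, needed)
    u5, u3 = _split_utrs(rng, length - needed)
    head = _heptamer_free_nt(rng, u5) + "TAA" + coding1 + "TAA" + mid + "TAA"
    start2 = len(head)
    seq = head + coding2 + "TAA" + _heptamer_free_nt(rng, u3)
    row = _truth_row(
        contig_id,
        "virus",
        virus_name=plan.name,
        orf_start=start2,
        orf_end=start2 + len(coding2),
        genetic_code=code,
        architecture=plan.genome_architecture,
        target_identity=plan.target_identity,
        realized_identity=percent_identity_ungapped(source, mutated),
        read_count=plan.read_count,
        protein=mutated,
    )
    return Contig(id=contig_id, seq=seq, library=library, read_count=plan.read_count), row


def _plant_frameshift(plan, rng, contig_id, library, source, mutated, code):
    """Overlapping-ORF genome: ORF1 runs through the slippery heptamer,
    the replicase continues in the −1 frame after a one-base slip.

    The heptamer is written as the last seven coding bases of the ORF1
    prefix (…ATG GAT TTT = …G GATTTT T), which pins residues around the
    slip to M/D/F and forces the first post-slip residue to use a
    T-starting codon."""
    F = list(mutated)
    n = len(F)
    m = max(40, n // 3)
    if n - m < 60:
        raise GenerationError(f"{plan.name}: replicase too short for a frameshift")
    F[m - 3], F[m - 2], F[m - 1] = "M", "D", "F"
    if F[m] not in _T_START[code]:
        F[m] = "S"
    F = "".join(F)
    prefix_codons = back_translate(F[:m], code, rng)
    prefix_codons[m - 3 : m] = ["ATG", "GAT", "TTT"]
    suffix_codons = back_translate(F[m:], code, rng)
    t_choices = _T_START[code][F[m]]
    suffix_codons[0] = t_choices[int(rng.integers(len(t_choices)))]
    coding = "".join(prefix_codons) + "".join(suffix_codons)[1:] + "TAA"
    needed = 3 + len(coding)
    length = _resolve_length(plan, needed)
    u5, u3 = _split_utrs(rng, length - needed)
    lead = _heptamer_free_nt(rng, u5) + "TAA"
    a = len(lead)  # ORF1 coding start
    seq = lead + coding + _heptamer_free_nt(rng, u3)
    slip_pos = a + 3 * m - 7
    assert seq[slip_pos : slip_pos + 7] == SLIPPERY_HEPTAMER
    row = _truth_row(
        contig_id,
        "virus",
        virus_name=plan.name,
        orf_start=a,
        orf_end=a + 3 * m - 1 + 3 * (n - m),  # through the −1 continuation
        genetic_code=code,
        architecture=plan.genome_architecture,
        target_identity=plan.target_identity,
        realized_identity=percent_identity_ungapped(source, F),
        slip_pos=slip_pos,
        read_count=plan.read_count,
        protein=F,
    )
    return Contig(id=contig_id, seq=seq, library=library, read_count=plan.read_count), row


# ---------------------------------------------------------------------------
# Whole-library generation


def _host_contig(plan: LibraryPlan, rng: np.random.Generator) -> str:
    lo, hi = plan.host_length_range
    length = int(rng.integers(lo, hi + 1))
    u = rng.random()
    if u < plan.host_coding_fraction:
        # Host-like coding contig: a diverged slice of a host reference
        # protein, so the similarity search finds a strong nonviral hit.
        host = HOST_SEEDS[int(rng.integers(len(HOST_SEEDS)))]
        n_aa = min(len(host), max(60, (length - 6) // 3))
        start = int(rng.integers(0, len(host) - n_aa + 1))
        piece = mutate_protein(host[start : start + n_aa], 95, int(rng.integers(2**31)))
        coding = "".join(back_translate(piece, 1, rng))
        pad = max(0, length - len(coding) - 6)
        return _random_nt(rng, pad // 2) + "TAA" + coding + "TAA" + _random_nt(
            rng, pad - pad // 2
        )
    # Noncoding-ish host contig: random codons with a stop-frequency knob
    # controlling whether long orphan ORFs appear.
    long_orf = u < plan.host_coding_fraction + plan.host_long_orf_fraction * (
        1 - plan.host_coding_fraction
    )
    p_stop = 0.0015 if long_orf else 0.05
    n_codons = length // 3
    codons = []
    sense = [c for c in _SYNONYMOUS[1].values() for c in c]
    for _ in range(n_codons):
        if rng.random() < p_stop:
            codons.append(_STOPS[1][int(rng.integers(3))])
        else:
            codons.append(sense[int(rng.integers(len(sense)))])
    return "".join(codons)


def _rrna_like_contig(rng: np.random.Generator) -> str:
    unit = _random_nt(rng, int(rng.integers(40, 80)))
    reps = int(rng.integers(8, 16))
    return (unit * reps)[: int(rng.integers(500, 1100))]


def _phage_decoy_contig(rng: np.random.Generator) -> tuple[str, str]:
    identity = float(rng.uniform(75, 90))
    protein = mutate_protein(PHAGE_SEED, identity, int(rng.integers(2**31)))
    coding = "".join(back_translate(protein, 1, rng))
    u5 = int(rng.integers(20, 120))
    u3 = int(rng.integers(20, 120))
    seq = _random_nt(rng, u5) + "TAA" + coding + "TAA" + _random_nt(rng, u3)
    return seq, protein


def generate_library(plan: LibraryPlan) -> LibraryBundle:
    """Materialize a library plan into contigs, counts and a truth table.

    Deterministic: the same plan (including its seed) yields the same
    contigs, ids, ordering and counts.
    """
    rng = np.random.default_rng(plan.seed)
    entries: list[tuple[Contig, dict]] = []
    for i in range(plan.n_host_contigs):
        seq = _host_contig(plan, rng)
        cid = f"{plan.library}_host_{i:03d}"
        entries.append((Contig(cid, seq, plan.library), _truth_row(cid, "host")))
    for i in range(plan.n_rrna_like):
        cid = f"{plan.library}_rrna_{i:03d}"
        entries.append(
            (Contig(cid, _rrna_like_contig(rng), plan.library), _truth_row(cid, "rrna_like"))
        )
    for i in range(plan.n_decoy_phage):
        seq, protein = _phage_decoy_contig(rng)
        cid = f"{plan.library}_phage_{i:03d}"
        entries.append(
            (
                Contig(cid, seq, plan.library),
                _truth_row(cid, "phage_decoy", protein=protein),
            )
        )
    for vp in plan.planted_viruses:
        cid = f"{plan.library}_{vp.name}"
        child_seed = int(rng.integers(2**31))
        contig, row = plant_viral_contig(vp, child_seed, contig_id=cid, library=plan.library)
        entries.append((contig, row))

    mu, sigma = plan.abundance_lognormal_params
    counts: dict[str, int] = {}
    for contig, row in entries:
        if row["class"] == "virus":
            counts[contig.id] = row["read_count"]
        else:
            count = int(np.round(rng.lognormal(mu, sigma))) + 1
            counts[contig.id] = count
            row["read_count"] = count
        contig.read_count = counts[contig.id]

    order = rng.permutation(len(entries))
    contigs = [entries[i][0] for i in order]
    truth = pd.DataFrame([entries[i][1] for i in order])
    return LibraryBundle(contigs=contigs, counts=counts, truth=truth, plan=plan)


def write_library(bundle: LibraryBundle, outdir) -> dict[str, Path]:
    """Write contigs.fasta, counts.tsv, truth.tsv and library.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "contigs.fasta",
        "counts": outdir / "counts.tsv",
        "truth": outdir / "truth.tsv",
        "meta": outdir / "library.yaml",
    }
    write_fasta(bundle.contigs, paths["fasta"])
    counts_df = pd.DataFrame(
        {"contig_id": [c.id for c in bundle.contigs],
         "read_count": [bundle.counts[c.id] for c in bundle.contigs]}
    )
    write_tsv(counts_df, paths["counts"])
    write_tsv(bundle.truth, paths["truth"])
    paths["meta"].write_text(
        yaml.safe_dump(
            {
                "library": bundle.plan.library,
                "seed": bundle.plan.seed,
                "total_non_rrna_reads": bundle.plan.total_non_rrna_reads,
            }
        )
    )
    return paths


def write_default_assets(outdir) -> dict[str, Path]:
    """Write the built-in profile set and labeled reference set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": outdir / "profiles.hmm",
        "reference": outdir / "reference.faa",
    }
    write_hmmer3_profile(make_default_profiles(), paths["profiles"])
    write_labeled_proteins(make_default_reference(), paths["reference"])
    return paths


def default_plan(seed: int = 0, library: str = "SYN_1") -> LibraryPlan:
    """The reference study conditions: three planted viruses at 80/60/40%
    identity spanning the three genome architectures, both genetic codes
    and the three abundance bands, on a host/decoy background."""
    return LibraryPlan(
        seed=seed,
        library=library,
        planted_viruses=[
            VirusPlan(
                name="amalga_like_hi",
                rdrp_source="rdrpA",
                target_identity=80,
                genome_architecture="two_orf_frameshift",
                genetic_code=4,
                read_count=12600,
            ),
            VirusPlan(
                name="partiti_like_mid",
                rdrp_source="rdrpA",
                target_identity=60,
                genome_architecture="single_orf",
                genetic_code=1,
                read_count=4000,
            ),
            VirusPlan(
                name="mito_like_lo",
                rdrp_source="rdrpB",
                target_identity=40,
                genome_architecture="single_orf",
                genetic_code=4,
                read_count=100,
            ),
        ],
    )


# ---------------------------------------------------------------------------
# YAML plan round-trip


def plan_to_yaml(plan: LibraryPlan, path) -> None:
    data = {
        "n_host_contigs": plan.n_host_contigs,
        "host_length_range": list(plan.host_length_range),
        "n_rrna_like": plan.n_rrna_like,
        "n_decoy_phage": plan.n_decoy_phage,
        "abundance_lognormal_params": list(plan.abundance_lognormal_params),
        "total_non_rrna_reads": plan.total_non_rrna_reads,
        "seed": plan.seed,
        "library": plan.library,
        "host_coding_fraction": plan.host_coding_fraction,
        "host_long_orf_fraction": plan.host_long_orf_fraction,
        "planted_viruses": [
            {
                "name": v.name,
                "rdrp_source": v.rdrp_source,
                "target_identity": v.target_identity,
                "genome_architecture": v.genome_architecture,
                "genetic_code": v.genetic_code,
                "genome_length": v.genome_length,
                "read_count": v.read_count,
            }
            for v in plan.planted_viruses
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def plan_from_yaml(path) -> LibraryPlan:
    data = yaml.safe_load(Path(path).read_text())
    viruses = [VirusPlan(**v) for v in data.pop("planted_viruses", [])]
    if "host_length_range" in data:
        data["host_length_range"] = tuple(data["host_length_range"])
    if "abundance_lognormal_params" in data:
        data["abundance_lognormal_params"] = tuple(data["abundance_lognormal_params"])
    return LibraryPlan(planted_viruses=viruses, **data)
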