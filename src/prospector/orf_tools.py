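"""Six-frame ORF prediction and −1 ribosomal frameshift handling.

An ORF here is a *maximal stop-free translated region*: no start codon is
required, regions abutting a contig end are flagged partial, and trailing
incomplete codons are dropped.  Two genetic codes are supported: the
standard code (NCBI table 1) and the protozoan/mold mitochondrial code
(table 4), under which TGA encodes tryptophan instead of stop.  Codons
containing N translate to X and never terminate a region.

Coordinates are 0-based half-open on the forward strand throughout; the
``frame`` of a record is the offset of its reading frame on its own
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import Contig

SLIPPERY_HEPTAMER = "GGATTTT"  # DNA form of the GGAUUUU −1 frameshift motif

SUPPORTED_CODES = (1, 4)

_CODON_MAPS: dict[int, dict[str, str]] = {}
for _code in SUPPORTED_CODES:
    _table = CodonTable.unambiguous_dna_by_id[_code]
    _m = dict(_table.forward_table)
    for _stop in _table.stop_codons:
        _m[_stop] = "*"
    _CODON_MAPS[_code] = _m


class StructuralError(ValueError):
    """ORF pair violates the frameshift geometry."""


@dataclass
class OrfRecord:
    """A maximal stop-free translated region.

    ``start``/``end`` are forward-strand nucleotide coordinates; for
    minus-strand records the amino sequence reads from ``end`` leftward.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_seq: str
    genetic_code: int = 1
    partial5: bool = False
    partial3: bool = False

    @property
    def id(self) -> str:
        return f"{self.contig_id}|{self.strand}|{self.start}-{self.end}|c{self.genetic_code}"

    def __len__(self) -> int:
        return len(self.aa_seq)


@dataclass
class FrameshiftCandidate:
    """Two overlapping ORFs fused through a slippery heptamer."""

    contig_id: str
    slip_pos: int
    orf1: OrfRecord
    orf2: OrfRecord
    fused_aa: str
    motif: str = SLIPPERY_HEPTAMER


def translate(seq: str, code: int = 1) -> str:
    """Translate complete codons; ambiguous codons become X, stops '*'."""
    if code not in SUPPORTED_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    table = _CODON_MAPS[code]
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append(table.get(codon, "X"))
    return "".join(aas)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_frames(seq: str, code: int, min_aa: int):
    """Yield (frame, codon_start_index, aa_seq, partial5, partial3) for
    maximal stop-free regions on one strand."""
    n = len(seq)
    table = _CODON_MAPS[code]
    for frame in range(3):
        n_codons = (n - frame) // 3
        if n_codons <= 0:
            continue
        region_start = 0  # codon index where the current region began
        region: list[str] = []
        for ci in range(n_codons):
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3]
            aa = table.get(codon, "X")
            if aa == "*":
                if len(region) >= min_aa:
                    yield frame, region_start, "".join(region), region_start == 0, False
                region = []
                region_start = ci + 1
            else:
                region.append(aa)
        if len(region) >= min_aa:
            # Partial at the 3' side: no stop before the contig end.
            yield frame, region_start, "".join(region), region_start == 0, True


def find_orfs(contig: Contig, code: int = 1, min_aa: int = 200) -> list[OrfRecord]:
    """All maximal stop-free regions of ≥ ``min_aa`` codons, six frames.

    The default length gate of 200 aa is the conventional floor for an
    RdRp-bearing ORF: shorter than most polymerases yet long enough for
    evolutionary inference.
    """
    if code not in SUPPORTED_CODES:
        raise ValueError(f"unsupported genetic code {code}")
    if min_aa < 1:
        raise ValueError("min_aa must be positive")
    n = len(contig.seq)
    records: list[OrfRecord] = []
    seq_fwd = contig.seq.upper()
    for frame, ci, aa_seq, p5, p3 in _scan_frames(seq_fwd, code, min_aa):
        start = frame + 3 * ci
        records.append(
            OrfRecord(
                contig_id=contig.id,
                strand="+",
                frame=frame,
                start=start,
                end=start + 3 * len(aa_seq),
                aa_seq=aa_seq,
                genetic_code=code,
                partial5=p5,
                partial3=p3,
            )
        )
    seq_rev = reverse_complement(seq_fwd)
    for frame, ci, aa_seq, p5, p3 in _scan_frames(seq_rev, code, min_aa):
        start_rev = frame + 3 * ci
        end_rev = start_rev + 3 * len(aa_seq)
        records.append(
            OrfRecord(
                contig_id=contig.id,
                strand="-",
                frame=frame,
                start=n - end_rev,
                end=n - start_rev,
                aa_seq=aa_seq,
                genetic_code=code,
                partial5=p5,
                partial3=p3,
            )
        )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records


def orf_nucleotides(orf: OrfRecord, contig: Contig) -> str:
    """The coding nucleotides of an ORF in reading order."""
    region = contig.seq[orf.start : orf.end]
    return region if orf.strand == "+" else reverse_complement(region)


def detect_slippery_sites(contig: Contig) -> list[int]:
    """All occurrences of the slippery heptamer on either strand, as
    0-based forward-strand positions of the leftmost base."""
    seq = contig.seq.upper()
    positions = set()
    for probe in (SLIPPERY_HEPTAMER, reverse_complement(SLIPPERY_HEPTAMER)):
        i = seq.find(probe)
        while i != -1:
            positions.add(i)
            i = seq.find(probe, i + 1)
    return sorted(positions)


def join_frameshift_orfs(
    orf1: OrfRecord, orf2: OrfRecord, slip_pos: int
) -> FrameshiftCandidate:
    """Fuse two overlapping ORFs through a −1 frameshift at ``slip_pos``.

    The ribosome translates ``orf1`` through the heptamer, slips back one
    nucleotide, and continues in the −1 frame along ``orf2``.  Only the
    forward-strand geometry is systematized here; minus-strand candidates
    can be fused on the reverse-complemented contig.
    """
    if orf1.contig_id != orf2.contig_id:
        raise StructuralError("ORFs come from different contigs")
    if orf1.strand != orf2.strand or orf1.strand != "+":
        raise StructuralError("frameshift fusion requires two forward-strand ORFs")
    if orf2.frame != (orf1.frame - 1) % 3:
        raise StructuralError(
            f"ORF2 must lie in the −1 frame of ORF1 "
            f"(frames {orf1.frame} vs {orf2.frame})"
        )
    overlap_start = max(orf1.start, orf2.start)
    overlap_end = min(orf1.end, orf2.end)
    if not (overlap_start <= slip_pos and slip_pos + 7 <= overlap_end):
        raise StructuralError("slippery heptamer not inside the ORF overlap")
    # Translate orf1 through the last codon covering the heptamer.
    cut = orf1.start + 3 * -(-(slip_pos + 7 - orf1.start) // 3)
    n_prefix = (cut - orf1.start) // 3
    prefix = orf1.aa_seq[:n_prefix]
    resume = cut - 1  # one nucleotide back: the −1 slip
    if (resume - orf2.start) % 3 != 0:
        raise StructuralError("slip resume point is out of phase with ORF2")
    suffix = orf2.aa_seq[(resume - orf2.start) // 3 :]
    return FrameshiftCandidate(
        contig_id=orf1.contig_id,
        slip_pos=slip_pos,
        orf1=orf1,
        orf2=orf2,
        fused_aa=prefix + suffix,
    )


def find_frameshift_candidates(
    contig: Contig, orfs: Iterable[OrfRecord]
) -> list[FrameshiftCandidate]:
    """Systematic scan: every heptamer occurrence lying inside the overlap
    of a −1-frame forward-strand ORF pair yields a candidate."""
    sites = detect_slippery_sites(contig)
    fwd = [o for o in orfs if o.strand == "+"]
    out = []
    for pos in sites:
        for o1 in fwd:
            if not (o1.start <= pos and pos + 7 <= o1.end):
                continue
            for o2 in fwd:
                if o2 is o1 or o2.frame != (o1.frame - 1) % 3:
                    continue
                if o2.start <= pos and pos + 7 <= o2.end and o2.end > o1.end:
                    try:
                        out.append(join_frameshift_orfs(o1, o2, pos))
                    except StructuralError:
                        continue
    return out
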