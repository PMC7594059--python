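"""Readers and writers for the formats the pipeline touches.

FASTA handling is delegated to Biopython; profile HMMs are read from and
written to the HMMER3 flat-text dialect (probabilities stored as negative
natural logs, ``*`` meaning probability zero).  Only protein-alphabet
profiles are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: HMMER's residue ordering for the amino alphabet.
AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

#: Robinson & Robinson amino-acid background frequencies, HMMER order.
BACKGROUND_FREQS = np.array(
    [
        0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
        0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
        0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
        0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
    ]
)
BACKGROUND_LOG = np.log(BACKGROUND_FREQS)

TRANSITION_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


class ParseError(ValueError):
    """Malformed input file."""


class UnsupportedAlphabetError(ParseError):
    """Profile uses an alphabet other than amino."""


@dataclass
class Contig:
    """A nucleotide contig: the pipeline's unit of triage."""

    id: str
    seq: str
    library: str = ""
    read_count: Optional[int] = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class ProfileHMM:
    """Match-state emission/transition model in log-probability space.

    ``match_emissions`` has one row per match state (shape ``(L, 20)``);
    ``insert_emissions`` and ``transitions`` include the begin node, so
    they have ``L + 1`` rows.  ``transitions`` columns follow
    :data:`TRANSITION_NAMES`.  ``calibration`` optionally maps a score
    kind (e.g. ``"FORWARD"``) to its ``(tau, lambda)`` fit, enabling
    analytic e-values; uncalibrated profiles fall back to a permutation
    null downstream.
    """

    name: str
    length: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(default_factory=lambda: BACKGROUND_LOG.copy())
    calibration: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("profile must have at least one match state")
        for dist in self.match_emissions:
            _check_normalized(dist, f"match emissions of {self.name}")
        for dist in self.insert_emissions:
            _check_normalized(dist, f"insert emissions of {self.name}")

    @property
    def consensus(self) -> str:
        """Most probable residue per match state."""
        return "".join(AMINO_ALPHABET[i] for i in self.match_emissions.argmax(axis=1))


def _check_normalized(log_dist: np.ndarray, what: str, tol: float = 1e-6) -> None:
    total = float(np.exp(log_dist).sum())
    if abs(total - 1.0) > tol:
        raise ParseError(f"{what} do not normalize (sum={total:.8f})")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, library: str = "", min_length: int = 1) -> list[Contig]:
    """Load contigs from a FASTA file, uppercasing sequences.

    ``min_length`` implements the common load-time filter that drops very
    short assembly artefacts (e.g. contigs under 200 nt).
    """
    contigs = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) >= min_length:
            contigs.append(Contig(id=rec.id, seq=seq, library=library))
    return contigs


def write_fasta(records: Iterable[Contig | tuple[str, str]], path) -> None:
    """Write contigs (or plain ``(id, seq)`` pairs) as FASTA."""
    seq_records = []
    for rec in records:
        if isinstance(rec, Contig):
            rid, seq = rec.id, rec.seq
        else:
            rid, seq = rec
        seq_records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seq_records, str(path), "fasta")


def read_labeled_proteins(path) -> list[tuple[str, str, str]]:
    """Read a reference protein FASTA whose headers carry ``label=viral``
    or ``label=nonviral`` tags; returns ``(id, sequence, label)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = "nonviral"
        for token in rec.description.split():
            if token.startswith("label="):
                label = token.split("=", 1)[1]
        if label not in ("viral", "nonviral"):
            raise ParseError(f"unknown reference label {label!r} for {rec.id}")
        out.append((rec.id, str(rec.seq).upper(), label))
    return out


def write_labeled_proteins(records: Iterable[tuple[str, str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description=f"label={label}")
        for rid, seq, label in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# HMMER3 flat text profiles


def _cost_to_logprob(token: str) -> float:
    if token == "*":
        return -math.inf
    return -float(token)


def _logprob_to_cost(value: float) -> str:
    if value == -math.inf:
        return "*"
    return f"{-value:.7f}"


def parse_hmmer3_profile(path) -> list[ProfileHMM]:
    """Parse a (possibly multi-model) HMMER3 flat-text profile file.

    Emission and transition values in the file are negative natural-log
    probabilities; they are converted back to log-probabilities here.
    ``STATS LOCAL`` lines, when present, populate ``calibration``.
    """
    profiles: list[ProfileHMM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("HMMER3"):
            raise ParseError(f"{path}:{i + 1}: expected HMMER3 header, got {line!r}")
        i += 1
        name = None
        length = None
        alphabet = None
        calibration: dict[str, tuple[float, float]] = {}
        while i < n_lines and not lines[i].startswith("HMM "):
            fields = lines[i].split()
            if fields:
                key = fields[0]
                if key == "NAME":
                    name = fields[1]
                elif key == "LENG":
                    length = int(fields[1])
                elif key == "ALPH":
                    alphabet = fields[1].lower()
                elif key == "STATS" and len(fields) >= 5:
                    calibration[fields[2]] = (float(fields[3]), float(fields[4]))
            i += 1
        if i >= n_lines:
            raise ParseError(f"{path}: truncated model (no HMM line)")
        if name is None or length is None or alphabet is None:
            raise ParseError(f"{path}: model missing NAME/LENG/ALPH lines")
        if alphabet != "amino":
            raise UnsupportedAlphabetError(
                f"{path}: profile {name} uses unsupported alphabet {alphabet!r}"
            )
        i += 2  # skip the residue header and transition header lines
        background = BACKGROUND_LOG.copy()
        if i < n_lines and lines[i].split()[:1] == ["COMPO"]:
            background = np.array(
                [_cost_to_logprob(t) for t in lines[i].split()[1:21]]
            )
            i += 1
        insert_rows = [np.array([_cost_to_logprob(t) for t in lines[i].split()[:20]])]
        i += 1
        trans_rows = [np.array([_cost_to_logprob(t) for t in lines[i].split()[:7]])]
        i += 1
        match_rows = []
        for k in range(1, length + 1):
            fields = lines[i].split()
            if int(fields[0]) != k:
                raise ParseError(
                    f"{path}:{i + 1}: expected match state {k}, got {fields[0]}"
                )
            match_rows.append(np.array([_cost_to_logprob(t) for t in fields[1:21]]))
            insert_rows.append(
                np.array([_cost_to_logprob(t) for t in lines[i + 1].split()[:20]])
            )
            trans_rows.append(
                np.array([_cost_to_logprob(t) for t in lines[i + 2].split()[:7]])
            )
            i += 3
        if i >= n_lines or lines[i].strip() != "//":
            raise ParseError(f"{path}:{i + 1}: expected model terminator '//'")
        i += 1
        profiles.append(
            ProfileHMM(
                name=name,
                length=length,
                match_emissions=np.vstack(match_rows),
                insert_emissions=np.vstack(insert_rows),
                transitions=np.vstack(trans_rows),
                background=background,
                calibration=calibration,
            )
        )
    if not profiles:
        raise ParseError(f"{path}: no models found")
    return profiles


def write_hmmer3_profile(profiles: Sequence[ProfileHMM] | ProfileHMM, path) -> None:
    """Write profiles in the HMMER3 flat-text dialect (amino alphabet)."""
    if isinstance(profiles, ProfileHMM):
        profiles = [profiles]
    out: list[str] = []
    for p in profiles:
        out.append("HMMER3/f [virus-prospector]")
        out.append(f"NAME  {p.name}")
        out.append(f"LENG  {p.length}")
        out.append("ALPH  amino")
        for kind, (tau, lam) in sorted(p.calibration.items()):
            out.append(f"STATS LOCAL {kind} {tau:.5f} {lam:.5f}")
        out.append("HMM          " + "        ".join(AMINO_ALPHABET))
        out.append(
            "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
        )
        out.append(
            "  COMPO   " + "  ".join(_logprob_to_cost(v) for v in p.background)
        )
        out.append("          " + "  ".join(_logprob_to_cost(v) for v in p.insert_emissions[0]))
        out.append("          " + "  ".join(_logprob_to_cost(v) for v in p.transitions[0]))
        consensus = p.consensus
        for k in range(1, p.length + 1):
            out.append(
                f"{k:7d}   "
                + "  ".join(_logprob_to_cost(v) for v in p.match_emissions[k - 1])
                + f"  {k} {consensus[k - 1].lower()} - - -"
            )
            out.append("          " + "  ".join(_logprob_to_cost(v) for v in p.insert_emissions[k]))
            out.append("          " + "  ".join(_logprob_to_cost(v) for v in p.transitions[k]))
        out.append("//")
    Path(path).write_text("\n".join(out) + "\n")


def build_profile(
    name: str,
    aligned_seqs: Sequence[str],
    pseudocount: Optional[float] = None,
    match_stay: float = 0.95,
) -> ProfileHMM:
    """Build a profile from an ungapped alignment (equal-length sequences).

    Match emissions are column frequencies smoothed toward the background
    with ``pseudocount`` total weight (default: one pseudo-observation
    per real sequence, a 50/50 blend that keeps remote homologs scorable
    rather than punishing every unseen residue); inserts emit the
    background; the transition structure is position-independent, with
    ``match_stay`` probability of staying on the match track.
    """
    if not aligned_seqs:
        raise ValueError("need at least one sequence")
    if pseudocount is None:
        pseudocount = float(len(aligned_seqs))
    length = len(aligned_seqs[0])
    if any(len(s) != length for s in aligned_seqs):
        raise ValueError("sequences must be aligned to equal length")
    counts = np.zeros((length, 20))
    for seq in aligned_seqs:
        for j, aa in enumerate(seq.upper()):
            if aa in AA_INDEX:
                counts[j, AA_INDEX[aa]] += 1.0
    freqs = counts + pseudocount * BACKGROUND_FREQS
    freqs /= freqs.sum(axis=1, keepdims=True)
    leave = (1.0 - match_stay) / 2.0
    row = np.log(
        np.array([match_stay, leave, leave, 0.8, 0.2, 0.8, 0.2])
    )
    transitions = np.tile(row, (length + 1, 1))
    # Last node: no onward insert/delete branches.
    transitions[length] = np.log(np.array([1.0, 1e-30, 1e-30, 1.0, 1e-30, 1.0, 1e-30]))
    transitions[length, 1:] = -np.inf
    transitions[length, [0, 3, 5]] = 0.0
    insert_emissions = np.tile(BACKGROUND_LOG, (length + 1, 1))
    return ProfileHMM(
        name=name,
        length=length,
        match_emissions=np.log(freqs),
        insert_emissions=insert_emissions,
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# TSV conventions

TSV_KWARGS = dict(sep="\t", index=False)


def write_tsv(df, path) -> None:
    df.to_csv(path, **TSV_KWARGS)
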