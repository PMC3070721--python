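"""FASTA I/O, primer anchoring and trimming.

The pipeline's only sequencing-quality rule is primer anchoring: a read is
retained iff it carries an exact (IUPAC-aware, zero-mismatch) match to the
proximal primer at its 5' end and to the distal primer at its 3' end, both
primers are trimmed, and the remaining insert must be over {A,C,G,T}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class RawRead:
    """A demultiplexed read as it came off the machine (uppercased, U->T)."""

    id: str
    sequence: str
    sample: str


@dataclass(frozen=True)
class Read:
    """A primer-screened, primer-trimmed read; insert over {A,C,G,T}."""

    id: str
    sequence: str
    sample: str


@dataclass(frozen=True)
class PrimerPair:
    """Amplification primers; ``distal`` is given in read orientation."""

    proximal: str
    distal: str

    def __post_init__(self) -> None:
        for name, seq in (("proximal", self.proximal), ("distal", self.distal)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _primer_regex(primer: str) -> re.Pattern[str]:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in primer.upper()))


def read_fasta(path: str | Path, sample: str) -> list[RawRead]:
    """Load one per-sample FASTA file into RawReads.

    Sequences are uppercased and U is mapped to T.  Records with empty
    sequences or duplicated ids raise, naming the offender.
    """
    reads: list[RawRead] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        reads.append(RawRead(id=rec.id, sequence=seq, sample=sample))
    return reads


def screen_primers(
    reads: Iterable[RawRead],
    primers: PrimerPair,
    distal_revcomp: bool = False,
) -> tuple[list[Read], list[RawRead]]:
    """Partition reads into primer-anchored (trimmed) and rejected.

    A read is kept iff its sequence starts with a string matching the
    proximal primer and ends with a string matching the distal primer
    (exact IUPAC match, no mismatches), and the trimmed insert is
    non-empty and free of N (or any non-ACGT character).  Rejection is a
    normal outcome; |kept| + |rejected| == |input|.
    """
    distal = reverse_complement(primers.distal) if distal_revcomp else primers.distal
    prox_re = _primer_regex(primers.proximal)
    dist_re = _primer_regex(distal)
    plen, dlen = len(primers.proximal), len(distal)
    acgt = frozenset("ACGT")

    kept: list[Read] = []
    rejected: list[RawRead] = []
    for read in reads:
        seq = read.sequence
        if len(seq) < plen + dlen + 1:
            rejected.append(read)
            continue
        if not prox_re.match(seq) or not dist_re.fullmatch(seq, len(seq) - dlen):
            rejected.append(read)
            continue
        insert = seq[plen: len(seq) - dlen]
        if not insert or set(insert) - acgt:
            rejected.append(read)
            continue
        kept.append(Read(id=read.id, sequence=insert, sample=read.sample))
    return kept, rejected


def write_fasta(records: Sequence, path: str | Path) -> None:
    """Write reads or abundance-annotated tags to FASTA.

    Anything with ``.id`` and ``.sequence`` is written as-is; objects that
    also carry ``.abundance`` (dereplicated tags) use the ``;size=N``
    header dialect.  Round-trips exactly through :func:`read_fasta`.
    """
    ids = set()
    with open(path, "w") as fh:
        for rec in records:
            if hasattr(rec, "abundance"):
                rid = f"{rec.rep_id};size={rec.abundance}"
            else:
                rid = rec.id
            if rid in ids:
                raise ValueError(f"duplicate id {rid!r}")
            ids.add(rid)
            fh.write(f">{rid}\n{rec.sequence}\n")


def write_plain_fasta(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in pairs:
            fh.write(f">{rid}\n{seq}\n")
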