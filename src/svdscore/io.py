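"""Alignment I/O and site-pattern counting for four-taxon data.

Alignments are read from FASTA or relaxed sequential PHYLIP through
Bio.AlignIO. The four sequences are mapped to the taxon roles (a, b, c,
d) either explicitly by name or by file order — never by name inference,
since the three splits are meaningless without a fixed role assignment.
Columns containing any symbol outside {A, C, G, T} (case-insensitive)
are dropped from the pattern counts and tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .flattening import SitePatternCounts
from .models import NUCLEOTIDES, TAXA, SitePatternDistribution

__all__ = [
    "AlignmentRecord",
    "read_alignment",
    "write_fasta",
    "write_phylip",
    "count_site_patterns",
    "generate_alignment",
]

# Maps nucleotide characters (either case) to 0..3; everything else to -1.
_CHAR_CODE = np.full(256, -1, dtype=np.int16)
for _i, _c in enumerate(NUCLEOTIDES):
    _CHAR_CODE[ord(_c)] = _i
    _CHAR_CODE[ord(_c.lower())] = _i


@dataclass(frozen=True)
class AlignmentRecord:
    """Four aligned sequences with labels mapped to the roles (a, b, c, d).

    ``names[i]`` and ``sequences[i]`` belong to role ``TAXA[i]``.
    """

    names: tuple[str, str, str, str]
    sequences: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != 4 or len(self.sequences) != 4:
            raise ValueError("an alignment record holds exactly four sequences")
        if len(set(self.names)) != 4:
            raise ValueError("sequence labels must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences must have equal lengths, got {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def read_alignment(
    path: str | Path, taxa: tuple[str, str, str, str] | None = None
) -> AlignmentRecord:
    """Read a four-sequence FASTA or relaxed PHYLIP alignment.

    ``taxa`` optionally names the sequences playing roles (a, b, c, d);
    when omitted, file order is used.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fasta" if first == ">" else "phylip-relaxed"
    aln = AlignIO.read(str(path), fmt)
    if len(aln) != 4:
        raise ValueError(f"expected exactly 4 sequences, found {len(aln)}")
    records = {rec.id: str(rec.seq) for rec in aln}
    if taxa is not None:
        missing = set(taxa) - records.keys()
        if missing:
            raise ValueError(f"labels not found in alignment: {sorted(missing)}")
        names = tuple(taxa)
    else:
        names = tuple(rec.id for rec in aln)
    return AlignmentRecord(names=names, sequences=tuple(records[n] for n in names))


def write_fasta(alignment: AlignmentRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(alignment.names, alignment.sequences):
            fh.write(f">{name}\n{seq}\n")


def write_phylip(alignment: AlignmentRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f" 4 {alignment.length}\n")
        for name, seq in zip(alignment.names, alignment.sequences):
            fh.write(f"{name}  {seq}\n")


def count_site_patterns(alignment: AlignmentRecord) -> SitePatternCounts:
    """Tally the 256 site patterns of an alignment.

    Columns with any non-ACGT symbol are dropped; the number of dropped
    columns is recorded on the returned counts.
    """
    codes = np.stack(
        [_CHAR_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)] for seq in alignment.sequences]
    )
    valid = np.all(codes >= 0, axis=0)
    idx = 64 * codes[0, valid] + 16 * codes[1, valid] + 4 * codes[2, valid] + codes[3, valid]
    counts = np.bincount(idx, minlength=256).astype(np.int64)
    return SitePatternCounts(counts=counts, dropped=int((~valid).sum()))


def generate_alignment(
    p: SitePatternDistribution,
    n: int,
    rng: np.random.Generator,
    names: tuple[str, str, str, str] = TAXA,
) -> AlignmentRecord:
    """Emit an n-column alignment of i.i.d. sites drawn from ``p``.

    Counting the patterns of the result recovers a Multinomial(n, p)
    draw, so this is the fixture generator matching the i.i.d.-site
    sampling assumption of the hypothesis tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = rng.choice(256, size=n, p=p.probs)
    nucs = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)
    seqs = []
    for shift in (6, 4, 2, 0):
        seqs.append(nucs[(idx >> shift) & 3].tobytes().decode())
    return AlignmentRecord(names=names, sequences=tuple(seqs))
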