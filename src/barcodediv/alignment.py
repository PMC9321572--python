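"""Equal-length nucleotide alignments and haplotype collapsing."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["SequenceAlignment", "collapse_haplotypes"]

# internal byte codes; indices 0-3 are the comparable bases
_ALPHABET = np.frombuffer(b"ACGT-N", dtype=np.uint8)
_DECODE = {i: chr(b) for i, b in enumerate(_ALPHABET)}
_ENCODE = np.full(256, 5, dtype=np.uint8)  # unknown symbols -> N
for i, b in enumerate(_ALPHABET):
    _ENCODE[b] = i
    _ENCODE[ord(chr(b).lower())] = i

N_BASES = 4  # codes < N_BASES are comparable {A,C,G,T}


class SequenceAlignment:
    """Named, equal-length nucleotide matrix over {A,C,G,T,-,N}.

    Rows are stored as small-integer codes (A=0, C=1, G=2, T=3, gap=4,
    N=5); anything unrecognised is treated as N.
    """

    def __init__(self, names: Sequence[str], codes: np.ndarray) -> None:
        codes = np.ascontiguousarray(codes, dtype=np.uint8)
        if codes.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(names) != codes.shape[0]:
            raise ValueError("one name per row required")
        if len(set(names)) != len(names):
            raise ValueError("sequence names must be unique")
        self.names = list(names)
        self.codes = codes

    # -- constructors -------------------------------------------------

    @classmethod
    def from_strings(cls, mapping_or_names, seqs: Iterable[str] | None = None):
        """Build from ``{name: sequence}`` or parallel name/sequence lists."""
        if seqs is None:
            names = list(mapping_or_names.keys())
            seqs = [mapping_or_names[n] for n in names]
        else:
            names = list(mapping_or_names)
            seqs = list(seqs)
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
        codes = _ENCODE[raw].reshape(len(names), -1) if names else raw.reshape(0, 0)
        return cls(names, codes)

    @classmethod
    def from_fasta(cls, path: str) -> "SequenceAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        return cls.from_strings([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str) -> None:
        records = [
            SeqRecord(Seq(self.row_str(i)), id=name, description="")
            for i, name in enumerate(self.names)
        ]
        SeqIO.write(records, path, "fasta")

    # -- queries ------------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def row_str(self, i: int) -> str:
        return "".join(_DECODE[c] for c in self.codes[i])

    def subset(self, names: Sequence[str]) -> "SequenceAlignment":
        idx = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"sequences not in alignment: {missing[:5]}")
        rows = np.asarray([idx[n] for n in names])
        return SequenceAlignment(list(names), self.codes[rows])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SequenceAlignment {self.n_sequences} x {self.length}>"


def collapse_haplotypes(
    aln: SequenceAlignment,
) -> tuple[SequenceAlignment, dict[str, list[str]]]:
    """Collapse identical rows to unique haplotypes.

    Returns the haplotype alignment (one representative row per distinct
    sequence, named after the first member in input order) and the
    membership map ``representative -> [all member names]``.  Every input
    name appears in exactly one membership list.
    """
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    members: dict[bytes, list[str]] = {}
    for i, name in enumerate(aln.names):
        members.setdefault(aln.codes[i].tobytes(), []).append(name)
    reps = [mem[0] for mem in members.values()]
    rows = np.vstack(
        [np.frombuffer(key, dtype=np.uint8) for key in members.keys()]
    )
    collapsed = SequenceAlignment(reps, rows)
    return collapsed, {mem[0]: mem for mem in members.values()}
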