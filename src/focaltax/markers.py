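"""16S marker-sequence utilities: V4 extraction and identity matrices.

The V4 sub-region is located by matching the 515F/806R degenerate primer
pair (IUPAC codes) against a full-length 16S sequence; the region between
the primer sites (primers excluded) is returned.  Pairwise percent
identity is computed on pre-aligned sequences, counting only columns
where neither sequence has a gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["PrimerPair", "V4_PRIMERS", "extract_v4", "identity_matrix",
           "reverse_complement"]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes: {sorted(bad)}")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


#: the 515FB/806RB pair used by large-scale gut amplicon surveys
V4_PRIMERS = PrimerPair("GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _primer_regex(primer: str) -> re.Pattern:
    # N in the target sequence matches any primer position
    parts = []
    for code in primer:
        opts = IUPAC[code]
        parts.append(f"[{opts}N]" if len(opts) < 4 else ".")
    return re.compile("".join(parts))


def extract_v4(sequence: str, primers: PrimerPair = V4_PRIMERS) -> str:
    """Region between the forward primer and the reverse-complemented
    reverse primer (primers excluded); first-match semantics."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence has non-ACGTN characters: {sorted(bad)}")
    fwd = _primer_regex(primers.forward).search(seq)
    if fwd is None:
        raise ValueError("forward primer not found in sequence")
    rev = _primer_regex(reverse_complement(primers.reverse)).search(seq, fwd.end())
    if rev is None:
        raise ValueError("reverse primer (reverse-complemented) not found in sequence")
    return seq[fwd.end():rev.start()]


def identity_matrix(aligned: Mapping[str, str] | Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pairwise percent identity of pre-aligned, equal-length sequences.

    identity(i, j) = 100 * matches / columns where neither sequence has a
    gap ('-' or '.'); NaN when the gapless overlap is empty; diagonal 100.
    """
    items = list(aligned.items()) if isinstance(aligned, Mapping) else list(aligned)
    names = [n for n, _ in items]
    seqs = [s.upper() for _, s in items]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"aligned sequences must have equal length; got {sorted(lengths)}")
    arrs = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    gaps = [np.isin(a, [b"-", b"."]) for a in arrs]
    n = len(names)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i] & ~gaps[j]
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            ident = 100.0 * float((arrs[i][ok] == arrs[j][ok]).mean())
            out[i, j] = out[j, i] = ident
    return pd.DataFrame(out, index=names, columns=names)
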