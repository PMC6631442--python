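"""Vectorized base encoding and motif-code extraction.

Internal engine shared by the counting layer and the simulator.  Bases are
encoded A=0, C=1, G=2, T=3; any ambiguous base (N) is 4 and poisons every
motif window it touches.  A motif of length k is packed into a base-4
integer in 0..4**k-1, most-significant digit first, so an integer bincount
replaces a dictionary of string counts.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
AMBIG = 4  # code for N / anything non-ACGT


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to uint8 codes (non-ACGT -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Complement encoded bases; ambiguous bases stay ambiguous."""
    out = 3 - codes.astype(np.int8)
    out[codes == AMBIG] = AMBIG
    return out.astype(np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a plain string (N self-complementary)."""
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def motif_codes_at(
    codes: np.ndarray,
    positions: np.ndarray,
    k: int,
    x_index: int,
    strand: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Packed motif codes around each position, in sense orientation.

    For a + strand gene the sense motif at position p covers genomic
    positions p-x_index .. p-x_index+k-1 left to right.  For a - strand
    gene the sense motif reads along decreasing genomic coordinate with
    each base complemented: sense letter j sits at genomic p+x_index-j.

    Returns (packed, valid); packed entries are meaningless where valid
    is False (window out of bounds or containing an ambiguous base).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if strand == "+":
        offsets = np.arange(k) - x_index
        base_codes_fn = lambda c: c  # noqa: E731
    elif strand == "-":
        offsets = x_index - np.arange(k)
        base_codes_fn = complement_codes
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    idx = positions[:, None] + offsets[None, :]
    valid = (idx >= 0).all(axis=1) & (idx < codes.size).all(axis=1)
    idx = np.clip(idx, 0, codes.size - 1)
    window = base_codes_fn(codes[idx])
    valid &= (window != AMBIG).all(axis=1)

    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    packed = (window.astype(np.int64) * weights[None, :]).sum(axis=1)
    return packed, valid


def code_to_motif(code: int, k: int) -> str:
    out = []
    for shift in range(k - 1, -1, -1):
        out.append(BASES[(code >> (2 * shift)) & 3])
    return "".join(out)


def motif_to_code(motif: str) -> int:
    code = 0
    for ch in motif:
        i = BASES.find(ch)
        if i < 0:
            raise ValueError(f"non-ACGT base in motif {motif!r}")
        code = (code << 2) | i
    return code


def all_motifs(k: int) -> list[str]:
    return [code_to_motif(c, k) for c in range(4**k)]
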