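"""Nucleotide sequence encoding helpers.

Sequences are held internally as ``numpy.uint8`` arrays with the encoding
A=0, C=1, G=2, T=3, N=4.  The ambiguous base N is carried through alignment
but never scores as a match.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str | bytes | np.ndarray) -> np.ndarray:
    """Encode a DNA string into a uint8 array (unknown letters become N)."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.asarray(arr, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement; N maps to N."""
    arr = np.asarray(arr, dtype=np.uint8)
    out = (3 - arr)[::-1]
    out[out > 3] = 4  # 3 - 4 wraps to 255 for N
    np.putmask(out, arr[::-1] == 4, 4)
    return out.astype(np.uint8)


def revcomp_rows(mat: np.ndarray) -> np.ndarray:
    """Reverse complement every row of a reads matrix."""
    out = (3 - mat)[:, ::-1]
    np.putmask(out, mat[:, ::-1] == 4, 4)
    return out.astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def kmer_codes(seq: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """Base-4 integer codes of k-mers of ``seq`` (or of each row of a reads
    matrix), taken every ``stride`` starting positions.  Windows containing
    N get code -1.  Requires k <= 31."""
    if k > 31:
        raise ValueError("k-mer size too large for 64-bit codes")
    seq = np.asarray(seq, dtype=np.uint8)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(seq, k, axis=-1)
    if stride > 1:
        win = win[..., ::stride, :]
    codes = win.astype(np.int64) @ weights
    bad = (win >= 4).any(axis=-1)
    codes[bad] = -1
    return codes
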