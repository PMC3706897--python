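"""Small sequence helpers shared across the package.

Sequences are plain uppercase Python strings over {A, C, G, T} (plus 'N' for
supercontig spacers). k-mers are packed into int64 codes (2 bits per base) so
that genome-scale counting can be done with numpy.
"""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A=0, C=1, G=2, T=3; everything else sentinel 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT string as uint8 codes 0..3; raises on other symbols."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return arr


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random DNA of length n with expected GC fraction `gc`."""
    if n < 0:
        raise ValueError("length must be non-negative")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=n, p=p)
    return "".join(BASES[c] for c in codes)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed int64 code of every k-window of an encoded sequence.

    Returns an array of length len(codes) - k + 1 (empty if shorter than k).
    """
    n = len(codes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > 62:
        raise ValueError("k too large for int64 packing")
    if n < k:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        out = (out << 2) | c[j : j + n - k + 1]
    return out


def canonical_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Per-window min(code, revcomp-code): strand-combined k-mer identity."""
    fwd = kmer_codes(codes, k)
    if len(fwd) == 0:
        return fwd
    rc_seq = (3 - codes)[::-1]
    rc = kmer_codes(rc_seq, k)[::-1]
    return np.minimum(fwd, rc)


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage seed (< 2**31) from a global seed and a label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
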