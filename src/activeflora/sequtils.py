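"""Integer sequence encodings shared by the simulator and the search core.

Nucleotides are encoded A=0, C=1, G=2, T=3; anything else becomes the
sentinel 4 and invalidates every k-mer window that contains it.  Amino
acids use the 20-letter alphabet below (codes 0..19), with 20 reserved
for stop codons and 21 for unknown residues.  All hot paths operate on
these ``uint8`` arrays rather than on Python strings.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_SENTINEL = 4
AA_STOP = 20
AA_SENTINEL = 21

_NT_LUT = np.full(256, NT_SENTINEL, dtype=np.uint8)
for _i, _c in enumerate(NT_ALPHABET):
    _NT_LUT[ord(_c)] = _i
    _NT_LUT[ord(_c.lower())] = _i

_AA_LUT = np.full(256, AA_SENTINEL, dtype=np.uint8)
for _i, _c in enumerate(AA_ALPHABET):
    _AA_LUT[ord(_c)] = _i
    _AA_LUT[ord(_c.lower())] = _i
_AA_LUT[ord("*")] = AA_STOP

# complement in code space; sentinel maps to itself
_NT_COMPLEMENT = np.array([3, 2, 1, 0, NT_SENTINEL], dtype=np.uint8)

_NT_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_AA_BYTES = np.frombuffer((AA_ALPHABET + "*X").encode(), dtype=np.uint8)


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _NT_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_nt(codes: np.ndarray) -> str:
    return _NT_BYTES[codes].tobytes().decode()


def encode_aa(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    return _AA_BYTES[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _NT_COMPLEMENT[codes][::-1]


def revcomp(seq: str) -> str:
    return decode_nt(revcomp_codes(encode_nt(seq)))


def kmer_codes(codes: np.ndarray, k: int, alphabet_size: int) -> tuple[np.ndarray, np.ndarray]:
    """All overlapping k-mer integer codes of a code array.

    Returns ``(kmers, valid)`` of length ``len(codes) - k + 1``; ``valid``
    is False wherever the window contains a sentinel code.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    powers = alphabet_size ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    kmers = windows.astype(np.int64) @ powers
    valid = ~(windows >= alphabet_size).any(axis=1)
    return kmers, valid


# --- translation ---------------------------------------------------------

_standard = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = np.full(64, AA_SENTINEL, dtype=np.uint8)
for _codon, _aa in _standard.forward_table.items():
    _idx = _NT_LUT[ord(_codon[0])] * 16 + _NT_LUT[ord(_codon[1])] * 4 + _NT_LUT[ord(_codon[2])]
    _CODON_AA[_idx] = _AA_LUT[ord(_aa)]
for _codon in _standard.stop_codons:
    _idx = _NT_LUT[ord(_codon[0])] * 16 + _NT_LUT[ord(_codon[1])] * 4 + _NT_LUT[ord(_codon[2])]
    _CODON_AA[_idx] = AA_STOP

# aa code -> padded matrix of synonymous codons (as nt code triplets)
_MAX_CODONS = 6
CODON_COUNTS = np.zeros(20, dtype=np.int64)
CODON_MATRIX = np.zeros((20, _MAX_CODONS, 3), dtype=np.uint8)
for _codon, _aa in sorted(_standard.forward_table.items()):
    _a = _AA_LUT[ord(_aa)]
    _j = CODON_COUNTS[_a]
    CODON_MATRIX[_a, _j] = [_NT_LUT[ord(_c)] for _c in _codon]
    CODON_COUNTS[_a] = _j + 1


def translate_frame(nt_codes: np.ndarray, frame: int) -> np.ndarray:
    """Translate one forward frame (1..3) of a nucleotide code array.

    Stop codons become ``AA_STOP``; codons containing a sentinel become
    ``AA_SENTINEL``.
    """
    sub = nt_codes[frame - 1:]
    ncod = sub.size // 3
    if ncod == 0:
        return np.empty(0, dtype=np.uint8)
    c = sub[: ncod * 3].reshape(-1, 3).astype(np.int64)
    bad = (c >= 4).any(axis=1)
    idx = np.where(bad, 0, c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2])
    aa = _CODON_AA[idx].copy()
    aa[bad] = AA_SENTINEL
    return aa


def six_frame_peptides(nt_codes: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
    """Six-frame translation split at stop codons.

    Yields ``(frame, aa_offset, peptide_codes)`` where ``frame`` is in
    {+1,+2,+3,-1,-2,-3}, ``aa_offset`` is the codon offset of the peptide
    within its frame (frames -n run along the reverse complement), and
    ``peptide_codes`` contains only residue codes 0..19.
    """
    out: list[tuple[int, int, np.ndarray]] = []
    rc = revcomp_codes(nt_codes)
    for strand_codes, sign in ((nt_codes, 1), (rc, -1)):
        for f in (1, 2, 3):
            aa = translate_frame(strand_codes, f)
            if aa.size == 0:
                continue
            breaks = np.flatnonzero(aa >= AA_STOP)
            start = 0
            for b in list(breaks) + [aa.size]:
                if b > start:
                    out.append((sign * f, start, aa[start:b]))
                start = b + 1
    return out


def reverse_translate(aa_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Back-translate residue codes to nucleotide codes with uniform codon choice."""
    counts = CODON_COUNTS[aa_codes]
    choice = (rng.random(aa_codes.size) * counts).astype(np.int64)
    return CODON_MATRIX[aa_codes, choice].reshape(-1)


def mutate_codes(codes: np.ndarray, rate, rng: np.random.Generator,
                 alphabet_size: int = 4) -> np.ndarray:
    """Substitute each position i.i.d. at ``rate`` (scalar or per-position
    array), always to a different letter."""
    hit = rng.random(codes.size) < rate
    if not hit.any():
        return codes.copy()
    out = codes.copy()
    shift = rng.integers(1, alphabet_size, size=int(hit.sum()))
    out[hit] = ((out[hit].astype(np.int64) + shift) % alphabet_size).astype(np.uint8)
    return out
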