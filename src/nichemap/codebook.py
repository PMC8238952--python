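"""Error-robust MERFISH barcode codebook.

RNA species are encoded as 16-bit binary barcodes read out over sequential
hybridization rounds (bit index = readout round).  The code is the
Hamming-weight-4 subset of the extended Hamming code of length 16
(minimum pairwise distance 4), which yields exactly 140 barcodes: any
single-bit readout error lands at distance 1 from the true barcode and at
distance >= 3 from every other one, so it is uniquely correctable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

N_BITS = 16

__all__ = [
    "Barcode",
    "Codebook",
    "build_extended_hamming_code",
    "build_mhd4_codebook",
    "decode_bits",
]


@dataclass(frozen=True)
class Barcode:
    """An ordered sequence of 16 binary readout values with Hamming weight 4."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_BITS:
            raise ValueError(f"barcode must have exactly {N_BITS} bits, got {len(self.bits)}")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("barcode bits must be 0 or 1")
        if sum(self.bits) != 4:
            raise ValueError(f"barcode must have Hamming weight 4, got weight {sum(self.bits)}")

    @classmethod
    def from_string(cls, s: str) -> "Barcode":
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def as_int(self) -> int:
        """Bits packed into an integer, bit 0 the most significant."""
        return int("".join(str(b) for b in self.bits), 2)


def _hamming_distance(a: Sequence[int], b: Sequence[int]) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class Codebook:
    """Gene <-> barcode map plus optional blank (unused) codewords.

    Blank barcodes are valid codewords assigned to no gene; decoded counts
    landing on them estimate the false-positive rate.  Invariants (pairwise
    distance >= 4, uniqueness, <= 140 total entries) are checked on
    construction.
    """

    entries: dict[str, Barcode]
    blank_entries: dict[str, Barcode] = field(default_factory=dict)

    def __post_init__(self) -> None:
        all_items = list(self.entries.items()) + list(self.blank_entries.items())
        if len(all_items) > 140:
            raise ValueError(f"codebook holds at most 140 entries, got {len(all_items)}")
        codes = [bc for _, bc in all_items]
        seen: dict[int, str] = {}
        for name, bc in all_items:
            if bc.as_int in seen:
                raise ValueError(f"duplicate barcode shared by {seen[bc.as_int]!r} and {name!r}")
            seen[bc.as_int] = name
        for i in range(len(codes)):
            for j in range(i + 1, len(codes)):
                d = _hamming_distance(codes[i].bits, codes[j].bits)
                if d < 4:
                    raise ValueError(
                        f"barcodes {codes[i]} and {codes[j]} are at Hamming distance {d} < 4"
                    )
        self._decode_lut: np.ndarray | None = None

    @property
    def gene_names(self) -> list[str]:
        return list(self.entries)

    @property
    def n_entries(self) -> int:
        return len(self.entries) + len(self.blank_entries)

    def encode(self, gene: str) -> Barcode:
        if gene in self.entries:
            return self.entries[gene]
        if gene in self.blank_entries:
            return self.blank_entries[gene]
        raise KeyError(f"unknown codebook entry {gene!r}")

    def decode_lut(self) -> np.ndarray:
        """int64 array of length 2**16 mapping a packed bit vector to the
        index of the entry within distance 1, or -1 when there is none.

        Entry order: genes first (in insertion order) then blanks.  With a
        distance-4 code the <=1-error neighborhoods of distinct entries are
        disjoint, so the table is well defined.
        """
        if self._decode_lut is None:
            lut = np.full(1 << N_BITS, -1, dtype=np.int64)
            names = list(self.entries) + list(self.blank_entries)
            for idx, name in enumerate(names):
                word = self.encode(name).as_int
                lut[word] = idx
                for bit in range(N_BITS):
                    lut[word ^ (1 << (N_BITS - 1 - bit))] = idx
            self._decode_lut = lut
        return self._decode_lut

    def entry_names(self) -> list[str]:
        return list(self.entries) + list(self.blank_entries)

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        records = [
            {"name": name, "barcode": str(bc), "is_blank": False}
            for name, bc in self.entries.items()
        ] + [
            {"name": name, "barcode": str(bc), "is_blank": True}
            for name, bc in self.blank_entries.items()
        ]
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        records = json.loads(Path(path).read_text())
        entries: dict[str, Barcode] = {}
        blanks: dict[str, Barcode] = {}
        for rec in records:
            bc = Barcode.from_string(rec["barcode"])
            (blanks if rec.get("is_blank") else entries)[rec["name"]] = bc
        return cls(entries=entries, blank_entries=blanks)


def build_extended_hamming_code(n_bits: int) -> np.ndarray:
    """All codewords of the extended Hamming code of length ``n_bits``.

    The extended Hamming code is the binary Hamming code of length
    ``n_bits - 1`` with an overall parity bit appended; its minimum
    pairwise distance is 4 and its size is ``2**(n_bits - log2(n_bits) - 1)``.

    Parameters
    ----------
    n_bits
        Codeword length; must be a supported power of two (8, 16 or 32).

    Returns
    -------
    (n_codewords, n_bits) uint8 array of codewords.
    """
    if n_bits not in (8, 16, 32):
        raise ValueError(f"unsupported code length {n_bits}; must be one of 8, 16, 32")
    m = int(np.log2(n_bits))  # parity bits of the underlying Hamming code
    n = n_bits - 1  # Hamming code length 2**m - 1
    k = n - m  # message bits

    # Systematic parity-check of the [n, k] Hamming code: H = [A | I_m]
    # where the columns of A are the non-unit-weight nonzero m-bit vectors.
    cols = [c for c in range(1, n + 1) if bin(c).count("1") > 1]
    A = np.array([[(c >> (m - 1 - i)) & 1 for c in cols] for i in range(m)], dtype=np.uint8)
    # Generator G = [I_k | A^T]; codeword = msg @ G (mod 2).
    messages = ((np.arange(1 << k)[:, None] >> np.arange(k - 1, -1, -1)) & 1).astype(np.uint8)
    parity = (messages @ A.T) % 2
    words = np.concatenate([messages, parity], axis=1)
    overall = words.sum(axis=1, dtype=np.int64) % 2
    return np.concatenate([words, overall[:, None].astype(np.uint8)], axis=1)


def build_mhd4_codebook(
    gene_names: Sequence[str],
    n_blanks: int = 0,
    seed: int = 0,
) -> Codebook:
    """Build the constant-weight-4, minimum-distance-4 MERFISH codebook.

    Takes the Hamming-weight-4 codewords of the length-16 extended Hamming
    code (140 of them), shuffles them with a seeded permutation, and assigns
    the first ``len(gene_names)`` to genes and the next ``n_blanks`` to
    blank entries named ``Blank-1`` ... ``Blank-n``.
    """
    words = build_extended_hamming_code(N_BITS)
    weight4 = words[words.sum(axis=1) == 4]
    # canonical order (packed-integer ascending) before the seeded shuffle
    packed = weight4 @ (1 << np.arange(N_BITS - 1, -1, -1, dtype=np.int64))
    weight4 = weight4[np.argsort(packed)]
    n_needed = len(gene_names) + n_blanks
    if n_needed > len(weight4):
        raise ValueError(
            f"requested {n_needed} barcodes but only {len(weight4)} weight-4 codewords exist"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(weight4))
    chosen = weight4[order[:n_needed]]
    entries = {
        name: Barcode(tuple(int(b) for b in chosen[i]))
        for i, name in enumerate(gene_names)
    }
    blanks = {
        f"Blank-{j + 1}": Barcode(tuple(int(b) for b in chosen[len(gene_names) + j]))
        for j in range(n_blanks)
    }
    return Codebook(entries=entries, blank_entries=blanks)


def decode_bits(
    bit_vector: Sequence[int] | np.ndarray,
    codebook: Codebook,
    max_errors: int = 1,
) -> str | None:
    """Decode a 16-bit readout vector to an entry name, or ``None``.

    Returns the unique codebook entry within Hamming distance ``max_errors``
    of ``bit_vector``.  With minimum distance 4 and ``max_errors=1`` the
    match, when it exists, is always unique; ``max_errors >= 2`` would be
    ambiguous and is rejected.
    """
    if max_errors >= 2:
        raise ValueError("max_errors >= 2 is ambiguous for a minimum-distance-4 code")
    bits = tuple(int(b) for b in bit_vector)
    if len(bits) != N_BITS:
        raise ValueError(f"bit vector must have length {N_BITS}, got {len(bits)}")
    names = codebook.entry_names()
    if max_errors == 0:
        packed = int("".join(map(str, bits)), 2)
        for name in names:
            if codebook.encode(name).as_int == packed:
                return name
        return None
    packed = int("".join(map(str, bits)), 2)
    idx = codebook.decode_lut()[packed]
    return names[idx] if idx >= 0 else None
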