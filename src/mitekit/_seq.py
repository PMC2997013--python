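"""Low-level nucleotide helpers shared by the scanning and simulation code."""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")

# integer codes used by the simulator
CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def normalize(seq: str) -> str:
    """Upper-case and collapse every non-ACGT character to N."""
    up = seq.upper()
    bad = set(up) - set("ACGTN")
    if bad:
        up = up.translate({ord(c): "N" for c in bad})
    return up


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes (0..3). N is not representable here."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in CODE.items():
        out[arr == ord(base)] = code
    return out


def array_to_seq(arr: np.ndarray) -> str:
    return _BASE_ARR[arr].tobytes().decode()


def random_seq(rng: np.random.Generator, length: int, at_content: float = 0.5) -> str:
    """I.i.d. nucleotides with the requested A+T fraction (A/T and C/G equiprobable)."""
    p_at = at_content / 2.0
    p_cg = (1.0 - at_content) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_cg, p_cg, p_at])
    return array_to_seq(codes.astype(np.uint8))


# transition partner under the two-rate substitution model: A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion alternatives for each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def mutate(seq: str, k: float, kappa: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each site with probability ``k``.

    A substituted site becomes a transition with probability kappa/(kappa+2)
    and each of its two transversions with probability 1/(kappa+2).
    Returns the mutated sequence and the realized substitution count.
    """
    if k <= 0:
        return seq, 0
    codes = seq_to_array(seq)
    hit = rng.random(codes.size) < k
    n_hit = int(hit.sum())
    if n_hit == 0:
        return seq, 0
    p_ts = kappa / (kappa + 2.0)
    is_ts = rng.random(n_hit) < p_ts
    old = codes[hit]
    new = old.copy()
    new[is_ts] = _TRANSITION[old[is_ts]]
    tv_pick = rng.integers(0, 2, size=n_hit)
    tv_mask = ~is_ts
    new[tv_mask] = _TRANSVERSIONS[old[tv_mask], tv_pick[tv_mask]]
    codes[hit] = new
    return array_to_seq(codes), n_hit
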