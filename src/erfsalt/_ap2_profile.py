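"""Bundled AP2-domain position profile.

The AP2 DNA-binding domain (~60 aa; three anti-parallel beta-sheets followed
by an amphipathic alpha-helix) is detected with a log-odds position-specific
scoring matrix (PSSM) built from the small SYNTHETIC seed alignment below.
The seed sequences are not database records: they are hand-written variants
around the canonical domain architecture (YRG element at the N-terminus,
the invariant WLG motif, and the RAYD element in the helix), constructed so
that the subfamily-diagnostic alignment columns carry the field's standard
residue numbering:

* column 14 -- Ala in ERF-type rows, Val in DREB-type rows
* column 19 -- Asp in ERF-type rows, Glu in DREB-type rows
* column 37 -- the invariant Ala of the alpha-helix

Scores are log2 odds against a uniform amino-acid background (p = 1/20) with
a pseudocount of 0.5 per residue per column.  A sequence window drawn from
the profile scores far above 0; unrelated protein sequence scores strongly
negative, so the default 8-bit threshold separates the two cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PROFILE_LENGTH = 60

# Diagnostic alignment columns (1-based, as used throughout the literature).
RES14, RES19, RES37 = 14, 19, 37

#                 1        10        20        30        40        50        60
#                 |        |         |         |         |         |         |
_ERF_CONSENSUS = "YRGVRQRPWGKWVAEIRDDPRKGVRVWLGTFDTAEEAARAYDAAALRFRGPRARTNFPVS"
_DREB_CONSENSUS = _ERF_CONSENSUS[:13] + "V" + _ERF_CONSENSUS[14:18] + "E" + _ERF_CONSENSUS[19:]

# Synthetic seed alignment: 5 ERF-type and 3 DREB-type rows with scattered
# substitutions away from the diagnostic columns.
SEED_ALIGNMENT = (
    _ERF_CONSENSUS,
    "YKGVRQRPWGKWVAEIRDDPRKGVRVWLGTFDTAEEAARAYDVAALRFRGPRAKTNFPVS",
    "YRGVRRRPWGKWVAEIRDDPRHGVRVWLGTFNTAEEAARAYDAAALRFHGPRARTNFALS",
    "YRGVRQRPWGKWVAEIRDDSRKGSRVWLGTFDTAEEAARAYDAAARRFRGPKARTNFPDS",
    "FRGVRQRPWGKWVAEIRDDPRKGVRLWLGTFDTAEEAAVAYDAAALRFRGPRARTNYPVE",
    _DREB_CONSENSUS,
    "YRGVRRRPWGKWVAEIREEPRKGSRVWLGTFDTAEEAARAYDAAALRFRGPRARTNFPYS",
    "YRGVRQRPWGKFVAEIREEPRKGVRVWLGTYDTAEEAARAYDAAALRMRGPRARTNFAVS",
)

assert all(len(s) == PROFILE_LENGTH for s in SEED_ALIGNMENT)


@dataclass(frozen=True)
class Ap2Pssm:
    """Ungapped log-odds profile over the 20-letter amino-acid alphabet.

    ``matrix`` has shape (length, 20); ``probs`` holds the pseudocounted
    per-column residue probabilities used both for scoring and, by the
    synthetic-data generator, for sampling domain sequences.
    """

    matrix: np.ndarray
    probs: np.ndarray
    alphabet: str = AA_ALPHABET

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def encode(self, sequence: str) -> np.ndarray:
        """Map a protein string to alphabet indices; unknowns (X etc.) -> -1."""
        lookup = np.full(128, -1, dtype=np.int64)
        for i, aa in enumerate(self.alphabet):
            lookup[ord(aa)] = i
        arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
        return lookup[arr]

    def score_windows(self, sequence: str) -> np.ndarray:
        """Log-odds score of every length-L window (empty if seq shorter).

        Unknown residues contribute 0 bits (background odds).
        """
        L = self.length
        n = len(sequence)
        if n < L:
            return np.zeros(0)
        idx = self.encode(sequence)
        # per-position scores for each profile column; unknown -> 0
        padded = np.hstack([self.matrix, np.zeros((L, 1))])  # column -1 = unknown
        # windows[i, j] = score of residue i+j under column j
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        return padded[np.arange(L)[None, :], windows].sum(axis=1)


def build_pssm(alignment=SEED_ALIGNMENT, pseudocount: float = 0.5) -> Ap2Pssm:
    """Build the log2-odds PSSM from an ungapped alignment."""
    length = len(alignment[0])
    if any(len(s) != length for s in alignment):
        raise ValueError("alignment rows must have equal length")
    counts = np.full((length, len(AA_ALPHABET)), pseudocount)
    col_of = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    for row in alignment:
        for pos, aa in enumerate(row):
            counts[pos, col_of[aa]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    matrix = np.log2(probs / (1.0 / len(AA_ALPHABET)))
    return Ap2Pssm(matrix=matrix, probs=probs)


@lru_cache(maxsize=1)
def default_pssm() -> Ap2Pssm:
    return build_pssm()


def sample_domain(rng: np.random.Generator, subfamily: str = "ERF",
                  pssm: Ap2Pssm | None = None) -> str:
    """Draw a domain sequence from the profile, forcing the diagnostic columns.

    ``subfamily`` is "ERF" (Ala14/Asp19) or "DREB" (Val14/Glu19); column 37 is
    always the invariant Ala.
    """
    pssm = pssm or default_pssm()
    letters = []
    for pos in range(pssm.length):
        aa = AA_ALPHABET[rng.choice(len(AA_ALPHABET), p=pssm.probs[pos])]
        letters.append(aa)
    res14, res19 = ("A", "D") if subfamily == "ERF" else ("V", "E")
    letters[RES14 - 1] = res14
    letters[RES19 - 1] = res19
    letters[RES37 - 1] = "A"
    return "".join(letters)
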