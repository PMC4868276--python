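"""Domain types: proteins, annotated lysine sites, sliding windows, profiles.

Site positions are 1-based inclusive throughout (the convention of sequence
biology); internal arrays are 0-based. A window of radius ``L`` covers offsets
``j = -L .. +L`` relative to the central lysine; offset ``j`` maps to array
index ``j + L``. Positions falling outside the protein are padded with the gap
symbol ``'-'`` and flagged invalid, so every encoder sees a fixed-length
window and can exclude the padding from its counts and denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: The 20 standard amino acids in alphabetical single-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"

#: Labels for annotated lysine sites.
LABELS = ("positive", "negative", "unknown")
_LABEL_SYNONYMS = {"1": "positive", "0": "negative", "?": "unknown"}


def normalize_label(raw: str) -> str:
    label = _LABEL_SYNONYMS.get(raw.strip(), raw.strip().lower())
    if label not in LABELS:
        raise ValueError(f"unrecognized site label {raw!r}")
    return label


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20-letter alphabet ('X' tolerated)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {UNKNOWN}
        if bad:
            raise ValueError(
                f"protein {self.id}: illegal characters {sorted(bad)} "
                "(sanitize on input: map to 'X')"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A 1-based lysine position in a protein with a class label."""

    protein_id: str
    position: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if self.label not in LABELS:
            raise ValueError(f"unrecognized label {self.label!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_id, self.position)


#: Terminal classes of a window (does it cross the N/C terminus?).
N_TERMINAL = "N-terminal"
MIDDLE = "middle"
C_TERMINAL = "C-terminal"


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-radius residue fragment centred on a candidate lysine.

    ``residues`` holds 2L+1 symbols; out-of-sequence positions hold ``'-'``
    and are flagged invalid in ``valid_mask``. A window touching both termini
    (very short protein) is classed N-terminal — a deterministic tie-break.
    """

    protein_id: str
    center_position: int
    radius: int
    residues: tuple[str, ...]
    valid_mask: tuple[bool, ...]
    terminal_class: str

    def __post_init__(self) -> None:
        n = 2 * self.radius + 1
        if len(self.residues) != n or len(self.valid_mask) != n:
            raise ValueError("window arrays must have length 2L+1")
        for r, v in zip(self.residues, self.valid_mask):
            if v == (r == GAP):
                raise ValueError("valid_mask must be false exactly at gap positions")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def center_residue(self) -> str:
        return self.residues[self.radius]

    def residue_at(self, offset: int) -> str:
        """Residue at window offset j in [-L, L]."""
        return self.residues[offset + self.radius]

    @property
    def n_valid(self) -> int:
        return sum(self.valid_mask)

    def valid_residues(self) -> str:
        """Concatenation of the in-sequence residues, in window order."""
        return "".join(r for r, v in zip(self.residues, self.valid_mask) if v)


def extract_window(protein: ProteinRecord, position: int, L: int) -> SequenceWindow:
    """Extract the 2L+1 window centred at a 1-based ``position``.

    Positions before 1 or after the sequence end are filled with the gap
    symbol and masked invalid; the terminal class records which terminus
    (if any) the window crosses.
    """
    if L < 1:
        raise ValueError(f"window radius must be >= 1, got {L}")
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        from .errors import BoundsError

        raise BoundsError(
            f"position {position} outside protein {protein.id} (length {len(seq)})"
        )
    residues = []
    mask = []
    for j in range(-L, L + 1):
        p = position + j  # 1-based
        if 1 <= p <= len(seq):
            residues.append(seq[p - 1])
            mask.append(True)
        else:
            residues.append(GAP)
            mask.append(False)
    upstream_invalid = not all(mask[:L])
    downstream_invalid = not all(mask[L + 1 :])
    if upstream_invalid:
        terminal = N_TERMINAL  # wins over C-terminal on very short proteins
    elif downstream_invalid:
        terminal = C_TERMINAL
    else:
        terminal = MIDDLE
    return SequenceWindow(
        protein_id=protein.id,
        center_position=position,
        radius=L,
        residues=tuple(residues),
        valid_mask=tuple(mask),
        terminal_class=terminal,
    )


class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid substitution matrix with min/max scores.

    Normalized similarity ``sim(a, b) = (M(a,b) - min M) / (max M - min M)``
    lies in [0, 1]; pairs involving a gap or 'X' get sim = 0 (maximal
    dissimilarity).
    """

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.name = name
        self.scores = scores
        self.min = float(scores.min())
        self.max = float(scores.max())
        if not self.min < self.max:
            raise ValueError("degenerate substitution matrix (min == max)")
        # similarity lookup padded with a row/col for gap/'X' (sim contribution 0)
        sim = (scores - self.min) / (self.max - self.min)
        self._sim = np.zeros((21, 21))
        self._sim[:20, :20] = sim

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        scores = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                scores[i, j] = m[a, b]
        return cls(scores, name="BLOSUM62")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def sim(self, a: str, b: str) -> float:
        """Normalized similarity in [0,1]; 0 for gap/'X' on either side."""
        ia = AA_INDEX.get(a, 20)
        ib = AA_INDEX.get(b, 20)
        return float(self._sim[ia, ib])

    def encode(self, residues) -> np.ndarray:
        """Integer codes (20 for gap/'X') for vectorized similarity lookups."""
        return np.array([AA_INDEX.get(r, 20) for r in residues], dtype=np.intp)

    @property
    def sim_table(self) -> np.ndarray:
        return self._sim


@dataclass
class ResidueProfile:
    """Per-position values from external sequence/structure predictors.

    Any subset of channels may be present (``None`` marks an absent channel);
    encoders that need an absent channel raise ``ChannelMissingError`` rather
    than silently emitting zeros. Probability rows are renormalized to sum
    to 1 on construction. Amino-acid columns of ``pssm_scores``, ``pssm_probs``
    and ``hh_probs`` follow alphabetical single-letter order.
    """

    length: int
    pssm_scores: np.ndarray | None = None  # (length, 20) log-odds
    pssm_probs: np.ndarray | None = None  # (length, 20), rows sum to 1
    hh_probs: np.ndarray | None = None  # (length, 20), rows sum to 1
    ss: np.ndarray | None = None  # (length,) labels in {H, E, C}
    rsa: np.ndarray | None = None  # (length,)
    phi: np.ndarray | None = None  # (length,) degrees
    psi: np.ndarray | None = None  # (length,) degrees
    disorder: np.ndarray | None = None  # (length,) bool
    hse: np.ndarray | None = None  # (length, 4): HSEAU, HSEAD, HSEBU, HSEBD

    def __post_init__(self) -> None:
        for name in ("pssm_scores", "pssm_probs", "hh_probs"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.length, 20):
                    raise ValueError(f"{name}: expected shape ({self.length}, 20), got {arr.shape}")
                setattr(self, name, arr)
        for name in ("rsa", "phi", "psi"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.length,):
                    raise ValueError(f"{name}: expected length {self.length}")
                setattr(self, name, arr)
        if self.ss is not None:
            self.ss = np.asarray(self.ss, dtype="U1")
            if self.ss.shape != (self.length,):
                raise ValueError("ss: length mismatch")
            bad = set(self.ss.tolist()) - {"H", "E", "C"}
            if bad:
                raise ValueError(f"ss: labels must be H/E/C, got {sorted(bad)}")
        if self.disorder is not None:
            self.disorder = np.asarray(self.disorder, dtype=bool)
            if self.disorder.shape != (self.length,):
                raise ValueError("disorder: length mismatch")
        if self.hse is not None:
            self.hse = np.asarray(self.hse, dtype=float)
            if self.hse.shape != (self.length, 4):
                raise ValueError(f"hse: expected shape ({self.length}, 4)")
            if (self.hse < 0).any():
                raise ValueError("hse: values must be >= 0")
        for name in ("pssm_probs", "hh_probs"):
            arr = getattr(self, name)
            if arr is not None:
                if (arr < 0).any():
                    raise ValueError(f"{name}: negative probability")
                sums = arr.sum(axis=1)
                if (sums <= 0).any():
                    raise ValueError(f"{name}: all-zero probability row")
                if np.abs(sums - 1.0).max() > 1e-3:
                    warnings.warn(
                        f"{name}: probability rows deviate from 1 by more than 1e-3; "
                        "renormalizing",
                        stacklevel=2,
                    )
                setattr(self, name, arr / sums[:, None])

    @property
    def channels(self) -> tuple[str, ...]:
        present = []
        for name in ("pssm_scores", "pssm_probs", "hh_probs", "ss", "rsa",
                     "phi", "psi", "disorder", "hse"):
            if getattr(self, name) is not None:
                present.append(name)
        return tuple(present)

    def require(self, *names: str) -> None:
        from .errors import ChannelMissingError

        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ChannelMissingError(f"profile channel(s) missing: {', '.join(missing)}")
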