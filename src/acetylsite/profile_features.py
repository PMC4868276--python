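"""Encoders over external-predictor profile channels.

Six subtypes: SS (one-hot secondary structure), RSA (solvent accessibility
with backbone torsions), Disorder, HSE (four half-sphere exposure counts),
PSSM (log-odds scores, occurrence probabilities and the entropy conservation
score) and HH (profile-HMM probabilities plus the conservation score).

Each encoder emits a constant dimensionality for a given window radius L,
with positions concatenated upstream-to-downstream (offsets j = -L .. +L);
invalid (gap-padded) positions contribute zeros. An encoder whose channel is
absent raises ``ChannelMissingError``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .records import AMINO_ACIDS, ResidueProfile, SequenceWindow

LOG2_20 = float(np.log2(20.0))


@dataclass
class WindowProfile:
    """The profile rows for the 2L+1 positions of one window.

    Built by slicing a protein's ResidueProfile at the window's 1-based
    centre; rows at gap-padded positions are flagged invalid and zeroed by
    the encoders.
    """

    window: SequenceWindow
    profile: ResidueProfile

    def __post_init__(self) -> None:
        if self.profile.length < self.window.center_position:
            raise ContractError(
                f"profile (length {self.profile.length}) shorter than window centre "
                f"{self.window.center_position}"
            )

    @property
    def radius(self) -> int:
        return self.window.radius

    def offsets(self):
        """Yield (offset j, 0-based sequence index or None when invalid)."""
        L = self.window.radius
        for j in range(-L, L + 1):
            if self.window.valid_mask[j + L]:
                yield j, self.window.center_position + j - 1
            else:
                yield j, None


def compute_ecs(probs: np.ndarray) -> np.ndarray:
    """Evolutionary conservation score: per-position Shannon entropy (bits)
    of a 20-way occurrence-probability vector, ECS = -sum p log2 p with
    0 log 0 = 0; ranges over [0, log2 20]."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if (probs < 0).any():
        raise ContractError("negative probability in conservation-score input")
    safe = np.where(probs > 0, probs, 1.0)  # log(1) = 0, so zeros drop out
    return -(safe * np.log2(safe)).sum(axis=1)


def encode_ss(wp: WindowProfile) -> dict[str, float]:
    """Per-position one-hot secondary structure: H -> 100, C -> 010, E -> 001."""
    wp.profile.require("ss")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        label = wp.profile.ss[idx] if idx is not None else None
        out[f"SS.H.j{j}"] = 1.0 if label == "H" else 0.0
        out[f"SS.C.j{j}"] = 1.0 if label == "C" else 0.0
        out[f"SS.E.j{j}"] = 1.0 if label == "E" else 0.0
    return out


def encode_rsa_torsion(wp: WindowProfile) -> dict[str, float]:
    """Per-position (rsa, psi, phi) triples; angles pass through in degrees."""
    wp.profile.require("rsa", "phi", "psi")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        out[f"RSA.rsa.j{j}"] = float(wp.profile.rsa[idx]) if idx is not None else 0.0
        out[f"RSA.psi.j{j}"] = float(wp.profile.psi[idx]) if idx is not None else 0.0
        out[f"RSA.phi.j{j}"] = float(wp.profile.phi[idx]) if idx is not None else 0.0
    return out


def encode_disorder(wp: WindowProfile) -> dict[str, float]:
    """Per-position disorder call: 1 disordered, 0 ordered (or invalid)."""
    wp.profile.require("disorder")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        out[f"Disorder.j{j}"] = float(wp.profile.disorder[idx]) if idx is not None else 0.0
    return out


HSE_CHANNELS = ("hseau", "hsead", "hsebu", "hsebd")


def encode_hse(wp: WindowProfile) -> dict[str, float]:
    """Per-position half-sphere exposure 4-tuples in the fixed order
    (HSEAU, HSEAD, HSEBU, HSEBD)."""
    wp.profile.require("hse")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        for c, name in enumerate(HSE_CHANNELS):
            out[f"HSE.{name}.j{j}"] = float(wp.profile.hse[idx, c]) if idx is not None else 0.0
    return out


def encode_pssm(wp: WindowProfile) -> dict[str, float]:
    """Per-position PSSM block: 20 log-odds scores, 20 occurrence
    probabilities and 1 conservation score -> 41(2L+1) features."""
    wp.profile.require("pssm_scores", "pssm_probs")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        for a, aa in enumerate(AMINO_ACIDS):
            out[f"PSSM.score.{aa}.j{j}"] = (
                float(wp.profile.pssm_scores[idx, a]) if idx is not None else 0.0
            )
        for a, aa in enumerate(AMINO_ACIDS):
            out[f"PSSM.prob.{aa}.j{j}"] = (
                float(wp.profile.pssm_probs[idx, a]) if idx is not None else 0.0
            )
        out[f"PSSM.ecs.j{j}"] = (
            float(compute_ecs(wp.profile.pssm_probs[idx])[0]) if idx is not None else 0.0
        )
    return out


def encode_hh(wp: WindowProfile) -> dict[str, float]:
    """Per-position profile-HMM block: 20 emission probabilities and 1
    conservation score -> 21(2L+1) features."""
    wp.profile.require("hh_probs")
    out: dict[str, float] = {}
    for j, idx in wp.offsets():
        for a, aa in enumerate(AMINO_ACIDS):
            out[f"HH.prob.{aa}.j{j}"] = (
                float(wp.profile.hh_probs[idx, a]) if idx is not None else 0.0
            )
        out[f"HH.ecs.j{j}"] = (
            float(compute_ecs(wp.profile.hh_probs[idx])[0]) if idx is not None else 0.0
        )
    return out
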