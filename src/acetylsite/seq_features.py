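"""Sequence-derived feature encoders over sliding windows.

Eight subtypes: LC (terminal location), PWAA (position-weight amino-acid
composition), EBGW (grouped binary weight), CKSAAP (k-spaced residue pair
composition), KNN (nearest-neighbour score under a BLOSUM62 distance), ACC
(auto/cross covariance of physicochemical factors), PC-PseAAC (parallel-
correlation pseudo amino-acid composition) and AAindex (averaged and
per-position property values).

Every encoder returns an ordered ``{feature_name: value}`` mapping with the
subtype tag as the name prefix, is pure (same input, bit-identical output),
and treats invalid (gap-padded) window positions as contributing nothing:
excluded from counts and denominators where a count is defined, zero where a
fixed-length encoding is defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .records import (
    AMINO_ACIDS,
    C_TERMINAL,
    MIDDLE,
    N_TERMINAL,
    SequenceWindow,
    SubstitutionMatrix,
)
from .tables import PropertyTable, atchley_factors, default_averaged_tables, pseaac_scales

# ---------------------------------------------------------------------------
# LC

def encode_lc(window: SequenceWindow) -> dict[str, float]:
    """One-hot terminal location: N-terminal 100, middle 010, C-terminal 001."""
    return {
        "LC.nterm": 1.0 if window.terminal_class == N_TERMINAL else 0.0,
        "LC.middle": 1.0 if window.terminal_class == MIDDLE else 0.0,
        "LC.cterm": 1.0 if window.terminal_class == C_TERMINAL else 0.0,
    }


# ---------------------------------------------------------------------------
# PWAA

def encode_pwaa(window: SequenceWindow) -> dict[str, float]:
    """Position-weight amino-acid composition.

    For each amino acid i, C_i = (1/(L(L+1))) * sum_{j=-L..L} x_ij (j + |j|/L)
    with x_ij = 1 iff the (valid) residue at offset j is i. The sum runs over
    the full window including the centre (whose weight is 0 at j = 0).
    """
    L = window.radius
    norm = 1.0 / (L * (L + 1))
    sums = dict.fromkeys(AMINO_ACIDS, 0.0)
    for j in range(-L, L + 1):
        r = window.residue_at(j)
        if r in sums:
            sums[r] += j + abs(j) / L
    return {f"PWAA.{aa}": norm * sums[aa] for aa in AMINO_ACIDS}


# ---------------------------------------------------------------------------
# EBGW

#: Hydropathy/charge groups: hydrophobic, polar, positively and negatively charged.
EBGW_GROUPS = {
    "C1": set("AFGILMPVW"),
    "C2": set("CNQSTY"),
    "C3": set("HKR"),
    "C4": set("DE"),
}


def _int_round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def encode_ebgw(window: SequenceWindow, K: int = 5) -> dict[str, float]:
    """Encoding based on grouped weight.

    The window is projected onto three binary sequences (H1: hydrophobic or
    polar, H2: hydrophobic or positively charged, H3: hydrophobic or
    negatively charged; invalid positions are 0 in all three). Each is
    summarized over K prefixes of length Int(N*k/K) (round half up) as the
    fraction of ones in the prefix.
    """
    if K < 1:
        raise ContractError(f"EBGW K must be >= 1, got {K}")
    one_sets = [
        EBGW_GROUPS["C1"] | EBGW_GROUPS["C2"],
        EBGW_GROUPS["C1"] | EBGW_GROUPS["C3"],
        EBGW_GROUPS["C1"] | EBGW_GROUPS["C4"],
    ]
    N = len(window)
    out: dict[str, float] = {}
    for h, ones in enumerate(one_sets, start=1):
        bits = [1 if r in ones else 0 for r in window.residues]
        for k in range(1, K + 1):
            n_k = _int_round_half_up(N * k / K)
            out[f"EBGW.h{h}.k{k}"] = sum(bits[:n_k]) / n_k
    return out


def ebgw_prefix_lengths(N: int, K: int = 5) -> list[int]:
    """Lengths Int(N*k/K) of the K prefix sub-sequences (round half up)."""
    return [_int_round_half_up(N * k / K) for k in range(1, K + 1)]


# ---------------------------------------------------------------------------
# CKSAAP

def encode_cksaap(window: SequenceWindow, k: int = 0) -> dict[str, float]:
    """Composition of k-spaced residue pairs: 400 ordered-pair frequencies.

    A pair (offset i, offset i+k+1) is counted when both endpoints are valid
    standard residues; the output is N_ab / N_Total and sums to 1 whenever at
    least one such pair exists (all-zero otherwise).
    """
    if k < 0:
        raise ContractError(f"CKSAAP spacing must be >= 0, got {k}")
    N = len(window)
    if N < k + 2:
        raise ContractError(f"window of length {N} has no {k}-spaced pairs")
    counts = {a + b: 0 for a in AMINO_ACIDS for b in AMINO_ACIDS}
    total = 0
    for i in range(N - k - 1):
        a, b = window.residues[i], window.residues[i + k + 1]
        if a in AMINO_ACIDS and b in AMINO_ACIDS:
            counts[a + b] += 1
            total += 1
    denom = total if total > 0 else 1
    return {f"CKSAAP.k{k}.{pair}": counts[pair] / denom for pair in counts}


# ---------------------------------------------------------------------------
# KNN

@dataclass
class KnnReference:
    """Labelled training fragments plus the substitution matrix and the
    neighbour fractions (defaults 1/2, 1/4, 1/8, 1/16, 1/32 of the reference
    size)."""

    fragments: list[tuple[SequenceWindow, str]]
    substitution: SubstitutionMatrix
    fractions: tuple[float, ...] = (1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32)

    def __post_init__(self) -> None:
        radii = {w.radius for w, _ in self.fragments}
        if len(radii) > 1:
            raise ContractError("all reference fragments must share one radius")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ContractError("fractions must lie in (0, 1]")
        if len(set(self.fractions)) != len(self.fractions) or list(self.fractions) != sorted(
            self.fractions, reverse=True
        ):
            raise ContractError("fractions must be strictly decreasing")
        self._codes = np.array(
            [self.substitution.encode(w.residues) for w, _ in self.fragments], dtype=np.intp
        ) if self.fragments else np.empty((0, 0), dtype=np.intp)
        self._positive = np.array([lab == "positive" for _, lab in self.fragments])
        self._keys = [(w.protein_id, w.center_position) for w, _ in self.fragments]


def knn_distance(
    s1: SequenceWindow, s2: SequenceWindow, matrix: SubstitutionMatrix
) -> float:
    """Normalized fragment distance D = 1 - sum_i sim(s1_i, s2_i) / (2L+1).

    Positions where either residue is a gap or 'X' contribute sim = 0
    (maximal dissimilarity for that position). Lies in [0, 1]; symmetric.
    """
    if s1.radius != s2.radius:
        raise ContractError("windows must share one radius")
    n = len(s1)
    total = sum(matrix.sim(a, b) for a, b in zip(s1.residues, s2.residues))
    return 1.0 - total / n


def encode_knn(
    window: SequenceWindow, ref: KnnReference, exclude_self: bool = True
) -> dict[str, float]:
    """KNN scores: per neighbour fraction f, the proportion of positive
    labels among the K = max(1, round(f * reference size)) reference
    fragments nearest to the query under the normalized BLOSUM distance.

    ``exclude_self`` omits any reference fragment with the query's own
    (protein_id, position) — the leave-one-out convention used when encoding
    training sites, which avoids label leakage. Ties in distance are broken
    by reference insertion order (stable sort).
    """
    if not ref.fragments:
        raise ContractError("empty KNN reference")
    if window.radius != ref.fragments[0][0].radius:
        raise ContractError("query radius differs from reference radius")
    keep = np.ones(len(ref.fragments), dtype=bool)
    if exclude_self:
        key = (window.protein_id, window.center_position)
        for i, k in enumerate(ref._keys):
            if k == key:
                keep[i] = False
    if not keep.any():
        raise ContractError("KNN reference empty after self-exclusion")
    codes_q = ref.substitution.encode(window.residues)
    sims = ref.substitution.sim_table[ref._codes[keep][:, :], codes_q[None, :]]
    dists = 1.0 - sims.sum(axis=1) / len(window)
    positive = ref._positive[keep]
    order = np.argsort(dists, kind="stable")
    n = keep.sum()
    out: dict[str, float] = {}
    for f in ref.fractions:
        K = max(1, _int_round_half_up(f * n))
        out[f"KNN.f{_fraction_tag(f)}"] = float(positive[order[:K]].mean())
    return out


def _fraction_tag(f: float) -> str:
    inv = 1.0 / f
    if abs(inv - round(inv)) < 1e-9:
        return f"1_{int(round(inv))}"
    return repr(f).replace(".", "_")


# ---------------------------------------------------------------------------
# ACC

def encode_acc(
    window: SequenceWindow,
    properties: tuple[PropertyTable, ...] | None = None,
    max_lag: int = 2,
) -> dict[str, float]:
    """Auto and cross covariance of physicochemical factor profiles.

    The valid standard residues of the window (always contiguous, since gaps
    only pad the termini) form a sequence of length N_v; for each property u
    and lag g, AC(u,g) = (1/(N_v - g)) sum_i (P_u(i) - mean_u)(P_u(i+g) -
    mean_u), and CC(u,v,g) analogously with the second factor from property
    v. Defaults: the five Atchley factors, lags 1..2 -> 50 features.
    """
    if properties is None:
        properties = atchley_factors()
    if max_lag < 1:
        raise ContractError(f"max_lag must be >= 1, got {max_lag}")
    seq = [r for r, v in zip(window.residues, window.valid_mask) if v and r in AMINO_ACIDS]
    nv = len(seq)
    if nv < max_lag + 1:
        raise ContractError(f"{nv} usable positions < max_lag + 1 = {max_lag + 1}")
    profiles = {p.name: np.array([p[r] for r in seq]) for p in properties}
    centered = {name: arr - arr.mean() for name, arr in profiles.items()}
    out: dict[str, float] = {}
    for g in range(1, max_lag + 1):
        for pu in properties:
            for pv in properties:
                cu = centered[pu.name]
                cv = centered[pv.name]
                val = float((cu[: nv - g] * cv[g:]).sum() / (nv - g))
                kind = "ac" if pu.name == pv.name else "cc"
                out[f"ACC.{kind}.g{g}.{pu.name}.{pv.name}"] = val
    return out


# ---------------------------------------------------------------------------
# PC-PseAAC

def encode_pc_pseaac(
    window: SequenceWindow, lam: int = 2, weight: float = 0.05
) -> dict[str, float]:
    """Parallel-correlation pseudo amino-acid composition of the window.

    20 normalized composition terms plus ``lam`` sequence-order correlation
    factors theta_k built from standardized hydrophobicity, hydrophilicity
    and side-chain mass scales:

        theta_k = (1/(N_v - k)) sum_i Theta(R_i, R_{i+k}),
        Theta(a, b) = mean over the three scales of (scale(a) - scale(b))^2,
        x_i = f_i / (1 + w sum theta),  x_{20+k} = w theta_k / (1 + w sum theta).

    Components sum to 1; lam = 0 reduces to the plain composition.
    """
    if lam < 0:
        raise ContractError(f"lambda must be >= 0, got {lam}")
    seq = [r for r, v in zip(window.residues, window.valid_mask) if v and r in AMINO_ACIDS]
    nv = len(seq)
    if lam >= nv:
        raise ContractError(f"lambda = {lam} must be < number of usable positions ({nv})")
    scales = [t.standardized() for t in pseaac_scales()]
    thetas: list[float] = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(nv - k):
            a, b = seq[i], seq[i + k]
            total += sum((s[a] - s[b]) ** 2 for s in scales) / len(scales)
        thetas.append(total / (nv - k))
    comp = dict.fromkeys(AMINO_ACIDS, 0)
    for r in seq:
        comp[r] += 1
    denom = 1.0 + weight * sum(thetas)
    out = {f"PC-PseAAC.comp.{aa}": (comp[aa] / nv) / denom for aa in AMINO_ACIDS}
    for k, theta in enumerate(thetas, start=1):
        out[f"PC-PseAAC.theta.{k}"] = weight * theta / denom
    return out


# ---------------------------------------------------------------------------
# AAindex

def encode_aaindex(
    window: SequenceWindow,
    averaged: tuple[PropertyTable, ...] | None = None,
    per_position: tuple[PropertyTable, ...] | None = None,
) -> dict[str, float]:
    """Physicochemical property features.

    For each averaged table, the mean property value over the valid standard
    residues of the window (A = (1/n_valid) sum p_j). For each per-position
    table (default: the five Atchley factors), one value per window offset,
    zero at invalid positions -> 5 x (2L+1) features by default.
    """
    if averaged is None:
        averaged = default_averaged_tables()
    if per_position is None:
        per_position = atchley_factors()
    usable = [r for r, v in zip(window.residues, window.valid_mask) if v and r in AMINO_ACIDS]
    out: dict[str, float] = {}
    for table in averaged:
        if usable:
            out[f"AAindex.avg.{table.name}"] = sum(table[r] for r in usable) / len(usable)
        else:
            out[f"AAindex.avg.{table.name}"] = 0.0
    L = window.radius
    for table in per_position:
        for j in range(-L, L + 1):
            r = window.residue_at(j)
            out[f"AAindex.pos.{table.name}.j{j}"] = table.get(r, 0.0)
    return out
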