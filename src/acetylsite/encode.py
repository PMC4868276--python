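"""Dispatch over the 14 feature subtypes: build a FeatureMatrix for a set of
annotated lysine sites."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ChannelMissingError, ContractError
from .io import FeatureMatrix
from .profile_features import (
    WindowProfile,
    encode_disorder,
    encode_hh,
    encode_hse,
    encode_pssm,
    encode_rsa_torsion,
    encode_ss,
)
from .records import ProteinRecord, ResidueProfile, SiteRecord, SubstitutionMatrix, extract_window
from .seq_features import (
    KnnReference,
    encode_aaindex,
    encode_acc,
    encode_cksaap,
    encode_ebgw,
    encode_knn,
    encode_lc,
    encode_pc_pseaac,
    encode_pwaa,
)

logger = logging.getLogger(__name__)

#: Fixed subtype order, used for feature-matrix columns and for assembling
#: per-subtype selections into the final feature set.
SUBTYPES = (
    "LC", "PWAA", "EBGW", "CKSAAP", "KNN", "ACC", "PC-PseAAC", "AAindex",
    "SS", "RSA", "Disorder", "HSE", "PSSM", "HH",
)

SEQUENCE_SUBTYPES = ("LC", "PWAA", "EBGW", "CKSAAP", "KNN", "ACC", "PC-PseAAC", "AAindex")
PROFILE_SUBTYPES = ("SS", "RSA", "Disorder", "HSE", "PSSM", "HH")


@dataclass
class EncoderConfig:
    """Tunable parameters of the 14 encoders.

    ``L`` is the window radius (window size 2L+1; default 6 -> the optimal
    window of 13, configurable over 2 <= L <= 9 for window-size sweeps).
    """

    L: int = 6
    subtypes: tuple[str, ...] = SUBTYPES
    ebgw_k: int = 5
    cksaap_k: int = 0
    knn_fractions: tuple[float, ...] = (1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32)
    knn_exclude_self: bool = True
    acc_max_lag: int = 2
    pseaac_lambda: int = 2
    pseaac_weight: float = 0.05

    def __post_init__(self) -> None:
        if not 2 <= self.L <= 9:
            raise ContractError(f"window radius L must be in [2, 9], got {self.L}")
        unknown = set(self.subtypes) - set(SUBTYPES)
        if unknown:
            raise ContractError(f"unknown subtype(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subtypes"] = list(self.subtypes)
        d["knn_fractions"] = list(self.knn_fractions)
        return d


def build_knn_reference(
    proteins: list[ProteinRecord],
    sites: list[SiteRecord],
    L: int = 6,
    fractions: tuple[float, ...] = (1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 32),
    matrix: SubstitutionMatrix | None = None,
) -> KnnReference:
    """Build the labelled fragment reference for KNN scoring from training sites."""
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    by_id = {p.id: p for p in proteins}
    fragments = []
    for s in sites:
        if s.label not in ("positive", "negative"):
            continue
        fragments.append((extract_window(by_id[s.protein_id], s.position, L), s.label))
    return KnnReference(fragments=fragments, substitution=matrix, fractions=fractions)


def encode_sites(
    proteins: list[ProteinRecord],
    sites: list[SiteRecord],
    config: EncoderConfig | None = None,
    profiles: dict[str, ResidueProfile] | None = None,
    knn_reference: KnnReference | None = None,
) -> FeatureMatrix:
    """Encode every site into one row of named features.

    Profile subtypes require ``profiles`` (protein_id -> ResidueProfile) with
    the relevant channels; the KNN subtype requires a ``knn_reference`` (built
    from the training sites; self-matches are excluded per the config).
    Raises ``ChannelMissingError`` when a requested subtype lacks its input.
    """
    if config is None:
        config = EncoderConfig()
    active = [st for st in SUBTYPES if st in config.subtypes]
    if "KNN" in active and knn_reference is None:
        raise ChannelMissingError("KNN subtype requested but no knn_reference given")
    by_id = {p.id: p for p in proteins}
    rows: list[dict[str, float]] = []
    keys: list[tuple[str, int]] = []
    raw_labels: list[int | None] = []
    for site in sites:
        if site.protein_id not in by_id:
            raise ContractError(f"site references unknown protein {site.protein_id!r}")
        window = extract_window(by_id[site.protein_id], site.position, config.L)
        row: dict[str, float] = {}
        wp = None
        for st in active:
            if st in PROFILE_SUBTYPES:
                if profiles is None or site.protein_id not in profiles:
                    raise ChannelMissingError(
                        f"subtype {st} requires a profile for protein {site.protein_id}"
                    )
                if wp is None:
                    wp = WindowProfile(window, profiles[site.protein_id])
            if st == "LC":
                row.update(encode_lc(window))
            elif st == "PWAA":
                row.update(encode_pwaa(window))
            elif st == "EBGW":
                row.update(encode_ebgw(window, K=config.ebgw_k))
            elif st == "CKSAAP":
                row.update(encode_cksaap(window, k=config.cksaap_k))
            elif st == "KNN":
                row.update(
                    encode_knn(window, knn_reference, exclude_self=config.knn_exclude_self)
                )
            elif st == "ACC":
                row.update(encode_acc(window, max_lag=config.acc_max_lag))
            elif st == "PC-PseAAC":
                row.update(
                    encode_pc_pseaac(window, lam=config.pseaac_lambda, weight=config.pseaac_weight)
                )
            elif st == "AAindex":
                row.update(encode_aaindex(window))
            elif st == "SS":
                row.update(encode_ss(wp))
            elif st == "RSA":
                row.update(encode_rsa_torsion(wp))
            elif st == "Disorder":
                row.update(encode_disorder(wp))
            elif st == "HSE":
                row.update(encode_hse(wp))
            elif st == "PSSM":
                row.update(encode_pssm(wp))
            elif st == "HH":
                row.update(encode_hh(wp))
        rows.append(row)
        keys.append(site.key)
        if site.label == "positive":
            raw_labels.append(1)
        elif site.label == "negative":
            raw_labels.append(0)
        else:
            raw_labels.append(None)
    index = pd.MultiIndex.from_tuples(keys, names=["protein_id", "position"])
    values = pd.DataFrame(rows, index=index)
    lab = None
    if raw_labels and all(v is not None for v in raw_labels):
        lab = pd.Series(raw_labels, index=index)
    fm = FeatureMatrix(values, lab)
    logger.info(
        "encoded %d sites into %d features across subtypes %s",
        fm.n_sites, len(fm.feature_names), ",".join(fm.subtypes()),
    )
    return fm


def subtype_dimensions(config: EncoderConfig | None = None) -> dict[str, int]:
    """Documented per-subtype feature counts for a given configuration."""
    if config is None:
        config = EncoderConfig()
    n = 2 * config.L + 1
    return {
        "LC": 3,
        "PWAA": 20,
        "EBGW": 3 * config.ebgw_k,
        "CKSAAP": 400,
        "KNN": len(config.knn_fractions),
        "ACC": config.acc_max_lag * 25,
        "PC-PseAAC": 20 + config.pseaac_lambda,
        "AAindex": 10 + 5 * n,
        "SS": 3 * n,
        "RSA": 3 * n,
        "Disorder": n,
        "HSE": 4 * n,
        "PSSM": 41 * n,
        "HH": 21 * n,
    }
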