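"""Readers and writers: FASTA, site tables, profile-file dialects, feature matrices.

Profile dialects (one file per protein in a profile directory, named
``<protein_id><ext>``):

``.pssm``
    PSI-BLAST ASCII matrix: header lines, then one row per residue with a
    1-based index, the residue, 20 integer log-odds and 20 percentage
    frequencies (divided by 100 into probabilities). The amino-acid column
    order is read from the header letter row.
``.hh``
    Per-residue table of 20 profile-HMM emission probabilities, columns in
    alphabetical single-letter order, preceded by a header line.
``.ss2``
    PSIPRED vertical format: index, residue, label in {H,E,C}, three
    probabilities.
``.struct``
    TSV with header; required columns rsa, phi, psi, hseau, hsead, hsebu,
    hsebd (per-residue structure/exposure predictions).
``.diso``
    TSV with header; required column ``disorder`` with values 0/1.

All probability rows are renormalized to sum to 1 (within 1e-9) on load.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    BoundsError,
    ContractError,
    FormatError,
    NonLysineError,
    SiteReferenceError,
)
from .records import (
    AMINO_ACIDS,
    ProteinRecord,
    ResidueProfile,
    SiteRecord,
    normalize_label,
)

logger = logging.getLogger(__name__)

PROFILE_EXTENSIONS = {
    "pssm": ".pssm",
    "hh": ".hh",
    "ss2": ".ss2",
    "struct": ".struct",
    "diso": ".diso",
}


# ---------------------------------------------------------------------------
# sequences and sites

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein records; sequences are upper-cased, whitespace stripped,
    and characters outside the 20-letter alphabet mapped to 'X' (warned)."""
    from Bio import SeqIO

    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        cleaned = []
        n_mapped = 0
        for ch in seq:
            if ch in AMINO_ACIDS or ch == "X":
                cleaned.append(ch)
            else:
                cleaned.append("X")
                n_mapped += 1
        if n_mapped:
            logger.warning(
                "protein %s: mapped %d non-standard characters to 'X'", rec.id, n_mapped
            )
        records.append(ProteinRecord(id=rec.id, sequence="".join(cleaned)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, proteins: list[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_sites(path, proteins: list[ProteinRecord], permissive: bool = False) -> list[SiteRecord]:
    """Read the sites TSV (columns protein_id, position, label; header required).

    Positions are validated against the sequences; a non-lysine centre is
    rejected unless ``permissive`` is set. Labels {1,0,?} are accepted as
    synonyms of {positive,negative,unknown}.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteins}
    sites: list[SiteRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty sites file")
        cols = header.rstrip("\n").split("\t")
        try:
            i_id = cols.index("protein_id")
            i_pos = cols.index("position")
            i_lab = cols.index("label")
        except ValueError as exc:
            raise FormatError(
                f"{path}: line 1: header must contain protein_id, position, label"
            ) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(cols):
                raise FormatError(f"{path}: line {lineno}: expected {len(cols)} columns")
            pid = parts[i_id]
            if pid not in by_id:
                raise SiteReferenceError(f"{path}: line {lineno}: unknown protein_id {pid!r}")
            try:
                pos = int(parts[i_pos])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: position not an integer") from exc
            protein = by_id[pid]
            if not 1 <= pos <= len(protein):
                raise BoundsError(
                    f"{path}: line {lineno}: position {pos} outside {pid} "
                    f"(length {len(protein)})"
                )
            residue = protein.sequence[pos - 1]
            if residue != "K" and not permissive:
                raise NonLysineError(
                    f"{path}: line {lineno}: residue at {pid}:{pos} is {residue!r}, not 'K'"
                )
            sites.append(SiteRecord(pid, pos, normalize_label(parts[i_lab])))
    return sites


def write_sites(path, sites: list[SiteRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def sample_negatives(
    proteins: list[ProteinRecord],
    positives: list[SiteRecord],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[SiteRecord]:
    """Uniformly sample non-annotated lysines of the positive proteins as negatives.

    The target count is round(ratio * n_positives); if fewer candidate lysines
    exist the sample is capped with a warning. Deterministic for a fixed seed.
    """
    if ratio <= 0:
        raise ContractError(f"ratio must be > 0, got {ratio}")
    positive_keys = {s.key for s in positives}
    positive_ids = {s.protein_id for s in positives}
    by_id = {p.id: p for p in proteins}
    candidates: list[tuple[str, int]] = []
    for pid in sorted(positive_ids):
        protein = by_id[pid]
        for i, ch in enumerate(protein.sequence, start=1):
            if ch == "K" and (pid, i) not in positive_keys:
                candidates.append((pid, i))
    if not candidates:
        raise ContractError("no candidate lysines available for negative sampling")
    target = int(round(ratio * len(positives)))
    if target > len(candidates):
        warnings.warn(
            f"only {len(candidates)} candidate lysines for a target of {target} "
            "negatives; sample capped at availability",
            stacklevel=2,
        )
        target = len(candidates)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=target, replace=False)
    picked = sorted(candidates[i] for i in chosen)
    return [SiteRecord(pid, pos, "negative") for pid, pos in picked]


# ---------------------------------------------------------------------------
# profile-file dialects

def _renormalize(rows: np.ndarray, what: str, path) -> np.ndarray:
    sums = rows.sum(axis=1)
    if (sums <= 0).any():
        raise FormatError(f"{path}: {what}: all-zero probability row")
    return rows / sums[:, None]


def parse_pssm(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a PSI-BLAST ASCII PSSM into (scores, probs), columns reordered
    to alphabetical amino-acid order and frequencies renormalized to 1."""
    path = Path(path)
    order: list[str] | None = None
    scores_rows: list[list[float]] = []
    prob_rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if order is None and len(tokens) >= 20 and all(
                t in AMINO_ACIDS and len(t) == 1 for t in tokens[:20]
            ):
                order = tokens[:20]
                continue
            if tokens[0].isdigit():
                if order is None:
                    raise FormatError(f"{path}: line {lineno}: data row before header letters")
                if len(tokens) < 42:
                    raise FormatError(
                        f"{path}: line {lineno}: expected index, residue and 40 values"
                    )
                try:
                    vals = [float(t) for t in tokens[2:42]]
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
                scores_rows.append(vals[:20])
                prob_rows.append([v / 100.0 for v in vals[20:40]])
    if order is None or not scores_rows:
        raise FormatError(f"{path}: no PSSM rows found")
    perm = [order.index(aa) for aa in AMINO_ACIDS]
    scores = np.asarray(scores_rows)[:, perm]
    probs = _renormalize(np.asarray(prob_rows)[:, perm], "frequencies", path)
    return scores, probs


def parse_hh(path) -> np.ndarray:
    """Parse a per-residue 20-probability profile table (alphabetical columns)."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.rstrip("\n").split("\t")
            if not line.strip() or tokens[0] in ("idx", "index"):
                continue
            # optional leading index / residue columns
            offset = 0
            if tokens[0].isdigit():
                offset += 1
                if offset < len(tokens) and len(tokens[offset]) == 1 and tokens[offset].isalpha():
                    offset += 1
            vals = tokens[offset:]
            if len(vals) < 20:
                raise FormatError(f"{path}: line {lineno}: expected 20 probabilities")
            try:
                rows.append([float(v) for v in vals[:20]])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise FormatError(f"{path}: no profile rows found")
    arr = np.asarray(rows)
    if (arr < 0).any():
        raise FormatError(f"{path}: negative probability")
    return _renormalize(arr, "probabilities", path)


def parse_ss2(path) -> np.ndarray:
    """Parse PSIPRED .ss2 output into an array of {H,E,C} labels."""
    path = Path(path)
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or line.startswith("#"):
                continue
            if not tokens[0].isdigit():
                continue
            if len(tokens) < 3 or tokens[2] not in ("H", "E", "C"):
                raise FormatError(f"{path}: line {lineno}: expected label in {{H,E,C}}")
            labels.append(tokens[2])
    if not labels:
        raise FormatError(f"{path}: no secondary-structure rows found")
    return np.asarray(labels, dtype="U1")


def parse_structure_table(path) -> dict[str, np.ndarray]:
    """Parse the per-residue structure TSV (rsa, phi, psi and four HSE columns)."""
    path = Path(path)
    required = ["rsa", "phi", "psi", "hseau", "hsead", "hsebu", "hsebd"]
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unparseable structure table: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in required if c not in cols]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out = {c: df[cols[c]].to_numpy(dtype=float) for c in required}
    hse = np.column_stack([out["hseau"], out["hsead"], out["hsebu"], out["hsebd"]])
    if (hse < 0).any():
        raise FormatError(f"{path}: negative HSE value")
    return {"rsa": out["rsa"], "phi": out["phi"], "psi": out["psi"], "hse": hse}


def parse_disorder(path) -> np.ndarray:
    """Parse the per-residue disorder TSV (column ``disorder`` with 0/1)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: unparseable disorder table: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "disorder" not in cols:
        raise FormatError(f"{path}: missing 'disorder' column")
    vals = df[cols["disorder"]].to_numpy()
    if not set(np.unique(vals)).issubset({0, 1}):
        raise FormatError(f"{path}: disorder values must be 0/1")
    return vals.astype(bool)


def parse_profiles(directory, protein: ProteinRecord) -> ResidueProfile:
    """Assemble a ResidueProfile from whatever per-protein files are present.

    Each channel's row count is checked against the sequence length; a
    mismatch raises AlignmentError naming the file.
    """
    directory = Path(directory)
    n = len(protein)
    kwargs: dict[str, np.ndarray] = {}

    def check(arr, path):
        if arr.shape[0] != n:
            raise AlignmentError(
                f"{path}: {arr.shape[0]} rows but protein {protein.id} has {n} residues"
            )
        return arr

    p = directory / f"{protein.id}{PROFILE_EXTENSIONS['pssm']}"
    if p.exists():
        scores, probs = parse_pssm(p)
        kwargs["pssm_scores"] = check(scores, p)
        kwargs["pssm_probs"] = check(probs, p)
    p = directory / f"{protein.id}{PROFILE_EXTENSIONS['hh']}"
    if p.exists():
        kwargs["hh_probs"] = check(parse_hh(p), p)
    p = directory / f"{protein.id}{PROFILE_EXTENSIONS['ss2']}"
    if p.exists():
        kwargs["ss"] = check(parse_ss2(p), p)
    p = directory / f"{protein.id}{PROFILE_EXTENSIONS['struct']}"
    if p.exists():
        st = parse_structure_table(p)
        for key in ("rsa", "phi", "psi", "hse"):
            kwargs[key] = check(st[key], p)
    p = directory / f"{protein.id}{PROFILE_EXTENSIONS['diso']}"
    if p.exists():
        kwargs["disorder"] = check(parse_disorder(p), p)
    return ResidueProfile(length=n, **kwargs)


# ---------------------------------------------------------------------------
# feature matrices

@dataclass
class FeatureMatrix:
    """Sites x named features, with each feature name carrying a subtype tag.

    Feature names follow ``<SUBTYPE>.<channel>.<detail>`` (the subtype is
    everything before the first dot), so selection results remain auditable.
    ``values`` is a DataFrame indexed by (protein_id, position); ``labels``
    is an optional 0/1 series aligned with it.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if self.labels is not None:
            self.labels = pd.Series(
                np.asarray(self.labels, dtype=int), index=self.values.index, name="label"
            )

    @property
    def site_keys(self) -> list[tuple[str, int]]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_sites(self) -> int:
        return len(self.values)

    def subtype_of(self, name: str) -> str:
        return name.split(".", 1)[0]

    @property
    def manifest(self) -> dict[str, str]:
        return {name: self.subtype_of(name) for name in self.feature_names}

    def subtypes(self) -> list[str]:
        seen: list[str] = []
        for name in self.feature_names:
            st = self.subtype_of(name)
            if st not in seen:
                seen.append(st)
        return seen

    def columns_for(self, subtype: str) -> list[str]:
        return [n for n in self.feature_names if self.subtype_of(n) == subtype]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"feature column(s) missing: {missing[:5]}")
        return FeatureMatrix(self.values[names].copy(), self.labels)


def write_feature_matrix(path, fm: FeatureMatrix) -> None:
    """Write the matrix as TSV plus a sidecar ``.manifest.json``.

    Values are written with ``repr`` precision so a read back is bit-exact.
    """
    path = Path(path)
    with open(path, "w") as fh:
        cols = ["protein_id", "position"]
        if fm.labels is not None:
            cols.append("label")
        fh.write("\t".join(cols + fm.feature_names) + "\n")
        for i, (pid, pos) in enumerate(fm.values.index):
            row = [pid, str(pos)]
            if fm.labels is not None:
                row.append(str(int(fm.labels.iloc[i])))
            row.extend(repr(float(v)) for v in fm.values.iloc[i])
            fh.write("\t".join(row) + "\n")
    manifest = {
        "feature_names": fm.feature_names,
        "subtypes": fm.manifest,
        "n_sites": fm.n_sites,
    }
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "protein_id" not in df.columns or "position" not in df.columns:
        raise FormatError(f"{path}: missing site-key columns")
    labels = None
    if "label" in df.columns:
        labels = df["label"].to_numpy(dtype=int)
        df = df.drop(columns=["label"])
    index = pd.MultiIndex.from_arrays(
        [df["protein_id"], df["position"]], names=["protein_id", "position"]
    )
    values = df.drop(columns=["protein_id", "position"]).astype(float)
    values.index = index
    fm = FeatureMatrix(values, pd.Series(labels, index=index) if labels is not None else None)
    return fm
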