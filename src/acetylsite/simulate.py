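"""Synthetic dataset generator.

Emulates the statistical structure the predictor exploits, at desk scale and
with no downloads: protein sequences drawn from a realistic amino-acid
background, planted acetylated lysines with compositional bias in their
flanks (glycine enriched, glutamate/aspartate depleted, lysine enriched
upstream), and per-residue profile channels in the exact file dialects the
parsers read. The class signal in the structural channels is a depression of
the half-sphere-exposure "up" counts at acetylated lysines: HSEAU mean 8.15
at positive sites vs 9.21 elsewhere, HSEBU 9.72 vs 11.07, shared sd 3.0,
truncated at 0 — the mechanism being that a sparser upper half-sphere leaves
the epsilon-amino group accessible to the acetyltransferase. The "down"
channels carry no class signal.

Profiles are drawn independently per position with only short-range
smoothing (secondary-structure and disorder runs come from two-state/
three-state Markov chains); real within-protein correlation structure is not
modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ContractError
from .io import sample_negatives, write_fasta, write_sites
from .records import AMINO_ACIDS, ProteinRecord, ResidueProfile, SiteRecord

#: SwissProt-like background amino-acid frequencies.
BACKGROUND_FREQS = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0674, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0595, "K": 0.0585, "L": 0.0966,
    "M": 0.0242, "N": 0.0406, "P": 0.0470, "Q": 0.0393, "R": 0.0553,
    "S": 0.0656, "T": 0.0534, "V": 0.0687, "W": 0.0108, "Y": 0.0292,
}

ALL_CHANNELS = ("pssm", "hh", "ss", "struct", "diso")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic acetylation dataset.

    Defaults give 200 proteins with one acetylated lysine each and 1:1
    sampled negatives (~400 sites), lengths uniform on [60, 180].
    """

    n_proteins: int = 200
    length_min: int = 60
    length_max: int = 180
    positives_per_protein: int = 1
    negative_ratio: float = 1.0
    background: dict[str, float] = field(default_factory=lambda: dict(BACKGROUND_FREQS))
    #: log-odds boosts applied to flanking residues of positive sites
    enrichment: dict[str, float] = field(
        default_factory=lambda: {"G": 0.7, "E": -0.7, "D": -0.7}
    )
    #: additional boosts applied to upstream flanks only
    upstream_enrichment: dict[str, float] = field(default_factory=lambda: {"K": 0.5})
    enrichment_radius: int = 6
    # half-sphere exposure effect (class signal on the "up" channels)
    hseau_pos_mean: float = 8.15
    hseau_neg_mean: float = 9.21
    hsebu_pos_mean: float = 9.72
    hsebu_neg_mean: float = 11.07
    hse_sd: float = 3.0
    hsead_mean: float = 20.0
    hsebd_mean: float = 22.0
    # profile noise
    dirichlet_base: float = 0.3
    dirichlet_true: float = 6.0
    ss_stay_prob: float = 0.8
    disorder_enter_prob: float = 0.05
    disorder_exit_prob: float = 0.2
    channels: tuple[str, ...] = ALL_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.positives_per_protein < 1:
            raise ContractError("need at least one protein and one site per protein")
        if not 1 <= self.length_min <= self.length_max:
            raise ContractError("invalid length range")
        if self.positives_per_protein > self.length_min:
            raise ContractError(
                "more planted sites per protein than the shortest possible sequence"
            )
        if self.hse_sd <= 0:
            raise ContractError("hse_sd must be > 0")
        for m in (self.hseau_pos_mean, self.hseau_neg_mean,
                  self.hsebu_pos_mean, self.hsebu_neg_mean,
                  self.hsead_mean, self.hsebd_mean):
            if m < 0:
                raise ContractError("HSE means must be >= 0")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ContractError(f"unknown channel(s): {sorted(unknown)}")
        total = sum(self.background.values())
        self.background = {aa: f / total for aa, f in self.background.items()}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        return d


def _draw_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> list[str]:
    idx = rng.choice(20, size=length, p=freqs)
    return [AMINO_ACIDS[i] for i in idx]


def _markov_labels(rng, n, states, stay: float, start_p=None):
    labels = np.empty(n, dtype="U1")
    k = len(states)
    p0 = np.full(k, 1.0 / k) if start_p is None else np.asarray(start_p)
    cur = rng.choice(k, p=p0)
    for i in range(n):
        labels[i] = states[cur]
        if rng.random() >= stay:
            others = [s for s in range(k) if s != cur]
            cur = others[rng.integers(len(others))]
    return labels


def _profile_for(
    rng: np.random.Generator,
    protein: ProteinRecord,
    pos_centers: set[int],
    spec: SyntheticSpec,
) -> ResidueProfile:
    n = len(protein)
    kwargs: dict[str, np.ndarray] = {}
    bg = np.array([spec.background[aa] for aa in AMINO_ACIDS])

    def dirichlet_rows() -> np.ndarray:
        rows = np.empty((n, 20))
        for i, r in enumerate(protein.sequence):
            alpha = np.full(20, spec.dirichlet_base)
            j = AMINO_ACIDS.find(r)
            if j >= 0:
                alpha[j] += spec.dirichlet_true
            rows[i] = rng.dirichlet(alpha)
        return rows

    if "pssm" in spec.channels:
        probs = dirichlet_rows()
        with np.errstate(divide="ignore"):
            scores = np.round(2.0 * np.log2(np.maximum(probs, 1e-4) / bg))
        kwargs["pssm_scores"] = np.clip(scores, -10, 12)
        kwargs["pssm_probs"] = probs
    if "hh" in spec.channels:
        kwargs["hh_probs"] = dirichlet_rows()
    if "ss" in spec.channels:
        kwargs["ss"] = _markov_labels(
            rng, n, ["H", "E", "C"], spec.ss_stay_prob, start_p=[0.35, 0.20, 0.45]
        )
    if "struct" in spec.channels:
        kwargs["rsa"] = rng.beta(2.0, 2.0, size=n)
        kwargs["phi"] = np.clip(rng.normal(-65.0, 35.0, size=n), -180.0, 180.0)
        kwargs["psi"] = np.clip(rng.normal(-35.0, 70.0, size=n), -180.0, 180.0)
        hseau = rng.normal(spec.hseau_neg_mean, spec.hse_sd, size=n)
        hsead = rng.normal(spec.hsead_mean, spec.hse_sd, size=n)
        hsebu = rng.normal(spec.hsebu_neg_mean, spec.hse_sd, size=n)
        hsebd = rng.normal(spec.hsebd_mean, spec.hse_sd, size=n)
        for p in sorted(pos_centers):
            hseau[p - 1] = rng.normal(spec.hseau_pos_mean, spec.hse_sd)
            hsebu[p - 1] = rng.normal(spec.hsebu_pos_mean, spec.hse_sd)
        hse = np.column_stack([hseau, hsead, hsebu, hsebd])
        kwargs["hse"] = np.clip(hse, 0.0, None)
    if "diso" in spec.channels:
        disorder = np.empty(n, dtype=bool)
        cur = False
        for i in range(n):
            disorder[i] = cur
            if cur:
                cur = rng.random() >= spec.disorder_exit_prob
            else:
                cur = rng.random() < spec.disorder_enter_prob
        kwargs["disorder"] = disorder
    return ResidueProfile(length=n, **kwargs)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[SiteRecord], dict[str, ResidueProfile]]:
    """Generate (proteins, sites, profiles) per the spec, reproducibly.

    Sites are the planted positives plus 1:1 (``negative_ratio``) sampled
    non-acetylated lysines, ordered by (protein, position).
    """
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([spec.background[aa] for aa in AMINO_ACIDS])
    width = len(str(spec.n_proteins))
    proteins: list[ProteinRecord] = []
    positives: list[SiteRecord] = []
    pos_by_protein: dict[str, set[int]] = {}
    for i in range(spec.n_proteins):
        pid = f"syn{i + 1:0{width}d}"
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        if spec.positives_per_protein > length:
            raise ContractError("more planted sites than residues")
        seq = _draw_sequence(rng, length, freqs)
        centers = 1 + rng.choice(length, size=spec.positives_per_protein, replace=False)
        centers = sorted(int(c) for c in centers)
        for c in centers:
            seq[c - 1] = "K"
        # compositional bias in the flanks of planted sites
        for c in centers:
            for j in range(-spec.enrichment_radius, spec.enrichment_radius + 1):
                if j == 0:
                    continue
                p = c + j
                if not 1 <= p <= length or p in centers:
                    continue
                boost = dict.fromkeys(AMINO_ACIDS, 0.0)
                for aa, b in spec.enrichment.items():
                    boost[aa] += b
                if j < 0:
                    for aa, b in spec.upstream_enrichment.items():
                        boost[aa] += b
                w = freqs * np.exp([boost[aa] for aa in AMINO_ACIDS])
                seq[p - 1] = AMINO_ACIDS[rng.choice(20, p=w / w.sum())]
        proteins.append(ProteinRecord(pid, "".join(seq)))
        pos_by_protein[pid] = set(centers)
        positives.extend(SiteRecord(pid, c, "positive") for c in centers)
    neg_seed = int(rng.integers(2 ** 31))
    negatives = sample_negatives(proteins, positives, ratio=spec.negative_ratio, seed=neg_seed)
    sites = sorted(positives + negatives, key=lambda s: (s.protein_id, s.position))
    profiles = {
        p.id: _profile_for(rng, p, pos_by_protein[p.id], spec) for p in proteins
    }
    return proteins, sites, profiles


# ---------------------------------------------------------------------------
# writing the file dialects

def _write_pssm(path, protein: ProteinRecord, profile: ResidueProfile) -> None:
    letters = " ".join(AMINO_ACIDS)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(f"            {letters}   {letters}\n")
        for i, r in enumerate(protein.sequence):
            scores = " ".join(f"{int(v):d}" for v in profile.pssm_scores[i])
            freqs = " ".join(f"{100.0 * v:.4f}" for v in profile.pssm_probs[i])
            fh.write(f"{i + 1} {r}  {scores}  {freqs}\n")


def _write_hh(path, protein: ProteinRecord, profile: ResidueProfile) -> None:
    with open(path, "w") as fh:
        fh.write("idx\tresidue\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, r in enumerate(protein.sequence):
            vals = "\t".join(repr(float(v)) for v in profile.hh_probs[i])
            fh.write(f"{i + 1}\t{r}\t{vals}\n")


def _write_ss2(path, protein: ProteinRecord, profile: ResidueProfile) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT-style\n\n")
        for i, r in enumerate(protein.sequence):
            label = profile.ss[i]
            row = [0.1, 0.1, 0.1]
            row[{"C": 0, "H": 1, "E": 2}[label]] = 0.8
            fh.write(f"{i + 1:>4} {r} {label}  {row[0]:.3f} {row[1]:.3f} {row[2]:.3f}\n")


def _write_struct(path, protein: ProteinRecord, profile: ResidueProfile) -> None:
    with open(path, "w") as fh:
        fh.write("idx\tresidue\trsa\tphi\tpsi\thseau\thsead\thsebu\thsebd\n")
        for i, r in enumerate(protein.sequence):
            vals = [profile.rsa[i], profile.phi[i], profile.psi[i], *profile.hse[i]]
            fh.write(f"{i + 1}\t{r}\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


def _write_diso(path, protein: ProteinRecord, profile: ResidueProfile) -> None:
    with open(path, "w") as fh:
        fh.write("idx\tresidue\tdisorder\n")
        for i, r in enumerate(protein.sequence):
            fh.write(f"{i + 1}\t{r}\t{int(profile.disorder[i])}\n")


def write_dataset(
    outdir,
    spec: SyntheticSpec,
    proteins: list[ProteinRecord] | None = None,
    sites: list[SiteRecord] | None = None,
    profiles: dict[str, ResidueProfile] | None = None,
) -> Path:
    """Write a generated dataset as the documented file dialects.

    Produces ``sequences.fasta``, ``sites.tsv``, ``profiles/<id>.{pssm,hh,
    ss2,struct,diso}`` and ``manifest.json`` (the spec actually used).
    Generates the data first if not supplied. Byte-identical for a fixed spec.
    """
    if proteins is None:
        proteins, sites, profiles = generate_dataset(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "sequences.fasta", proteins)
    write_sites(outdir / "sites.tsv", sites)
    pdir = outdir / "profiles"
    pdir.mkdir(exist_ok=True)
    writers = {
        "pssm": (_write_pssm, ".pssm", "pssm_probs"),
        "hh": (_write_hh, ".hh", "hh_probs"),
        "ss": (_write_ss2, ".ss2", "ss"),
        "struct": (_write_struct, ".struct", "rsa"),
        "diso": (_write_diso, ".diso", "disorder"),
    }
    for p in proteins:
        prof = profiles[p.id]
        for chan in spec.channels:
            writer, ext, attr = writers[chan]
            if getattr(prof, attr) is not None:
                writer(pdir / f"{p.id}{ext}", p, prof)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir


# ---------------------------------------------------------------------------
# worked example

WORKED_EXAMPLE_SEQUENCE = "MSTAGKLLRVQWERTKYIPASDFGHKLCVNMQWKRTYAAG"
WORKED_EXAMPLE_SITES = (
    (6, "positive"),
    (16, "negative"),
    (26, "positive"),
    (34, "negative"),
)


def make_worked_example() -> tuple[list[ProteinRecord], list[SiteRecord], dict[str, ResidueProfile]]:
    """A miniature, fully deterministic fixture: one 40-residue protein with
    two positive and two negative lysine sites and complete profile channels."""
    protein = ProteinRecord("wex1", WORKED_EXAMPLE_SEQUENCE)
    sites = [SiteRecord("wex1", pos, label) for pos, label in WORKED_EXAMPLE_SITES]
    spec = SyntheticSpec(n_proteins=1, length_min=40, length_max=40, seed=20160516)
    rng = np.random.default_rng(spec.seed)
    pos_centers = {pos for pos, label in WORKED_EXAMPLE_SITES if label == "positive"}
    profiles = {"wex1": _profile_for(rng, protein, pos_centers, spec)}
    return [protein], sites, profiles
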