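"""Bundled amino-acid property tables (Atchley factors, default averaged
physicochemical indices, pseudo-composition scales)."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from .records import AMINO_ACIDS


@dataclass(frozen=True)
class PropertyTable:
    """A named amino-acid -> real mapping; 'X' and '-' have no value
    (contribute zero and are excluded from averages)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(f"property table {self.name}: must cover exactly the 20 amino acids")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]

    def get(self, aa: str, default: float = 0.0) -> float:
        return self.values.get(aa, default)

    def standardized(self) -> "PropertyTable":
        """Standardize over the 20 residues (population mean 0, sd 1)."""
        vals = [self.values[aa] for aa in AMINO_ACIDS]
        mean = sum(vals) / 20.0
        sd = (sum((v - mean) ** 2 for v in vals) / 20.0) ** 0.5
        return PropertyTable(
            self.name, {aa: (self.values[aa] - mean) / sd for aa in AMINO_ACIDS}
        )


def _read_table_file(filename: str) -> list[PropertyTable]:
    text = resources.files("acetylsite.data").joinpath(filename).read_text()
    header: list[str] | None = None
    columns: dict[str, dict[str, float]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            for name in header[1:]:
                columns[name] = {}
            continue
        aa = parts[0]
        for name, val in zip(header[1:], parts[1:]):
            columns[name][aa] = float(val)
    assert header is not None
    return [PropertyTable(name, columns[name]) for name in header[1:]]


@lru_cache(maxsize=None)
def atchley_factors() -> tuple[PropertyTable, ...]:
    """The five Atchley (2005) factors, in order F1..F5."""
    return tuple(_read_table_file("atchley_factors.tsv"))


@lru_cache(maxsize=None)
def default_averaged_tables() -> tuple[PropertyTable, ...]:
    """The default 10 window-averaged tables: 5 literature indices plus the
    5 Atchley factors."""
    return tuple(_read_table_file("aaindex_default.tsv")) + atchley_factors()


@lru_cache(maxsize=None)
def pseaac_scales() -> tuple[PropertyTable, ...]:
    """Hydrophobicity, hydrophilicity and side-chain mass (unstandardized)."""
    return tuple(_read_table_file("pseaac_scales.tsv"))
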