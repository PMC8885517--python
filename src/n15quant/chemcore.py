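"""Peptide elemental compositions under whole-proteome ¹⁵N metabolic labeling.

In ¹⁵N metabolic labeling (SILIA) every nitrogen a peptide acquires during
growth — backbone and side chain — is subject to enrichment, while nitrogens
introduced chemically after extraction (the carbamidomethyl reagent nitrogen)
always carry natural abundance. Compositions therefore track the total atom
counts *and* the split of nitrogen into labeled and unlabeled pools; the
heavy/light "channel" of an ion decides whether the labeled pool is read at
the ¹⁵N or the natural ¹⁴N mass.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ELEMENTS",
    "ElementalComposition",
    "PeptideIon",
    "Isotope",
    "residue_nitrogens",
    "residue_formula",
    "modification_delta",
    "build_composition",
    "monoisotopic_mass",
    "mz",
    "counterpart",
    "parse_modifications",
    "format_modifications",
    "MASS_ELECTRON",
    "MASS_PROTON",
    "DELTA_15N",
]

MASS_ELECTRON = 0.00054857990907

LIGHT = "light"
HEAVY = "heavy"


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float
    abundance: float


def _load_elements() -> dict[str, tuple[Isotope, ...]]:
    table: dict[str, list[Isotope]] = {}
    text = resources.files("n15quant.data").joinpath("elements.tsv").read_text()
    for row in _tsv_rows(text):
        table.setdefault(row["element"], []).append(
            Isotope(int(row["mass_number"]), float(row["exact_mass"]), float(row["abundance"]))
        )
    return {el: tuple(sorted(iso, key=lambda i: i.mass_number)) for el, iso in table.items()}


def _tsv_rows(text: str) -> Iterable[dict[str, str]]:
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    yield from reader


#: element -> isotopes sorted by mass number; index 0 is the lightest.
ELEMENTS: dict[str, tuple[Isotope, ...]] = _load_elements()

MASS_PROTON = ELEMENTS["H"][0].mass - MASS_ELECTRON

#: m(15N) - m(14N), the mass shift contributed by each labeled nitrogen.
DELTA_15N = ELEMENTS["N"][1].mass - ELEMENTS["N"][0].mass


def _load_residues() -> dict[str, dict[str, int]]:
    text = resources.files("n15quant.data").joinpath("residues.tsv").read_text()
    out = {}
    for row in _tsv_rows(text):
        out[row["code"]] = {el: int(row[el]) for el in ("C", "H", "N", "O", "S")}
    return out


def _load_modifications() -> dict[str, tuple[dict[str, int], int]]:
    text = resources.files("n15quant.data").joinpath("modifications.tsv").read_text()
    out = {}
    for row in _tsv_rows(text):
        delta = {el: int(row["d" + el]) for el in ("C", "H", "N", "O", "S")}
        out[row["name"]] = (delta, int(row["d_labeled_N"]))
    return out


RESIDUES = _load_residues()
MODIFICATIONS = _load_modifications()

# Accepted spelling variants for the pyro-glutamate modification.
_MOD_ALIASES = {
    "Gln→pyro-Glu": "Gln->pyro-Glu",
    "pyro-Glu": "Gln->pyro-Glu",
}

_WATER = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}


class UnknownResidueError(ValueError):
    pass


class UnknownModificationError(ValueError):
    pass


def residue_nitrogens(amino_acid: str) -> int:
    """Number of nitrogen atoms in a residue = its ¹⁵N label multiplicity.

    Arginine carries four nitrogens, histidine three, Lys/Asn/Gln/Trp two and
    every other standard residue one (the backbone amide).
    """
    try:
        return RESIDUES[amino_acid]["N"]
    except KeyError:
        raise UnknownResidueError(
            f"unknown residue {amino_acid!r}; expected one of the 20 standard codes"
        ) from None


def residue_formula(amino_acid: str) -> dict[str, int]:
    """Monoisotopic residue formula (amino acid minus water) as element counts."""
    try:
        return dict(RESIDUES[amino_acid])
    except KeyError:
        raise UnknownResidueError(
            f"unknown residue {amino_acid!r}; expected one of the 20 standard codes"
        ) from None


def modification_delta(name: str) -> tuple[dict[str, int], int]:
    """Formula delta and labeled-nitrogen delta for a (possibly combined) mod name."""
    total = {el: 0 for el in ("C", "H", "N", "O", "S")}
    labeled = 0
    for part in name.split("+"):
        part = part.strip()
        part = _MOD_ALIASES.get(part, part)
        if part not in MODIFICATIONS:
            raise UnknownModificationError(
                f"unknown modification {part!r}; supported: {sorted(MODIFICATIONS)}"
            )
        delta, d_lab = MODIFICATIONS[part]
        for el, v in delta.items():
            total[el] += v
        labeled += d_lab
    return total, labeled


@dataclass(frozen=True)
class ElementalComposition:
    """Element counts with the labeled/unlabeled nitrogen split.

    ``counts`` includes charge-carrier protons in the hydrogen count (so the
    printed formula of an [M+H]+ ion shows them), while ``charge_protons``
    records how many of those hydrogens are bare protons. ``n_labeled_N`` +
    ``n_unlabeled_N`` always equals ``counts["N"]``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    n_labeled_N: int = 0
    n_unlabeled_N: int = 0
    charge_protons: int = 0

    def __post_init__(self):
        counts = {el: int(v) for el, v in self.counts.items() if v != 0}
        object.__setattr__(self, "counts", counts)
        for el, v in counts.items():
            if v < 0:
                raise ValueError(f"negative atom count for {el}: {v}")
            if el not in ELEMENTS:
                raise ValueError(f"element {el!r} has no isotope data")
        if self.n_labeled_N < 0 or self.n_unlabeled_N < 0:
            raise ValueError("nitrogen pool counts must be non-negative")
        if self.n_labeled_N + self.n_unlabeled_N != counts.get("N", 0):
            raise ValueError(
                f"nitrogen split {self.n_labeled_N}+{self.n_unlabeled_N} "
                f"!= total N {counts.get('N', 0)}"
            )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self.counts)
        for el, v in other.counts.items():
            counts[el] = counts.get(el, 0) + v
        return ElementalComposition(
            counts,
            self.n_labeled_N + other.n_labeled_N,
            self.n_unlabeled_N + other.n_unlabeled_N,
            self.charge_protons + other.charge_protons,
        )

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self.counts)
        for el, v in other.counts.items():
            counts[el] = counts.get(el, 0) - v
        return ElementalComposition(
            counts,
            self.n_labeled_N - other.n_labeled_N,
            self.n_unlabeled_N - other.n_unlabeled_N,
            self.charge_protons - other.charge_protons,
        )

    def hill_formula(self) -> str:
        order = ["C", "H"] + sorted(el for el in self.counts if el not in ("C", "H"))
        return " ".join(f"{el}{self.counts[el]}" for el in order if self.counts.get(el, 0))


@dataclass(frozen=True)
class PeptideIon:
    """A peptide ion: sequence, modifications, charge and labeling channel."""

    sequence: str
    modifications: tuple[tuple[object, str], ...] = ()
    charge: int = 1
    channel: str = LIGHT

    def __post_init__(self):
        if self.charge < 0:
            raise ValueError("charge must be >= 0")
        if self.channel not in (LIGHT, HEAVY):
            raise ValueError(f"channel must be 'light' or 'heavy', got {self.channel!r}")
        mods = tuple((pos, name) for pos, name in self.modifications)
        object.__setattr__(self, "modifications", mods)
        n = len(self.sequence)
        for pos, _name in mods:
            if pos in ("Nterm", "Cterm"):
                continue
            if not (isinstance(pos, int) and 1 <= pos <= n):
                raise ValueError(
                    f"modification position {pos!r} outside 1..{n} (or 'Nterm'/'Cterm')"
                )


def parse_modifications(spec: str) -> tuple[tuple[object, str], ...]:
    """Parse ``name@position`` strings: ``Carbamidomethyl@6;Acetyl@Nterm``.

    Positions are 1-based; ``Nterm``/``Cterm`` address the termini. An empty
    string means no modifications.
    """
    spec = spec.strip()
    if not spec:
        return ()
    mods = []
    for item in spec.split(";"):
        item = item.strip()
        if not item:
            continue
        if "@" not in item:
            raise ValueError(f"modification {item!r} lacks '@position'")
        name, _, pos = item.rpartition("@")
        pos = pos.strip()
        mods.append((pos if pos in ("Nterm", "Cterm") else int(pos), name.strip()))
    return tuple(mods)


def format_modifications(mods: Iterable[tuple[object, str]]) -> str:
    return ";".join(f"{name}@{pos}" for pos, name in mods)


def build_composition(ion: PeptideIon) -> ElementalComposition:
    """Elemental composition of a peptide ion.

    Sum of residue formulas + one water + modification deltas + one proton per
    charge. For the heavy channel every residue-derived nitrogen goes into the
    labeled pool; reagent nitrogens (carbamidomethyl) stay unlabeled. For the
    light channel the labeled pool is empty — labeling changes isotopes, never
    the element counts.
    """
    counts = dict(_WATER)
    residue_n = 0
    for aa in ion.sequence:
        f = residue_formula(aa)
        for el, v in f.items():
            counts[el] = counts.get(el, 0) + v
        residue_n += f["N"]
    unlabeled_n = 0
    for _pos, name in ion.modifications:
        delta, d_lab = modification_delta(name)
        for el, v in delta.items():
            counts[el] = counts.get(el, 0) + v
        residue_n += d_lab
        unlabeled_n += delta["N"] - d_lab
    counts["H"] = counts.get("H", 0) + ion.charge
    if ion.channel == HEAVY:
        labeled, unlabeled = residue_n, unlabeled_n
    else:
        labeled, unlabeled = 0, residue_n + unlabeled_n
    return ElementalComposition(counts, labeled, unlabeled, charge_protons=ion.charge)


def monoisotopic_mass(comp: ElementalComposition, channel: str = HEAVY) -> float:
    """Monoisotopic mass in Da: every atom at its lightest isotope, except
    labeled nitrogens which sit at ¹⁵N when ``channel='heavy'``.

    Charge-carrier protons weigh m(¹H) − m(e). For a charged composition this
    is the ion mass (so m/z = mass / z); for ``charge_protons == 0`` it is the
    neutral mass.
    """
    mass = 0.0
    for el, n in comp.counts.items():
        mass += n * ELEMENTS[el][0].mass
    if channel == HEAVY:
        mass += comp.n_labeled_N * DELTA_15N
    mass -= comp.charge_protons * MASS_ELECTRON
    return mass


def mz(comp: ElementalComposition, channel: str = HEAVY) -> float:
    """m/z of the monoisotopic peak; requires ``charge_protons >= 1``."""
    z = comp.charge_protons
    if z < 1:
        raise ValueError("m/z undefined for a neutral composition")
    return monoisotopic_mass(comp, channel) / z


def counterpart(ion: PeptideIon) -> PeptideIon:
    """The other channel's ion: same sequence/modifications/charge, channel flipped."""
    return replace(ion, channel=HEAVY if ion.channel == LIGHT else LIGHT)
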