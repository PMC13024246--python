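"""Parsing and structural annotation of lipid shorthand names.

The module covers the five lipid classes quantified by choline-centric
targeted plasma panels -- acylcarnitines (CAR), diacyl phosphatidylcholines
(PC), ether-linked phosphatidylcholines (PC O-), lysophosphatidylcholines
(LPC) and sphingomyelins (SM) -- written in LIPID MAPS shorthand, e.g.
``"CAR 12:0"``, ``"PC O-34:2"`` or ``"SM 18:1;O2/26:0"``.

Parsed species carry their acyl-chain composition and are mapped onto the
LIPID MAPS taxonomy (category / subcategory / subclass codes), species-level
structural totals (Total FA: cumulative carbons, double bonds and oxygen
modifiers over all esterified chains), a saturation class, and a set of
qualitative membrane-biophysics labels (bilayer thickness, lateral
diffusion, intrinsic curvature, functional role, cellular component)
assigned from a packaged, versioned rule table keyed on headgroup class and
chain steric properties.

Two shorthand dialects seen in practice are normalised on input: the
Unicode minus in ``"PC O−34:2"`` becomes an ASCII hyphen, and a bare
numeric oxygen suffix (``"PC O-36:4;2.0"``) is read as ``;O2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AcylChain",
    "LipidStructure",
    "StructuralAnnotation",
    "BiophysAnnotation",
    "BiophysRuleTable",
    "LipidParseError",
    "UnsupportedClassError",
    "AnnotationGapError",
    "parse_lipid_name",
    "format_lipid",
    "total_fa",
    "classify",
    "saturation_class",
    "annotate_biophysics",
    "annotate_table",
    "SUPPORTED_CLASSES",
]


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


class UnsupportedClassError(LipidParseError):
    """Raised when the class prefix of a name is not one of the supported five."""


class AnnotationGapError(KeyError):
    """Raised when a species falls outside the coverage of a biophysics rule table."""


#: Class prefixes ordered longest-first so that "PC O-" wins over "PC".
SUPPORTED_CLASSES = ("PC O-", "CAR", "LPC", "PC", "SM")

# LIPID MAPS taxonomy: class -> (category, subcategory, subclass).
# FA0707 acyl carnitines; GP0101 diacyl-GPC; GP0102 1-alkyl,2-acyl-GPC;
# GP0105 monoacyl-GPC (lyso); SP0301 sphingomyelins.
_CLASS_TAXONOMY: Mapping[str, tuple[str, str, str]] = {
    "CAR": ("FA", "FA07", "FA0707"),
    "PC": ("GP", "GP01", "GP0101"),
    "PC O-": ("GP", "GP01", "GP0102"),
    "LPC": ("GP", "GP01", "GP0105"),
    "SM": ("SP", "SP03", "SP0301"),
}

_SINGLE_CHAIN_CLASSES = frozenset({"CAR", "LPC"})

# Unicode dash variants occasionally used for the ether-bond hyphen.
_DASH_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})

_CHAIN_RE = re.compile(r"^(\d+):(\d+)$")


@dataclass(frozen=True)
class AcylChain:
    """One (possibly aggregate) acyl/alkyl chain: carbons:double_bonds;O<k>."""

    carbons: int
    double_bonds: int
    oxygens: int = 0
    ether_linked: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain needs >= 1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.oxygens < 0:
            raise ValueError("chain counts must be non-negative")
        if self.double_bonds > self.carbons:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible on {self.carbons} carbons"
            )

    def label(self) -> str:
        return _fa_label(self.carbons, self.double_bonds, self.oxygens)


@dataclass(frozen=True)
class LipidStructure:
    """A parsed lipid species: class plus one aggregate or two resolved chains."""

    raw_name: str
    lipid_class: str
    chains: tuple[AcylChain, ...]

    @property
    def category(self) -> str:
        return _CLASS_TAXONOMY[self.lipid_class][0]

    @property
    def subcategory_code(self) -> str:
        return _CLASS_TAXONOMY[self.lipid_class][1]

    @property
    def subclass_code(self) -> str:
        return _CLASS_TAXONOMY[self.lipid_class][2]

    @property
    def ether_bond(self) -> bool:
        return any(c.ether_linked for c in self.chains)

    @property
    def canonical_name(self) -> str:
        return format_lipid(self)


@dataclass(frozen=True)
class StructuralAnnotation:
    """Species-level Total FA summary: sums over all esterified chains."""

    total_c: int
    total_db: int
    total_oh: int
    ether_bond: bool
    saturation_class: str
    total_fa_label: str


@dataclass(frozen=True)
class BiophysAnnotation:
    """Qualitative membrane-biophysics labels assigned by rule lookup."""

    bilayer_thickness: str
    lateral_diffusion: str
    intrinsic_curvature: str
    function: str
    cellular_component: str


def _fa_label(c: int, db: int, oh: int) -> str:
    if oh == 0:
        return f"{c}:{db}"
    if oh == 1:
        return f"{c}:{db};O"
    return f"{c}:{db};O{oh}"


def _parse_oxygen_modifier(token: str, name: str) -> int:
    """Parse the ';<mod>' suffix of a chain into an oxygen count.

    Accepts 'O' (one oxygen), 'O<k>', and the bare numeric dialect '2.0'
    (normalised to two oxygens).
    """
    if token.startswith("O"):
        rest = token[1:]
        if rest == "":
            return 1
        if rest.isdigit():
            return int(rest)
        raise LipidParseError(f"cannot parse oxygen modifier ';{token}' in {name!r}")
    # dialect: ';2.0' meaning two oxygen modifiers
    try:
        value = float(token)
    except ValueError:
        raise LipidParseError(
            f"cannot parse chain modifier ';{token}' in {name!r}"
        ) from None
    if value != int(value) or value < 0:
        raise LipidParseError(f"cannot parse chain modifier ';{token}' in {name!r}")
    return int(value)


def _parse_chain(token: str, name: str, ether_linked: bool) -> AcylChain:
    parts = token.split(";")
    m = _CHAIN_RE.match(parts[0])
    if m is None:
        raise LipidParseError(f"cannot parse chain token {token!r} in {name!r}")
    oxygens = sum(_parse_oxygen_modifier(p, name) for p in parts[1:])
    try:
        return AcylChain(
            carbons=int(m.group(1)),
            double_bonds=int(m.group(2)),
            oxygens=oxygens,
            ether_linked=ether_linked,
        )
    except ValueError as exc:
        raise LipidParseError(f"invalid chain {token!r} in {name!r}: {exc}") from None


def parse_lipid_name(name: str) -> LipidStructure:
    """Parse a shorthand lipid name into a :class:`LipidStructure`.

    Species-level names ("PC 36:0") yield one aggregate chain; molecular
    species names with "/" ("SM 18:1;O2/26:0") yield per-chain resolution.

    Raises
    ------
    UnsupportedClassError
        If the class prefix is not one of CAR, PC, PC O-, LPC, SM.
    LipidParseError
        If any chain token cannot be parsed.
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError("lipid name must be non-empty text")
    normalised = name.translate(_DASH_VARIANTS).strip()

    lipid_class = None
    for prefix in SUPPORTED_CLASSES:
        if normalised.startswith(prefix):
            lipid_class = prefix
            remainder = normalised[len(prefix):].lstrip()
            break
    if lipid_class is None:
        head = normalised.split(" ")[0]
        raise UnsupportedClassError(
            f"unsupported lipid class prefix {head!r} in {name!r}; "
            f"supported classes: {', '.join(sorted(SUPPORTED_CLASSES))}"
        )
    if not remainder:
        raise LipidParseError(f"missing chain composition in {name!r}")

    tokens = remainder.split("/")
    chains = tuple(
        _parse_chain(tok, name, ether_linked=(lipid_class == "PC O-" and i == 0))
        for i, tok in enumerate(tokens)
    )

    if lipid_class in _SINGLE_CHAIN_CLASSES and len(chains) != 1:
        raise LipidParseError(
            f"{lipid_class} species carry exactly one chain, got {len(chains)} in {name!r}"
        )
    if len(chains) > 2:
        raise LipidParseError(f"more than two chains in {name!r}")
    return LipidStructure(raw_name=name, lipid_class=lipid_class, chains=chains)


def format_lipid(s: LipidStructure) -> str:
    """Canonical shorthand for a parsed species (dialects normalised)."""
    chains = "/".join(c.label() for c in s.chains)
    if s.lipid_class == "PC O-":
        return f"PC O-{chains}"
    return f"{s.lipid_class} {chains}"


def saturation_class(total_db: int) -> str:
    """Saturation category from the species-level double-bond total."""
    if total_db < 0:
        raise ValueError("double-bond count must be non-negative")
    if total_db == 0:
        return "saturated"
    if total_db == 1:
        return "monounsaturated"
    if total_db == 2:
        return "diunsaturated"
    return "polyunsaturated"


def total_fa(s: LipidStructure) -> StructuralAnnotation:
    """Species-level Total FA: sums of carbons, double bonds and oxygens.

    Totals run over all esterified acyl chains of the intact lipid; they do
    not describe free fatty acids.
    """
    c = sum(ch.carbons for ch in s.chains)
    db = sum(ch.double_bonds for ch in s.chains)
    oh = sum(ch.oxygens for ch in s.chains)
    return StructuralAnnotation(
        total_c=c,
        total_db=db,
        total_oh=oh,
        ether_bond=s.ether_bond,
        saturation_class=saturation_class(db),
        total_fa_label=_fa_label(c, db, oh),
    )


def classify(s: LipidStructure) -> tuple[str, str, str]:
    """LIPID MAPS (category, subcategory, subclass) codes for a species."""
    return _CLASS_TAXONOMY[s.lipid_class]


@dataclass(frozen=True)
class _BiophysRule:
    lipid_class: str
    c_min: int | None
    c_max: int | None
    db_min: int | None
    db_max: int | None
    labels: BiophysAnnotation
    provenance: str = ""

    def matches(self, lipid_class: str, total_c: int, total_db: int) -> bool:
        if lipid_class != self.lipid_class:
            return False
        if self.c_min is not None and total_c < self.c_min:
            return False
        if self.c_max is not None and total_c > self.c_max:
            return False
        if self.db_min is not None and total_db < self.db_min:
            return False
        if self.db_max is not None and total_db > self.db_max:
            return False
        return True


@dataclass
class BiophysRuleTable:
    """Ordered lookup of qualitative biophysics labels; first match wins.

    Rules are keyed on (headgroup class, total-carbon range, double-bond
    range). The packaged default table encodes coarse empirical headgroup
    relationships (lyso species promote positive curvature, ether bonds
    increase rigidity and lower lateral mobility, long saturated chains
    thicken bilayers, sphingomyelins partition to ordered plasma-membrane
    domains); its carbon/double-bond bin edges are approximate and are
    documented row by row in the shipped file.
    """

    rules: list[_BiophysRule] = field(default_factory=list)
    version: str = "unversioned"

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, version: str = "unversioned") -> "BiophysRuleTable":
        def _bound(v) -> int | None:
            if pd.isna(v) or v == "*" or v == "":
                return None
            return int(v)

        rules = []
        for _, row in frame.iterrows():
            rules.append(
                _BiophysRule(
                    lipid_class=row["lipid_class"],
                    c_min=_bound(row["c_min"]),
                    c_max=_bound(row["c_max"]),
                    db_min=_bound(row["db_min"]),
                    db_max=_bound(row["db_max"]),
                    labels=BiophysAnnotation(
                        bilayer_thickness=row["bilayer_thickness"],
                        lateral_diffusion=row["lateral_diffusion"],
                        intrinsic_curvature=row["intrinsic_curvature"],
                        function=row["function"],
                        cellular_component=row["cellular_component"],
                    ),
                    provenance=str(row.get("provenance", "")),
                )
            )
        return cls(rules=rules, version=version)

    @classmethod
    def default(cls) -> "BiophysRuleTable":
        path = resources.files("lipidlens.data").joinpath("biophys_rules.tsv")
        with resources.as_file(path) as p:
            frame = pd.read_csv(p, sep="\t", comment="#", dtype=str)
        return cls.from_frame(frame, version="default-1")

    def lookup(self, lipid_class: str, total_c: int, total_db: int) -> BiophysAnnotation:
        for rule in self.rules:
            if rule.matches(lipid_class, total_c, total_db):
                return rule.labels
        raise AnnotationGapError(
            f"no biophysics rule covers (class={lipid_class!r}, "
            f"total_c={total_c}, total_db={total_db}) in rule table {self.version!r}"
        )


def annotate_biophysics(s: LipidStructure, rules: BiophysRuleTable) -> BiophysAnnotation:
    """Assign the five qualitative biophysics labels by table lookup."""
    ann = total_fa(s)
    return rules.lookup(s.lipid_class, ann.total_c, ann.total_db)


def annotate_table(
    names: Iterable[str] | Sequence[str],
    rules: BiophysRuleTable | None = None,
) -> pd.DataFrame:
    """Full annotation table for a list of shorthand names.

    One row per species with structural, taxonomic and biophysical columns;
    the row index is the raw input name. This is the per-species annotation
    consumed by stratified differential abundance.
    """
    if rules is None:
        rules = BiophysRuleTable.default()
    records = []
    for name in names:
        s = parse_lipid_name(name)
        ann = total_fa(s)
        bio = annotate_biophysics(s, rules)
        records.append(
            {
                "raw_name": name,
                "canonical_name": s.canonical_name,
                "lipid_class": s.lipid_class,
                "category": s.category,
                "subcategory": s.subcategory_code,
                "subclass": s.subclass_code,
                "total_c": ann.total_c,
                "total_db": ann.total_db,
                "total_oh": ann.total_oh,
                "total_fa_label": ann.total_fa_label,
                "ether_bond": ann.ether_bond,
                "saturation_class": ann.saturation_class,
                "bilayer_thickness": bio.bilayer_thickness,
                "lateral_diffusion": bio.lateral_diffusion,
                "intrinsic_curvature": bio.intrinsic_curvature,
                "function": bio.function,
                "cellular_component": bio.cellular_component,
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame.index = frame["raw_name"]
    frame.index.name = "species"
    return frame
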