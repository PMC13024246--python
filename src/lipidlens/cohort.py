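"""Synthetic case-control lipidomic cohorts.

Generates abundance tables with the statistical structure the downstream
analysis assumes: a fixed species panel, log-normal within-group
concentrations, and class-structured log2 group shifts. The default design
emulates a treatment-naive CLL vs healthy-control plasma study measured on
a choline-centric targeted panel: 124 species over five classes (PC
dominant, then LPC and SM, with PC O- and CAR as minority fractions), 30
cases against 11 controls.

Model: the log2 abundance of species j in sample i is

    baseline_j + shift_j * 1[i is case] + eps_ij,   eps_ij ~ N(0, sigma^2)

exponentiated back to a linear concentration scale. The default log-scale
noise sigma = 0.5 makes a log2 shift of 1 a standardized effect of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .nomenclature import parse_lipid_name

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "AbundanceTable",
    "default_panel",
    "default_baselines",
    "cll_like_effects",
    "null_effects",
    "generate",
    "ENRICHED_SPECIES",
    "DEPLETED_SPECIES",
    "STABLE_DISCRIMINATORS",
]

#: Species enriched in cases under the emulated disease pattern, ordered by
#: increasing fold change; CAR 12:0 carries the largest shift.
ENRICHED_SPECIES: tuple[str, ...] = (
    "SM 18:1;O2/22:2;O",
    "SM 18:1;O2/26:0",
    "PC O-40:1",
    "PC O-38:5",
    "PC 38:0",
    "PC O-36:3",
    "PC O-36:5",
    "PC O-34:2",
    "LPC 18:0",
    "PC O-36:4;2.0",
    "LPC 17:0",
    "PC O-38:6",
    "PC O-34:3",
    "PC 34:4",
    "PC 36:6",
    "LPC 18:2",
    "PC 36:0",
    "CAR 12:0",
)

#: Species depleted in cases (higher in controls).
DEPLETED_SPECIES: tuple[str, ...] = ("PC 34:1", "PC 26:0")

#: The seven species used as the stable-discriminator recovery target.
STABLE_DISCRIMINATORS: tuple[str, ...] = (
    "CAR 12:0",
    "LPC 18:0",
    "LPC 16:0",
    "CAR 10:0",
    "PC O-36:5",
    "LPC 18:1",
    "LPC 18:2",
)


def _load_panel_frame() -> pd.DataFrame:
    path = resources.files("lipidlens.data").joinpath("panel.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def default_panel() -> list[str]:
    """The packaged 124-species panel (names in shorthand, all parseable)."""
    return _load_panel_frame()["species"].tolist()


def default_baselines() -> dict[str, float]:
    """Per-species log2 median control abundance from the packaged panel."""
    frame = _load_panel_frame()
    return dict(zip(frame["species"], frame["baseline_log2"]))


@dataclass(frozen=True)
class CohortDesign:
    """Sample sizes, panel and seed for one synthetic cohort."""

    n_case: int = 30
    n_control: int = 11
    panel: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        panel = tuple(self.panel) if self.panel else tuple(default_panel())
        if len(set(panel)) != len(panel):
            raise ValueError("panel species names must be unique")
        for name in panel:
            parse_lipid_name(name)  # raises on unparseable entries
        object.__setattr__(self, "panel", panel)


@dataclass(frozen=True)
class EffectSpec:
    """Log2 group shifts (case minus control), noise level and baselines.

    ``class_rho`` switches on an equicorrelated log-scale noise block per
    lipid class (0 = independent species, the default): within a class the
    noise of any two species has correlation ``class_rho``.
    """

    shifts: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.5
    baseline: Mapping[str, float] = field(default_factory=dict)
    class_rho: float = 0.0

    def __post_init__(self) -> None:
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be positive")
        if not 0 <= self.class_rho < 1:
            raise ValueError("class_rho must lie in [0, 1)")
        for name, value in self.shifts.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite shift for {name!r}")

    def shift_for(self, species: str) -> float:
        return float(self.shifts.get(species, 0.0))


def null_effects(noise_sigma: float = 0.5) -> EffectSpec:
    """No group difference on any species."""
    return EffectSpec(shifts={}, noise_sigma=noise_sigma)


def cll_like_effects(
    magnitude: float = 1.0,
    top_magnitude: float = 2.0,
    noise_sigma: float = 0.5,
) -> EffectSpec:
    """Effect pattern emulating the reference disease signature.

    Positive shifts of ``magnitude`` on the 18 enriched species (with
    ``top_magnitude`` on CAR 12:0, the most dysregulated species), negative
    shifts of ``magnitude`` on the two depleted PC species, zero elsewhere.
    """
    shifts = {name: magnitude for name in ENRICHED_SPECIES}
    shifts["CAR 12:0"] = top_magnitude
    for name in DEPLETED_SPECIES:
        shifts[name] = -magnitude
    return EffectSpec(shifts=shifts, noise_sigma=noise_sigma)


@dataclass
class AbundanceTable:
    """Samples x species concentration matrix with per-sample group labels."""

    abundance: pd.DataFrame  # index sample_id, columns species, linear scale
    groups: pd.Series  # index sample_id, values in {"case", "control"}

    def __post_init__(self) -> None:
        if not self.abundance.index.is_unique:
            raise ValueError("duplicate sample identifiers")
        if not self.abundance.columns.is_unique:
            raise ValueError("duplicate species identifiers")
        if not self.groups.index.equals(self.abundance.index):
            self.groups = self.groups.reindex(self.abundance.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples missing group labels: {missing}")
        if (self.abundance.values < 0).any():
            raise ValueError("negative concentrations are not allowed")

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def group_values(self, species: str, group: str) -> np.ndarray:
        mask = (self.groups == group).values
        return self.abundance[species].values[mask]

    def case_matrix(self) -> pd.DataFrame:
        return self.abundance.loc[self.groups == "case"]

    def control_matrix(self) -> pd.DataFrame:
        return self.abundance.loc[self.groups == "control"]

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        """Write abundance.csv (first column sample_id) and metadata.csv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        abundance_path = directory / "abundance.csv"
        metadata_path = directory / "metadata.csv"
        self.abundance.rename_axis("sample_id").to_csv(abundance_path)
        self.groups.rename("group").rename_axis("sample_id").to_csv(metadata_path)
        return abundance_path, metadata_path

    @classmethod
    def read(cls, abundance_path: str | Path, metadata_path: str | Path) -> "AbundanceTable":
        abundance = pd.read_csv(abundance_path, index_col="sample_id")
        metadata = pd.read_csv(metadata_path, index_col="sample_id")
        return cls(abundance=abundance, groups=metadata["group"])


def generate(design: CohortDesign, effects: EffectSpec) -> AbundanceTable:
    """Draw one cohort from the log-normal group-shift model.

    Fully reproducible for a given (design, effects): all randomness comes
    from ``design.seed``.
    """
    unknown = set(effects.shifts) - set(design.panel)
    if unknown:
        raise KeyError(f"effects reference species outside the panel: {sorted(unknown)}")
    baseline = dict(effects.baseline) if effects.baseline else default_baselines()
    missing = set(design.panel) - set(baseline)
    if missing:
        raise KeyError(f"no baseline for panel species: {sorted(missing)}")

    rng = np.random.default_rng(design.seed)
    n = design.n_case + design.n_control
    p = len(design.panel)
    base = np.array([baseline[s] for s in design.panel])
    shift = np.array([effects.shift_for(s) for s in design.panel])
    is_case = np.concatenate(
        [np.ones(design.n_case, dtype=bool), np.zeros(design.n_control, dtype=bool)]
    )
    noise = rng.normal(0.0, 1.0, size=(n, p))
    if effects.class_rho > 0:
        # equicorrelated block per class: eps = sqrt(rho) z_class + sqrt(1-rho) z_ij
        classes = [parse_lipid_name(s).lipid_class for s in design.panel]
        class_names = sorted(set(classes))
        shared = rng.normal(0.0, 1.0, size=(n, len(class_names)))
        col = np.array([class_names.index(c) for c in classes])
        noise = (
            np.sqrt(effects.class_rho) * shared[:, col]
            + np.sqrt(1.0 - effects.class_rho) * noise
        )
    log2_values = (
        base[None, :]
        + np.where(is_case[:, None], shift[None, :], 0.0)
        + effects.noise_sigma * noise
    )
    values = np.exp2(log2_values)
    sample_ids = [f"CASE_{i + 1:02d}" for i in range(design.n_case)] + [
        f"CTRL_{i + 1:02d}" for i in range(design.n_control)
    ]
    abundance = pd.DataFrame(values, index=sample_ids, columns=list(design.panel))
    abundance.index.name = "sample_id"
    groups = pd.Series(
        np.where(is_case, "case", "control"), index=abundance.index, name="group"
    )
    return AbundanceTable(abundance=abundance, groups=groups)
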