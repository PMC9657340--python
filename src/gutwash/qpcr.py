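"""Absolute quantification of a tracked organism from qPCR measurements.

Converts measured DNA mass to genome copies through the genome-mass formula

    copies = ng DNA * N_A / (genome_length_bp * 660 g/mol/bp * 1e9 ng/g)

treats one chromosomal copy as one cell, and produces baseline-adjusted
concentration series: the endogenous pre-dose level of the organism is
estimated and subtracted from post-dose measurements so that the remainder
reflects the dosed cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenomeModel",
    "LGG_GENOME",
    "QpcrSample",
    "QpcrSeries",
    "copies_from_mass",
    "cells_from_copies",
    "estimate_baseline",
    "baseline_subtract",
    "series_from_frame",
]


@dataclass(frozen=True)
class GenomeModel:
    """Constants converting DNA mass to genome copies.

    Defaults are for the Lacticaseibacillus rhamnosus GG chromosome:
    3,010,111 bp at a mean 660 g/mol per base pair.
    """

    genome_length_bp: float = 3_010_111.0
    mean_bp_mass: float = 660.0  # g/mol per bp
    avogadro: float = 6.0221e23  # molecules/mol

    def __post_init__(self) -> None:
        if min(self.genome_length_bp, self.mean_bp_mass, self.avogadro) <= 0:
            raise ValueError("all genome-model constants must be positive")

    @property
    def genome_mass_g(self) -> float:
        """Mass of a single genome in grams (~3.30 fg for the default)."""
        return self.genome_length_bp * self.mean_bp_mass / self.avogadro


LGG_GENOME = GenomeModel()


def copies_from_mass(mass_ng: float, genome: GenomeModel = LGG_GENOME) -> float:
    """Genome copies in ``mass_ng`` nanograms of DNA.  Linear in mass."""
    if mass_ng < 0:
        raise ValueError(f"mass_ng must be >= 0, got {mass_ng}")
    return mass_ng * genome.avogadro / (genome.genome_length_bp * genome.mean_bp_mass * 1e9)


def cells_from_copies(copies: float, copies_per_cell: float = 1.0) -> float:
    """Cells corresponding to a copy count (single chromosomal target by default)."""
    if copies < 0 or copies_per_cell <= 0:
        raise ValueError("copies must be >= 0 and copies_per_cell > 0")
    return copies / copies_per_cell


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR measurement of the tracked organism."""

    sample_id: str
    bioreplicate: str
    compartment: str
    phase: str  # "lumen" | "mucin"
    cycle: int  # feeding-cycle index; negative = pre-dose
    cells_per_ml: float | None = None
    dna_mass_ng: float | None = None
    copies: float | None = None

    def __post_init__(self) -> None:
        present = [v for v in (self.cells_per_ml, self.dna_mass_ng, self.copies) if v is not None]
        if not present:
            raise ValueError("at least one of cells_per_ml, dna_mass_ng, copies required")
        if any(v < 0 for v in present):
            raise ValueError("measurements must be >= 0")

    def resolve_cells(self, genome: GenomeModel = LGG_GENOME, copies_per_cell: float = 1.0) -> float:
        """Concentration in cells/mL, deriving it from copies or mass if needed."""
        if self.cells_per_ml is not None:
            return self.cells_per_ml
        if self.copies is not None:
            return cells_from_copies(self.copies, copies_per_cell)
        return cells_from_copies(copies_from_mass(self.dna_mass_ng, genome), copies_per_cell)


@dataclass
class QpcrSeries:
    """Measurements for one (bioreplicate, compartment, phase), cycle-ordered."""

    bioreplicate: str
    compartment: str
    phase: str
    cycles: np.ndarray
    cells_per_ml: np.ndarray
    baseline: float | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.cells_per_ml = np.asarray(self.cells_per_ml, dtype=float)
        if self.cycles.shape != self.cells_per_ml.shape:
            raise ValueError("cycles and cells_per_ml must align")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")
        if np.any(self.cells_per_ml < 0):
            raise ValueError("concentrations must be >= 0")
        if self.baseline is not None and self.baseline < 0:
            raise ValueError("baseline must be >= 0")

    def pre_dose_mask(self, dose_cycle: int = 0) -> np.ndarray:
        return self.cycles < dose_cycle

    def key(self) -> tuple[str, str, str]:
        return (self.bioreplicate, self.compartment, self.phase)


def estimate_baseline(
    series: QpcrSeries, dose_cycle: int = 0, method: str = "mean"
) -> float:
    """Endogenous level of the organism before dosing.

    Summarises the pre-dose measurements (cycle < ``dose_cycle``) by their
    arithmetic mean (default) or median.

    Raises
    ------
    ValueError
        If the series has no pre-dose samples (caller may then supply 0).
    """
    mask = series.pre_dose_mask(dose_cycle)
    if not mask.any():
        raise ValueError(
            f"no pre-dose samples in series {series.key()}; baseline unavailable"
        )
    values = series.cells_per_ml[mask]
    if method == "mean":
        return float(np.mean(values))
    if method == "median":
        return float(np.median(values))
    raise ValueError(f"unknown baseline method {method!r}")


def baseline_subtract(series: QpcrSeries, dose_cycle: int = 0) -> QpcrSeries:
    """Remove the endogenous baseline from post-dose measurements.

    Post-dose values become ``max(0, value - baseline)``; pre-dose samples
    are untouched.  Values clamped at 0 are counted in ``n_clamped`` (a true
    abundance cannot be negative, but subtraction noise can be).
    """
    if series.baseline is None:
        raise ValueError("series.baseline must be set before subtracting")
    post = ~series.pre_dose_mask(dose_cycle)
    adjusted = series.cells_per_ml.copy()
    raw = adjusted[post] - series.baseline
    n_clamped = int(np.sum(raw < 0))
    adjusted[post] = np.maximum(raw, 0.0)
    return replace(
        series,
        cycles=series.cycles.copy(),
        cells_per_ml=adjusted,
        n_clamped=series.n_clamped + n_clamped,
    )


def series_from_frame(
    frame: pd.DataFrame,
    genome: GenomeModel = LGG_GENOME,
    copies_per_cell: float = 1.0,
) -> list[QpcrSeries]:
    """Group a long qPCR table into per-(bioreplicate, compartment, phase) series.

    The frame needs columns ``bioreplicate, compartment, phase, cycle`` and at
    least one of ``cells_per_ml, copies, dna_mass_ng``; concentrations are
    resolved via the genome model where only mass or copies are present.
    """
    required = {"bioreplicate", "compartment", "phase", "cycle"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")

    def resolve(row: pd.Series) -> float:
        sample = QpcrSample(
            sample_id=str(row.get("sample_id", "")),
            bioreplicate=str(row["bioreplicate"]),
            compartment=str(row["compartment"]),
            phase=str(row["phase"]),
            cycle=int(row["cycle"]),
            cells_per_ml=_opt(row, "cells_per_ml"),
            dna_mass_ng=_opt(row, "dna_mass_ng"),
            copies=_opt(row, "copies"),
        )
        return sample.resolve_cells(genome, copies_per_cell)

    out = []
    for (br, comp, phase), grp in frame.groupby(
        ["bioreplicate", "compartment", "phase"], sort=True
    ):
        grp = grp.sort_values("cycle")
        if grp["cycle"].duplicated().any():
            raise ValueError(f"duplicate cycles in series ({br}, {comp}, {phase})")
        out.append(
            QpcrSeries(
                bioreplicate=str(br),
                compartment=str(comp),
                phase=str(phase),
                cycles=grp["cycle"].to_numpy(dtype=int),
                cells_per_ml=np.array([resolve(r) for _, r in grp.iterrows()]),
            )
        )
    return out


def _opt(row: pd.Series, key: str) -> float | None:
    if key not in row or pd.isna(row[key]):
        return None
    return float(row[key])
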