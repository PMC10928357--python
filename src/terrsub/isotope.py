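"""Exchangeable-hydrogen correction and standard normalization for δ²H.

Organic tissues carry a pool of hydrogen (amide, hydroxyl, ...) that
exchanges freely with ambient water vapour, so the measured bulk value
δ²H_tot of a dried sample depends on the water it last equilibrated with.
Comparative equilibration removes this: the fraction of exchangeable
hydrogen ``f_ex`` of each material class is estimated by equilibrating
test material with two isotopically distinct waters, and the measured
total is then decomposed as

    δ²H_tot = f_ex · δ²H_ex + (1 − f_ex) · δ²H_n

where δ²H_n is the non-exchangeable (diet-derived, ecologically
informative) value and δ²H_ex the isotopic composition of the
exchangeable pool, taken here as the equilibration water.  All values are
per-mil (‰) relative to V-SMOW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EquilibrationExperiment",
    "MaterialCorrection",
    "StandardSet",
    "DEFAULT_F_EX",
    "DEFAULT_D2H_EXCHANGEABLE",
    "PRECISION_GATE_PERMIL",
    "compute_fraction_exchangeable",
    "nonexchangeable_d2h",
    "normalize_to_standards",
    "correct_samples",
]

#: Shipped per-material exchangeable fractions from two-water equilibration
#: of muscle, chitin and algal test material.
DEFAULT_F_EX: dict[str, float] = {"muscle": 0.0279, "chitin": 0.0180, "algae": 0.0210}

#: δ²H of the exchangeable pool: the equilibration water used for samples (‰).
DEFAULT_D2H_EXCHANGEABLE: float = -54.42

#: Replicate-SD gate (‰); samples above it are flagged, never dropped.
PRECISION_GATE_PERMIL: float = 1.1


class DataQualityError(ValueError):
    """Raised when inputs are formally valid but physically implausible."""


@dataclass(frozen=True)
class EquilibrationExperiment:
    """One two-water equilibration of a material class.

    ``d2h_after_enriched`` / ``d2h_after_depleted`` are the material's
    measured δ²H after equilibration with the enriched and depleted
    water; ``water_enriched`` / ``water_depleted`` are those waters'
    δ²H values.  Everything in ‰ V-SMOW.
    """

    material_class: str
    d2h_after_enriched: float
    d2h_after_depleted: float
    water_enriched: float
    water_depleted: float

    def __post_init__(self) -> None:
        vals = (
            self.d2h_after_enriched,
            self.d2h_after_depleted,
            self.water_enriched,
            self.water_depleted,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("equilibration values must be finite")
        if self.water_enriched == self.water_depleted:
            raise ValueError("equilibration waters must be isotopically distinct")


@dataclass(frozen=True)
class MaterialCorrection:
    """Exchangeable-H fraction for one material class."""

    material_class: str
    f_ex: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_ex <= 1.0:
            raise ValueError(f"f_ex must lie in [0, 1], got {self.f_ex}")


@dataclass(frozen=True)
class StandardSet:
    """In-house standards bracketing a measurement sequence.

    ``standards`` is a sequence of (standard_id, accepted δ²H, measured δ²H).
    """

    standards: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.standards) < 2:
            raise ValueError("need at least two standards")
        accepted = [a for _, a, _ in self.standards]
        if len(set(accepted)) < 2:
            raise ValueError("accepted standard values must be distinct")


def compute_fraction_exchangeable(exp: EquilibrationExperiment) -> MaterialCorrection:
    """Estimate f_ex from a two-water equilibration experiment.

    f_ex = (δ²H_mat-EW − δ²H_mat-DW) / (δ²H_w-EW − δ²H_w-DW): the shift
    the material picks up between the two waters, relative to the shift
    of the waters themselves.  The ratio is invariant to swapping the
    two waters.

    Raises
    ------
    DataQualityError
        If the estimated fraction falls outside [−0.01, 1.01]; values
        within numerical tolerance of the bounds are clamped.
    """
    f_ex = (exp.d2h_after_enriched - exp.d2h_after_depleted) / (
        exp.water_enriched - exp.water_depleted
    )
    if not -0.01 <= f_ex <= 1.01:
        raise DataQualityError(
            f"f_ex = {f_ex:.4f} for {exp.material_class!r} outside plausible [0, 1]"
        )
    f_ex = min(max(f_ex, 0.0), 1.0)
    return MaterialCorrection(material_class=exp.material_class, f_ex=f_ex)


def nonexchangeable_d2h(
    d2h_total: float | np.ndarray,
    f_ex: float,
    d2h_exchangeable: float = DEFAULT_D2H_EXCHANGEABLE,
) -> float | np.ndarray:
    """Invert the bulk decomposition to the non-exchangeable value.

    δ²H_n = (δ²H_tot − f_ex · δ²H_ex) / (1 − f_ex).  ``f_ex = 0`` is the
    identity; ``f_ex = 1`` means the material has no non-exchangeable
    hydrogen and is rejected.
    """
    if not 0.0 <= f_ex <= 1.0:
        raise ValueError(f"f_ex must lie in [0, 1], got {f_ex}")
    if f_ex == 1.0:
        raise ZeroDivisionError("f_ex = 1: no non-exchangeable hydrogen to recover")
    return (d2h_total - f_ex * d2h_exchangeable) / (1.0 - f_ex)


def normalize_to_standards(
    measured: StandardSet, raw_values: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Map raw instrument values onto the accepted scale of the standards.

    Fits measured → accepted by least squares; with exactly two standards
    the line interpolates them exactly.  When the standards already read
    their accepted values the map is the identity.
    """
    meas = np.array([m for _, _, m in measured.standards], dtype=float)
    acc = np.array([a for _, a, _ in measured.standards], dtype=float)
    if np.ptp(meas) == 0:
        raise ValueError("measured standard values are identical; fit is singular")
    slope, intercept = np.polyfit(meas, acc, 1)
    return slope * np.asarray(raw_values, dtype=float) + intercept


def correct_samples(
    samples: pd.DataFrame,
    f_ex_by_material: dict[str, float] | None = None,
    d2h_exchangeable: float = DEFAULT_D2H_EXCHANGEABLE,
    standards: StandardSet | None = None,
    replicate_sd: pd.Series | None = None,
) -> pd.DataFrame:
    """Full correction for a sample table: normalize, then remove exchangeable H.

    ``samples`` needs columns ``sample_id, taxon, role, site, section,
    material_class, d2h_total``.  Returns a copy with
    ``d2h_nonexchangeable`` added and, when ``replicate_sd`` is given, a
    boolean ``precision_flag`` marking samples whose replicate SD exceeds
    the 1.1 ‰ gate (flagged, not dropped).
    """
    f_ex_by_material = dict(DEFAULT_F_EX if f_ex_by_material is None else f_ex_by_material)
    required = {"sample_id", "role", "section", "material_class", "d2h_total"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    bad_sections = set(samples["section"]) - {"upstream", "downstream"}
    if bad_sections:
        raise ValueError(f"unknown section labels: {sorted(bad_sections)}")

    out = samples.copy()
    raw = out["d2h_total"].to_numpy(dtype=float)
    if standards is not None:
        raw = normalize_to_standards(standards, raw)

    unknown = set(out["material_class"]) - set(f_ex_by_material)
    if unknown:
        raise ValueError(f"no f_ex for material class(es): {sorted(unknown)}")
    f_ex = out["material_class"].map(f_ex_by_material).to_numpy(dtype=float)
    out["d2h_nonexchangeable"] = (raw - f_ex * d2h_exchangeable) / (1.0 - f_ex)

    if replicate_sd is not None:
        out["precision_flag"] = (
            replicate_sd.reindex(out.index).to_numpy(dtype=float) > PRECISION_GATE_PERMIL
        )
    return out
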