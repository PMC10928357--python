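"""Dietary-water compounding and the two-endmember terrestrial index.

A fish's tissue δ²H mixes hydrogen from its food with hydrogen from
environmental (dietary) water.  The water contribution compounds over
trophic steps:

    ω_compound = 1 − (1 − ω)^(TL − 1)

with ω the per-step proportion of water hydrogen entering the consumer
and TL its trophic level.  The hypothetical consumer feeding 100 % on a
resource pool with non-exchangeable δ²H_source is then

    δ²H_C^100% = ω_compound · δ²H_water + (1 − ω_compound) · δ²H_source

and the terrestrial index of a measured consumer is the linear
two-endmember solution

    T = (δ²H_C − δ²H_C^100%aquatic) / (δ²H_C^100%terrestrial − δ²H_C^100%aquatic).

T ranges from 0 (fully seston-based, aquatic) to 1 (fully terrestrial-
insect-based); raw values outside [0, 1] are kept and flagged, never
silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixingParameters",
    "EndmemberSet",
    "TerrestrialIndexResult",
    "water_compounding",
    "correct_source_for_water",
    "build_endmembers",
    "terrestrial_index",
    "indices_for_consumers",
    "sensitivity_scan",
]


class DegenerateEndmembersError(ValueError):
    """Aquatic and terrestrial endmembers coincide; the index is undefined."""


@dataclass(frozen=True)
class MixingParameters:
    """Parameters of the water-compounding mixing model.

    omega
        Proportion of tissue H derived from environmental water per
        trophic step; 0.28 by default (0.17–0.30 spans the literature).
    trophic_level_consumer
        Assumed trophic level of the fish consumers (omnivores: 2.5).
    trophic_level_terrestrial_source
        Trophic level at which terrestrial insect sources are corrected
        for their own water contribution (primary consumers: 2).
    d2h_water
        River-water δ²H in ‰ V-SMOW (−55.06 default).
    source_correction
        ``"invert"`` removes the water contribution from measured insect
        values so the endmember equation re-adds it at the consumer's
        trophic level; ``"apply"`` uses the forward mixture instead.
    """

    omega: float = 0.28
    trophic_level_consumer: float = 2.5
    trophic_level_terrestrial_source: float = 2.0
    d2h_water: float = -55.06
    source_correction: Literal["invert", "apply"] = "invert"

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega < 1.0:
            raise ValueError(f"omega must lie in [0, 1), got {self.omega}")
        if self.trophic_level_consumer < 1 or self.trophic_level_terrestrial_source < 1:
            raise ValueError("trophic levels must be >= 1")
        if self.source_correction not in ("invert", "apply"):
            raise ValueError(f"unknown source_correction {self.source_correction!r}")


@dataclass(frozen=True)
class EndmemberSet:
    """Section-specific modeled 100 %-aquatic / 100 %-terrestrial consumers."""

    section: str
    d2h_aquatic_source: float
    d2h_terrestrial_source: float
    d2h_c_100_aquatic: float
    d2h_c_100_terrestrial: float
    omega_compound: float

    def __post_init__(self) -> None:
        if self.d2h_c_100_aquatic == self.d2h_c_100_terrestrial:
            raise DegenerateEndmembersError(
                f"endmembers coincide at {self.d2h_c_100_aquatic} ‰ for {self.section!r}"
            )

    @property
    def separation(self) -> float:
        """δ²H distance between the two endmembers (‰)."""
        return self.d2h_c_100_terrestrial - self.d2h_c_100_aquatic


@dataclass(frozen=True)
class TerrestrialIndexResult:
    sample_id: str
    index: float
    clipped: bool

    @property
    def index_clipped(self) -> float:
        """The index truncated to [0, 1] (raw value kept in ``index``)."""
        return min(max(self.index, 0.0), 1.0)


def water_compounding(omega: float, trophic_level: float) -> float:
    """Water contribution compounded over trophic steps: 1 − (1 − ω)^(TL−1)."""
    if not 0.0 <= omega < 1.0:
        raise ValueError(f"omega must lie in [0, 1), got {omega}")
    if trophic_level < 1:
        raise ValueError(f"trophic_level must be >= 1, got {trophic_level}")
    return 1.0 - (1.0 - omega) ** (trophic_level - 1.0)


def correct_source_for_water(
    d2h_measured: float | np.ndarray,
    params: MixingParameters,
    trophic_level: float | None = None,
) -> float | np.ndarray:
    """Remove the dietary-water contribution from a measured source value.

    Inverts δ²H_meas = ω_c·δ²H_water + (1 − ω_c)·δ²H_source at the given
    trophic level (the terrestrial-source level by default).  With ω = 0
    this is the identity, and the water value itself is a fixed point.
    """
    if trophic_level is None:
        trophic_level = params.trophic_level_terrestrial_source
    omega_c = water_compounding(params.omega, trophic_level)
    if omega_c >= 1.0:
        raise ValueError("compounded water fraction reached 1; inversion undefined")
    return (d2h_measured - omega_c * params.d2h_water) / (1.0 - omega_c)


def _consumer_from_source(d2h_source: float, omega_c: float, d2h_water: float) -> float:
    return omega_c * d2h_water + (1.0 - omega_c) * d2h_source


def build_endmembers(
    seston: Sequence[float] | np.ndarray,
    terrestrial_insects: Sequence[float] | np.ndarray,
    params: MixingParameters,
    section: str = "pooled",
) -> EndmemberSet:
    """Model section endmembers from seston and terrestrial-insect δ²H_n.

    The aquatic source is the arithmetic mean of the section's seston
    values; the terrestrial source is the mean insect value corrected for
    the insects' own water contribution at trophic level 2 (per
    ``params.source_correction``).  Both are then projected to consumer
    endmembers with ω compounded at the consumer trophic level.
    """
    seston = np.asarray(seston, dtype=float)
    insects = np.asarray(terrestrial_insects, dtype=float)
    if seston.size == 0 or insects.size == 0:
        raise ValueError(f"need >=1 seston and >=1 insect sample for {section!r}")

    d2h_aquatic = float(seston.mean())
    insect_mean = float(insects.mean())
    if params.source_correction == "invert":
        d2h_terrestrial = float(correct_source_for_water(insect_mean, params))
    else:
        omega_c_src = water_compounding(
            params.omega, params.trophic_level_terrestrial_source
        )
        d2h_terrestrial = _consumer_from_source(
            insect_mean, omega_c_src, params.d2h_water
        )

    omega_c = water_compounding(params.omega, params.trophic_level_consumer)
    return EndmemberSet(
        section=section,
        d2h_aquatic_source=d2h_aquatic,
        d2h_terrestrial_source=d2h_terrestrial,
        d2h_c_100_aquatic=_consumer_from_source(d2h_aquatic, omega_c, params.d2h_water),
        d2h_c_100_terrestrial=_consumer_from_source(
            d2h_terrestrial, omega_c, params.d2h_water
        ),
        omega_compound=omega_c,
    )


def terrestrial_index(
    d2h_consumer: float, endmembers: EndmemberSet, sample_id: str = ""
) -> TerrestrialIndexResult:
    """Two-endmember mixing solution for one consumer measurement."""
    t = (d2h_consumer - endmembers.d2h_c_100_aquatic) / endmembers.separation
    return TerrestrialIndexResult(
        sample_id=sample_id, index=t, clipped=not 0.0 <= t <= 1.0
    )


def indices_for_consumers(
    consumers: pd.DataFrame,
    seston: pd.DataFrame,
    insects: pd.DataFrame,
    params: MixingParameters | None = None,
    pooled: bool = False,
    value_col: str = "d2h_nonexchangeable",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual terrestrial indices with section-specific endmembers.

    ``consumers``, ``seston`` and ``insects`` are corrected-isotope tables
    (columns ``sample_id, taxon, section`` and ``value_col``).  With
    ``pooled=True`` a single endmember pair is built from all sources.
    Returns (per-individual index table, endmember summary table).
    """
    params = params or MixingParameters()
    sections = sorted(consumers["section"].unique())
    ends: dict[str, EndmemberSet] = {}
    if pooled:
        shared = build_endmembers(
            seston[value_col], insects[value_col], params, section="pooled"
        )
        ends = {s: shared for s in sections}
    else:
        for s in sections:
            ends[s] = build_endmembers(
                seston.loc[seston["section"] == s, value_col],
                insects.loc[insects["section"] == s, value_col],
                params,
                section=s,
            )

    rows = []
    for rec in consumers.itertuples(index=False):
        res = terrestrial_index(
            getattr(rec, value_col), ends[rec.section], sample_id=str(rec.sample_id)
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "species": rec.taxon,
                "section": rec.section,
                "index": res.index,
                "index_clipped": res.index_clipped,
                "clipped": res.clipped,
            }
        )
    end_rows = [
        {
            "section": e.section,
            "d2h_aquatic_source": e.d2h_aquatic_source,
            "d2h_terrestrial_source": e.d2h_terrestrial_source,
            "d2h_c_100_aquatic": e.d2h_c_100_aquatic,
            "d2h_c_100_terrestrial": e.d2h_c_100_terrestrial,
            "omega_compound": e.omega_compound,
        }
        for e in dict.fromkeys(ends.values())
    ]
    return pd.DataFrame(rows), pd.DataFrame(end_rows)


def sensitivity_scan(
    consumers: pd.DataFrame,
    seston: pd.DataFrame,
    insects: pd.DataFrame,
    omega_grid: Sequence[float],
    tl_grid: Sequence[float],
    base_params: MixingParameters | None = None,
    value_col: str = "d2h_nonexchangeable",
) -> pd.DataFrame:
    """Recompute group-mean indices over an (ω, TL) grid.

    One row per (omega, trophic level, species, section) with the mean
    index; cells whose endmembers degenerate are recorded with NaN and an
    ``error`` message rather than aborting the scan.  Output sorted by
    (omega, TL).
    """
    if len(omega_grid) == 0 or len(tl_grid) == 0:
        raise ValueError("omega_grid and tl_grid must be non-empty")
    base = base_params or MixingParameters()
    rows = []
    for omega in omega_grid:
        for tl in tl_grid:
            params = MixingParameters(
                omega=omega,
                trophic_level_consumer=tl,
                trophic_level_terrestrial_source=base.trophic_level_terrestrial_source,
                d2h_water=base.d2h_water,
                source_correction=base.source_correction,
            )
            try:
                idx, _ = indices_for_consumers(
                    consumers, seston, insects, params, value_col=value_col
                )
            except (DegenerateEndmembersError, ValueError) as exc:
                rows.append(
                    {
                        "omega": omega,
                        "trophic_level": tl,
                        "species": None,
                        "section": None,
                        "mean_index": np.nan,
                        "n": 0,
                        "error": str(exc),
                    }
                )
                continue
            grp = idx.groupby(["species", "section"])["index"]
            for (species, section), mean in grp.mean().items():
                rows.append(
                    {
                        "omega": omega,
                        "trophic_level": tl,
                        "species": species,
                        "section": section,
                        "mean_index": mean,
                        "n": int(grp.size()[(species, section)]),
                        "error": "",
                    }
                )
    return (
        pd.DataFrame(rows)
        .sort_values(["omega", "trophic_level", "species", "section"])
        .reset_index(drop=True)
    )
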