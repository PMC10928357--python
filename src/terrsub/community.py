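"""Electrofishing and benthic community metrics.

CPUE/BPUE standardize electrofishing catches to individuals (or grams)
per 1000 m of fished bank; benthic grab counts become individuals per m²;
Fulton's condition factor K = 100·W/L³ (W in g, L in cm) indexes fish
body condition.  A pooled rare-species filter drops species whose total
relative abundance falls at or below a threshold before community-level
comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EKMAN_AREA_M2",
    "cpue",
    "bpue",
    "fulton_k",
    "benthic_density",
    "rare_species_filter",
    "site_by_species_matrix",
]

#: Sampling area of a small Ekman grab (m²); configurable assumption.
DEFAULT_EKMAN_AREA_M2 = 0.0225

_CATCH_COLS = {"site", "section", "species", "count", "section_length_m"}


def _per_unit_effort(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    missing = (_CATCH_COLS | {value_col}) - set(records.columns)
    if missing:
        raise ValueError(f"catch table missing columns: {sorted(missing)}")
    if (records["section_length_m"] <= 0).any():
        raise ValueError("section_length_m must be positive")
    if (records["count"] < 0).any():
        raise ValueError("counts must be non-negative")

    def one_site(g: pd.DataFrame) -> pd.Series:
        lengths = g["section_length_m"].unique()
        if len(lengths) > 1:
            raise ValueError(
                f"inconsistent fished lengths at site {g.name!r}: {lengths}"
            )
        return pd.Series(
            {
                "section": g["section"].iloc[0],
                "value": g[value_col].sum() * 1000.0 / lengths[0],
            }
        )

    out = (
        records.groupby("site", sort=True)[records.columns]
        .apply(one_site)
        .reset_index()
    )
    return out


def cpue(records: pd.DataFrame) -> pd.DataFrame:
    """Catch per unit effort per site (individuals 1000 m⁻¹).

    All passes at a site are summed before standardizing by the fished
    length.  Returns columns ``site, section, cpue``.
    """
    out = _per_unit_effort(records, "count")
    return out.rename(columns={"value": "cpue"})


def bpue(records: pd.DataFrame) -> pd.DataFrame:
    """Biomass per unit effort per site (g 1000 m⁻¹); needs ``biomass_g``."""
    out = _per_unit_effort(records, "biomass_g")
    return out.rename(columns={"value": "bpue"})


def fulton_k(
    weight_g: float | np.ndarray, total_length_cm: float | np.ndarray
) -> float | np.ndarray:
    """Fulton's condition factor K = 100 · W / L³ with L in centimeters."""
    weight_g = np.asarray(weight_g, dtype=float)
    total_length_cm = np.asarray(total_length_cm, dtype=float)
    if (weight_g <= 0).any() or (total_length_cm <= 0).any():
        raise ValueError("weight and length must be positive")
    k = 100.0 * weight_g / total_length_cm**3
    return float(k) if k.ndim == 0 else k


def benthic_density(samples: pd.DataFrame) -> pd.DataFrame:
    """Benthic invertebrate density per site (individuals m⁻²).

    Each replicate grab gives a per-taxon density count/area; replicates
    are averaged per (site, taxon) and taxa summed into a site total.
    Returns per-taxon densities and a ``__total__`` row per site.
    """
    required = {"site", "section", "taxon", "count", "sampled_area_m2", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"benthic table missing columns: {sorted(missing)}")
    if (samples["sampled_area_m2"] <= 0).any():
        raise ValueError("sampled_area_m2 must be positive")

    df = samples.copy()
    df["density"] = df["count"] / df["sampled_area_m2"]
    per_taxon = (
        df.groupby(["site", "section", "taxon"])["density"].mean().reset_index()
    )
    totals = (
        per_taxon.groupby(["site", "section"])["density"]
        .sum()
        .reset_index()
        .assign(taxon="__total__")
    )
    return pd.concat([per_taxon, totals], ignore_index=True)[
        ["site", "section", "taxon", "density"]
    ]


def site_by_species_matrix(
    records: pd.DataFrame, value_col: str = "count"
) -> pd.DataFrame:
    """Pivot a long catch/benthos table into a site × species matrix."""
    return (
        records.pivot_table(
            index="site", columns="species", values=value_col, aggfunc="sum", fill_value=0
        )
        .sort_index()
        .sort_index(axis=1)
    )


def rare_species_filter(
    matrix: pd.DataFrame, threshold: float = 0.001
) -> pd.DataFrame:
    """Drop species with pooled relative abundance ≤ ``threshold``.

    The proportion is computed on totals pooled over every site (both
    river sections together), not per site.  Idempotent: species kept
    once are kept again because removal only raises relative abundances
    of the survivors.
    """
    if matrix.size == 0:
        raise ValueError("empty site × species matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = matrix.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("matrix contains no individuals")
    keep = totals / grand > threshold
    return matrix.loc[:, keep]
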