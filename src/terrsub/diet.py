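"""Gut-content incidence processing downstream of metabarcoding.

Takes long-format read-count tables (fish × detected species × technical
replicate), keeps only detections confirmed in both technical replicates,
removes non-dietary taxa (by default the two bat species whose DNA enters
guts via ingested feces), classifies each detection as aquatic or
terrestrial from a user-supplied habitat map, and summarizes per-fish
species-presence counts.  Counts are presences, not read proportions:
metabarcoding read depth is not a quantitative measure of diet biomass.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUSIONS",
    "merge_replicates",
    "apply_exclusions",
    "count_terrestrial",
]

#: Bat species removed by default: gut presence reflects feces, not prey.
#: Both spellings of the Daubenton's bat binomial occur in source tables.
DEFAULT_EXCLUSIONS: tuple[str, ...] = (
    "Myotis daubentonii",
    "Myotis daubentoniid",
    "Pipistrellus pygmaeus",
)

_GUT_COLS = {"fish_id", "species_detected", "technical_replicate", "read_count"}


def merge_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Sum technical replicates, dropping single-replicate detections.

    A (fish, species) pair with positive reads in both replicates keeps
    the summed count; a pair detected in only one replicate is treated
    as noise and removed.  Returns columns
    ``fish_id, species_detected, read_count``.
    """
    missing = _GUT_COLS - set(table.columns)
    if missing:
        raise ValueError(f"gut table missing columns: {sorted(missing)}")
    if (table["read_count"] < 0).any():
        raise ValueError("read counts must be non-negative")
    bad = set(table["technical_replicate"]) - {1, 2}
    if bad:
        raise ValueError(f"technical_replicate must be 1 or 2, got {sorted(bad)}")
    dup = table.groupby(["fish_id", "species_detected", "technical_replicate"]).size()
    if (dup > 1).any():
        raise ValueError("more than one row per (fish, species, replicate)")
    if table.empty:
        return pd.DataFrame(columns=["fish_id", "species_detected", "read_count"])

    g = table.groupby(["fish_id", "species_detected"])["read_count"]
    summed = g.sum()
    n_positive = g.apply(lambda s: int((s > 0).sum()))
    kept = summed[n_positive == 2]
    return kept.reset_index()


def apply_exclusions(
    counts: pd.DataFrame, exclusion_list: Sequence[str] = DEFAULT_EXCLUSIONS
) -> pd.DataFrame:
    """Remove rows whose detected species is on the exclusion list."""
    return counts[~counts["species_detected"].isin(set(exclusion_list))].reset_index(
        drop=True
    )


def count_terrestrial(
    counts: pd.DataFrame,
    habitat: Mapping[str, str],
    fish_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fish aquatic/terrestrial species-presence counts and a group summary.

    ``counts`` holds merged detections (``fish_id, species_detected,
    read_count``); ``habitat`` maps every detected species to
    ``"aquatic"`` or ``"terrestrial"``.  ``fish_meta`` (``fish_id,
    species, section``) attaches consumer identity; fish present there
    but with zero retained detections are kept with counts (0, 0) and
    ``no_detections=True``.

    Returns ``(per_fish, summary)`` where summary gives mean ± SD of
    aquatic and terrestrial species per consumer species × section.
    """
    unclassified = sorted(set(counts["species_detected"]) - set(habitat))
    if unclassified:
        raise ValueError(f"species without habitat classification: {unclassified}")
    bad = {v for v in habitat.values()} - {"aquatic", "terrestrial"}
    if bad:
        raise ValueError(f"habitat labels must be aquatic/terrestrial, got {sorted(bad)}")

    detected = counts[counts["read_count"] > 0].copy()
    detected["habitat"] = detected["species_detected"].map(habitat)
    per_fish = (
        detected.drop_duplicates(["fish_id", "species_detected"])
        .pivot_table(
            index="fish_id", columns="habitat", values="species_detected",
            aggfunc="nunique", fill_value=0,
        )
        .reindex(columns=["aquatic", "terrestrial"], fill_value=0)
        .reset_index()
    )
    per_fish.columns.name = None

    if fish_meta is not None:
        per_fish = fish_meta.merge(per_fish, on="fish_id", how="left")
        per_fish[["aquatic", "terrestrial"]] = (
            per_fish[["aquatic", "terrestrial"]].fillna(0).astype(int)
        )
    per_fish["total"] = per_fish["aquatic"] + per_fish["terrestrial"]
    per_fish["no_detections"] = per_fish["total"] == 0

    group_cols = (
        ["species", "section"]
        if fish_meta is not None and {"species", "section"} <= set(per_fish.columns)
        else []
    )
    if group_cols:
        summary = (
            per_fish.groupby(group_cols)[["aquatic", "terrestrial"]]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        summary.columns = [
            "_".join(c).rstrip("_") if isinstance(c, tuple) else c
            for c in summary.columns
        ]
    else:
        summary = pd.DataFrame(
            {
                "aquatic_mean": [per_fish["aquatic"].mean()],
                "aquatic_std": [per_fish["aquatic"].std()],
                "terrestrial_mean": [per_fish["terrestrial"].mean()],
                "terrestrial_std": [per_fish["terrestrial"].std()],
                "n": [len(per_fish)],
            }
        )
    return per_fish, summary
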