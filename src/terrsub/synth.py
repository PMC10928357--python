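"""Seeded synthetic-data generator for the whole pipeline.

Emulates a two-section river study — an iron-impacted reach upstream of a
dam and a remediated reach downstream — with known ground truth, so every
stage (isotope correction, mixing, community metrics, diet counts,
statistics) is testable without field data:

* benthic grab counts and electrofishing catches with section-distinct
  means (negative binomial: the field SDs are strongly overdispersed);
* consumer δ²H generated forward through the same mixing model the
  analysis inverts, from configured true terrestrial fractions per
  species × section plus Gaussian measurement noise;
* gut-content read tables with two technical replicates and a dropout
  rate, with section-dependent terrestrial species rates.

One global seed; each generator derives an independent stream from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .isotope import DEFAULT_F_EX, DEFAULT_D2H_EXCHANGEABLE
from .mixing import MixingParameters, build_endmembers

__all__ = ["SynthConfig", "GroundTruth", "generate_isotopes",
           "generate_catch_and_benthos", "generate_gut", "generate_all"]

SECTIONS = ("upstream", "downstream")


def _hash_stable(s: str) -> int:
    """Deterministic (process-independent) FNV-1a string hash."""
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % 2**32
    return h


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent child generator for a named stream under one global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _hash_stable(stream)]))

#: True terrestrial fractions per (species, section): high allochthony in
#: the iron-rich upstream reach, low downstream.
DEFAULT_TRUE_FRACTIONS: dict[tuple[str, str], float] = {
    ("roach", "upstream"): 0.41,
    ("roach", "downstream"): 0.19,
    ("perch", "upstream"): 0.68,
    ("perch", "downstream"): 0.13,
    ("bleak", "upstream"): 0.64,
    ("bleak", "downstream"): 0.10,
}

#: Mean terrestrial species per fish gut, per (species, section); zero
#: downstream (terrestrial prey effectively absent there).
DEFAULT_GUT_TERRESTRIAL_RATE: dict[tuple[str, str], float] = {
    ("roach", "upstream"): 0.0,
    ("roach", "downstream"): 0.0,
    ("perch", "upstream"): 4.0,
    ("perch", "downstream"): 0.0,
    ("bleak", "upstream"): 1.0,
    ("bleak", "downstream"): 0.0,
}

DEFAULT_GUT_AQUATIC_RATE: dict[tuple[str, str], float] = {
    ("roach", "upstream"): 2.0,
    ("roach", "downstream"): 4.0,
    ("perch", "upstream"): 3.0,
    ("perch", "downstream"): 3.0,
    ("bleak", "upstream"): 1.0,
    ("bleak", "downstream"): 2.0,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generating conditions for the synthetic study.

    Section-level means mirror the field contrast (benthos 982 vs 5945
    individuals m⁻², CPUE 60 vs 158 individuals 1000 m⁻¹); true
    terrestrial fractions per species × section are the group means the
    isotope pipeline should recover.  δ²H noise (SD 3 ‰) lumps
    measurement error and individual ecological variation.
    """

    seed: int = 0
    n_sites_per_section: int = 3
    benthic_mean_per_section: Mapping[str, float] = field(
        default_factory=lambda: {"upstream": 982.0, "downstream": 5945.0}
    )
    # Gamma shape of between-site density variation: k = (mean/SD)² matches
    # the field site-level SDs (982±1100 upstream, 5945±2106 downstream).
    benthic_dispersion: Mapping[str, float] | float = field(
        default_factory=lambda: {"upstream": 0.80, "downstream": 7.97}
    )
    n_benthic_replicates: int = 3
    ekman_area_m2: float = 0.0225
    cpue_mean_per_section: Mapping[str, float] = field(
        default_factory=lambda: {"upstream": 60.0, "downstream": 158.0}
    )
    # Site-level CPUE spread from the printed 60±35 / 158±49.
    cpue_dispersion: Mapping[str, float] | float = field(
        default_factory=lambda: {"upstream": 2.94, "downstream": 10.4}
    )
    true_terrestrial_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_FRACTIONS)
    )
    d2h_noise_sd: float = 3.0
    seston_mean_per_section: Mapping[str, float] = field(
        default_factory=lambda: {"upstream": -150.0, "downstream": -150.0}
    )
    insect_mean_per_section: Mapping[str, float] = field(
        default_factory=lambda: {"upstream": -90.0, "downstream": -90.0}
    )
    n_seston_per_section: int = 3
    n_insects_per_section: int = 6
    n_fish_per_group: int = 30
    gut_terrestrial_rate: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GUT_TERRESTRIAL_RATE)
    )
    gut_aquatic_rate: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GUT_AQUATIC_RATE)
    )
    n_fish_gut_per_group: int = 6
    replicate_dropout: float = 0.2
    mixing: MixingParameters = field(default_factory=MixingParameters)

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.true_terrestrial_fraction.values()):
            raise ValueError("true terrestrial fractions must lie in [0, 1]")
        if self.d2h_noise_sd < 0:
            raise ValueError("d2h_noise_sd must be >= 0")
        if not 0.0 <= self.replicate_dropout <= 1.0:
            raise ValueError("replicate_dropout must lie in [0, 1]")
        for m in (self.benthic_mean_per_section, self.cpue_mean_per_section):
            if any(v < 0 for v in m.values()):
                raise ValueError("section means must be non-negative")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted({sp for sp, _ in self.true_terrestrial_fraction}))

    def rng(self, stream: str) -> np.random.Generator:
        """Independent child stream derived from the global seed."""
        return _stream_rng(self.seed, stream)


@dataclass(frozen=True)
class GroundTruth:
    """The exact quantities the generator used, serialized alongside outputs."""

    true_fraction_per_fish: pd.DataFrame
    endmembers: pd.DataFrame
    expected_benthic_density: Mapping[str, float]
    expected_cpue: Mapping[str, float]


def _sites(config: SynthConfig) -> dict[str, list[str]]:
    return {
        sec: [f"{sec}_{i + 1}" for i in range(config.n_sites_per_section)]
        for sec in SECTIONS
    }


def generate_isotopes(config: SynthConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Seston, terrestrial-insect and consumer δ²H tables with ground truth.

    Source samples are drawn Gaussian around their section means.  Each
    consumer's value comes forward through the mixing model: the two
    section endmembers are built from the configured section *means*
    (the true endmembers), and δ²H_C = t·δ²H_C^100%terr +
    (1−t)·δ²H_C^100%aq + N(0, d2h_noise_sd) for that fish's true
    fraction t.  The table carries measured-scale bulk values
    (``d2h_total``) re-composed with the material f_ex so the isotope
    module's correction is exercised end to end.
    """
    rng = config.rng("isotopes")
    rows: list[dict] = []
    truth_rows: list[dict] = []
    end_rows: list[dict] = []
    sites = _sites(config)

    for sec in SECTIONS:
        true_ends = build_endmembers(
            [config.seston_mean_per_section[sec]],
            [config.insect_mean_per_section[sec]],
            config.mixing,
            section=sec,
        )
        end_rows.append(
            {
                "section": sec,
                "d2h_c_100_aquatic": true_ends.d2h_c_100_aquatic,
                "d2h_c_100_terrestrial": true_ends.d2h_c_100_terrestrial,
            }
        )
        for i in range(config.n_seston_per_section):
            d2h_n = rng.normal(config.seston_mean_per_section[sec], config.d2h_noise_sd)
            rows.append(
                _isotope_row(
                    f"seston_{sec}_{i + 1}", "seston", "aquatic_source",
                    sites[sec][i % len(sites[sec])], sec, d2h_n, "algae",
                )
            )
        for i in range(config.n_insects_per_section):
            d2h_n = rng.normal(config.insect_mean_per_section[sec], config.d2h_noise_sd)
            rows.append(
                _isotope_row(
                    f"insect_{sec}_{i + 1}", "terrestrial_insect", "terrestrial_source",
                    sites[sec][i % len(sites[sec])], sec, d2h_n, "chitin",
                )
            )
        for species in config.species:
            t = config.true_terrestrial_fraction[(species, sec)]
            for i in range(config.n_fish_per_group):
                d2h_n = (
                    t * true_ends.d2h_c_100_terrestrial
                    + (1 - t) * true_ends.d2h_c_100_aquatic
                    + rng.normal(0.0, config.d2h_noise_sd)
                )
                sid = f"{species}_{sec}_{i + 1}"
                rows.append(
                    _isotope_row(
                        sid, species, "consumer",
                        sites[sec][i % len(sites[sec])], sec, d2h_n, "muscle",
                    )
                )
                truth_rows.append(
                    {"sample_id": sid, "species": species, "section": sec,
                     "true_fraction": t}
                )

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        true_fraction_per_fish=pd.DataFrame(truth_rows),
        endmembers=pd.DataFrame(end_rows),
        expected_benthic_density=dict(config.benthic_mean_per_section),
        expected_cpue=dict(config.cpue_mean_per_section),
    )
    return table, truth


def _isotope_row(
    sample_id: str, taxon: str, role: str, site: str, section: str,
    d2h_n: float, material: str,
) -> dict:
    f_ex = DEFAULT_F_EX[material]
    d2h_total = f_ex * DEFAULT_D2H_EXCHANGEABLE + (1 - f_ex) * d2h_n
    return {
        "sample_id": sample_id, "taxon": taxon, "role": role, "site": site,
        "section": section, "material_class": material, "d2h_total": d2h_total,
    }


def generate_catch_and_benthos(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Electrofishing catch and benthic grab tables with section contrast.

    Hierarchical gamma–Poisson (marginally negative binomial): each site's
    expected CPUE / density is gamma-distributed around the section mean
    with shape k (site SD = mean/√k), and observed counts are Poisson
    around the site expectation.  Fished lengths uniform in 300–640 m;
    catch totals split over species by fixed composition; benthic counts
    per grab over a small taxon list.
    """
    rng = config.rng("community")
    sites = _sites(config)
    species_pool = list(config.species) + ["pike", "gudgeon"]
    comp = np.array([0.376, 0.157, 0.175, 0.1, 0.05])
    comp = comp / comp.sum()
    taxa = ["chironomidae", "bivalvia", "gastropoda", "ephemeroptera"]

    catch_rows, benthic_rows = [], []
    for sec in SECTIONS:
        k_cpue = _dispersion_for(config.cpue_dispersion, sec)
        k_benthic = _dispersion_for(config.benthic_dispersion, sec)
        for site in sites[sec]:
            length = rng.uniform(300.0, 640.0)
            site_cpue = _gamma_site_level(
                rng, config.cpue_mean_per_section[sec], k_cpue
            )
            total = int(rng.poisson(site_cpue * length / 1000.0))
            counts = rng.multinomial(total, comp)
            for sp, c in zip(species_pool, counts):
                catch_rows.append(
                    {
                        "site": site, "section": sec, "species": sp,
                        "count": int(c),
                        "biomass_g": float(c) * float(rng.uniform(8.0, 40.0)),
                        "section_length_m": length,
                    }
                )
            site_density = _gamma_site_level(
                rng, config.benthic_mean_per_section[sec], k_benthic
            )
            for rep in range(1, config.n_benthic_replicates + 1):
                for taxon, w in zip(taxa, (0.55, 0.2, 0.15, 0.1)):
                    lam = site_density * config.ekman_area_m2 * w
                    benthic_rows.append(
                        {
                            "site": site, "section": sec, "taxon": taxon,
                            "count": int(rng.poisson(lam)),
                            "sampled_area_m2": config.ekman_area_m2,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(catch_rows), pd.DataFrame(benthic_rows)


def _dispersion_for(dispersion: Mapping[str, float] | float, section: str) -> float:
    return dispersion[section] if isinstance(dispersion, Mapping) else float(dispersion)


def _gamma_site_level(rng: np.random.Generator, mean: float, k: float) -> float:
    """Site-level expectation: Gamma(shape k, mean ``mean``); mean itself as k→∞."""
    if mean <= 0:
        return 0.0
    if k > 1e5:  # Poisson limit: no between-site heterogeneity
        return mean
    return float(rng.gamma(k, mean / k))


TERRESTRIAL_POOL = [f"terr_sp_{i:02d}" for i in range(1, 18)]
AQUATIC_POOL = [f"aqua_sp_{i:02d}" for i in range(1, 33)]


def generate_gut(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gut read-count table (two technical replicates) and habitat map.

    Per-fish terrestrial and aquatic species counts are Poisson; each
    detection gets a log-normal read count, duplicated into both
    replicates, each replicate copy independently zeroed with probability
    ``replicate_dropout`` (so the merge filter has real work to do).  The
    configured group rates are the expected *confirmed* (both-replicate)
    species counts: the latent ingestion rate is inflated by
    1/(1 − dropout)² so the post-filter table matches the configuration.
    """
    rng = config.rng("gut")
    keep_prob = (1.0 - config.replicate_dropout) ** 2
    inflate = 1.0 / keep_prob if keep_prob > 0 else 1.0
    rows = []
    for sec in SECTIONS:
        for species in config.species:
            n_terr_rate = config.gut_terrestrial_rate[(species, sec)] * inflate
            n_aqua_rate = config.gut_aquatic_rate[(species, sec)] * inflate
            for i in range(config.n_fish_gut_per_group):
                fish_id = f"gut_{species}_{sec}_{i + 1}"
                n_terr = rng.poisson(n_terr_rate)
                n_aqua = max(int(rng.poisson(n_aqua_rate)), 1)
                prey = list(
                    rng.choice(TERRESTRIAL_POOL, size=min(n_terr, len(TERRESTRIAL_POOL)),
                               replace=False)
                ) + list(
                    rng.choice(AQUATIC_POOL, size=min(n_aqua, len(AQUATIC_POOL)),
                               replace=False)
                )
                for prey_sp in prey:
                    reads = float(np.exp(rng.normal(5.0, 1.0)))
                    for rep in (1, 2):
                        dropped = rng.random() < config.replicate_dropout
                        rows.append(
                            {
                                "fish_id": fish_id,
                                "fish_species": species,
                                "section": sec,
                                "species_detected": prey_sp,
                                "technical_replicate": rep,
                                "read_count": 0 if dropped else int(round(reads)),
                            }
                        )
    table = pd.DataFrame(rows)
    habitat = pd.DataFrame(
        {
            "species_detected": TERRESTRIAL_POOL + AQUATIC_POOL,
            "habitat": ["terrestrial"] * len(TERRESTRIAL_POOL)
            + ["aquatic"] * len(AQUATIC_POOL),
        }
    )
    return table, habitat


def generate_all(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """All five input tables plus ground-truth sidecars, keyed by name."""
    isotopes, truth = generate_isotopes(config)
    catch, benthos = generate_catch_and_benthos(config)
    gut, habitat = generate_gut(config)
    return {
        "isotopes": isotopes,
        "catch": catch,
        "benthos": benthos,
        "gut": gut,
        "habitat": habitat,
        "truth_fractions": truth.true_fraction_per_fish,
        "truth_endmembers": truth.endmembers,
    }
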