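"""Synthetic data with known ground truth.

Generates everything the pipeline consumes -- admixed diploid genotypes with
missing calls, per-clade trait and climate matrices, and geographic
coordinates -- under the same statistical model the analysis assumes, so the
downstream stages can be validated against a known truth without any
external download.

Genotype model
--------------
Per site a shared ancestral frequency p ~ Uniform(0.05, 0.95) is drawn; each
of the K clusters receives a frequency from a Balding-Nichols Beta around p
with spread F = ``allele_freq_divergence``:

    p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F)

Individuals belong to clades (one cluster per clade); their ancestry rows
are Dirichlet with expected minor-ancestry mass ``admixture_level``, or
exact one-hot rows when that level is zero. Genotypes are
Binomial(2, q_i . p_j) with entries masked missing i.i.d. at
``missing_rate`` (missingness completely at random).

Defaults mirror the study design this emulates: two lineages of ten
individuals each, a couple of thousand filtered SNPs, 42 morphological
characters, 19 bioclim-style climate variables with a low-rank (2-factor)
correlation structure, and clade centroids placed so pairwise great-circle
distances fall in the 50-250 km range.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import QMatrix
from .divergence import TraitMatrix
from .io import SITE_COLUMNS, GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_traits_and_climate"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    n_clusters: int = 2
    n_individuals_per_clade: int = 10
    n_sites: int = 2000
    allele_freq_divergence: float = 0.1
    admixture_level: float = 0.05
    missing_rate: float = 0.1
    n_traits: int = 42
    trait_divergence: float = 3.0
    n_climate_vars: int = 19
    seed: int = 0
    admixed_fraction: float = 0.5  # fraction of individuals carrying any admixture
    dirichlet_scale: float = 30.0  # concentration controlling q-row spread

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        for name in ("n_individuals_per_clade", "n_sites", "n_traits", "n_climate_vars"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.allele_freq_divergence < 1:
            raise ConfigError("allele_freq_divergence must be in (0, 1)")
        if not 0 <= self.admixture_level <= 1:
            raise ConfigError("admixture_level must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.trait_divergence < 0:
            raise ConfigError("trait_divergence must be nonnegative")
        if not 0 < self.admixed_fraction <= 1:
            raise ConfigError("admixed_fraction must be in (0, 1]")
        if self.admixture_level / self.admixed_fraction > 0.5:
            raise ConfigError(
                "admixture_level / admixed_fraction > 0.5: admixed individuals "
                "would carry mostly foreign ancestry"
            )

    def clade_labels(self) -> list[str]:
        letters = string.ascii_uppercase
        return [f"clade_{letters[k % 26]}{k // 26 or ''}" for k in range(self.n_clusters)]


@dataclass
class SimTruth:
    true_Q: QMatrix
    ancestral_freqs: np.ndarray  # clusters x sites
    true_pair_effects: dict = field(default_factory=dict)
    trait_means: np.ndarray | None = None


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw an admixed genotype matrix plus its generating truth.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng_freq, rng_q, rng_g, rng_m = _streams(config.seed, 4)
    K, n_per, J = config.n_clusters, config.n_individuals_per_clade, config.n_sites
    n = K * n_per
    F = config.allele_freq_divergence

    p_anc = rng_freq.uniform(0.05, 0.95, size=J)
    shape = (1.0 - F) / F
    P = rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape, size=(K, J))
    P = np.clip(P, 1e-6, 1 - 1e-6)

    clade_of = np.repeat(np.arange(K), n_per)
    a = config.admixture_level
    if a == 0.0 or K == 1:
        Q = np.eye(K)[clade_of]
    else:
        # only a fraction of individuals carry admixture (the rest are
        # one-hot), with the per-admixed-individual minor mass scaled so the
        # population-level expectation stays at admixture_level
        a_ind = a / config.admixed_fraction
        c = config.dirichlet_scale
        Q = np.eye(K)[clade_of].astype(float)
        admixed = rng_q.random(n) < config.admixed_fraction
        for i, k in enumerate(clade_of):
            if not admixed[i]:
                continue
            conc = np.full(K, c * a_ind / (K - 1))
            conc[k] = c * (1.0 - a_ind)
            Q[i] = rng_q.dirichlet(conc)

    Fmat = Q @ P
    G = rng_g.binomial(2, Fmat).astype(float)
    if config.missing_rate > 0:
        G[rng_m.random(G.shape) < config.missing_rate] = np.nan

    labels = config.clade_labels()
    samples = [f"{labels[k]}_{i % n_per:02d}" for i, k in enumerate(clade_of)]
    sites = pd.DataFrame(
        {
            "chrom": "sim1",
            "pos": np.arange(1, J + 1),
            "id": [f"snp{j + 1}" for j in range(J)],
            "ref": "A",
            "alt": "T",
            "qual": 60.0,
        }
    )[SITE_COLUMNS]
    truth = SimTruth(
        true_Q=QMatrix(samples, Q),
        ancestral_freqs=P,
        true_pair_effects={
            (labels[i], labels[j]): a for i in range(K) for j in range(i + 1, K)
        },
    )
    return GenotypeMatrix(samples, sites, G), truth


def simulate_traits_and_climate(
    config: SimConfig,
) -> tuple[TraitMatrix, TraitMatrix, pd.DataFrame]:
    """Per-clade trait matrix, climate matrix and sample coordinates.

    Trait centroids are separated by ``trait_divergence`` along random
    directions on top of unit-scale noise, so zero divergence leaves
    between-clade distances at the noise scale. Climate rows follow a
    rank-2 factor model (two latent gradients across 19 variables), giving
    the few-dominant-PC structure characteristic of bioclim data. Clade
    centres sit along a roughly 1-degree-spaced arc near 24N, 100W so
    inter-clade great-circle distances span about 50-250 km.
    """
    config.validate()
    rng_t, rng_c, rng_xy = _streams(config.seed + 1, 3)
    K = config.n_clusters
    labels = config.clade_labels()

    directions = rng_t.standard_normal((K, config.n_traits))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    centroids = config.trait_divergence * directions
    traits = centroids + rng_t.standard_normal((K, config.n_traits))
    trait_m = TraitMatrix(labels, [f"char{v + 1}" for v in range(config.n_traits)],
                          traits)

    loadings = rng_c.standard_normal((config.n_climate_vars, 2)) * np.array([3.0, 1.5])
    factors = rng_c.standard_normal((K, 2))
    climate = factors @ loadings.T + 0.05 * rng_c.standard_normal((K, config.n_climate_vars))
    climate_m = TraitMatrix(labels, [f"bio{v + 1}" for v in range(config.n_climate_vars)],
                            climate)

    n_per = config.n_individuals_per_clade
    recs = []
    for k, lab in enumerate(labels):
        lat0 = 24.0 + 0.35 * (k % 3)
        lon0 = -101.0 + 1.0 * k
        for i in range(n_per):
            recs.append(
                (f"{lab}_{i:02d}", lab, f"{lab}_pop{i // max(n_per // 2, 1)}",
                 lat0 + rng_xy.uniform(-0.1, 0.1), lon0 + rng_xy.uniform(-0.1, 0.1))
            )
    coords = pd.DataFrame(recs, columns=["sample", "clade", "population",
                                         "latitude", "longitude"])
    return trait_m, climate_m, coords
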