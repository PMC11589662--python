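"""Packaged datasets.

The package ships the published 21-pair comparison table for the *Sceloporus*
poinsettii group of northeastern Mexico: per lineage pair, the two gene-flow
summaries (mean admixture frequency on the 0-100 scale and proportion of
admixed individuals), PC-weighted morphological and climatic divergence,
divergence time in Myr, and clade-centroid great-circle distance in km.
"""

from importlib import resources

import pandas as pd

__all__ = [
    "load_sceloporus_pairs",
    "SPECIES_OF_CLADE",
    "comparison3_assignments",
]

#: Seven-species taxonomy adopted for the intra- vs interspecific split:
#: clade number -> species label. Clades 1-4 are one species (S. minor),
#: 9-10 one species (S. ornatus), 11-12 one species (S. oberon); the two
#: undescribed lineages (clades 6 and 7) are treated as distinct species.
SPECIES_OF_CLADE = {
    1: "S. minor",
    2: "S. minor",
    3: "S. minor",
    4: "S. minor",
    5: "S. cyanogenys",
    6: "Sceloporus sp. N",
    7: "Sceloporus sp. S",
    8: "S. cyanostictus",
    9: "S. ornatus",
    10: "S. ornatus",
    11: "S. oberon",
    12: "S. oberon",
}


def load_sceloporus_pairs() -> pd.DataFrame:
    """Return the 21-row lineage-pair table as a DataFrame.

    Columns: ``comparison``, ``clade_a``, ``clade_b``, ``taxon_a``,
    ``taxon_b``, ``n_individuals``, ``n_snps``,
    ``clade_admixture_mean_freq``, ``clade_admixture_prop_ind``,
    ``pop_admixture_mean_freq``, ``pop_admixture_prop_ind``,
    ``morphology_pc``, ``climate_pc``, ``time_myr``, ``distance_km``.
    """
    with resources.files("pairflow.data").joinpath("sceloporus_pairs.csv").open() as fh:
        return pd.read_csv(fh)


def comparison3_assignments():
    """Other-clade assignment probabilities (percent) for comparison 3.

    The published worked example for the clade 1 vs clade 12 comparison: one
    individual of clade 1 has 2.7% assignment to the other clade and four
    have 0%, while the five individuals of clade 12 have 7.1, 5.3, 5.8, 4.3
    and 3.3%. Averaging the ten gives the pair's mean admixture frequency.
    """
    clade1 = [2.7, 0.0, 0.0, 0.0, 0.0]
    clade12 = [7.1, 5.3, 5.8, 4.3, 3.3]
    return clade1, clade12
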