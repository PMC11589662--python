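"""Assembly of the lineage-pair table.

One row per declared pair of lineages: the two gene-flow statistics at clade
and population level, PC-weighted morphological and climatic divergence,
divergence time (Myr, consumed as input -- optionally extracted from an
ultrametric Newick tree) and the great-circle distance between the clades'
mean coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairDefinition",
    "haversine_km",
    "mean_coordinates",
    "build_pair_table",
    "read_pair_definitions",
    "divergence_times_from_tree",
    "PAIR_TABLE_COLUMNS",
]

#: WGS84 equatorial radius, the default of the geosphere haversine routine.
EARTH_RADIUS_KM = 6378.137

PAIR_TABLE_COLUMNS = [
    "comparison",
    "clade_a",
    "clade_b",
    "n_individuals",
    "n_snps",
    "clade_admixture_mean_freq",
    "clade_admixture_prop_ind",
    "pop_admixture_mean_freq",
    "pop_admixture_prop_ind",
    "morphology_pc",
    "climate_pc",
    "time_myr",
    "distance_km",
]


@dataclass
class PairDefinition:
    pair_id: object
    clade_a: object
    clade_b: object
    divergence_time_myr: float
    population_a: object | None = None
    population_b: object | None = None

    def __post_init__(self):
        if self.clade_a == self.clade_b:
            raise ValueError(f"pair {self.pair_id}: clades must differ")
        if not self.divergence_time_myr > 0:
            raise ValueError(f"pair {self.pair_id}: divergence time must be positive")


def _check_coords(lat, lon):
    lat, lon = np.asarray(lat, float), np.asarray(lon, float)
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise ValueError("coordinates outside valid decimal-degree ranges")
    return lat, lon


def haversine_km(lat1, lon1, lat2, lon2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km on a sphere of ``radius_km``."""
    lat1, lon1 = _check_coords(lat1, lon1)
    lat2, lon2 = _check_coords(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.isscalar(lat1) or d.ndim == 0 else d


def mean_coordinates(meta: pd.DataFrame, unit, unit_col: str = "clade"):
    """Arithmetic mean latitude/longitude of a unit's samples.

    Plain averaging of decimal degrees, not a great-circle centroid; no
    antimeridian handling (documented limitation, irrelevant at the
    regional scales targeted).
    """
    rows = meta[meta[unit_col] == unit]
    if rows.empty:
        raise ValueError(f"no located samples for {unit_col} {unit!r}")
    return float(rows["latitude"].mean()), float(rows["longitude"].mean())


def build_pair_table(
    defs,
    geneflow_clade: dict,
    geneflow_pop: dict,
    morphology: dict,
    climate: dict,
    meta: pd.DataFrame,
    n_snps: dict | None = None,
    radius_km: float = EARTH_RADIUS_KM,
) -> pd.DataFrame:
    """Join all per-pair metrics into the analysis table.

    ``geneflow_clade``/``geneflow_pop`` map pair id to a
    :class:`~pairflow.admixture.GeneFlowEstimate`; ``morphology``/``climate``
    map pair id to a :class:`~pairflow.divergence.DivergenceValue` or plain
    number. Distances use clade-based mean coordinates. Missing metrics
    raise an error listing every gap; output row order follows sorted pair
    ids so the table is invariant to the order of definitions.
    """
    defs = list(defs)
    gaps = []
    for d in defs:
        for name, store in (("clade gene flow", geneflow_clade),
                            ("population gene flow", geneflow_pop),
                            ("morphology divergence", morphology),
                            ("climate divergence", climate)):
            if d.pair_id not in store:
                gaps.append(f"pair {d.pair_id}: {name}")
    if gaps:
        raise ValueError("missing metrics:\n  " + "\n  ".join(gaps))

    def _val(x):
        return float(getattr(x, "value", x))

    rows = []
    for d in sorted(defs, key=lambda d: str(d.pair_id)):
        gc, gp = geneflow_clade[d.pair_id], geneflow_pop[d.pair_id]
        lat_a, lon_a = mean_coordinates(meta, d.clade_a)
        lat_b, lon_b = mean_coordinates(meta, d.clade_b)
        rows.append({
            "comparison": d.pair_id,
            "clade_a": d.clade_a,
            "clade_b": d.clade_b,
            "n_individuals": gc.n_individuals,
            "n_snps": (n_snps or {}).get(d.pair_id, np.nan),
            "clade_admixture_mean_freq": gc.mean_admixture_freq,
            "clade_admixture_prop_ind": gc.prop_admixed,
            "pop_admixture_mean_freq": gp.mean_admixture_freq,
            "pop_admixture_prop_ind": gp.prop_admixed,
            "morphology_pc": _val(morphology[d.pair_id]),
            "climate_pc": _val(climate[d.pair_id]),
            "time_myr": d.divergence_time_myr,
            "distance_km": haversine_km(lat_a, lon_a, lat_b, lon_b, radius_km),
        })
    return pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)


def read_pair_definitions(path) -> list[PairDefinition]:
    """Read pair definitions from CSV (pair_id, clade_a, clade_b,
    divergence_time_myr[, population_a, population_b])."""
    df = pd.read_csv(path)
    defs = []
    for _, r in df.iterrows():
        defs.append(PairDefinition(
            pair_id=r["pair_id"],
            clade_a=r["clade_a"],
            clade_b=r["clade_b"],
            divergence_time_myr=float(r["divergence_time_myr"]),
            population_a=r.get("population_a"),
            population_b=r.get("population_b"),
        ))
    return defs


def divergence_times_from_tree(path, pairs) -> dict:
    """MRCA ages for clade pairs from an ultrametric Newick tree.

    Taxon labels must match clade labels; the age of a pair is the depth of
    the tree minus the depth of the pair's most recent common ancestor
    (valid for ultrametric trees, units as in the tree's branch lengths).
    """
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = True
    tree.encode_bipartitions()
    tree.calc_node_ages(ultrametricity_precision=1e-3)
    out = {}
    for a, b in pairs:
        taxa = [t for t in tree.taxon_namespace if t.label in (str(a), str(b))]
        if len(taxa) != 2:
            raise ValueError(f"tree lacks taxa for pair ({a}, {b})")
        out[(a, b)] = float(tree.mrca(taxa=taxa).age)
    return out
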