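"""Reading/writing the standard formats and the SNP filters.

Genotypes live in a :class:`GenotypeMatrix`: samples x biallelic sites,
diploid alternate-allele counts in {0, 1, 2} stored as floats with NaN for
missing calls, alongside per-site metadata (chrom, pos, ref, alt, qual).

The SNP filter reproduces the three-step screen commonly applied before
clustering analyses of RADseq data: a site is retained when it is called in
at least half of the individuals, has QUAL >= 30 and a minor allele count of
at least 3 among the non-missing calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .admixture import QMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "FormatError",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "per_sample_missingness",
    "read_qmatrix",
    "read_sample_metadata",
    "validate_sample_metadata",
]

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "qual"]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic sites alternate-allele count matrix."""

    samples: list[str]
    sites: pd.DataFrame  # columns SITE_COLUMNS, 1-based VCF positions
    calls: np.ndarray  # float, NaN = missing

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape inconsistent with samples/sites")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("calls must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            self.calls[:, np.asarray(mask)],
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(list(names), self.sites.copy(), self.calls[idx])


def read_vcf(path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF 4.x file.

    Multiallelic records and indels are skipped (a count is logged). VCF's
    1-based positions are preserved in the site table. Raises
    :class:`FormatError` when the file has no GT field.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF contains no samples/GT field")
    rows, cols, skipped = [], [], 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        g = np.empty(len(samples))
        for i, gt in enumerate(v.genotypes):
            alleles = gt[:-1]
            g[i] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((v.CHROM, v.POS, vid, v.REF, v.ALT[0],
                     np.nan if v.QUAL is None else float(v.QUAL)))
        cols.append(g)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    calls = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, sites, calls)


_GT_STR = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 file (GT only, './.' for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, site in g.sites.iterrows():
            qual = "." if pd.isna(site["qual"]) else f"{site['qual']:g}"
            gts = "\t".join(
                "./." if np.isnan(c) else _GT_STR[c] for c in g.calls[:, j]
            )
            fh.write(f"{site['chrom']}\t{site['pos']}\t{site['id']}\t{site['ref']}"
                     f"\t{site['alt']}\t{qual}\t.\t.\tGT\t{gts}\n")


def _minor_allele_count(calls: np.ndarray) -> np.ndarray:
    """Per-site minor allele count over non-missing calls (het counts 1)."""
    called = (~np.isnan(calls)).sum(axis=0)
    alt = np.nansum(calls, axis=0)
    return np.minimum(alt, 2 * called - alt)


def filter_snps(
    g: GenotypeMatrix,
    max_missing_frac: float = 0.5,
    min_quality: float = 30.0,
    min_mac: int = 3,
    allow_missing_qual: bool = False,
) -> GenotypeMatrix:
    """Apply the three-step SNP screen; site order is preserved.

    Retains sites called in at least ``1 - max_missing_frac`` of samples,
    with QUAL >= ``min_quality`` and minor allele count >= ``min_mac``
    (computed over non-missing calls only; heterozygotes contribute one
    alternate allele). Sites with a missing QUAL fail the quality filter
    unless ``allow_missing_qual``. The three criteria commute, so the
    operation is idempotent and order-independent.
    """
    if g.n_sites == 0:
        raise ValueError("empty genotype matrix")
    miss = np.isnan(g.calls).mean(axis=0)
    qual = g.sites["qual"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok_qual = qual >= min_quality
    if allow_missing_qual:
        ok_qual |= np.isnan(qual)
    keep = ((1.0 - miss) >= (1.0 - max_missing_frac)) & ok_qual
    keep &= _minor_allele_count(g.calls) >= min_mac
    if not keep.any():
        warnings.warn("filter_snps removed every site", stacklevel=2)
    return g.take_sites(keep)


def per_sample_missingness(g: GenotypeMatrix) -> pd.Series:
    """Fraction of missing calls per sample."""
    if g.n_sites == 0:
        raise ValueError("empty genotype matrix")
    return pd.Series(np.isnan(g.calls).mean(axis=1), index=g.samples, name="missingness")


def read_qmatrix(path, n_clusters: int, row_sum_tol: float = 1e-3) -> QMatrix:
    """Read a Q-matrix from CSV or clustering-program per-individual output.

    Two layouts are accepted: a CSV whose first column is the sample id
    followed by K probability columns, or the whitespace layout of Bayesian
    clustering programs where label columns precede a ':' and the K
    probabilities follow it. Rows whose sum is within ``row_sum_tol`` of 1
    are renormalised; larger deviations raise :class:`FormatError`.
    """
    samples, rows = [], []
    text = open(path).read().strip().splitlines()
    if any(":" in line for line in text):
        for line in text:
            if ":" not in line:
                continue
            head, tail = line.split(":", 1)
            toks = head.split()
            samples.append(toks[1] if len(toks) > 1 else toks[0])
            rows.append([float(t) for t in tail.split()])
    else:
        df = pd.read_csv(path)
        samples = df.iloc[:, 0].astype(str).tolist()
        rows = df.iloc[:, 1:].to_numpy(dtype=float).tolist()
    q = np.asarray(rows, dtype=float)
    if q.ndim != 2 or q.shape[1] != n_clusters:
        raise FormatError(
            f"{path}: expected {n_clusters} probability columns, found "
            f"{q.shape[1] if q.ndim == 2 else 'ragged rows'}"
        )
    sums = q.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > row_sum_tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise FormatError(f"{path}: row {bad} sums to {sums[bad]:.6f}")
    return QMatrix(samples, q / sums[:, None])


META_COLUMNS = ["sample", "clade", "population", "latitude", "longitude"]


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    if meta["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    lat, lon = meta["latitude"], meta["longitude"]
    if ((lat < -90) | (lat > 90)).any() or ((lon < -180) | (lon > 180)).any():
        raise FormatError("coordinates outside valid ranges")
    return meta


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV
    (sample, clade, population, latitude, longitude)."""
    return validate_sample_metadata(pd.read_csv(path))
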