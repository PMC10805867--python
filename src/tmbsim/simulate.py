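"""Synthetic MAF cohorts with the statistical structure of a pan-cancer
whole-exome call set.

The generator emulates the features the downstream experiments rely on:

* a right-skewed (log-normal) whole-exome TMB distribution with a small
  hypermutator subpopulation multiplied up from the bulk;
* per-mutation ``Variant_Classification`` categories drawn from configured
  proportions (defaults approximate exome class frequencies: mostly
  missense, ~22% silent, a few percent truncating and splice calls);
* clonal variant allele frequencies scaled by per-sample tumor purity,
  VAF = 0.5 x purity x clonal_fraction, observed through negative-binomial
  read depths and binomial alt counts;
* hotspot flags concentrated in a configured subset of genes.

It makes no claim to sequence-level realism: no trinucleotide signatures,
no strand bias, no germline leakage, no FFPE artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    MUTATION_COLUMNS,
    TMB_HIGH,
    TMB_NON_HIGH,
    ValidationError,
)
from .tmb import ComputationRule, classify_tmb, filter_frame

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "CohortConfig",
    "generate_genome",
    "generate_cohort",
    "simulate_real_gene_sets",
    "DEFAULT_CLASS_PROPORTIONS",
]

_BASES = np.array(list("ACGT"))

#: Approximate exome-wide Variant_Classification frequencies.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "Missense_Mutation": 0.62,
    "Silent": 0.22,
    "Nonsense_Mutation": 0.04,
    "Splice_Site": 0.03,
    "Frame_Shift_Del": 0.04,
    "Frame_Shift_Ins": 0.02,
    "In_Frame_Del": 0.015,
    "In_Frame_Ins": 0.005,
    "Nonstop_Mutation": 0.002,
    "Translation_Start_Site": 0.008,
}


@dataclass(frozen=True)
class GeneModel:
    """A gene as a set of non-overlapping, sorted half-open exon intervals."""

    gene_symbol: str
    chromosome: str
    exons: tuple[tuple[int, int], ...]
    exonic_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.gene_symbol} has no exons")
        prev_end = -1
        total = 0
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"gene {self.gene_symbol}: empty exon [{s}, {e})")
            if s < prev_end:
                raise ValidationError(f"gene {self.gene_symbol}: exons overlap or unsorted")
            prev_end = e
            total += e - s
        object.__setattr__(self, "exonic_length", total)


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs to state a cohort.

    TMB parameters are on the natural-log scale of mut/Mb; the defaults give
    a bulk median of ~2.5 mut/Mb with a heavy right tail, plus 3% of samples
    multiplied 10x (hypermutators), which puts a realistic minority of the
    cohort above the 10 mut/Mb TMB-H cutoff.
    """

    n_samples: int = 500
    n_genes: int = 2000
    tmb_log_mean: float = math.log(2.5)
    tmb_log_sd: float = 1.0
    hypermutator_fraction: float = 0.03
    hypermutator_tmb_multiplier: float = 10.0
    purity_range: tuple[float, float] = (0.2, 0.9)
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    hotspot_gene_fraction: float = 0.05
    hotspot_site_rate: float = 0.2
    depth_mean: float = 300.0
    depth_dispersion: float = 5.0
    subclonal_fraction: float = 0.25
    subclonal_vaf_range: tuple[float, float] = (0.1, 1.0)
    mean_exons_per_gene: float = 9.0
    mean_exon_length: float = 160.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_proportions sum to {total}, expected 1")
        for name, p in self.class_proportions.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"class_proportions[{name!r}] = {p} outside [0, 1]")
        for name in (
            "hypermutator_fraction",
            "hotspot_gene_fraction",
            "hotspot_site_rate",
            "subclonal_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} = {v} outside [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError(f"purity_range {self.purity_range} invalid")
        if self.tmb_log_sd <= 0:
            raise ValidationError("tmb_log_sd must be > 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValidationError("depth parameters must be > 0")


def generate_genome(config: CohortConfig) -> list[GeneModel]:
    """Draw a synthetic exome: gene models laid out over 22 autosomes.

    Exon counts are 1 + Poisson, exon lengths log-normal around
    ``mean_exon_length``; genes are placed sequentially with intergenic
    gaps so exons never overlap.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_chroms = min(22, config.n_genes)
    chrom_of = [f"chr{(i % n_chroms) + 1}" for i in range(config.n_genes)]
    cursors = {f"chr{i + 1}": 10_000 for i in range(n_chroms)}
    genes: list[GeneModel] = []
    sigma = 0.6  # log-scale spread of exon lengths
    mu = math.log(config.mean_exon_length) - sigma**2 / 2
    for i in range(config.n_genes):
        chrom = chrom_of[i]
        n_exons = 1 + rng.poisson(config.mean_exons_per_gene - 1)
        lengths = np.maximum(10, rng.lognormal(mu, sigma, size=n_exons).astype(int))
        introns = rng.integers(100, 5_000, size=n_exons)
        pos = cursors[chrom]
        exons = []
        for length, intron in zip(lengths, introns):
            exons.append((pos, pos + int(length)))
            pos += int(length) + int(intron)
        cursors[chrom] = pos + int(rng.integers(5_000, 50_000))
        genes.append(
            GeneModel(gene_symbol=f"GENE{i:05d}", chromosome=chrom, exons=tuple(exons))
        )
    return genes


def _exome_index(genome: Sequence[GeneModel]):
    """Flat arrays mapping a uniform exonic offset to (gene, chrom, position)."""
    starts, ends, gene_idx, chroms = [], [], [], []
    for gi, g in enumerate(genome):
        for s, e in g.exons:
            starts.append(s)
            ends.append(e)
            gene_idx.append(gi)
            chroms.append(g.chromosome)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    lengths = ends - starts
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return starts, np.asarray(gene_idx), np.asarray(chroms), offsets


def exome_size_mb(genome: Sequence[GeneModel]) -> float:
    """Total exonic size of the genome in Mb (sum over genes)."""
    return sum(g.exonic_length for g in genome) / 1e6


def generate_cohort(
    genome: Sequence[GeneModel],
    config: CohortConfig,
    tmb_cutoff: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of tumor samples over a synthetic exome.

    Returns ``(samples, mutations)`` DataFrames.  Each sample draws a latent
    wesTMB from the log-normal (hypermutators multiplied up), a Poisson
    mutation count at that rate over the exome, uniform exonic loci,
    multinomial classes, and VAFs from 0.5 x purity x clonal_fraction
    observed through sampled read depths.  Mutations whose sampled alt count
    is zero are dropped as undetectable.  The stored ``ref_wes_tmb`` is the
    realized FOCR-filtered wesTMB of the emitted records, so recomputing
    wesTMB from the MAF reproduces it exactly.

    ``samples`` columns: sample_id, tumor_purity, ref_wes_tmb, tmb_class,
    latent_tmb.  ``mutations`` columns: the :class:`MutationRecord` schema.
    """
    if len(genome) == 0:
        raise ValidationError("genome must be nonempty")
    rng = np.random.default_rng(config.seed)
    exon_starts, exon_gene, exon_chrom, offsets = _exome_index(genome)
    total_bp = int(offsets[-1])
    exome_mb = total_bp / 1e6
    gene_symbols = np.asarray([g.gene_symbol for g in genome])

    n_hot = int(round(config.hotspot_gene_fraction * len(genome)))
    hotspot_genes = set(rng.choice(len(genome), size=n_hot, replace=False)) if n_hot else set()

    class_names = list(config.class_proportions)
    class_p = np.asarray([config.class_proportions[c] for c in class_names])

    latent = rng.lognormal(config.tmb_log_mean, config.tmb_log_sd, size=config.n_samples)
    hyper = rng.random(config.n_samples) < config.hypermutator_fraction
    latent[hyper] *= config.hypermutator_tmb_multiplier
    purity = rng.uniform(*config.purity_range, size=config.n_samples)

    sample_rows = []
    mut_rows = []
    focr = ComputationRule()  # reference wesTMB rule
    for si in range(config.n_samples):
        sid = f"S{si:05d}"
        n_mut = rng.poisson(latent[si] * exome_mb)
        if n_mut > 0:
            flat = rng.integers(0, total_bp, size=n_mut)
            ei = np.searchsorted(offsets, flat, side="right") - 1
            pos = exon_starts[ei] + (flat - offsets[ei])
            gidx = exon_gene[ei]
            classes = rng.choice(len(class_names), size=n_mut, p=class_p)
            clonal = np.ones(n_mut)
            sub = rng.random(n_mut) < config.subclonal_fraction
            lo, hi = config.subclonal_vaf_range
            clonal[sub] = rng.uniform(lo, hi, size=int(sub.sum()))
            exp_vaf = np.clip(0.5 * purity[si] * clonal, 1e-6, 1.0)
            # NB depth: Gamma-Poisson mixture with shape = dispersion
            shape = config.depth_dispersion
            depth = rng.poisson(rng.gamma(shape, config.depth_mean / shape, size=n_mut))
            depth = np.maximum(depth, 1)
            alt = rng.binomial(depth, exp_vaf)
            keep = alt > 0
            n_dropped = int((~keep).sum())
            if n_dropped:
                logger.debug("sample %s: dropped %d undetectable mutations", sid, n_dropped)
            ref = rng.choice(4, size=n_mut)
            alt_base = (ref + rng.integers(1, 4, size=n_mut)) % 4
            hot = np.zeros(n_mut, dtype=bool)
            in_hot_gene = np.isin(gidx, list(hotspot_genes)) if hotspot_genes else hot
            hot[in_hot_gene] = rng.random(int(in_hot_gene.sum())) < config.hotspot_site_rate
            for j in np.flatnonzero(keep):
                mut_rows.append(
                    (
                        sid,
                        gene_symbols[gidx[j]],
                        exon_chrom[ei[j]],
                        int(pos[j]),
                        _BASES[ref[j]],
                        _BASES[alt_base[j]],
                        class_names[classes[j]],
                        alt[j] / depth[j],
                        int(depth[j]),
                        int(alt[j]),
                        bool(hot[j]),
                    )
                )
        sample_rows.append((sid, float(purity[si]), float(latent[si])))

    mutations = pd.DataFrame(mut_rows, columns=MUTATION_COLUMNS)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "tumor_purity", "latent_tmb"])

    focr_counts = (
        filter_frame(mutations, focr).groupby("sample_id").size()
        if len(mutations)
        else pd.Series(dtype=int)
    )
    samples["ref_wes_tmb"] = (
        samples["sample_id"].map(focr_counts).fillna(0).astype(float) / exome_mb
    )
    samples["tmb_class"] = [
        classify_tmb(t, tmb_cutoff) for t in samples["ref_wes_tmb"]
    ]
    samples = samples[["sample_id", "tumor_purity", "ref_wes_tmb", "tmb_class", "latent_tmb"]]
    return samples, mutations


def simulate_real_gene_sets(
    genome: Sequence[GeneModel],
    n_panels: int = 10,
    size_range: tuple[int, int] = (100, 800),
    popularity_concentration: float = 1.5,
    seed: int = 0,
) -> list[set[str]]:
    """Emulate the gene content of a collection of real commercial panels.

    Panels share a popular core and diverge in the tail: genes get a
    Zipf-like popularity weight and each panel samples its members without
    replacement proportional to that weight, so coverage counts span the
    full range from covered-by-all to covered-by-one.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    ranks = rng.permutation(n) + 1
    weights = 1.0 / ranks.astype(float) ** popularity_concentration
    weights /= weights.sum()
    symbols = np.asarray([g.gene_symbol for g in genome])
    out = []
    for _ in range(n_panels):
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        k = min(k, n)
        chosen = rng.choice(n, size=k, replace=False, p=weights)
        out.append(set(symbols[chosen]))
    return out
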