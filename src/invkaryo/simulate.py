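"""Synthetic diploid cohorts with inversion-linked structure.

The generator produces genotype matrices whose statistical features mirror
what the karyotyping pipeline consumes in real population-genomic cohorts:

* three karyotype classes (0/1/2 copies of the inverted arrangement) drawn
  under Hardy-Weinberg from a per-population inversion frequency;
* a subset of in-inversion sites fixed-different between arrangements, with
  the alternate allele riding the inverted arrangement (the reference
  genome carries the standard arrangement), eroded by gene flux;
* breakpoint-flanking sites in linkage with the arrangement, supporting
  distance-tree analyses;
* taxon-level background allele-frequency differentiation;
* genotyping artifacts applied in order: genotype error, then low-coverage
  heterozygote dropout (a true het read as a random homozygote), then
  missingness; and a per-cell GQ layer.

The model is allele-frequency based with per-site independence: it is not a
coalescent simulation and carries no linkage disequilibrium beyond the
arrangement itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geno_io
from .types import MISSING, ConfigError, GenotypeMatrix, InversionDef, SampleRecord


@dataclass
class Population:
    """One sampled population: name, taxon label, size, inversion frequency."""

    name: str
    taxon: str = "gambiae"
    n: int = 100
    p: float = 0.4  # frequency of the inverted arrangement

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ConfigError(f"inversion frequency must be in [0,1], got {self.p}")
        if self.n < 0:
            raise ConfigError("population size must be non-negative")


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Defaults describe a single mid-frequency inversion polymorphism in one
    population: 600 diploids, inversion frequency 0.4, 2,000 in-span SNPs of
    which 5% are fixed-different between arrangements, no genotyping
    artifacts. Artifact rates are opt-in so that clean runs are exactly
    noiseless.
    """

    populations: list[Population] = field(
        default_factory=lambda: [Population("pop1", "gambiae", 600, 0.4)]
    )
    inversion_name: str = "2Rx"
    chrom: str = "2R"
    span: tuple[int, int] = (3_000_000, 4_000_000)
    flank: int = 5_000
    n_sites_inversion: int = 2_000
    n_sites_flank: int = 200
    frac_fixed_diff: float = 0.05
    frac_fixed_diff_flank: float | None = None  # defaults to frac_fixed_diff
    frac_taxon_diff: float = 0.0
    gene_flux: float = 0.0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    het_dropout: float = 0.0
    gq_mean: float = 45.0
    gq_sd: float = 10.0
    gq_correlated: bool = False  # if set, erroneous/dropped genotypes get low GQ
    cyt_fraction: float = 0.25  # share of samples with a cytogenetic karyotype
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("frac_fixed_diff", "frac_taxon_diff", "gene_flux", "error_rate",
                   "missing_rate", "het_dropout", "cyt_fraction"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{nm} must be in [0,1], got {v}")
        if self.n_sites_inversion < 0 or self.n_sites_flank < 0:
            raise ConfigError("site counts must be non-negative")
        if self.frac_fixed_diff_flank is None:
            self.frac_fixed_diff_flank = self.frac_fixed_diff


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated cohort."""

    true_dose: dict[str, int]
    diagnostic_sites: list[int]  # column indices of in-span fixed-diff sites
    flank_diagnostic_sites: list[int]  # arrangement-linked breakpoint-flank sites
    params: SimParams


def _rand_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_off = rng.integers(1, 4, size=n)
    return bases[ref_idx], bases[(ref_idx + alt_off) % 4]


def simulate_cohort(
    params: SimParams, seed: int | None = None
) -> tuple[GenotypeMatrix, SimTruth, list[SampleRecord]]:
    """Draw a synthetic cohort; fully reproducible from the seed.

    Per sample, the inversion dose is Binomial(2, p) for its population's
    inversion frequency p. Haplotype alleles at diagnostic sites follow the
    arrangement (alternate allele = inverted), flipped with probability
    ``gene_flux``; neutral sites draw from shared (or taxon-shifted)
    frequencies. Artifacts are applied genotype error -> het dropout ->
    missingness, then GQ is drawn per cell.
    """
    n_samples = sum(pop.n for pop in params.populations)
    n_inv, n_flank = params.n_sites_inversion, params.n_sites_flank
    if n_samples == 0 or (n_inv + n_flank) == 0:
        raise ConfigError("simulation needs at least one sample and one site")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    # -- samples ---------------------------------------------------------
    sample_ids, taxa, pops = [], [], []
    dose = np.empty(n_samples, dtype=np.int16)
    i0 = 0
    for pop in params.populations:
        ids = [f"{pop.name}_{k:04d}" for k in range(pop.n)]
        sample_ids += ids
        taxa += [pop.taxon] * pop.n
        pops += [pop.name] * pop.n
        dose[i0:i0 + pop.n] = rng.binomial(2, pop.p, size=pop.n)
        i0 += pop.n
    taxa_arr = np.array(taxa)

    # -- site coordinates ------------------------------------------------
    start, end = params.span
    span_len = end - start + 1
    if n_inv > span_len or n_flank > 2 * params.flank:
        raise ConfigError("more sites requested than available positions")
    inv_pos = np.sort(rng.choice(span_len, size=n_inv, replace=False)) + start
    n_up = n_flank // 2
    up_pos = np.sort(rng.choice(params.flank, size=n_up, replace=False)) + (start - params.flank)
    down_pos = np.sort(rng.choice(params.flank, size=n_flank - n_up, replace=False)) + end + 1
    positions = np.concatenate([up_pos, inv_pos, down_pos])
    is_inv_site = np.zeros(len(positions), dtype=bool)
    is_inv_site[n_up:n_up + n_inv] = True
    n_sites = len(positions)

    # -- site roles ------------------------------------------------------
    inv_idx = np.flatnonzero(is_inv_site)
    flank_idx = np.flatnonzero(~is_inv_site)
    n_diag = int(round(params.frac_fixed_diff * n_inv))
    diag = np.sort(rng.choice(inv_idx, size=n_diag, replace=False)) if n_diag else np.array([], int)
    n_fdiag = int(round(params.frac_fixed_diff_flank * n_flank))
    fdiag = np.sort(rng.choice(flank_idx, size=n_fdiag, replace=False)) if n_fdiag else np.array([], int)
    diag_mask = np.zeros(n_sites, dtype=bool)
    diag_mask[diag] = True
    diag_mask[fdiag] = True

    neutral_idx = np.flatnonzero(~diag_mask)
    base_freq = rng.uniform(0.05, 0.95, size=n_sites)
    taxon_site = np.zeros(n_sites, dtype=bool)
    if params.frac_taxon_diff > 0 and len(neutral_idx):
        n_tax = int(round(params.frac_taxon_diff * len(neutral_idx)))
        taxon_site[rng.choice(neutral_idx, size=n_tax, replace=False)] = True
    uniq_taxa = sorted(set(taxa))
    taxon_freq = {t: base_freq.copy() for t in uniq_taxa}
    for t in uniq_taxa:
        taxon_freq[t][taxon_site] = rng.uniform(0.05, 0.95, size=int(taxon_site.sum()))

    # -- genotypes -------------------------------------------------------
    alt = np.empty((n_samples, n_sites), dtype=np.int16)
    # neutral / taxon-shifted sites: Binomial(2, f_taxon)
    for t in uniq_taxa:
        rows = np.flatnonzero(taxa_arr == t)
        alt[np.ix_(rows, neutral_idx)] = rng.binomial(
            2, taxon_freq[t][neutral_idx][None, :], size=(len(rows), len(neutral_idx))
        )
    # diagnostic sites: alt allele rides the inverted arrangement, with leakage
    dmask = np.flatnonzero(diag_mask)
    if len(dmask):
        k = dose[:, None].astype(np.int64)
        shape = (n_samples, len(dmask))
        leaked_inv = rng.binomial(np.broadcast_to(k, shape), params.gene_flux)
        leaked_std = rng.binomial(np.broadcast_to(2 - k, shape), params.gene_flux)
        alt[:, dmask] = (k - leaked_inv + leaked_std).astype(np.int16)

    # -- artifacts: error -> het dropout -> missingness ------------------
    err_mask = np.zeros_like(alt, dtype=bool)
    drop_mask = np.zeros_like(alt, dtype=bool)
    if params.error_rate > 0:
        err_mask = rng.random(alt.shape) < params.error_rate
        alt[err_mask] = rng.integers(0, 3, size=int(err_mask.sum()))
    if params.het_dropout > 0:
        drop_mask = (alt == 1) & (rng.random(alt.shape) < params.het_dropout)
        alt[drop_mask] = 2 * rng.integers(0, 2, size=int(drop_mask.sum()))
    if params.missing_rate > 0:
        miss_mask = rng.random(alt.shape) < params.missing_rate
        alt[miss_mask] = MISSING

    gq = np.rint(rng.normal(params.gq_mean, params.gq_sd, size=alt.shape))
    if params.gq_correlated:
        bad = err_mask | drop_mask
        gq[bad] = np.rint(rng.uniform(0, 15, size=int(bad.sum())))
    gq = np.clip(gq, 0, 99).astype(np.int32)

    ref_al, alt_al = _rand_alleles(rng, n_sites)
    sites = pd.DataFrame(
        {"chrom": params.chrom, "pos": positions, "ref": ref_al, "alt": alt_al}
    )
    gm = GenotypeMatrix(samples=sample_ids, sites=sites, alt_counts=alt, gq=gq)

    # -- metadata & truth ------------------------------------------------
    has_cyt = rng.random(n_samples) < params.cyt_fraction
    miss_2r = dict(
        zip(gm.samples, (gm.alt_counts == MISSING).sum(axis=1).astype(int))
    )
    records = [
        SampleRecord(
            sample_id=s,
            taxon=taxa[i],
            population=pops[i],
            country="SIM",
            cyt_karyotypes={params.inversion_name: int(dose[i])} if has_cyt[i] else {},
            wga=False,
            missing_2R=int(miss_2r[s]),
        )
        for i, s in enumerate(sample_ids)
    ]
    truth = SimTruth(
        true_dose={s: int(dose[i]) for i, s in enumerate(sample_ids)},
        diagnostic_sites=[int(j) for j in diag],
        flank_diagnostic_sites=[int(j) for j in fdiag],
        params=params,
    )
    return gm, truth, records


def inversion_def(params: SimParams) -> InversionDef:
    """The inversion definition matching a simulated cohort's span."""
    return InversionDef(
        name=params.inversion_name,
        chrom=params.chrom,
        span=params.span,
        breakpoints=params.span,
        flank=params.flank,
    )


def write_cohort(
    gm: GenotypeMatrix,
    truth: SimTruth,
    metadata: list[SampleRecord],
    outdir: str | Path,
) -> dict[str, Path]:
    """Serialise a simulated cohort: VCF, metadata TSV, truth TSV, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "inversions.yaml",
    }
    geno_io.write_vcf(gm, paths["vcf"])
    geno_io.write_metadata(metadata, paths["metadata"],
                           inversions=[truth.params.inversion_name])
    sites = gm.sites
    diag_rows = [
        {"site_index": j, "chrom": sites.iloc[j]["chrom"], "pos": int(sites.iloc[j]["pos"]),
         "kind": "inversion" if j in set(truth.diagnostic_sites) else "flank"}
        for j in list(truth.diagnostic_sites) + list(truth.flank_diagnostic_sites)
    ]
    pd.DataFrame(
        {"sample_id": list(truth.true_dose), "true_dose": list(truth.true_dose.values())}
    ).to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(diag_rows).to_csv(outdir / "diagnostic_sites.tsv", sep="\t", index=False)
    geno_io.write_inversion_config(
        {truth.params.inversion_name: inversion_def(truth.params)}, paths["config"]
    )
    return paths
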