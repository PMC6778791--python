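"""Discovery of tag SNPs predictive of inversion orientation.

A tag SNP is a biallelic variant whose alternate-allele count matches the
inversion dose (the reference assembly carries the standard arrangement, so
the alternate allele is expected to mark the inverted one). Candidate tags
are found on a training partition of PCA-karyotyped samples, through ten
"bootstrap" replicates — stratified 75% subsamples drawn without
replacement — with concordance and call rate computed separately per
karyotype class to guard against class imbalance. Per site, class-wise
statistics are averaged over the replicates in which the site was
evaluated, and the conservative summary statistic is the minimum of the
three class-mean concordances.

Selection keeps sites that were (i) evaluated in at least ``min_reps``
replicates, (ii) called at a rate strictly greater than the call-rate
threshold in every class, and (iii) concordant strictly more often than the
per-inversion concordance threshold in every class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import geno_io
from .types import MISSING, DataError, GenotypeMatrix, InversionDef

DOSES = (0, 1, 2)

PANEL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "n_reps",
    "conc0", "conc1", "conc2", "min_conc",
    "cr0", "cr1", "cr2", "partition",
]


@dataclass
class SplitPlan:
    """A stratified train/validation split of karyotyped samples."""

    train_ids: list[str]
    validation_ids: list[str]
    fraction: float
    seed: int


class TagSnp(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str
    n_reps: int
    conc_by_class: tuple[float, float, float]
    callrate_by_class: tuple[float, float, float]
    min_concordance: float


def _allocate(class_sizes: list[int], fraction: float) -> list[int]:
    """Per-class take counts: floor + largest-remainder so the total matches
    round(fraction * n). Ties break toward the lower class index."""
    target_total = int(round(fraction * sum(class_sizes)))
    raw = [fraction * s for s in class_sizes]
    base = [int(np.floor(r)) for r in raw]
    base = [min(b, s) for b, s in zip(base, class_sizes)]
    leftover = target_total - sum(base)
    remainders = sorted(
        range(len(class_sizes)), key=lambda i: (-(raw[i] - base[i]), i)
    )
    for i in remainders:
        if leftover <= 0:
            break
        if base[i] < class_sizes[i]:
            base[i] += 1
            leftover -= 1
    return base


def stratified_split(
    samples: list[str],
    doses: Mapping[str, int],
    fraction: float = 0.75,
    seed: int = 0,
) -> SplitPlan:
    """Partition samples into train/validation, balanced by inversion dose.

    Per dose class, ``round(fraction x class size)`` samples (largest-
    remainder corrected so the overall train share matches) go to training;
    the split is otherwise random and deterministic per seed.
    """
    classes: dict[int, list[str]] = {}
    for s in samples:
        d = doses[s]
        if d not in DOSES:
            raise DataError(f"sample {s} has dose {d!r}; expected 0/1/2")
        classes.setdefault(d, []).append(s)
    for d, members in classes.items():
        if len(members) < 2:
            raise DataError(f"dose class {d} too small to stratify ({len(members)} sample(s))")
    keys = sorted(classes)
    counts = _allocate([len(classes[d]) for d in keys], fraction)
    rng = np.random.default_rng(seed)
    train, valid = [], []
    for d, k in zip(keys, counts):
        members = classes[d]
        perm = rng.permutation(len(members))
        chosen = set(perm[:k].tolist())
        for idx, s in enumerate(members):
            (train if idx in chosen else valid).append(s)
    order = {s: i for i, s in enumerate(samples)}
    train.sort(key=order.get)
    valid.sort(key=order.get)
    return SplitPlan(train_ids=train, validation_ids=valid, fraction=fraction, seed=seed)


def bootstrap_subsamples(
    train_ids: list[str],
    doses: Mapping[str, int],
    n_reps: int = 10,
    fraction: float = 0.75,
    seed: int = 0,
) -> list[list[str]]:
    """Stratified subsamples of the training set, one per replicate.

    Each replicate is a without-replacement draw of ``fraction`` of the
    training samples, preserving dose-class balance (the same allocation
    rule as :func:`stratified_split`). Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        plan = stratified_split(
            train_ids, doses, fraction=fraction, seed=int(rng.integers(0, 2**31 - 1))
        )
        reps.append(plan.train_ids)
    return reps


def concordance_per_class(
    gm: GenotypeMatrix, doses: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site, per-dose-class concordance and call rate.

    For class k: call rate is the fraction of class-k samples with a
    non-missing genotype; concordance is the fraction of *non-missing*
    class-k samples whose alternate-allele count equals k (missingness is
    measured by the call rate, not folded into concordance). Entries are
    NaN where a class is absent or entirely missing at a site.

    Returns ``(conc, callrate)`` arrays of shape ``(n_sites, 3)``.
    """
    dose_arr = np.array([doses[s] for s in gm.samples])
    conc = np.full((gm.n_sites, 3), np.nan)
    cr = np.full((gm.n_sites, 3), np.nan)
    for k in DOSES:
        members = dose_arr == k
        if not members.any():
            continue
        sub = gm.alt_counts[members]
        nonmiss = sub != MISSING
        denom = nonmiss.sum(axis=0).astype(float)
        cr[:, k] = denom / members.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            conc[:, k] = np.where(denom > 0, ((sub == k) & nonmiss).sum(axis=0) / denom, np.nan)
    return conc, cr


def evaluate_replicate(
    gm: GenotypeMatrix,
    doses: Mapping[str, int],
    replicate_ids: list[str],
    maf_min: float,
    maf_mode: str = "minor",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Statistics of one bootstrap replicate.

    A site counts as *evaluated* in the replicate when it passes the
    in-replicate MAF filter (recomputed on the subsample — this is what
    makes a site droppable from some replicates) and every dose class has
    at least one non-missing call. Replicates missing an entire dose class
    evaluate nothing.

    Returns ``(evaluated mask, conc, callrate)``.
    """
    sub = gm.take_samples(replicate_ids)
    dose_arr = np.array([doses[s] for s in replicate_ids])
    evaluated = np.zeros(gm.n_sites, dtype=bool)
    conc = np.full((gm.n_sites, 3), np.nan)
    cr = np.full((gm.n_sites, 3), np.nan)
    if any((dose_arr == k).sum() == 0 for k in DOSES):
        return evaluated, conc, cr
    alt_freq, minor_freq, _ = geno_io._allele_freqs(sub)
    freq = alt_freq if maf_mode == "alternate" else minor_freq
    conc, cr = concordance_per_class(sub, doses)
    evaluated = (freq >= maf_min) & ~np.isnan(conc).any(axis=1)
    return evaluated, conc, cr


def aggregate_replicates(
    sites: pd.DataFrame,
    replicate_stats: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    partition: str = "all",
) -> pd.DataFrame:
    """Average per-class statistics over the replicates where each site was
    evaluated; the summary statistic is the minimum of the three class-mean
    concordances."""
    if not replicate_stats:
        raise DataError("need at least one replicate")
    ev = np.stack([e for e, _, _ in replicate_stats])          # (reps, sites)
    conc = np.stack([c for _, c, _ in replicate_stats])        # (reps, sites, 3)
    cr = np.stack([r for _, _, r in replicate_stats])
    n_reps = ev.sum(axis=0)
    w = ev[:, :, None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc_mean = np.nansum(np.where(w > 0, conc, 0.0) * w, axis=0) / np.maximum(
            n_reps[:, None], 1
        )
        cr_mean = np.nansum(np.where(w > 0, cr, 0.0) * w, axis=0) / np.maximum(
            n_reps[:, None], 1
        )
    conc_mean[n_reps == 0] = np.nan
    cr_mean[n_reps == 0] = np.nan
    out = sites.reset_index(drop=True).copy()
    out["n_reps"] = n_reps.astype(int)
    for k in DOSES:
        out[f"conc{k}"] = conc_mean[:, k]
        out[f"cr{k}"] = cr_mean[:, k]
    out["min_conc"] = conc_mean.min(axis=1)
    out["partition"] = partition
    return out[PANEL_COLUMNS]


def select_tags(
    panel: pd.DataFrame,
    min_reps: int = 8,
    callrate_min: float = 0.90,
    concordance_min: float = 0.80,
) -> pd.DataFrame:
    """Apply the three tag-selection criteria (strict inequalities for the
    rate thresholds): evaluated in >= ``min_reps`` replicates; every class
    call rate > ``callrate_min``; every class concordance >
    ``concordance_min``."""
    ok = panel["n_reps"] >= min_reps
    for k in DOSES:
        ok &= panel[f"cr{k}"] > callrate_min
        ok &= panel[f"conc{k}"] > concordance_min
    return panel.loc[ok.fillna(False)].reset_index(drop=True)


def discover(
    gm: GenotypeMatrix,
    inv: InversionDef,
    doses: Mapping[str, int],
    partition_of: Mapping[str, str] | None = None,
    train_fraction: float = 0.75,
    n_reps: int = 10,
    subsample_fraction: float = 0.75,
    gq_min: int = 20,
    min_reps: int = 8,
    callrate_min: float = 0.90,
    seed: int = 0,
    maf_mode: str = "minor",
) -> dict[str, dict]:
    """End-to-end tag discovery for one inversion.

    ``doses`` maps sample id to its (PCA-imputed) inversion dose; samples
    without a dose are ignored. ``partition_of`` optionally assigns each
    sample to a named partition (e.g. by taxon); discovery then runs
    independently per partition and panels are never merged — taxon
    structure can make tags private to one taxon.

    Returns, per partition: ``{"panel": all aggregated sites, "selected":
    the tag panel, "split": SplitPlan}``.
    """
    in_span = geno_io.site_filter(
        gm, spans=[inv.span], exclusions=inv.exclusion_spans, chrom=inv.chrom
    )
    if in_span.gq is not None:
        in_span = geno_io.mask_low_gq(in_span, gq_min=gq_min)
    karyotyped = [s for s in gm.samples if doses.get(s) in DOSES]
    if partition_of is None:
        groups = {"all": karyotyped}
    else:
        groups = {}
        for s in karyotyped:
            groups.setdefault(partition_of.get(s, "all"), []).append(s)

    results: dict[str, dict] = {}
    rng = np.random.default_rng(seed)
    for name in sorted(groups):
        members = groups[name]
        part_seed = int(rng.integers(0, 2**31 - 1))
        split = stratified_split(members, doses, fraction=train_fraction, seed=part_seed)
        reps = bootstrap_subsamples(
            split.train_ids, doses, n_reps=n_reps,
            fraction=subsample_fraction, seed=part_seed,
        )
        stats = [
            evaluate_replicate(in_span, doses, rep, inv.maf_min_tags, maf_mode=maf_mode)
            for rep in reps
        ]
        panel = aggregate_replicates(in_span.sites, stats, partition=name)
        selected = select_tags(
            panel, min_reps=min_reps, callrate_min=callrate_min,
            concordance_min=inv.concordance_threshold,
        )
        results[name] = {"panel": panel, "selected": selected, "split": split}
    return results


def write_panel(panel: pd.DataFrame, path, *, thresholds: dict | None = None,
                seed: int | None = None, maf_mode: str = "minor") -> None:
    """Write a tag panel TSV with a provenance header."""
    with open(path, "w") as fh:
        if thresholds:
            fh.write("# thresholds: " + ", ".join(f"{k}={v}" for k, v in thresholds.items()) + "\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        fh.write(f"# maf_mode: {maf_mode}\n")
        panel.to_csv(fh, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
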