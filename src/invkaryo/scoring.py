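"""Computational karyotyping of samples from a tag-SNP panel.

Each sample's *computational karyotype score* is the mean alternate-allele
count across the panel tags that could be ascertained (non-missing genotype
passing the GQ mask). Scores cluster near the genotypic optima 0, 1 and 2;
a dose is assigned by rounding, with ties at 0.5 and 1.5 resolving to the
heterozygote (the direction low-coverage artifacts push away from). The
*supporting-tag fraction* — the share of scored tags whose genotype equals
the assigned dose — flags low-confidence calls: heterozygotes genotyped at
low coverage keep a mean near 1 while their supporting fraction collapses,
because true heterozygous sites are often read as one or the other
homozygote.

Panels discovered within one taxon partition should not be applied across
taxa; a taxon-mismatch flag is raised (the score is still reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import warnings

from .types import MISSING, ConfigError, GenotypeMatrix, SampleRecord


@dataclass
class KaryotypeScore:
    """Per-sample, per-inversion computational karyotype call."""

    sample_id: str
    inversion: str
    n_tags_scored: int
    mean_score: float | None           # None = no tags ascertained (no call)
    assigned_dose: int | None
    supporting_fraction: float | None
    flags: list[str] = field(default_factory=list)


def assign_dose(mean_score: float, counts: Mapping[int, int]) -> tuple[int, float]:
    """Round a mean score to a dose and compute the supporting-tag fraction.

    Boundary convention: [0, 0.5) -> 0, [0.5, 1.5] -> 1, (1.5, 2] -> 2
    (ties resolve toward the heterozygote). ``counts`` maps each genotype
    value 0/1/2 to its count among scored tags.
    """
    if mean_score < 0.5:
        dose = 0
    elif mean_score <= 1.5:
        dose = 1
    else:
        dose = 2
    total = sum(counts.values())
    support = counts.get(dose, 0) / total if total else 0.0
    return dose, support


def score_sample(
    alt_counts: np.ndarray,
    gq: np.ndarray | None = None,
    gq_min: int = 20,
    sample_id: str = "",
    inversion: str = "",
) -> KaryotypeScore:
    """Score one sample over one panel's tag genotypes.

    ``alt_counts`` holds the sample's genotypes at the panel sites, already
    matched by (chrom, pos, ref, alt). Tags with a missing genotype, or a
    GQ strictly below ``gq_min``, are excluded from the mean. Zero
    ascertained tags yields an explicit no-call.
    """
    alt_counts = np.asarray(alt_counts)
    ok = alt_counts != MISSING
    if gq is not None:
        gq = np.asarray(gq)
        ok &= ~((gq != MISSING) & (gq < gq_min))
    scored = alt_counts[ok]
    n = int(ok.sum())
    if n == 0:
        return KaryotypeScore(sample_id, inversion, 0, None, None, None, ["no_call"])
    mean = float(scored.mean())
    counts = {k: int((scored == k).sum()) for k in (0, 1, 2)}
    dose, support = assign_dose(mean, counts)
    return KaryotypeScore(sample_id, inversion, n, mean, dose, support)


def match_panel(gm: GenotypeMatrix, panel: pd.DataFrame) -> np.ndarray:
    """Indices of matrix sites matching panel tags by (chrom, pos, ref, alt).

    A site at a tag's position with different alleles is excluded with a
    warning — allele polarity is the entire information content of a tag.
    """
    key = {(r.chrom, int(r.pos), r.ref, r.alt): None for r in panel.itertuples(index=False)}
    pos_only = {(r.chrom, int(r.pos)) for r in panel.itertuples(index=False)}
    idx = []
    for j, site in enumerate(gm.sites.itertuples(index=False)):
        k = (site.chrom, int(site.pos), site.ref, site.alt)
        if k in key:
            idx.append(j)
        elif (site.chrom, int(site.pos)) in pos_only:
            warnings.warn(
                f"allele mismatch at {site.chrom}:{site.pos}; tag excluded", stacklevel=2
            )
    return np.array(idx, dtype=int)


def batch_karyotype(
    gm: GenotypeMatrix,
    panels: Mapping[str, pd.DataFrame],
    metadata: list[SampleRecord] | None = None,
    gq_min: int = 20,
    low_tag_floor: int = 10,
) -> pd.DataFrame:
    """Score every sample against every inversion panel.

    ``panels`` maps inversion name to its tag panel (with a ``partition``
    column when discovery was taxon-partitioned). Heterospecific use is
    flagged, not blocked: a sample whose taxon differs from a panel's
    partition gets ``taxon_mismatch``. Calls resting on fewer than
    ``low_tag_floor`` ascertained tags get ``low_tag_count``.
    """
    taxon_of = {r.sample_id: r.taxon for r in (metadata or [])}
    rows = []
    for inv_name, panel in panels.items():
        if panel is None or not len(panel):
            raise ConfigError(f"empty or unknown panel for inversion {inv_name!r}")
        idx = match_panel(gm, panel)
        partitions = set(panel["partition"].unique()) if "partition" in panel else {"all"}
        partition = next(iter(partitions)) if len(partitions) == 1 else "mixed"
        sub_ac = gm.alt_counts[:, idx]
        sub_gq = gm.gq[:, idx] if gm.gq is not None else None
        for i, sid in enumerate(gm.samples):
            ks = score_sample(
                sub_ac[i],
                sub_gq[i] if sub_gq is not None else None,
                gq_min=gq_min,
                sample_id=sid,
                inversion=inv_name,
            )
            if ks.n_tags_scored and ks.n_tags_scored < low_tag_floor:
                ks.flags.append("low_tag_count")
            taxon = taxon_of.get(sid)
            if (
                taxon is not None
                and partition not in ("all", "both", "mixed")
                and taxon != partition
            ):
                ks.flags.append("taxon_mismatch")
            rows.append(
                {
                    "sample_id": ks.sample_id,
                    "inversion": ks.inversion,
                    "n_tags_scored": ks.n_tags_scored,
                    "mean_score": ks.mean_score,
                    "assigned_dose": ks.assigned_dose,
                    "supporting_fraction": ks.supporting_fraction,
                    "flags": ";".join(ks.flags),
                }
            )
    return pd.DataFrame(rows)
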