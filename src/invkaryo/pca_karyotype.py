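"""Karyotype imputation by local PCA.

PCA restricted to SNPs inside an inversion's span separates samples into
three clusters ("stripes") along the leading principal component: the two
flank stripes are the alternative homokaryotypes and the middle stripe the
heterokaryotype, which is geometrically a 1:1 admixture of the two
homokaryotype classes. Stripe identity is anchored either by specimens with
cytogenetically determined karyotypes or, failing that, by reference
polarity: the reference genome carries the standard (uninverted)
arrangement, so the stripe with the lower mean alternate-allele count is
the standard homokaryotype (dose 0).

Stripe assignment is algorithmic — one-dimensional 3-means on PC1 with
deterministic initialisation — with a silhouette floor standing in for the
visual judgement that stripes are "discernable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import geno_io
from .types import MISSING, DataError, GenotypeMatrix, InversionDef, SampleRecord

STRIPES = ("A", "B", "C")  # ordered along increasing PC1


@dataclass
class StripeDiagnostics:
    silhouette: float
    failed: bool
    centers: np.ndarray
    counts: dict[str, int]
    conflict: str | None = None


@dataclass
class PcaKaryotypeResult:
    """Per-sample local-PCA karyotyping outcome."""

    sample_id: str
    pc1: float
    pc2: float
    stripe: str | None          # 'A'/'B'/'C' or None when clustering failed
    imputed_dose: int | None    # 0/1/2, None when the stripe is unanchored
    anchor_source: str          # 'cytogenetic' | 'reference_polarity' | 'none'


def select_inversion_sites(gm: GenotypeMatrix, inv: InversionDef) -> GenotypeMatrix:
    """Sites inside the inversion span passing the PCA polymorphism filters.

    Applies the inversion's MAF/MAC thresholds (alternate-allele frequency
    for this stage) and drops sites within exclusion spans, e.g. the span of
    a nested inversion.
    """
    sub = geno_io.site_filter(
        gm,
        maf_min=inv.maf_min_pca,
        mac_min=inv.mac_min_pca,
        spans=[inv.span],
        exclusions=inv.exclusion_spans,
        chrom=inv.chrom,
        maf_mode="alternate",
    )
    if sub.n_sites < 2:
        raise DataError(
            f"inversion {inv.name} not analyzable: {sub.n_sites} site(s) survive filters"
        )
    return sub


def _impute_and_center(ac: np.ndarray, scale: bool = False) -> np.ndarray:
    X = ac.astype(float)
    miss = ac == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X = np.where(miss, col_mean[None, :], X)
    X -= col_mean[None, :]
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X /= sd[None, :]
    return X


def local_pca(gm: GenotypeMatrix, n_components: int = 2, scale: bool = False) -> np.ndarray:
    """PCA of the alternate-allele count matrix.

    Missing cells are mean-imputed per site; sites are centered (variance
    standardisation is off by default, preserving the exact rank-1 dose
    geometry). Components are ordered by decreasing explained variance.
    Eigenvector sign is fixed: PC1 correlates positively with per-sample
    mean alternate-allele count; further PCs have their largest-magnitude
    sample coordinate positive.
    """
    if gm.n_samples < 3 or gm.n_sites < 2:
        raise DataError("local_pca needs >= 3 samples and >= 2 sites")
    X = _impute_and_center(gm.alt_counts, scale=scale)
    if not np.any(X):
        raise DataError("no variation: genotype matrix is constant after centering")
    n_components = min(n_components, min(X.shape))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_components] * S[:n_components]
    mean_alt = np.where(gm.alt_counts == MISSING, np.nan, gm.alt_counts.astype(float))
    mean_alt = np.nanmean(np.nan_to_num(mean_alt, nan=0.0), axis=1)
    for k in range(coords.shape[1]):
        c = coords[:, k]
        if k == 0:
            r = np.dot(c - c.mean(), mean_alt - mean_alt.mean())
            sign = np.sign(r) if r != 0 else np.sign(c[np.argmax(np.abs(c))])
        else:
            sign = np.sign(c[np.argmax(np.abs(c))])
        if sign < 0:
            coords[:, k] = -c
    return coords


def cluster_stripes(
    pc_coords: np.ndarray,
    silhouette_floor: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, StripeDiagnostics]:
    """Partition samples into three stripes along PC1.

    One-dimensional 3-means initialised at the minimum, median and maximum
    of PC1. The silhouette score on PC1 is the separation diagnostic;
    clustering is declared failed below ``silhouette_floor`` (stripes not
    discernable) and all labels are returned unassigned.
    """
    pc_coords = np.atleast_2d(np.asarray(pc_coords, dtype=float))
    if pc_coords.shape[0] == 1:
        pc_coords = pc_coords.T
    pc1 = pc_coords[:, 0]
    n = len(pc1)
    if n < 3:
        raise DataError("need >= 3 samples to fit three stripes")
    if np.ptp(pc1) == 0:
        diag = StripeDiagnostics(0.0, True, np.array([pc1[0]] * 3), {s: 0 for s in STRIPES})
        return np.full(n, None, dtype=object), diag
    init = np.array([[pc1.min()], [np.median(pc1)], [pc1.max()]])
    km = KMeans(n_clusters=3, init=init, n_init=1, random_state=seed)
    raw = km.fit_predict(pc1[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = {int(old): STRIPES[rank] for rank, old in enumerate(order)}
    labels = np.array([relabel[int(r)] for r in raw], dtype=object)
    if len(set(raw)) < 2:
        sil = 0.0
    else:
        sil = float(silhouette_score(pc1[:, None], raw))
    centers = km.cluster_centers_.ravel()[order]
    counts = {s: int((labels == s).sum()) for s in STRIPES}
    failed = sil < silhouette_floor or len(set(raw)) < 3
    if failed:
        labels = np.full(n, None, dtype=object)
    return labels, StripeDiagnostics(sil, failed, centers, counts)


def anchor_and_assign(
    gm: GenotypeMatrix,
    pc_coords: np.ndarray,
    labels: np.ndarray,
    diagnostics: StripeDiagnostics,
    cyt: dict[str, int] | None = None,
    anchor_tolerance: float = 0.05,
) -> list[PcaKaryotypeResult]:
    """Map stripes to inversion doses using cytogenetic anchors.

    The middle stripe is always the heterokaryotype (dose 1). Flank-stripe
    polarity comes from anchored homokaryotypes; anchors may disagree with
    their stripe up to ``anchor_tolerance`` (absorbing known cytogenetic
    error) before a conflict is declared and the flank stripes are left
    unassigned. With no usable anchors, polarity falls back to the
    reference convention: the stripe with lower mean alternate-allele count
    is the standard homokaryotype (dose 0).
    """
    cyt = cyt or {}
    n = gm.n_samples
    results: list[PcaKaryotypeResult] = []
    assigned = {s: None for s in STRIPES}
    source = "none"
    conflict = None

    if not diagnostics.failed:
        anchors = [
            (i, cyt[s]) for i, s in enumerate(gm.samples)
            if s in cyt and labels[i] is not None
        ]
        hom_anchors = [(i, d) for i, d in anchors if d in (0, 2)]
        if hom_anchors:
            # two candidate polarities for the flank stripes
            mappings = ({"A": 0, "B": 1, "C": 2}, {"A": 2, "B": 1, "C": 0})
            viol = []
            for m in mappings:
                viol.append(sum(1 for i, d in anchors if m[labels[i]] != d))
            best = int(np.argmin(viol))
            if len(anchors) and viol[best] / len(anchors) <= anchor_tolerance:
                assigned = {s: d for s, d in mappings[best].items()}
                source = "cytogenetic"
            else:
                conflict = (
                    f"anchor conflict: {viol[best]}/{len(anchors)} anchors disagree "
                    "with the best stripe polarity"
                )
                assigned = {"A": None, "B": 1, "C": None}
                source = "cytogenetic"
        else:
            # reference polarity: dose 0 = lower mean alt-count stripe
            mean_alt = np.where(gm.alt_counts == MISSING, np.nan, gm.alt_counts.astype(float))
            sample_mean = np.nanmean(mean_alt, axis=1)
            mask_a = labels == "A"
            mask_c = labels == "C"
            mean_a = np.nanmean(sample_mean[mask_a]) if mask_a.any() else np.inf
            mean_c = np.nanmean(sample_mean[mask_c]) if mask_c.any() else np.inf
            if mean_a <= mean_c:
                assigned = {"A": 0, "B": 1, "C": 2}
            else:
                assigned = {"A": 2, "B": 1, "C": 0}
            source = "reference_polarity"

    diagnostics.conflict = conflict
    pc_coords = np.atleast_2d(pc_coords)
    for i, sid in enumerate(gm.samples):
        stripe = labels[i]
        dose = assigned.get(stripe) if stripe is not None else None
        results.append(
            PcaKaryotypeResult(
                sample_id=sid,
                pc1=float(pc_coords[i, 0]),
                pc2=float(pc_coords[i, 1]) if pc_coords.shape[1] > 1 else 0.0,
                stripe=stripe,
                imputed_dose=dose,
                anchor_source=source if dose is not None else "none",
            )
        )
    return results


def impute_karyotypes(
    gm: GenotypeMatrix,
    inv: InversionDef,
    metadata: list[SampleRecord] | None = None,
    silhouette_floor: float = 0.6,
    scale: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Full karyotyping pipeline: site selection -> PCA -> stripes -> doses.

    Returns a table with columns ``sample_id, PC1, PC2, stripe,
    imputed_dose, anchor_source``; clustering diagnostics are attached in
    ``.attrs["diagnostics"]``.
    """
    sub = select_inversion_sites(gm, inv)
    coords = local_pca(sub, n_components=2, scale=scale)
    labels, diag = cluster_stripes(coords, silhouette_floor=silhouette_floor, seed=seed)
    cyt = {}
    if metadata:
        cyt = {
            r.sample_id: r.cyt_karyotypes[inv.name]
            for r in metadata
            if inv.name in r.cyt_karyotypes and r.sample_id in set(gm.samples)
        }
    results = anchor_and_assign(sub, coords, labels, diag, cyt=cyt)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "PC1": [r.pc1 for r in results],
            "PC2": [r.pc2 for r in results],
            "stripe": [r.stripe for r in results],
            "imputed_dose": [r.imputed_dose for r in results],
            "anchor_source": [r.anchor_source for r in results],
        }
    )
    df.attrs["diagnostics"] = diag
    df.attrs["n_sites"] = sub.n_sites
    return df


def leave_out_diagnostics(
    gm: GenotypeMatrix,
    inv: InversionDef,
    grouping: dict[str, str],
    min_samples: int = 10,
    silhouette_floor: float = 0.6,
    seed: int = 0,
) -> list[dict]:
    """Leave-one-population-out stripe-separation diagnostics.

    For each population, karyotyping PCA is rerun without it and the change
    in silhouette is reported (positive gain: removing the population
    sharpens the stripes). Purely advisory — which populations to exclude
    remains the analyst's decision.
    """
    pops = sorted(set(grouping.get(s, "") for s in gm.samples))
    if len(pops) < 2:
        raise DataError("leave-one-out diagnostics need >= 2 populations")

    def _silhouette(sub_gm: GenotypeMatrix) -> float:
        sites = select_inversion_sites(sub_gm, inv)
        coords = local_pca(sites, n_components=2)
        _, diag = cluster_stripes(coords, silhouette_floor=silhouette_floor, seed=seed)
        return diag.silhouette

    base = _silhouette(gm)
    rows = []
    for pop in pops:
        keep = [s for s in gm.samples if grouping.get(s, "") != pop]
        if len(keep) < min_samples:
            rows.append({"population": pop, "gain": None,
                         "note": f"skipped: only {len(keep)} samples would remain"})
            continue
        try:
            sil = _silhouette(gm.take_samples(keep))
        except DataError as exc:
            rows.append({"population": pop, "gain": None, "note": str(exc)})
            continue
        rows.append({"population": pop, "gain": sil - base, "note": ""})
    rows.sort(key=lambda r: (r["gain"] is None, -(r["gain"] or 0.0)))
    return rows
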