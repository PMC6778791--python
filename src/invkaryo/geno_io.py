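"""Reading, writing and filtering genotype data and sample metadata.

VCF parsing is delegated to cyvcf2; only biallelic SNP records enter the
in-memory representation. Diploid GT fields are mapped to alternate-allele
counts (0/1/2); any absent or partial genotype becomes :data:`~invkaryo.types.MISSING`.
Per-genotype quality (GQ) is carried alongside when the VCF provides it.

Sample-level exclusion follows the cohort QC used for deep-sequenced
mosquito data: drop specimens with excessive missingness on arm 2R and
specimens subjected to whole-genome amplification (WGA), which biases PCA.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    MISSING,
    ConfigError,
    DataError,
    GenotypeMatrix,
    InversionDef,
    SampleRecord,
)

_SNP_ALLELES = frozenset("ACGT")

_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    m = _REGION_RE.match(region)
    if not m:
        raise ConfigError(f"malformed region {region!r}; expected chrom[:start-end]")
    chrom, start, end = m.groups()
    return chrom, (int(start) if start else None), (int(end) if end else None)


def read_vcf(
    path: str | Path,
    region: str | None = None,
    sample_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multiallelic records and indels
    are skipped (never decomposed). ``region`` is ``chrom`` or
    ``chrom:start-end`` with 1-based inclusive coordinates; an index is used
    when present, otherwise the file is streamed and filtered.

    Raises
    ------
    DataError
        If the file is unreadable or a requested sample is absent.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise DataError(f"cannot open VCF {path}: {exc}") from exc

    all_samples = list(vcf.samples)
    if sample_ids is not None:
        absent = [s for s in sample_ids if s not in all_samples]
        if absent:
            raise DataError(f"requested samples absent from VCF: {absent}")
        vcf.close()
        vcf = VCF(str(path), gts012=False, samples=sample_ids)
        samples = list(vcf.samples)
    else:
        samples = all_samples

    want_chrom = want_start = want_end = None
    iterator = vcf
    if region is not None:
        want_chrom, want_start, want_end = _parse_region(region)
        has_index = any(
            Path(str(path) + ext).exists() for ext in (".tbi", ".csi")
        )
        if has_index:
            iterator = vcf(region)
            want_chrom = None  # the index already restricted the records
        if want_end is None:
            want_start, want_end = 1, 2**62  # bare chromosome region

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    counts: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    any_gq = False

    for v in iterator:
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= v.POS <= want_end):
                continue
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
            continue
        geno = np.array([g[:-1] for g in v.genotypes], dtype=np.int16)
        row = geno.sum(axis=1)
        row[(geno < 0).any(axis=1)] = MISSING
        counts.append(row)
        gq_arr = v.format("GQ")
        if gq_arr is not None:
            any_gq = True
            g = np.asarray(gq_arr, dtype=float).reshape(len(samples), -1)[:, 0]
            g = np.where(np.isfinite(g) & (g >= 0), g, MISSING)
            gqs.append(g.astype(np.int32))
        else:
            gqs.append(np.full(len(samples), MISSING, dtype=np.int32))
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(ref)
        alts.append(alt)
    vcf.close()

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if len(sites):
        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        sites = sites.iloc[order]
        alt_counts = np.stack(counts, axis=1)[:, order]
        gq = np.stack(gqs, axis=1)[:, order] if any_gq else None
    else:
        alt_counts = np.zeros((len(samples), 0), dtype=np.int16)
        gq = None
    return GenotypeMatrix(samples=samples, sites=sites, alt_counts=alt_counts, gq=gq)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal plain-text VCF 4.2 file."""
    path = Path(path)
    has_gq = gm.gq is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=invkaryo\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gq:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        fmt = "GT:GQ" if has_gq else "GT"
        for j, site in enumerate(gm.sites.itertuples(index=False)):
            cells = []
            for i in range(gm.n_samples):
                gt = _GT_STRINGS[int(gm.alt_counts[i, j])]
                if has_gq:
                    q = int(gm.gq[i, j])
                    gt = f"{gt}:{q if q >= 0 else '.'}"
                cells.append(gt)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def compute_missing_per_sample(gm: GenotypeMatrix, chrom: str = "2R") -> dict[str, int]:
    """Count missing genotypes per sample on one chromosome arm."""
    mask = gm.chroms == chrom
    miss = (gm.alt_counts[:, mask] == MISSING).sum(axis=1)
    return dict(zip(gm.samples, miss.astype(int)))


def filter_samples(
    metadata: list[SampleRecord],
    max_missing_2R: int = 50_000,
    exclude_wga: bool = True,
) -> list[str]:
    """Apply cohort-level sample exclusion, preserving input order.

    Samples with more than ``max_missing_2R`` missing genotypes on arm 2R are
    removed (a sample at exactly the threshold is retained), as are
    WGA-amplified samples when ``exclude_wga`` is set.
    """
    kept = []
    for rec in metadata:
        miss = rec.missing_2R if rec.missing_2R is not None else 0
        if miss > max_missing_2R:
            continue
        if exclude_wga and rec.wga:
            continue
        kept.append(rec.sample_id)
    return kept


def _allele_freqs(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt_freq, minor_freq, minor_count) over non-missing alleles."""
    ac = gm.alt_counts
    nonmiss = ac != MISSING
    alt = np.where(nonmiss, ac, 0).sum(axis=0).astype(float)
    total = 2.0 * nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(total > 0, alt / total, 0.0)
    minor_count = np.minimum(alt, total - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_freq = np.where(total > 0, minor_count / total, 0.0)
    return alt_freq, minor_freq, minor_count


def _in_spans(pos: np.ndarray, spans) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for start, end in spans:
        mask |= (pos >= start) & (pos <= end)
    return mask


def site_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.0,
    mac_min: int = 0,
    spans: list[tuple[int, int]] | None = None,
    exclusions: list[tuple[int, int]] | None = None,
    chrom: str | None = None,
    maf_mode: str = "minor",
) -> GenotypeMatrix:
    """Filter sites by genomic span and allele-frequency criteria.

    ``maf_mode`` selects the frequency definition: ``"minor"`` uses the minor
    allele frequency, ``"alternate"`` the alternate-allele frequency. The
    minor-allele *count* criterion (``mac_min``) is always on the minor
    allele. Frequencies are computed over non-missing alleles only.
    """
    if maf_mode not in ("minor", "alternate"):
        raise ConfigError(f"maf_mode must be 'minor' or 'alternate', got {maf_mode!r}")
    if chrom is not None and gm.n_sites and chrom not in set(gm.chroms):
        raise ConfigError(f"span chromosome {chrom!r} not present in genotype matrix")
    keep = np.ones(gm.n_sites, dtype=bool)
    pos = gm.positions
    if chrom is not None:
        keep &= gm.chroms == chrom
    if spans:
        keep &= _in_spans(pos, spans)
    if exclusions:
        keep &= ~_in_spans(pos, exclusions)
    if maf_min > 0 or mac_min > 0:
        alt_freq, minor_freq, minor_count = _allele_freqs(gm)
        freq = alt_freq if maf_mode == "alternate" else minor_freq
        keep &= (freq >= maf_min) & (minor_count >= mac_min)
    return gm.take_sites(keep)


def mask_low_gq(gm: GenotypeMatrix, gq_min: int = 20) -> GenotypeMatrix:
    """Set genotypes with GQ strictly below ``gq_min`` to missing.

    Cells whose GQ is itself missing are left untouched (no evidence either
    way). A matrix without a GQ layer is returned unchanged with a warning.
    """
    if gq_min < 0:
        raise ConfigError(f"gq_min must be non-negative, got {gq_min}")
    out = gm.copy()
    if gm.gq is None or not (gm.gq != MISSING).any():
        warnings.warn("no GQ data present; mask_low_gq is a no-op", stacklevel=2)
        return out
    mask = (gm.gq != MISSING) & (gm.gq < gq_min)
    out.alt_counts[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# metadata and configuration tables
# ---------------------------------------------------------------------------

_META_FIXED = ["sample_id", "taxon", "population", "country", "wga"]


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read a sample-metadata TSV.

    Fixed columns ``sample_id, taxon, population, country, wga`` are followed
    by one column per inversion holding the cytogenetic dose ('.', '0', '1',
    '2') and, optionally, a ``missing_2R`` count column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    for col in _META_FIXED:
        if col not in df.columns:
            raise DataError(f"metadata missing required column {col!r}")
    inv_cols = [c for c in df.columns if c not in _META_FIXED + ["missing_2R"]]
    records = []
    for d in df.to_dict("records"):  # not itertuples: inversion names like
        cyt = {}                     # "2Rb" are not valid identifiers
        for inv in inv_cols:
            val = d[inv]
            if val in ("0", "1", "2"):
                cyt[inv] = int(val)
        miss = d.get("missing_2R", ".")
        records.append(
            SampleRecord(
                sample_id=d["sample_id"],
                taxon=d["taxon"],
                population=d["population"],
                country=d["country"],
                cyt_karyotypes=cyt,
                wga=str(d["wga"]).lower() in ("true", "1", "yes"),
                missing_2R=int(miss) if miss not in (".", "") else None,
            )
        )
    return records


def write_metadata(records: list[SampleRecord], path: str | Path,
                   inversions: list[str] | None = None) -> None:
    """Write sample metadata as a TSV (inverse of :func:`read_metadata`)."""
    if inversions is None:
        inversions = sorted({inv for r in records for inv in r.cyt_karyotypes})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "taxon": r.taxon,
            "population": r.population,
            "country": r.country,
            "wga": str(r.wga).lower(),
            "missing_2R": r.missing_2R if r.missing_2R is not None else ".",
        }
        for inv in inversions:
            row[inv] = r.cyt_karyotypes.get(inv, ".")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_inversion_config(path: str | Path) -> dict[str, InversionDef]:
    """Read inversion definitions from a YAML file.

    The file maps inversion names to their fields (1-based inclusive spans)::

        2La:
          chrom: 2L
          span: [20524058, 42165532]
          breakpoints: [20524058, 42165532]
          maf_min_pca: 0.15
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"inversion config {path} must be a mapping of name -> fields")
    out = {}
    for name, fields in raw.items():
        fields = dict(fields)
        fields["span"] = tuple(fields["span"])
        if "breakpoints" in fields and fields["breakpoints"] is not None:
            fields["breakpoints"] = tuple(fields["breakpoints"])
        if "exclusion_spans" in fields:
            fields["exclusion_spans"] = [tuple(s) for s in fields["exclusion_spans"]]
        out[name] = InversionDef(name=name, **fields)
    return out


def write_inversion_config(invs: dict[str, InversionDef], path: str | Path) -> None:
    payload = {}
    for name, inv in invs.items():
        payload[name] = {
            "chrom": inv.chrom,
            "span": list(inv.span),
            "breakpoints": list(inv.breakpoints),
            "exclusion_spans": [list(s) for s in inv.exclusion_spans],
            "maf_min_pca": inv.maf_min_pca,
            "mac_min_pca": inv.mac_min_pca,
            "maf_min_tags": inv.maf_min_tags,
            "concordance_threshold": inv.concordance_threshold,
            "taxon_scope": inv.taxon_scope,
            "flank": inv.flank,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
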