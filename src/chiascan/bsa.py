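"""Bulked-segregant-analysis SNP-index scan.

Mapping-by-sequencing of a phenotype-selected bulk: at each variant the
SNP index is the fraction of reads carrying the mutant allele,
ad_alt / (ad_ref + ad_alt).  In a bulk of recessive homozygotes the index
approaches 1 at the causal locus and decays toward 0.5 with genetic
distance.  Indices are averaged in a 200-kb sliding window advanced in
50-kb steps, and windows whose mean index exceeds 0.9 are merged into
candidate regions.

Coordinate conventions: VCF positions are 1-based; windows and BED output
are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "VariantRecord",
    "GenomicWindow",
    "CandidateRegion",
    "snp_index",
    "read_vcf",
    "window_scan",
    "call_candidate_regions",
    "windows_to_dataframe",
    "write_windows",
    "write_regions_bed",
    "DEFAULT_WINDOW_BP",
    "DEFAULT_STEP_BP",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MIN_VARIANTS",
]

DEFAULT_WINDOW_BP = 200_000
DEFAULT_STEP_BP = 50_000
DEFAULT_THRESHOLD = 0.9
# the source protocol states neither a depth filter nor a per-window variant
# floor; these defaults stabilise indices at ~30x coverage and are configurable
DEFAULT_MIN_DEPTH = 8
DEFAULT_MIN_VARIANTS = 10


def snp_index(ad_ref: int, ad_alt: int, min_depth: int = DEFAULT_MIN_DEPTH) -> Optional[float]:
    """Mutant-allele read fraction, or None when total depth < min_depth."""
    if ad_ref < 0 or ad_alt < 0:
        raise ValueError("allele depths must be >= 0")
    depth = ad_ref + ad_alt
    if depth < min_depth or depth == 0:
        return None
    return ad_alt / depth


@dataclass
class VariantRecord:
    """One biallelic variant with bulk (and optionally control) allele depths."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    ad_ref: int
    ad_alt: int
    control_ad_ref: Optional[int] = None
    control_ad_alt: Optional[int] = None

    def snp_index(self, min_depth: int = DEFAULT_MIN_DEPTH) -> Optional[float]:
        return snp_index(self.ad_ref, self.ad_alt, min_depth)

    def delta_index(self, min_depth: int = DEFAULT_MIN_DEPTH) -> Optional[float]:
        """Bulk index minus control index; None if either is missing."""
        if self.control_ad_ref is None or self.control_ad_alt is None:
            return None
        bulk = self.snp_index(min_depth)
        ctrl = snp_index(self.control_ad_ref, self.control_ad_alt, min_depth)
        if bulk is None or ctrl is None:
            return None
        return bulk - ctrl


@dataclass
class GenomicWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_variants: int
    mean_index: Optional[float]


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    peak_index: float


def read_vcf(
    path,
    sample: Optional[str] = None,
    control_sample: Optional[str] = None,
) -> list[VariantRecord]:
    """Read biallelic variants with per-sample AD fields from a VCF.

    ``sample`` defaults to the first sample in the file.  Multiallelic
    records and records without AD are skipped.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError("VCF has no samples (AD fields required)")
        bulk = sample if sample is not None else samples[0]
        if bulk not in samples:
            raise ValueError(f"sample {bulk!r} not in VCF ({samples})")
        if control_sample is not None and control_sample not in samples:
            raise ValueError(f"control sample {control_sample!r} not in VCF")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ad = rec.samples[bulk].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            ctrl_ref = ctrl_alt = None
            if control_sample is not None:
                cad = rec.samples[control_sample].get("AD")
                if cad is not None and len(cad) >= 2 and cad[0] is not None:
                    ctrl_ref, ctrl_alt = int(cad[0]), int(cad[1])
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    ad_ref=int(ad[0]),
                    ad_alt=int(ad[1]),
                    control_ad_ref=ctrl_ref,
                    control_ad_alt=ctrl_alt,
                )
            )
    return records


def _check_sorted(variants: Sequence[VariantRecord]) -> None:
    for a, b in zip(variants, variants[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise ValueError(
                f"variants not sorted: {a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def window_scan(
    variants: Sequence[VariantRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int = DEFAULT_STEP_BP,
    min_variants: int = DEFAULT_MIN_VARIANTS,
    min_depth: int = DEFAULT_MIN_DEPTH,
    statistic: str = "index",
) -> list[GenomicWindow]:
    """Sliding-window mean SNP index along each chromosome.

    Windows are anchored at position 0 of each chromosome (reproducible
    across variant subsets) and advance by ``step_bp``; the last window is
    the first whose end reaches the final variant.  A window's mean is the
    arithmetic mean of the non-missing indices of variants it contains
    (start <= pos-1 < end); it is missing when fewer than ``min_variants``
    contribute.  ``statistic="delta"`` averages bulk-minus-control indices.
    """
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if statistic not in ("index", "delta"):
        raise ValueError(f"unknown statistic {statistic!r}")
    _check_sorted(variants)

    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    windows: list[GenomicWindow] = []
    for chrom, recs in by_chrom.items():
        pos0 = np.array([v.pos - 1 for v in recs])
        if statistic == "index":
            idx = np.array(
                [np.nan if (i := v.snp_index(min_depth)) is None else i for v in recs]
            )
        else:
            idx = np.array(
                [np.nan if (i := v.delta_index(min_depth)) is None else i for v in recs]
            )
        last_pos = int(pos0.max()) + 1
        n_windows = max(0, math.ceil((last_pos - window_bp) / step_bp)) + 1
        starts = np.arange(n_windows) * step_bp
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + window_bp, side="left")
        for k in range(n_windows):
            vals = idx[lo[k] : hi[k]]
            vals = vals[~np.isnan(vals)]
            n = int(vals.size)
            mean = float(vals.mean()) if n >= min_variants else None
            windows.append(
                GenomicWindow(
                    chrom=chrom,
                    start=int(starts[k]),
                    end=int(starts[k] + window_bp),
                    n_variants=n,
                    mean_index=mean,
                )
            )
    return windows


def call_candidate_regions(
    windows: Sequence[GenomicWindow], threshold: float = DEFAULT_THRESHOLD
) -> list[CandidateRegion]:
    """Merge windows with mean index strictly above ``threshold``.

    Overlapping or book-ended above-threshold windows coalesce into one
    region whose peak is the maximum member-window mean.  Output regions
    are disjoint and sorted; the operation is idempotent.
    """
    hits = [w for w in windows if w.mean_index is not None and w.mean_index > threshold]
    hits.sort(key=lambda w: (w.chrom, w.start))
    regions: list[CandidateRegion] = []
    for w in hits:
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.peak_index = max(r.peak_index, w.mean_index)
        else:
            regions.append(CandidateRegion(w.chrom, w.start, w.end, w.mean_index))
    return regions


def windows_to_dataframe(windows: Sequence[GenomicWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_variants": [w.n_variants for w in windows],
            "mean_index": [w.mean_index for w in windows],
        }
    )


def write_windows(windows: Sequence[GenomicWindow], path, sep: str = "\t") -> None:
    df = windows_to_dataframe(windows)
    df["mean_index"] = df["mean_index"].map(
        lambda x: "NA" if pd.isna(x) else f"{x:.6f}"
    )
    df.to_csv(path, sep=sep, index=False)


def write_regions_bed(regions: Sequence[CandidateRegion], path) -> None:
    """BED3+score: chrom, start, end, peak mean index."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_index:.6f}\n")
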