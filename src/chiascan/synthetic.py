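"""Synthetic inputs for every pipeline stage.

Generates cytology tables through meiosis-simulator presets calibrated to
the two study regimes (an interference-rich wild type averaging 38.50
chiasmata per meiocyte with SD 1.41, and an MLH1-null regime whose residual
chiasmata are Poisson with mean 8.41), F2 phenotype counts under 3:1
Mendelian segregation, and a BSA-seq bulk VCF with a planted recessive
causal locus, so the scan can be exercised end to end without any
sequencing data.

The BSA genetic model uses the Haldane (no-interference) map function with
a fixed kb-per-cM scaling; the bulk is sampled plant by plant (each sterile
F2 plant homozygous at the locus, flanking alleles drawn per gamete) so the
finite-bulk noise of 39 plants is realistic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pysam
import yaml

from .bsa import VariantRecord
from .segregation import SegregationCounts
from .simulate import MeiosisParams

__all__ = [
    "WT_MEAN_CHIASMATA",
    "WT_SD_CHIASMATA",
    "MUTANT_MEAN_CHIASMATA",
    "F2SimConfig",
    "BsaSimConfig",
    "preset",
    "simulate_f2_counts",
    "haldane_r",
    "simulate_bsa_bulk",
    "write_vcf",
    "config_echo",
]

# study regime calibration: wild type n=123, mutant n=158 meiocytes
WT_MEAN_CHIASMATA = 38.50
WT_SD_CHIASMATA = 1.41
MUTANT_MEAN_CHIASMATA = 8.41
_N_PAIRS = 20


def preset(name: str) -> MeiosisParams:
    """Meiosis-simulator parameter presets for the two study regimes.

    ``wildtype``: Class I enabled with an obligate crossover per pair
    (reproducing 20 bivalents in every cell) and the extra-crossover
    dispersion set so per-cell chiasma counts have mean 38.50 and SD 1.41.
    ``mlh1_mutant``: Class I disabled; Class II rate 8.41/20 per pair, so
    per-cell totals are Poisson with mean 8.41.
    """
    if name == "wildtype":
        return MeiosisParams(
            n_pairs=_N_PAIRS,
            class1_enabled=True,
            obligate_co=True,
            class1_mean_extra=WT_MEAN_CHIASMATA / _N_PAIRS - 1.0,
            class1_dispersion=WT_SD_CHIASMATA**2 / WT_MEAN_CHIASMATA,
            class2_rate=0.0,
        )
    if name == "mlh1_mutant":
        return MeiosisParams(
            n_pairs=_N_PAIRS,
            class1_enabled=False,
            class1_mean_extra=0.0,
            class2_rate=MUTANT_MEAN_CHIASMATA / _N_PAIRS,
        )
    raise ValueError(f"unknown preset {name!r} (wildtype, mlh1_mutant)")


@dataclass(frozen=True)
class F2SimConfig:
    """F2 phenotype-count generator: sterile plants are recessive homozygotes."""

    n_plants: int = 181
    p_mutant: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if not 0 <= self.p_mutant < 1:
            raise ValueError("p_mutant must be in [0, 1)")


def simulate_f2_counts(
    config: F2SimConfig, rng: Optional[np.random.Generator] = None
) -> SegregationCounts:
    """Draw fertile/sterile counts: sterile ~ Binomial(n, p_mutant)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sterile = int(rng.binomial(config.n_plants, config.p_mutant))
    fertile = config.n_plants - sterile
    return SegregationCounts(
        n_class_a=fertile, n_class_b=sterile, expected_ratio=(3.0, 1.0)
    )


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction from distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class BsaSimConfig:
    """Sterile-bulk BSA generator with a planted recessive locus.

    Defaults follow the study design: 39 recessive-homozygote F2 plants
    sequenced to ~30x.  The focal chromosome is 40 Mb (a typical soybean
    chromosome) with markers every 2 kb — sparser than the ~2.9 variants/kb
    the real bulks yielded, but dense enough that 200-kb windows average
    ~100 markers.  A second, unlinked 10-Mb chromosome provides markers at
    recombination fraction 1/2, where the expected index is 0.5.
    """

    n_plants: int = 39
    mean_depth: float = 30.0
    chrom_length_bp: int = 40_000_000
    marker_spacing_bp: int = 2_000
    locus_pos: int = 20_000_000
    kb_per_cM: float = 400.0
    chrom_name: str = "Chr04"
    unlinked_chrom_length_bp: int = 10_000_000  # 0 disables
    unlinked_chrom_name: str = "Chr09"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.locus_pos <= self.chrom_length_bp:
            raise ValueError("locus must lie within the chromosome")
        if self.marker_spacing_bp <= 0 or self.mean_depth <= 0:
            raise ValueError("spacing and depth must be > 0")
        if self.n_plants < 1 or self.kb_per_cM <= 0:
            raise ValueError("n_plants and kb_per_cM must be positive")

    @property
    def contig_lengths(self) -> dict[str, int]:
        contigs = {self.chrom_name: self.chrom_length_bp}
        if self.unlinked_chrom_length_bp > 0:
            contigs[self.unlinked_chrom_name] = self.unlinked_chrom_length_bp
        return contigs


def _flip_parity(
    n_gametes: int, interval_cM: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative crossover parity along consecutive marker intervals.

    A gamete's allele switches between adjacent markers with probability
    r(interval) under Haldane's map; because 1 - 2*r(d) = exp(-2d/100)
    composes multiplicatively, the chain's marginal switch probability at
    distance d from the anchor is exactly r(d).
    """
    flip_p = np.asarray(haldane_r(interval_cM))
    flips = rng.random((n_gametes, flip_p.size)) < flip_p[None, :]
    return np.cumsum(flips, axis=1) % 2 == 1


def _selected_gamete_carries(
    positions: np.ndarray,
    locus_pos: int,
    kb_per_cM: float,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutant-allele indicators for gametes selected at the causal locus.

    Every selected gamete carries the mutant allele at the locus; flanking
    alleles follow the crossover parity chain outward on each flank, so
    haplotypes are spatially coherent as in a real bulk.
    """
    per_cM_bp = kb_per_cM * 1000.0
    carries = np.empty((n_gametes, positions.size), dtype=bool)
    left = positions < locus_pos
    right = ~left
    if right.any():
        pr = positions[right].astype(float)
        anchored = np.concatenate(([float(locus_pos)], pr))
        parity = _flip_parity(n_gametes, np.diff(anchored) / per_cM_bp, rng)
        carries[:, right] = ~parity
    if left.any():
        pl = positions[left].astype(float)[::-1]  # outward from the locus
        anchored = np.concatenate(([float(locus_pos)], pl))
        parity = _flip_parity(n_gametes, -np.diff(anchored) / per_cM_bp, rng)
        carries[:, np.flatnonzero(left)[::-1]] = ~parity
    return carries


def _unlinked_gamete_carries(
    positions: np.ndarray,
    kb_per_cM: float,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele indicators on a chromosome unlinked to the selected locus:
    a fair coin at the first marker, then the same parity chain along."""
    start = rng.random(n_gametes) < 0.5
    if positions.size == 1:
        return start[:, None]
    interval_cM = np.diff(positions.astype(float)) / (kb_per_cM * 1000.0)
    parity = _flip_parity(n_gametes, interval_cM, rng)
    return start[:, None] ^ np.concatenate(
        (np.zeros((n_gametes, 1), dtype=bool), parity), axis=1
    )


def _read_sample(
    carries: np.ndarray, mean_depth: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depths and binomial alt counts at the realised bulk frequency."""
    bulk_freq = carries.mean(axis=0)
    depth = rng.poisson(mean_depth, size=bulk_freq.size)
    ad_alt = rng.binomial(depth, bulk_freq)
    return depth - ad_alt, ad_alt


def simulate_bsa_bulk(
    config: BsaSimConfig, rng: Optional[np.random.Generator] = None
) -> list[VariantRecord]:
    """Simulate the sterile-bulk allele depths along the genome.

    At a marker d cM from the causal locus a selected gamete carries the
    mutant-linked allele with probability 1 - r(d) under Haldane's map;
    at the locus itself every gamete carries it (r = 0), and on the
    unlinked chromosome the probability is exactly 1/2.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[VariantRecord] = []

    n_gametes = 2 * config.n_plants

    pos = np.arange(
        config.marker_spacing_bp,
        config.chrom_length_bp + 1,
        config.marker_spacing_bp,
        dtype=np.int64,
    )
    carries = _selected_gamete_carries(
        pos, config.locus_pos, config.kb_per_cM, n_gametes, rng
    )
    ad_ref, ad_alt = _read_sample(carries, config.mean_depth, rng)
    for p, r_, a_ in zip(pos, ad_ref, ad_alt):
        records.append(
            VariantRecord(config.chrom_name, int(p), "A", "G", int(r_), int(a_))
        )

    if config.unlinked_chrom_length_bp > 0:
        pos_u = np.arange(
            config.marker_spacing_bp,
            config.unlinked_chrom_length_bp + 1,
            config.marker_spacing_bp,
            dtype=np.int64,
        )
        carries_u = _unlinked_gamete_carries(
            pos_u, config.kb_per_cM, n_gametes, rng
        )
        ad_ref_u, ad_alt_u = _read_sample(carries_u, config.mean_depth, rng)
        for p, r_, a_ in zip(pos_u, ad_ref_u, ad_alt_u):
            records.append(
                VariantRecord(
                    config.unlinked_chrom_name, int(p), "A", "G", int(r_), int(a_)
                )
            )
    return records


def write_vcf(
    records: list[VariantRecord],
    path,
    contig_lengths: dict[str, int],
    sample: str = "sterile_bulk",
) -> None:
    """Write variants with per-sample AD to an uncompressed VCF."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in records:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
            )
            rec.samples[sample]["AD"] = (v.ad_ref, v.ad_alt)
            out.write(rec)


def config_echo(config) -> str:
    """YAML echo of a generator config, for provenance alongside outputs."""
    payload = {type(config).__name__: asdict(config)}
    return yaml.safe_dump(payload, sort_keys=False)
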