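"""Windowed nucleotide diversity and the pi_wild / pi_domesticated sweep scan.

Nucleotide diversity at a site with n called chromosomes and allele
frequencies p_a is estimated without bias as

    pi_site = n / (n - 1) * (1 - sum_a p_a^2),

which equals the mean pairwise difference over all chromosome pairs at the
site.  Window diversity is the sum of site values over a window divided by
the full window length (monomorphic positions contribute zero implicitly).
Windows tile the region as BED-style 0-based half-open intervals of fixed
size (default 20 kb, non-overlapping); input positions are 1-based.

A domestication sweep reduces diversity in the domesticated but not the wild
population, so the ratio pi_W / pi_D is elevated in swept windows.  A window
is called significant when its ratio strictly exceeds the nearest-rank
(1 - top_fraction) quantile of all defined ratios (default: the 99th
percentile, i.e. the top 1%).  Windows with pi_D = 0 but pi_W > 0 have an
unbounded ratio and are flagged and reported significant; windows with both
zero have no defined ratio and are excluded from the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

POPULATIONS = ("wild", "domesticated")


@dataclass
class SiteFrequencyRecord:
    chrom: str
    pos: int  # 1-based
    population: str
    allele_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError("negative allele count")

    @property
    def n_chromosomes(self) -> int:
        return sum(self.allele_counts.values())


@dataclass
class DiversityWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int
    pi_w: float
    pi_d: float
    ratio: float  # NaN when undefined or unbounded
    significant: bool
    unbounded: bool = False
    defined: bool = True


def site_pi(record: SiteFrequencyRecord) -> float:
    """Unbiased expected heterozygosity; equals mean pairwise difference."""
    counts = list(record.allele_counts.values())
    n = sum(counts)
    if n < 2:
        raise ValueError(f"site {record.chrom}:{record.pos} has n = {n} < 2")
    # integer arithmetic keeps the estimator exact: (n^2 - sum c^2) / (n (n-1))
    return (n * n - sum(c * c for c in counts)) / (n * (n - 1))


def window_pi(
    records: list[SiteFrequencyRecord],
    window_size: int,
    span_end: int,
    span_start: int = 0,
) -> tuple[np.ndarray, int]:
    """Per-bp diversity for each window of a [span_start, span_end) tiling.

    Returns (per-window per-bp pi, number of sites skipped for n < 2).
    Positions outside the tiling raise; the tiling must be a whole number of
    windows.
    """
    span = span_end - span_start
    if span <= 0 or span % window_size:
        raise ValueError("span must be a positive multiple of window_size")
    n_windows = span // window_size
    totals = np.zeros(n_windows)
    skipped = 0
    for rec in records:
        idx0 = rec.pos - 1 - span_start  # to 0-based offset
        if not 0 <= idx0 < span:
            raise ValueError(f"position {rec.pos} outside tiling [{span_start}, {span_end})")
        if rec.n_chromosomes < 2:
            skipped += 1
            continue
        totals[idx0 // window_size] += site_pi(rec)
    return totals / window_size, skipped


def pi_ratio_scan(
    pi_wild: np.ndarray,
    pi_dom: np.ndarray,
    window_size: int,
    top_fraction: float = 0.01,
    chrom: str = "chr",
    span_start: int = 0,
) -> list[DiversityWindow]:
    """Call sweep windows from matching wild/domesticated window tilings."""
    pi_wild = np.asarray(pi_wild, dtype=float)
    pi_dom = np.asarray(pi_dom, dtype=float)
    if pi_wild.shape != pi_dom.shape:
        raise ValueError("mismatching tilings")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")

    defined = pi_dom > 0
    ratios = np.full(pi_wild.shape, np.nan)
    ratios[defined] = pi_wild[defined] / pi_dom[defined]
    defined_ratios = ratios[defined]
    if defined_ratios.size == 0:
        raise ValueError("no window has a defined pi ratio")

    # nearest-rank (1 - top_fraction) quantile
    rank = math.ceil((1.0 - top_fraction) * defined_ratios.size)
    cutoff = float(np.sort(defined_ratios)[rank - 1])

    windows = []
    for i in range(pi_wild.size):
        start = span_start + i * window_size
        unbounded = (not defined[i]) and pi_wild[i] > 0
        is_defined = bool(defined[i])
        significant = bool(is_defined and ratios[i] > cutoff) or unbounded
        windows.append(
            DiversityWindow(
                chrom=chrom,
                start=start,
                end=start + window_size,
                pi_w=float(pi_wild[i]),
                pi_d=float(pi_dom[i]),
                ratio=float(ratios[i]) if is_defined else float("nan"),
                significant=significant,
                unbounded=unbounded,
                defined=is_defined,
            )
        )
    return windows


def sweep_scan(
    records: list[SiteFrequencyRecord],
    window_size: int = 20_000,
    span_end: int | None = None,
    top_fraction: float = 0.01,
    chrom: str = "chr",
) -> list[DiversityWindow]:
    """Convenience wrapper: split records by population, window, and scan."""
    if span_end is None:
        last = max(r.pos for r in records)
        span_end = window_size * math.ceil(last / window_size)
    wild = [r for r in records if r.population == "wild"]
    dom = [r for r in records if r.population == "domesticated"]
    pw, _ = window_pi(wild, window_size, span_end)
    pd_, _ = window_pi(dom, window_size, span_end)
    return pi_ratio_scan(pw, pd_, window_size, top_fraction, chrom=chrom)


def _format_counts(counts: dict[str, int]) -> str:
    return ",".join(f"{a}={c}" for a, c in sorted(counts.items()))


def _parse_counts(text: str) -> dict[str, int]:
    out = {}
    for item in text.split(","):
        allele, count = item.split("=")
        out[allele] = int(count)
    return out


def write_counts_tsv(records: list[SiteFrequencyRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tpopulation\tcounts\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.population}\t{_format_counts(r.allele_counts)}\n")


def read_counts_tsv(path) -> list[SiteFrequencyRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError("counts TSV must start with a chrom/pos/population/counts header")
        for line in fh:
            chrom, pos, population, counts = line.rstrip("\n").split("\t")
            records.append(
                SiteFrequencyRecord(chrom, int(pos), population, _parse_counts(counts))
            )
    return records


def read_vcf_counts(
    path, wild_samples: list[str], domesticated_samples: list[str]
) -> list[SiteFrequencyRecord]:
    """Per-site allele counts for two sample lists from a VCF.

    Counts called chromosomes per allele (missing genotypes excluded).
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = {
        "wild": [samples.index(s) for s in wild_samples],
        "domesticated": [samples.index(s) for s in domesticated_samples],
    }
    for variant in vcf:
        alleles = [variant.REF] + list(variant.ALT)
        gts = variant.genotypes  # [allele_1, allele_2, phased]
        for population, cols in idx.items():
            counts: dict[str, int] = {}
            for c in cols:
                for a in gts[c][:-1]:
                    if a is None or a < 0:
                        continue
                    counts[alleles[a]] = counts.get(alleles[a], 0) + 1
            if counts:
                records.append(
                    SiteFrequencyRecord(variant.CHROM, variant.POS, population, counts)
                )
    return records


def write_sweep_tsv(windows: list[DiversityWindow], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpi_w\tpi_d\tratio\tsignificant\tunbounded\n")
        for w in windows:
            ratio = f"{w.ratio:.6g}" if w.defined else ("inf" if w.unbounded else "NA")
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.pi_w:.6g}\t{w.pi_d:.6g}\t"
                f"{ratio}\t{int(w.significant)}\t{int(w.unbounded)}\n"
            )
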