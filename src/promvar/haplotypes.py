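"""Haplotype partitioning and per-haplotype phenotype summaries.

Accessions sharing an identical, fully observed allele vector across the
polymorphic sites form one haplotype.  Accessions with any missing call are
reported unassigned rather than imputed.  Haplotypes are numbered 1..H by
descending member count, ties by first occurrence in the input order, so the
partition itself is invariant to input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import EMPTY_TOKEN, PolymorphicSite, SUBGROUPS


@dataclass
class Haplotype:
    hap_id: int
    allele_vector: tuple[str, ...]
    members: list[str]


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    site_order: list[str]
    unassigned: list[str] = field(default_factory=list)

    def partition(self) -> set[frozenset[str]]:
        """Membership as a set of frozensets (numbering-independent)."""
        return {frozenset(h.members) for h in self.haplotypes}

    def membership(self) -> dict[str, int]:
        return {m: h.hap_id for h in self.haplotypes for m in h.members}


@dataclass
class PhenotypeTable:
    """Accession -> (subgroup, replicate chlorophyll values).

    Values are instrument chlorophyll units measured in flag leaves at six
    weeks after heading; every accession carries >= 1 finite non-negative
    replicate.
    """

    rows: dict[str, tuple[str, list[float]]]

    def __post_init__(self) -> None:
        for acc, (subgroup, reps) in self.rows.items():
            if subgroup not in SUBGROUPS:
                raise ValueError(f"unknown subgroup {subgroup!r} for {acc!r}")
            if not reps:
                raise ValueError(f"accession {acc!r} has no replicates")
            if not all(math.isfinite(v) and v >= 0 for v in reps):
                raise ValueError(f"accession {acc!r} has non-finite or negative values")

    @property
    def accessions(self) -> list[str]:
        return list(self.rows)

    def subgroup(self, accession: str) -> str:
        return self.rows[accession][0]

    def accession_mean(self, accession: str) -> float:
        return float(np.mean(self.rows[accession][1]))

    def means(self) -> dict[str, float]:
        return {a: self.accession_mean(a) for a in self.rows}

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        """Read a long-format TSV: accession, subgroup, chlorophyll."""
        df = pd.read_csv(path, sep="\t", comment="#")
        rows: dict[str, tuple[str, list[float]]] = {}
        for acc, grp in df.groupby("accession", sort=False):
            subgroups = grp["subgroup"].unique()
            if len(subgroups) != 1:
                raise ValueError(f"accession {acc!r} has conflicting subgroups")
            rows[str(acc)] = (str(subgroups[0]), [float(v) for v in grp["chlorophyll"]])
        return cls(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\tsubgroup\tchlorophyll\n")
            for acc, (subgroup, reps) in self.rows.items():
                for v in reps:
                    fh.write(f"{acc}\t{subgroup}\t{v!r}\n")


def assign_haplotypes(
    sites: list[PolymorphicSite], accessions: list[str]
) -> HaplotypeTable:
    """Partition accessions into haplotypes by exact allele-vector match."""
    if not sites:
        raise ValueError("empty site list")
    site_order = [s.site_id for s in sites]

    groups: dict[tuple[str, ...], list[str]] = {}
    unassigned: list[str] = []
    for acc in accessions:
        vector = tuple(s.calls.get(acc) for s in sites)
        if any(a is None for a in vector):
            unassigned.append(acc)
        else:
            groups.setdefault(vector, []).append(acc)

    order = sorted(
        groups,
        key=lambda v: (-len(groups[v]), accessions.index(groups[v][0])),
    )
    haplotypes = [
        Haplotype(hap_id=i + 1, allele_vector=v, members=list(groups[v]))
        for i, v in enumerate(order)
    ]
    return HaplotypeTable(haplotypes, site_order, unassigned)


def haplotype_phenotype_summary(
    haps: HaplotypeTable, pheno: PhenotypeTable
) -> pd.DataFrame:
    """Per-haplotype mean +/- SE of member accession mean chlorophyll.

    The summary unit is the accession mean (not the raw replicate): mean is
    the arithmetic mean over phenotyped members, SE the sample SD / sqrt(n).
    Haplotypes with a single phenotyped member report SE as NaN (undefined);
    haplotypes with none are kept with n = 0 rather than silently dropped.
    """
    rows = []
    for h in haps.haplotypes:
        values = [pheno.accession_mean(m) for m in h.members if m in pheno.rows]
        n = len(values)
        mean = float(np.mean(values)) if n else float("nan")
        se = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {"hap_id": h.hap_id, "n": n, "mean": mean, "se": se, "size": len(h.members)}
        )
    return pd.DataFrame(rows, columns=["hap_id", "n", "mean", "se", "size"])


def write_haplotype_table(haps: HaplotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# sites\t" + "\t".join(haps.site_order) + "\n")
        fh.write("hap_id\tsize\tallele_vector\tmembers\n")
        for h in haps.haplotypes:
            vector = ",".join(a if a != "" else EMPTY_TOKEN for a in h.allele_vector)
            fh.write(f"{h.hap_id}\t{len(h.members)}\t{vector}\t{','.join(h.members)}\n")
        if haps.unassigned:
            fh.write(f"unassigned\t{len(haps.unassigned)}\t-\t{','.join(haps.unassigned)}\n")
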