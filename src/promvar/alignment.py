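"""Aligned promoter panels and polymorphic-site discovery.

The input is a pre-aligned multi-FASTA of promoter sequences (gap character
``-``) for a panel of accessions, with one designated reference accession and
the alignment column of the first base of the start codon (ATG).  Every
alignment column upstream of the ATG is promoter sequence and is screened for
variation: substitution columns become SNP sites, and maximal runs of columns
gapped in at least one accession are merged into single indel events.

Coordinates are 1-based negative and ATG-relative: -1 is the base immediately
5' of the A of ATG, counted over *reference* (non-gap) bases only.  Insertions
absent from the reference are anchored at the coordinate of the first
reference base 3' of the gap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUBGROUPS = (
    "indica",
    "temperate_japonica",
    "tropical_japonica",
    "aromatic",
    "aus",
    "wild_nivara",
    "wild_rufipogon",
    "other",
)
WILD_SUBGROUPS = frozenset({"wild_nivara", "wild_rufipogon"})
ALPHABET = frozenset("ACGTN-")

#: encoding of awkward allele strings in site-table TSVs
MISSING_TOKEN = "."
EMPTY_TOKEN = "-"


class AlignmentError(ValueError):
    """Raised for malformed alignments or invalid coordinates."""


@dataclass(frozen=True)
class AlignmentRecord:
    accession_id: str
    subgroup: str
    sequence: str

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise AlignmentError(
                f"unknown subgroup {self.subgroup!r} for {self.accession_id!r}"
            )
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise AlignmentError(
                f"record {self.accession_id!r} contains non-alphabet "
                f"characters {sorted(bad)!r}"
            )


@dataclass
class PromoterAlignment:
    """An aligned promoter panel with a reference accession and ATG column."""

    records: list[AlignmentRecord]
    reference_id: str
    atg_column: int

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        (self.n_columns,) = lengths
        ids = [r.accession_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate accession ids in alignment")
        self._index = {r.accession_id: r for r in self.records}
        if self.reference_id not in self._index:
            raise AlignmentError(f"reference id {self.reference_id!r} not in alignment")
        if not 0 < self.atg_column <= self.n_columns:
            raise AlignmentError(
                f"atg_column {self.atg_column} outside alignment of "
                f"{self.n_columns} columns"
            )

    def record(self, accession_id: str) -> AlignmentRecord:
        return self._index[accession_id]

    @property
    def accession_ids(self) -> list[str]:
        return [r.accession_id for r in self.records]

    @property
    def reference_sequence(self) -> str:
        return self._index[self.reference_id].sequence

    @property
    def subgroups(self) -> dict[str, str]:
        return {r.accession_id: r.subgroup for r in self.records}

    def subset(self, accession_ids: list[str]) -> "PromoterAlignment":
        keep = [self._index[a] for a in accession_ids]
        return PromoterAlignment(keep, self.reference_id, self.atg_column)

    def cultivated(self) -> "PromoterAlignment":
        """Drop wild outgroup records (kept for phylogeny, not for calling)."""
        ids = [r.accession_id for r in self.records if r.subgroup not in WILD_SUBGROUPS]
        return self.subset(ids)


@dataclass
class PolymorphicSite:
    """One variant event (SNP or merged indel) of the promoter alignment."""

    site_id: str
    coordinate: int
    kind: str  # "SNP" | "indel"
    ref_allele: str
    alt_alleles: list[str]
    calls: dict[str, str | None] = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "indel"):
            raise ValueError(f"bad site kind {self.kind!r}")
        if self.coordinate >= 0:
            raise ValueError("site coordinates are negative (ATG-relative)")

    def alleles(self) -> list[str]:
        return [self.ref_allele, *self.alt_alleles]


def read_aligned_fasta(
    path, reference_id: str, atg_column: int
) -> PromoterAlignment:
    """Read an aligned multi-FASTA; lowercase is uppercased on input.

    A ``subgroup=<name>`` token in the description assigns the record's
    subgroup; records without one are ``other``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        subgroup = "other"
        for token in rec.description.split():
            if token.startswith("subgroup="):
                subgroup = token.split("=", 1)[1]
        records.append(AlignmentRecord(rec.id, subgroup, str(rec.seq).upper()))
    return PromoterAlignment(records, reference_id, atg_column)


def write_aligned_fasta(aln: PromoterAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.accession_id, description=f"subgroup={r.subgroup}")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def column_to_coordinate(aln: PromoterAlignment, column: int) -> int:
    """ATG-relative coordinate of an alignment column.

    The coordinate is minus the number of non-gap reference bases in columns
    ``[column, atg_column)``; the base immediately 5' of the ATG is -1.  For a
    reference-gap column (an insertion) this anchors at the first reference
    base 3' of the gap.
    """
    if not 0 <= column < aln.atg_column:
        raise AlignmentError(
            f"column {column} not upstream of ATG column {aln.atg_column}"
        )
    ref = aln.reference_sequence
    n_bases = sum(1 for c in ref[column : aln.atg_column] if c != "-")
    if n_bases == 0:
        raise AlignmentError(
            f"column {column}: insertion abuts the ATG, no upstream reference base"
        )
    return -n_bases


def _site_id(kind: str, coordinate: int) -> str:
    return f"{kind.lower()}@{coordinate}"


def _alt_alleles(calls: dict[str, str | None], ref_allele: str) -> list[str]:
    observed = [a for a in calls.values() if a is not None and a != ref_allele]
    counts: dict[str, int] = {}
    for a in observed:
        counts[a] = counts.get(a, 0) + 1
    return sorted(counts, key=lambda a: (-counts[a], a))


def call_polymorphic_sites(aln: PromoterAlignment) -> list[PolymorphicSite]:
    """Call SNP and indel sites in the promoter columns of the alignment.

    A column (or merged maximal gap run) yields a site iff it carries at least
    two distinct non-missing alleles.  ``N`` is missing data, never an allele;
    a column varying only through N is not a site.  Sites are returned sorted
    by coordinate ascending (most upstream first).
    """
    n_prom = aln.atg_column
    if n_prom <= 0:
        raise AlignmentError("alignment has zero promoter columns")
    seqs = {r.accession_id: r.sequence for r in aln.records}
    ref_id = aln.reference_id

    gapped = [any(seq[c] == "-" for seq in seqs.values()) for c in range(n_prom)]

    sites: list[PolymorphicSite] = []

    # maximal gap runs -> one indel event each
    for is_gap, group in itertools.groupby(range(n_prom), key=lambda c: gapped[c]):
        cols = list(group)
        if not is_gap:
            continue
        a, b = cols[0], cols[-1] + 1
        calls: dict[str, str | None] = {}
        for acc, seq in seqs.items():
            segment = seq[a:b]
            calls[acc] = None if "N" in segment else segment.replace("-", "")
        ref_allele = calls[ref_id]
        if ref_allele is None:
            raise AlignmentError(f"reference has missing data in indel run at column {a}")
        distinct = {v for v in calls.values() if v is not None}
        if len(distinct) < 2:
            continue
        coord = column_to_coordinate(aln, a)
        sites.append(
            PolymorphicSite(
                site_id=_site_id("indel", coord),
                coordinate=coord,
                kind="indel",
                ref_allele=ref_allele,
                alt_alleles=_alt_alleles(calls, ref_allele),
                calls=calls,
            )
        )

    # remaining columns -> SNPs
    for c in range(n_prom):
        if gapped[c]:
            continue
        column = {acc: seq[c] for acc, seq in seqs.items()}
        calls = {acc: (None if b == "N" else b) for acc, b in column.items()}
        distinct = {v for v in calls.values() if v is not None}
        if len(distinct) < 2:
            continue
        ref_allele = calls[ref_id]
        if ref_allele is None:
            raise AlignmentError(f"reference has missing data at column {c}")
        coord = column_to_coordinate(aln, c)
        sites.append(
            PolymorphicSite(
                site_id=_site_id("snp", coord),
                coordinate=coord,
                kind="SNP",
                ref_allele=ref_allele,
                alt_alleles=_alt_alleles(calls, ref_allele),
                calls=calls,
            )
        )

    sites.sort(key=lambda s: (s.coordinate, s.kind != "indel", s.site_id))
    return sites


def _encode(allele: str | None) -> str:
    if allele is None:
        return MISSING_TOKEN
    if allele == "":
        return EMPTY_TOKEN
    return allele


def _decode(token: str) -> str | None:
    if token == MISSING_TOKEN:
        return None
    if token == EMPTY_TOKEN:
        return ""
    return token


def write_site_table(sites: list[PolymorphicSite], path) -> None:
    """Write sites as TSV: id, coordinate, kind, ref/alt alleles, calls.

    Empty alleles (deletions / absent insertions) are encoded ``-`` and
    missing calls ``.``; :func:`read_site_table` round-trips exactly.
    """
    if not sites:
        raise ValueError("no sites to write")
    accessions = list(sites[0].calls)
    with open(path, "w") as fh:
        fh.write(
            "site_id\tcoordinate\tkind\tref_allele\talt_alleles\t"
            + "\t".join(accessions)
            + "\n"
        )
        for s in sites:
            row = [
                s.site_id,
                str(s.coordinate),
                s.kind,
                _encode(s.ref_allele),
                ",".join(_encode(a) for a in s.alt_alleles),
            ]
            row += [_encode(s.calls.get(a)) for a in accessions]
            fh.write("\t".join(row) + "\n")


def read_site_table(path) -> list[PolymorphicSite]:
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        accessions = header[5:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            site_id, coord, kind, ref, alts = fields[:5]
            calls = {a: _decode(tok) for a, tok in zip(accessions, fields[5:])}
            sites.append(
                PolymorphicSite(
                    site_id=site_id,
                    coordinate=int(coord),
                    kind=kind,
                    ref_allele=_decode(ref),
                    alt_alleles=[_decode(a) for a in alts.split(",")] if alts else [],
                    calls=calls,
                )
            )
    return sites
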