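"""Consensus-motif scanning in promoter sequences.

Motifs are lists of IUPAC consensus patterns scanned on the forward strand;
optionally the reverse complement of each pattern is scanned too.  All
overlapping occurrences are counted by default (a ``--no-overlap`` mode
counts left-to-right non-overlapping matches per pattern).  ``N`` in the
sequence never matches any pattern position.

The shipped defaults follow field conventions: the Dof-binding consensus is
AAAG with reverse complement CTTT -- scanning both on the forward strand
already covers both strands -- and the WRKY W-box core is TTGAC/GTCAA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
import yaml

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifDef:
    name: str
    patterns: list[str]
    both_strands: bool = False

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif {self.name!r} has no patterns")
        for p in self.patterns:
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"pattern {p!r}: invalid IUPAC characters {sorted(bad)}")
        self.patterns = [p.upper() for p in self.patterns]


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based start on the forward sequence
    pattern: str
    strand: str  # "+" | "-"


def default_motifs() -> list[MotifDef]:
    return [
        MotifDef("Dof", ["AAAG", "CTTT"]),  # CTTT is the AAAG reverse complement
        MotifDef("WRKY_Wbox", ["TTGAC", "GTCAA"]),
    ]


def _pattern_body(pattern: str) -> str:
    return "".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in pattern)


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead makes overlapping matches visible to finditer
    return re.compile(f"(?=({_pattern_body(pattern)}))")


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    return sequence


def scan_motifs(sequence: str, motif: MotifDef) -> list[MotifHit]:
    """All (overlapping) occurrences of a motif's patterns, 1-based positions."""
    sequence = _validate_sequence(sequence)
    strands = [(p, "+") for p in motif.patterns]
    if motif.both_strands:
        strands += [(reverse_complement(p), "-") for p in motif.patterns]
    hits = []
    for pattern, strand in strands:
        for m in _pattern_regex(pattern).finditer(sequence):
            hits.append(MotifHit(m.start() + 1, pattern, strand))
    hits.sort(key=lambda h: (h.position, h.pattern, h.strand))
    return hits


def count_motifs(sequence: str, motif: MotifDef, overlapping: bool = True) -> int:
    if overlapping:
        return len(scan_motifs(sequence, motif))
    sequence = _validate_sequence(sequence)
    strands = list(motif.patterns)
    if motif.both_strands:
        strands += [reverse_complement(p) for p in motif.patterns]
    total = 0
    for pattern in strands:
        total += len(re.findall(_pattern_body(pattern), sequence))
    return total


def differential_motifs(
    seq_a: str, seq_b: str, motifs: list[MotifDef] | None = None, overlapping: bool = True
) -> pd.DataFrame:
    """Per-motif counts in two sequences and their difference (b - a)."""
    motifs = motifs if motifs is not None else default_motifs()
    rows = [
        {
            "motif": m.name,
            "count_a": count_motifs(seq_a, m, overlapping),
            "count_b": count_motifs(seq_b, m, overlapping),
        }
        for m in motifs
    ]
    df = pd.DataFrame(rows)
    df["delta"] = df["count_b"] - df["count_a"]
    return df


def load_motifs_yaml(path) -> list[MotifDef]:
    """Read motif definitions from YAML: a list of {name, patterns, both_strands}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        MotifDef(
            name=item["name"],
            patterns=list(item["patterns"]),
            both_strands=bool(item.get("both_strands", False)),
        )
        for item in raw
    ]


def write_motif_counts(df: pd.DataFrame, path, overlapping: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# overlapping={overlapping}\n")
        df.to_csv(fh, sep="\t", index=False)
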