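"""Synthetic data generators with ground-truth records.

Every generator is a pure function of its configuration (including the
seed) and returns, alongside the data, a truth record describing what was
planted, so downstream tests consume truth instead of re-deriving it.

The promoter panel generator emulates the structure of a candidate-gene
promoter resequencing study: ~105 cultivated accessions from five subgroups,
a 2-kb aligned promoter with 21 polymorphic sites (SNPs + indels) collapsing
into 8 haplotypes, 15 of the sites differential between the indica-like and
japonica-like halves of the panel, chlorophyll phenotypes whose means differ
between the two halves, and wild outgroup sequences derived from the two
founder promoters.  The indica-like haplotypes optionally carry an AAAAGCTC
insertion anchored at coordinate -1377, which adds exactly one Dof (AAAG)
motif; all other planted variants are chosen motif-neutral so that promoter
pairs differ in Dof count only through the insertion.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from skimage.color import hsv2rgb

from .alignment import AlignmentRecord, PolymorphicSite, PromoterAlignment
from .diversity import SiteFrequencyRecord
from .haplotypes import PhenotypeTable
from .phylogeny import DistanceMatrix
from .traits import COLOR_CLASSES, ColorThresholdConfig

# patterns kept invariant when planting variants (Dof + W-box, both strands)
_MOTIF_PATTERNS = ("AAAG", "CTTT", "TTGAC", "GTCAA")

DEFAULT_SUBGROUP_COUNTS = {
    "indica": 30,
    "temperate_japonica": 41,
    "tropical_japonica": 16,
    "aromatic": 8,
    "aus": 10,
}
_INDICA_LIKE = ("indica", "aus")
_JAPONICA_LIKE = ("temperate_japonica", "tropical_japonica", "aromatic")
_ABBREV = {
    "indica": "IND",
    "temperate_japonica": "TEJ",
    "tropical_japonica": "TRJ",
    "aromatic": "ARO",
    "aus": "AUS",
}


class ConfigError(ValueError):
    pass


@dataclass
class PanelConfig:
    """Study conditions for the synthetic promoter panel."""

    n_per_subgroup: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_COUNTS)
    )
    n_sites: int = 21
    n_indels: int = 3
    n_differential_sites: int = 15
    n_haplotypes: int = 8
    causal_effect: float = -10.0  # chlorophyll units per causal (alt) allele
    baseline: float = 300.0  # japonica-like expected chlorophyll
    noise_sd: float = 40.0  # accession-level Gaussian noise
    replicate_sd: float = 0.0  # optional replicate-level noise
    n_replicates: int = 3
    promoter_length: int = 2000
    insertion_event: bool = True
    insertion_coordinate: int = -1377
    insertion_sequence: str = "AAAAGCTC"
    n_wild_per_species: int = 2
    n_wild_private_snps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.n_per_subgroup.values()):
            raise ConfigError("subgroup counts must be positive")
        if not 0 <= self.n_differential_sites <= self.n_sites:
            raise ConfigError("n_differential_sites must be within n_sites")
        if self.n_indels > self.n_sites:
            raise ConfigError("more indels than sites")
        if not (math.isfinite(self.causal_effect) and math.isfinite(self.noise_sd)):
            raise ConfigError("effect and noise must be finite")
        if self.n_haplotypes < 2:
            raise ConfigError("need at least two haplotypes")


@dataclass
class PanelTruth:
    """What the panel generator planted."""

    haplotype_members: list[list[str]]  # indica-like haps first, then japonica-like
    indica_like_accessions: list[str]
    japonica_like_accessions: list[str]
    differential_coordinates: list[int]
    neutral_coordinates: list[int]
    causal_coordinates: list[int]  # == differential (the causal block)
    expected_phenotype: dict[str, float]
    wild_accessions: dict[str, list[str]]
    reference_id: str
    insertion_coordinate: int | None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PanelTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def partition(self) -> set[frozenset[str]]:
        return {frozenset(m) for m in self.haplotype_members}


@dataclass
class PanelResult:
    alignment: PromoterAlignment  # cultivated + wild records
    phenotype: PhenotypeTable  # cultivated accessions only
    truth: PanelTruth

    def cultivated_alignment(self) -> PromoterAlignment:
        return self.alignment.cultivated()


def _motif_counts(segment: str) -> tuple[int, ...]:
    return tuple(
        sum(1 for i in range(len(segment)) if segment.startswith(p, i))
        for p in _MOTIF_PATTERNS
    )


def _quota_split(total: int, weights: list[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` across weights."""
    raw = [total * w / sum(weights) for w in weights]
    counts = [int(x) for x in raw]
    remainders = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


def _neutral_carrier_sets(n_haps_per_group: int, n_neutral: int) -> list[list[int]]:
    """Within-group hap indices carrying the alt allele at each neutral site.

    The subsets cycle through singletons and adjacent pairs (hap 0 last), so
    that the first sites already separate haplotypes within each group.
    """
    base: list[list[int]] = [[i] for i in range(1, n_haps_per_group)]
    base += [[i, i + 1] for i in range(1, n_haps_per_group - 1)]
    base += [[0]]
    if not base:
        base = [[0]]
    return [base[i % len(base)] for i in range(n_neutral)]


def simulate_promoter_panel(cfg: PanelConfig) -> PanelResult:
    """Generate the aligned panel, phenotypes, and the truth record."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.promoter_length

    # ---- base (japonica-founder) promoter sequence -------------------------
    base = rng.choice(list("ACGT"), size=L).tolist()

    def plant(pos0: int, text: str) -> None:
        base[pos0 : pos0 + len(text)] = list(text)

    used = np.zeros(L, dtype=bool)  # positions reserved by planted events

    def reserve(a: int, b: int) -> None:
        used[max(a, 0) : min(b, L)] = True

    # insertion event: fixed motif-free flanks around the anchor
    ins_anchor = None
    if cfg.insertion_event:
        ins_anchor = L + cfg.insertion_coordinate  # 0-based anchor index
        if not 6 <= ins_anchor <= L - 6:
            raise ConfigError("insertion coordinate outside the promoter")
        plant(ins_anchor - 6, "CACCGC")
        plant(ins_anchor, "CACGCC")
        reserve(ins_anchor - 12, ins_anchor + 12)

    # deletion events: GC-only flanks, deleted bases from {C, A}
    n_deletions = cfg.n_indels - (1 if cfg.insertion_event else 0)
    if n_deletions < 0:
        raise ConfigError("insertion_event requires n_indels >= 1")
    deletion_coords = [-850, -400, -1100, -1650, -600, -1900][:n_deletions]
    if n_deletions > 6:
        raise ConfigError("at most 6 deletion events supported")
    deletions = []  # (coordinate, anchor0, deleted_bases)
    for k, coord in enumerate(deletion_coords):
        anchor = L + coord
        width = 2 if k % 2 == 0 else 1
        deleted = "CA"[:width]
        plant(anchor - 6, "CGGCGC")
        plant(anchor, deleted)
        plant(anchor + width, "GCGGCG")
        reserve(anchor - 12, anchor + width + 12)
        deletions.append((coord, anchor, deleted))

    # ---- SNP sites: motif-neutral substitutions ----------------------------
    n_snps = cfg.n_sites - cfg.n_indels
    if n_snps < 0:
        raise ConfigError("n_indels exceeds n_sites")
    snp_sites = []  # (coordinate, pos0, ref_base, alt_base)
    guard = 0
    while len(snp_sites) < n_snps:
        guard += 1
        if guard > 200_000:
            raise ConfigError("could not place motif-neutral SNPs; relax the config")
        pos0 = int(rng.integers(6, L - 6))
        if used[pos0 - 6 : pos0 + 7].any():
            continue
        ref_base = base[pos0]
        window = "".join(base[pos0 - 5 : pos0 + 6])
        before = _motif_counts(window)
        candidates = [b for b in "ACGT" if b != ref_base]
        rng.shuffle(candidates)
        alt = None
        for b in candidates:
            w = window[:5] + b + window[6:]
            if _motif_counts(w) == before:
                alt = b
                break
        if alt is None:
            continue
        reserve(pos0 - 6, pos0 + 7)
        snp_sites.append((pos0 - L, pos0, ref_base, alt))

    # ---- differential vs neutral assignment --------------------------------
    events: list[dict] = []
    if cfg.insertion_event:
        events.append(
            {"kind": "insertion", "coordinate": cfg.insertion_coordinate, "anchor": ins_anchor}
        )
    for k, (coord, anchor, deleted) in enumerate(deletions):
        events.append(
            {"kind": "deletion", "coordinate": coord, "anchor": anchor, "bases": deleted,
             "differential": k % 2 == 0}
        )
    n_diff_indels = (1 if cfg.insertion_event else 0) + sum(
        1 for e in events if e["kind"] == "deletion" and e["differential"]
    )
    if n_diff_indels > cfg.n_differential_sites:
        raise ConfigError("differential indels exceed n_differential_sites")
    n_diff_snps = cfg.n_differential_sites - n_diff_indels
    if n_diff_snps > n_snps:
        raise ConfigError("not enough SNPs for the differential block")
    snp_sites.sort()
    for i, (coord, pos0, ref_base, alt) in enumerate(snp_sites):
        events.append(
            {"kind": "snp", "coordinate": coord, "anchor": pos0, "ref": ref_base,
             "alt": alt, "differential": i < n_diff_snps}
        )
    if cfg.insertion_event:
        events[0]["differential"] = True

    differential = [e for e in events if e["differential"]]
    neutral = [e for e in events if not e["differential"]]
    if len(neutral) < 1 and cfg.n_haplotypes > 2:
        raise ConfigError("no neutral sites to distinguish haplotypes within groups")

    # ---- haplotype design ---------------------------------------------------
    n_a = (cfg.n_haplotypes + 1) // 2  # indica-like haplotypes
    n_b = cfg.n_haplotypes - n_a
    carriers = _neutral_carrier_sets(max(n_a, n_b), len(neutral))

    def neutral_signature(group_size: int, hap_index: int) -> tuple[bool, ...]:
        return tuple(
            hap_index in carrier and hap_index < group_size for carrier in carriers
        )

    sigs_a = [neutral_signature(n_a, i) for i in range(n_a)]
    sigs_b = [neutral_signature(n_b, i) for i in range(n_b)]
    if len(set(sigs_a)) != n_a or len(set(sigs_b)) != n_b:
        raise ConfigError(
            "config demands more haplotypes than distinct allele vectors; "
            "add neutral sites or reduce n_haplotypes"
        )

    # ---- accession allocation ----------------------------------------------
    weights = [0.5, 0.25, 0.15, 0.1, 0.06, 0.04]

    def allocate(subgroup_order: tuple[str, ...], n_haps: int) -> list[list[str]]:
        accs: list[str] = []
        for sg in subgroup_order:
            count = cfg.n_per_subgroup.get(sg, 0)
            accs += [f"{_ABBREV[sg]}{i + 1:03d}" for i in range(count)]
        quotas = _quota_split(len(accs), weights[:n_haps])
        out, start = [], 0
        for q in quotas:
            out.append(accs[start : start + q])
            start += q
        return out

    members_a = allocate(_INDICA_LIKE, n_a)
    members_b = allocate(_JAPONICA_LIKE, n_b)
    if any(not m for m in members_a + members_b):
        raise ConfigError("empty haplotype under this subgroup allocation")

    subgroup_of: dict[str, str] = {}
    for sg in (*_INDICA_LIKE, *_JAPONICA_LIKE):
        for i in range(cfg.n_per_subgroup.get(sg, 0)):
            subgroup_of[f"{_ABBREV[sg]}{i + 1:03d}"] = sg

    # ---- build aligned haplotype sequences ---------------------------------
    snp_alt = {e["anchor"]: e["alt"] for e in events if e["kind"] == "snp"}
    del_by_anchor = {
        e["anchor"]: e for e in events if e["kind"] == "deletion"
    }
    ins_len = len(cfg.insertion_sequence) if cfg.insertion_event else 0

    def build_sequence(carries: dict[int, bool]) -> str:
        """Aligned promoter for a haplotype; ``carries`` maps anchor -> alt?"""
        cells = list(base)
        for anchor, e in del_by_anchor.items():
            if carries.get(anchor, False):
                for k in range(len(e["bases"])):
                    cells[anchor + k] = "-"
        for anchor, alt in snp_alt.items():
            if carries.get(anchor, False):
                cells[anchor] = alt
        if cfg.insertion_event:
            segment = (
                cfg.insertion_sequence
                if carries.get(ins_anchor, False)
                else "-" * ins_len
            )
            cells.insert(ins_anchor, segment)
        return "".join(cells)

    def carries_for(is_indica_like: bool, sig: tuple[bool, ...]) -> dict[int, bool]:
        carries: dict[int, bool] = {}
        for e in differential:
            carries[e["anchor"]] = is_indica_like
        for j, e in enumerate(neutral):
            carries[e["anchor"]] = sig[j]
        return carries

    hap_seqs_a = [build_sequence(carries_for(True, s)) for s in sigs_a]
    hap_seqs_b = [build_sequence(carries_for(False, s)) for s in sigs_b]

    atg_column = L + ins_len
    suffix = "ATGGCT"  # start codon + one downstream codon

    records: list[AlignmentRecord] = []
    for members, seqs in ((members_a, hap_seqs_a), (members_b, hap_seqs_b)):
        for hap_members, seq in zip(members, seqs):
            for acc in hap_members:
                records.append(AlignmentRecord(acc, subgroup_of[acc], seq + suffix))

    # ---- wild outgroups -----------------------------------------------------
    founder_a = build_sequence(carries_for(True, tuple(False for _ in neutral)))
    founder_b = build_sequence(carries_for(False, tuple(False for _ in neutral)))
    wild_accessions: dict[str, list[str]] = {"wild_nivara": [], "wild_rufipogon": []}

    def add_wild(prefix: str, subgroup: str, founder: str) -> None:
        for w in range(cfg.n_wild_per_species):
            seq = list(founder)
            placed = 0
            while placed < cfg.n_wild_private_snps:
                pos = int(rng.integers(0, len(seq)))
                if seq[pos] in "ACGT":
                    # map back to promoter index to respect reserved zones
                    prom_pos = pos if pos < (ins_anchor or len(seq)) else pos - ins_len
                    if cfg.insertion_event and ins_anchor <= pos < ins_anchor + ins_len:
                        continue
                    if 0 <= prom_pos < L and used[prom_pos]:
                        continue
                    choices = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = choices[int(rng.integers(0, 3))]
                    placed += 1
            acc = f"{prefix}{w + 1:02d}"
            wild_accessions[subgroup].append(acc)
            records.append(AlignmentRecord(acc, subgroup, "".join(seq) + suffix))

    if cfg.n_wild_per_species > 0:
        add_wild("NIV", "wild_nivara", founder_a)
        add_wild("RUF", "wild_rufipogon", founder_b)

    # the first japonica-like (all-reference-pattern at the differential
    # block) accession serves as the Nipponbare-like reference
    reference_id = members_b[0][0]
    alignment = PromoterAlignment(records, reference_id, atg_column)

    # ---- phenotypes ---------------------------------------------------------
    n_causal = len(differential)
    expected: dict[str, float] = {}
    rows: dict[str, tuple[str, list[float]]] = {}
    for members, is_a in ((members_a, True), (members_b, False)):
        for hap_members in members:
            for acc in hap_members:
                mu = cfg.baseline + cfg.causal_effect * (n_causal if is_a else 0)
                expected[acc] = mu
    for acc in [r.accession_id for r in records if r.subgroup not in wild_accessions]:
        mu = expected[acc]
        value = mu + rng.normal(0.0, cfg.noise_sd)
        reps = value + rng.normal(0.0, cfg.replicate_sd, size=cfg.n_replicates)
        reps = np.clip(reps, 0.0, None)
        rows[acc] = (subgroup_of[acc], [float(v) for v in reps])
    phenotype = PhenotypeTable(rows)

    truth = PanelTruth(
        haplotype_members=[list(m) for m in members_a + members_b],
        indica_like_accessions=[a for m in members_a for a in m],
        japonica_like_accessions=[a for m in members_b for a in m],
        differential_coordinates=sorted(e["coordinate"] for e in differential),
        neutral_coordinates=sorted(e["coordinate"] for e in neutral),
        causal_coordinates=sorted(e["coordinate"] for e in differential),
        expected_phenotype=expected,
        wild_accessions=wild_accessions,
        reference_id=reference_id,
        insertion_coordinate=cfg.insertion_coordinate if cfg.insertion_event else None,
    )
    return PanelResult(alignment, phenotype, truth)


def simulate_null_association_sites(
    n_sites: int = 1000,
    n_accessions: int = 105,
    seed: int = 0,
    phenotype_mean: float = 300.0,
    phenotype_sd: float = 40.0,
) -> tuple[list[PolymorphicSite], PhenotypeTable]:
    """Independent random sites plus genotype-independent phenotypes.

    Each site splits the accessions at a random allele frequency in
    [0.2, 0.8] (both groups at least 2); phenotypes are iid normal, so every
    site is null.  Used for calibration of the permutation p-values.
    """
    rng = np.random.default_rng(seed)
    accs = [f"ACC{i + 1:04d}" for i in range(n_accessions)]
    sites = []
    for s in range(n_sites):
        while True:
            maf = rng.uniform(0.2, 0.8)
            alleles = np.where(rng.random(n_accessions) < maf, "A", "G")
            alleles[0] = "A"  # the reference accession
            n_ref = int(np.sum(alleles == "A"))
            if 2 <= n_ref <= n_accessions - 2:
                break
        coord = -(s + 1)
        sites.append(
            PolymorphicSite(
                site_id=f"null@{coord}",
                coordinate=coord,
                kind="SNP",
                ref_allele="A",
                alt_alleles=["G"],
                calls={a: str(b) for a, b in zip(accs, alleles)},
            )
        )
    values = rng.normal(phenotype_mean, phenotype_sd, size=n_accessions)
    values = np.clip(values, 0.0, None)
    pheno = PhenotypeTable({a: ("other", [float(v)]) for a, v in zip(accs, values)})
    return sites, pheno


@dataclass
class DiversityTruth:
    sweep_window_indices: list[int]
    pi_background: float
    sweep_reduction: float
    n_chromosomes: int
    expected_neutral_ratio: float = 1.0


def simulate_diversity_profile(
    n_windows: int = 202,
    window_size: int = 20_000,
    pi_background: float = 1e-3,
    sweep_windows: list[int] | None = None,
    sweep_reduction: float = 10.0,
    n_chromosomes: int = 20,
    seed: int = 0,
) -> tuple[list[SiteFrequencyRecord], DiversityTruth]:
    """Windowed allele-count records with planted sweep windows.

    Per window and population, the number of segregating sites is Poisson
    with mean chosen so the expected window diversity matches the target;
    allele frequencies are uniform in [0.1, 0.9] and counts binomial, which
    makes the unbiased site estimator exactly unbiased for 2p(1-p).  In
    sweep windows the domesticated target diversity is divided by
    ``sweep_reduction``.
    """
    if sweep_reduction <= 1.0 and sweep_windows:
        raise ValueError("sweep_reduction <= 1 is not a sweep")
    sweep = set(sweep_windows or [])
    if any(not 0 <= w < n_windows for w in sweep):
        raise ValueError("sweep window index outside the tiling")
    rng = np.random.default_rng(seed)
    lo, hi = 0.1, 0.9
    # E[2p(1-p)] for p ~ U(lo, hi); binomial sampling then makes
    # E[pi_site] = 2p(1-p) exactly under the unbiased estimator
    e_p = (lo + hi) / 2.0
    e_p2 = (lo * lo + lo * hi + hi * hi) / 3.0
    mean_site_pi = 2.0 * (e_p - e_p2)

    records: list[SiteFrequencyRecord] = []
    for w in range(n_windows):
        start = w * window_size
        for population in ("wild", "domesticated"):
            target = pi_background
            if population == "domesticated" and w in sweep:
                target /= sweep_reduction
            lam = target * window_size / mean_site_pi
            n_seg = int(rng.poisson(lam))
            n_seg = min(n_seg, window_size)
            positions = rng.choice(window_size, size=n_seg, replace=False) + start + 1
            freqs = rng.uniform(lo, hi, size=n_seg)
            counts = rng.binomial(n_chromosomes, freqs)
            for pos, c in zip(np.sort(positions), counts[np.argsort(positions)]):
                records.append(
                    SiteFrequencyRecord(
                        "chr", int(pos), population,
                        {"A": int(c), "G": int(n_chromosomes - c)},
                    )
                )
    truth = DiversityTruth(
        sweep_window_indices=sorted(sweep),
        pi_background=pi_background,
        sweep_reduction=sweep_reduction,
        n_chromosomes=n_chromosomes,
    )
    return records, truth


@dataclass
class ImageTruth:
    fractions: dict[str, float]  # realized (pixel-exact) class fractions
    counts: dict[str, int]
    n_foreground: int


def simulate_leaf_image(
    width: int = 120,
    height: int = 160,
    fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    jitter: float = 0.0,
    seed: int = 0,
    thresholds: ColorThresholdConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Leaf-shaped image with planted class fractions and its mask.

    Foreground pixels draw HSV colors strictly inside each class's bin;
    ``jitter`` in [0, 1] scales hue jitter as a fraction of the bin half
    width.  Background is white.  Realized fractions (largest-remainder
    pixel counts) are recorded in the truth.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    if not 0.0 <= jitter <= 1.0:
        raise ValueError("jitter must be in [0, 1]")
    cfg = thresholds or ColorThresholdConfig()
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    mask = ((yy - cy) / (height * 0.45)) ** 2 + ((xx - cx) / (width * 0.3)) ** 2 <= 1.0
    n_fore = int(mask.sum())

    counts = [int(x) for x in np.floor(fr * n_fore)]
    order = np.argsort(fr * n_fore - np.array(counts))[::-1]
    for i in order[: n_fore - sum(counts)]:
        counts[i] += 1

    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)

    hue = np.empty(n_fore)
    value = np.full(n_fore, 0.70) + rng.uniform(-0.03, 0.03, size=n_fore)
    for idx, name in enumerate(COLOR_CLASSES):
        sel = labels == idx
        lo, hi = cfg.hue_bin(name)
        center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        hue[sel] = center + rng.uniform(-1, 1, size=int(sel.sum())) * jitter * half * 0.995

    hsv = np.stack(
        [hue / 360.0, np.full(n_fore, 0.85), value], axis=1
    )
    rgb = hsv2rgb(hsv[None, :, :])[0]
    image = np.full((height, width, 3), 255, dtype=np.uint8)
    image[mask] = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    truth = ImageTruth(
        fractions={n: c / n_fore for n, c in zip(COLOR_CLASSES, counts)},
        counts=dict(zip(COLOR_CLASSES, counts)),
        n_foreground=n_fore,
    )
    return image, mask, truth


@dataclass
class YieldTruth:
    parent_mean: float
    effect_percent: float
    nil_mean: float
    sd: float
    n_per_arm: int


def simulate_growth_yield(
    parent_mean: float = 29.0,
    effect_percent: float = 12.7,
    sd: float = 2.9,
    n_per_arm: int = 16,
    seed: int = 0,
) -> tuple[dict[str, list[float]], YieldTruth]:
    """Per-plant grain yields for a parent/NIL pair with a planted effect."""
    if parent_mean <= 0:
        raise ValueError("parent_mean must be positive")
    if n_per_arm < 2:
        raise ValueError("need at least two plants per arm")
    rng = np.random.default_rng(seed)
    nil_mean = parent_mean * (1.0 + effect_percent / 100.0)
    arms = {
        "parent": [float(v) for v in rng.normal(parent_mean, sd, size=n_per_arm)],
        "nil": [float(v) for v in rng.normal(nil_mean, sd, size=n_per_arm)],
    }
    truth = YieldTruth(parent_mean, effect_percent, nil_mean, sd, n_per_arm)
    return arms, truth


def simulate_additive_distances(
    n_taxa: int, seed: int = 0, min_length: float = 0.05, max_length: float = 1.0
) -> tuple[DistanceMatrix, str]:
    """A random unrooted binary tree and its (exactly additive) leaf distances.

    Returns the distance matrix and the generating topology as Newick.  Any
    consistent distance-based method must recover the topology exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]

    def new_len() -> float:
        return float(rng.uniform(min_length, max_length))

    # adjacency: node -> {neighbor: length}; leaves are labels, internals ints
    adj: dict = {labels[0]: {}, labels[1]: {}, labels[2]: {}, 0: {}}
    for leaf in labels[:3]:
        ln = new_len()
        adj[0][leaf] = ln
        adj[leaf][0] = ln
    next_internal = 1
    edges = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    for leaf in labels[3:]:
        u, v = edges[int(rng.integers(0, len(edges)))]
        mid = next_internal
        next_internal += 1
        old = adj[u].pop(v)
        adj[v].pop(u)
        split = float(rng.uniform(0.25, 0.75)) * old
        adj[mid] = {u: split, v: old - split}
        adj[u][mid] = split
        adj[v][mid] = old - split
        ln = new_len()
        adj[leaf] = {mid: ln}
        adj[mid][leaf] = ln
        edges.remove((u, v) if (u, v) in edges else (v, u))
        edges += [(u, mid), (v, mid), (leaf, mid)]

    def distances_from(src) -> dict:
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, ln in adj[node].items():
                if nb not in out:
                    out[nb] = out[node] + ln
                    stack.append(nb)
        return out

    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        dist = distances_from(a)
        for j, b in enumerate(labels):
            d[i, j] = dist[b]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0

    def newick(node, parent) -> str:
        if isinstance(node, str):
            return node
        parts = [
            f"{newick(nb, node)}:{ln:.10f}"
            for nb, ln in adj[node].items()
            if nb != parent
        ]
        return "(" + ",".join(parts) + ")"

    return DistanceMatrix(labels, d), newick(0, None) + ";"
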