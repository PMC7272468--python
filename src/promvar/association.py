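"""Per-site phenotype association with a permutation empirical null.

At each polymorphic site the accessions split into two groups: those whose
allele equals the reference accession's allele and those whose allele differs
(exact string match, so indel alleles work unchanged).  Group chlorophyll
means are compared with the pooled-variance (equal-variance) Student t
statistic.  An empirical null is built by shuffling the accession-level
phenotype vector ``n_perm`` times -- one shuffle shared by all sites per
iteration, genotypes fixed -- and recomputing T at every non-degenerate site.
By default the permuted T values are pooled over sites into a single null
distribution; a per-site null is available with ``pooled=False``.  The
two-tailed adjusted p-value is add-one smoothed,

    p = (1 + #{ |t*| >= |T_obs| }) / (1 + N_null),

so p is in (0, 1] and never exactly zero.  Sites where either group has
fewer than two phenotyped accessions (or where the pooled variance vanishes
with unequal means) are flagged degenerate and excluded from both the null
and the significance tally.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .alignment import PolymorphicSite
from .haplotypes import PhenotypeTable


class DegenerateGroupsError(ValueError):
    """A two-group comparison without a defined t statistic."""


@dataclass
class SiteAssociation:
    site_id: str
    coordinate: int
    n_same: int
    n_diff: int
    t: float
    p_adjusted: float
    significant: bool
    differentiates_subspecies: bool
    degenerate: bool = False


@dataclass
class AssociationReport:
    n_sites: int
    n_significant: int
    n_significant_and_differential: int
    n_degenerate: int


def split_by_reference(
    site: PolymorphicSite, pheno: PhenotypeTable
) -> tuple[list[float], list[float]]:
    """Accession-mean phenotypes grouped by reference vs non-reference allele."""
    same, diff = [], []
    for acc in pheno.accessions:
        allele = site.calls.get(acc)
        if allele is None:
            continue
        (same if allele == site.ref_allele else diff).append(pheno.accession_mean(acc))
    return same, diff


def t_statistic(a, b) -> float:
    """Pooled-variance Student two-sample t, T = (mean a - mean b) / (s_p sqrt(1/na+1/nb))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise DegenerateGroupsError(f"group sizes {na}, {nb} below 2")
    delta = a.mean() - b.mean()
    sp2 = (a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1)) / (na + nb - 2)
    if sp2 <= 0.0:
        if delta == 0.0:
            return 0.0
        raise DegenerateGroupsError("zero pooled variance with unequal means")
    return float(delta / math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def _site_masks(
    sites: list[PolymorphicSite], pheno: PhenotypeTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[bool]]:
    """Boolean same/diff membership matrices over phenotyped accessions."""
    accs = pheno.accessions
    values = np.array([pheno.accession_mean(a) for a in accs])
    n_sites = len(sites)
    same = np.zeros((n_sites, len(accs)), dtype=bool)
    diff = np.zeros((n_sites, len(accs)), dtype=bool)
    for i, site in enumerate(sites):
        for j, acc in enumerate(accs):
            allele = site.calls.get(acc)
            if allele is None:
                continue
            (same if allele == site.ref_allele else diff)[i, j] = True
    degenerate = [
        same[i].sum() < 2 or diff[i].sum() < 2 for i in range(n_sites)
    ]
    return values, same, diff, degenerate


def _batch_t(values: np.ndarray, same: np.ndarray, diff: np.ndarray) -> np.ndarray:
    """T at each site (rows of same/diff) for each row of ``values``.

    ``values`` is (n_vectors, n_accessions); returns (n_vectors, n_sites).
    Sites must be non-degenerate (both groups >= 2).
    """
    values = np.atleast_2d(values)
    a_mask = same.T.astype(float)  # (n_acc, n_sites)
    b_mask = diff.T.astype(float)
    na = a_mask.sum(axis=0)
    nb = b_mask.sum(axis=0)
    s1a = values @ a_mask
    s1b = values @ b_mask
    sq = values**2
    s2a = sq @ a_mask
    s2b = sq @ b_mask
    ma = s1a / na
    mb = s1b / nb
    ssa = s2a - s1a**2 / na
    ssb = s2b - s1b**2 / nb
    sp2 = (ssa + ssb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def permutation_null(
    sites: list[PolymorphicSite],
    pheno: PhenotypeTable,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Pooled empirical null T values from phenotype permutations.

    Each permutation shuffles the accession-mean phenotype vector once and
    recomputes T at every non-degenerate site with the observed group
    memberships; all T values are pooled.  With ``exhaustive=True`` all
    orderings of the phenotype vector are enumerated instead (small n only).
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values, same, diff, degenerate = _site_masks(sites, pheno)
    keep = ~np.asarray(degenerate)
    if not keep.any():
        raise DegenerateGroupsError("all sites degenerate")
    same, diff = same[keep], diff[keep]
    if exhaustive:
        perms = np.array(list(itertools.permutations(values)), dtype=float)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(values) for _ in range(n_perm)])
    return _batch_t(perms, same, diff).ravel()


def adjusted_p(t_obs: float, null_t) -> float:
    """Add-one smoothed two-tailed empirical p-value against a null T set."""
    null_abs = np.abs(np.asarray(null_t, dtype=float))
    if null_abs.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.sum(null_abs >= abs(t_obs))) / (1 + null_abs.size))


def differentiates_subspecies(site: PolymorphicSite, subgroups: dict[str, str]) -> bool:
    """True iff the site's majority allele differs between the *indica* and
    *temperate japonica* subgroups (missing calls excluded)."""

    def majority(group: str) -> str | None:
        counts: dict[str, int] = {}
        for acc, allele in site.calls.items():
            if allele is not None and subgroups.get(acc) == group:
                counts[allele] = counts.get(allele, 0) + 1
        if not counts:
            return None
        return sorted(counts, key=lambda a: (-counts[a], a))[0]

    m_ind = majority("indica")
    m_jap = majority("temperate_japonica")
    if m_ind is None or m_jap is None:
        return False
    return m_ind != m_jap


def associate_sites(
    sites: list[PolymorphicSite],
    pheno: PhenotypeTable,
    subgroups: dict[str, str] | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pooled: bool = True,
) -> list[SiteAssociation]:
    """Full per-site association: observed T, permutation-adjusted p, flags."""
    if subgroups is None:
        subgroups = {a: pheno.subgroup(a) for a in pheno.accessions}
    values, same, diff, degenerate = _site_masks(sites, pheno)
    keep = ~np.asarray(degenerate)
    t_obs = np.full(len(sites), np.nan)
    if keep.any():
        t_obs[keep] = _batch_t(values, same[keep], diff[keep])[0]

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(values) for _ in range(n_perm)])
    null_t = _batch_t(perms, same[keep], diff[keep]) if keep.any() else np.empty((0, 0))

    results = []
    kept_index = np.flatnonzero(keep)
    col_of = {site_i: col for col, site_i in enumerate(kept_index)}
    pooled_null = null_t.ravel()
    for i, site in enumerate(sites):
        if degenerate[i]:
            results.append(
                SiteAssociation(
                    site_id=site.site_id,
                    coordinate=site.coordinate,
                    n_same=int(same[i].sum()),
                    n_diff=int(diff[i].sum()),
                    t=float("nan"),
                    p_adjusted=1.0,
                    significant=False,
                    differentiates_subspecies=differentiates_subspecies(site, subgroups),
                    degenerate=True,
                )
            )
            continue
        null = pooled_null if pooled else null_t[:, col_of[i]]
        p = adjusted_p(t_obs[i], null)
        results.append(
            SiteAssociation(
                site_id=site.site_id,
                coordinate=site.coordinate,
                n_same=int(same[i].sum()),
                n_diff=int(diff[i].sum()),
                t=float(t_obs[i]),
                p_adjusted=p,
                significant=p < alpha,
                differentiates_subspecies=differentiates_subspecies(site, subgroups),
            )
        )
    return results


def classify_sites(
    assocs: list[SiteAssociation], alpha: float = 0.05
) -> AssociationReport:
    """Tally significant sites and the significant-and-differential overlap."""
    if not assocs:
        raise ValueError("no associations to classify")
    sig = [a for a in assocs if not a.degenerate and a.p_adjusted < alpha]
    return AssociationReport(
        n_sites=len(assocs),
        n_significant=len(sig),
        n_significant_and_differential=sum(a.differentiates_subspecies for a in sig),
        n_degenerate=sum(a.degenerate for a in assocs),
    )


def write_association_tsv(
    assocs: list[SiteAssociation], path, n_perm: int, alpha: float, seed: int
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_perm={n_perm} alpha={alpha} seed={seed} null=pooled\n")
        fh.write(
            "site_id\tcoordinate\tn_same\tn_diff\tT\tp_adjusted\t"
            "significant\tdifferentiates_subspecies\tdegenerate\n"
        )
        for a in assocs:
            fh.write(
                f"{a.site_id}\t{a.coordinate}\t{a.n_same}\t{a.n_diff}\t"
                f"{a.t:.6g}\t{a.p_adjusted:.6g}\t{int(a.significant)}\t"
                f"{int(a.differentiates_subspecies)}\t{int(a.degenerate)}\n"
            )
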