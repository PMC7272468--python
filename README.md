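# promvar

Candidate-gene **prom**oter **var**iation analysis for resequencing panels,
built around the rice senescence locus use case: a ~2-kb promoter amplified
and Sanger-sequenced in ~105 accessions from five *Oryza sativa* subgroups,
with flag-leaf chlorophyll measured six weeks after heading as the
senescence phenotype.

The package implements the full desk-side analysis chain for such a study:

1. **Polymorphic-site discovery** in an aligned promoter panel — SNPs and
   merged indel events, reported at ATG-relative coordinates (−1 is the
   base 5′ of the start codon).
2. **Haplotype partitioning** by exact allele-vector match, with per-haplotype
   chlorophyll mean ± SE over accession means.
3. **Per-site association**: accessions split at each site into
   reference-allele vs other-allele groups, compared with the pooled-variance
   Student statistic

   *T* = (x̄₁ − x̄₂) / (s_p √(1/n₁ + 1/n₂)),

   against an empirical null built from 1000 phenotype permutations (one
   shuffle shared by all sites per iteration), two-tailed add-one adjusted
   *p* = (1 + #{|t\*| ≥ |T|}) / (1 + N). A `differentiates_subspecies` flag
   marks sites whose majority allele differs between *indica* and temperate
   *japonica*.
4. **Neighbor-joining phylogeny** (Saitou–Nei, implemented here, with
   deterministic tie-breaking) on pairwise-deletion p-distances or JC69,
   relating haplotypes to wild *O. nivara* / *O. rufipogon* outgroups;
   Newick output.
5. **Selective-sweep scan**: per-site nucleotide diversity
   π = n/(n−1)·(1 − Σₐ pₐ²) summed over 20-kb non-overlapping windows for a
   wild and a domesticated population; windows whose π_W/π_D exceeds the
   99th nearest-rank percentile are called significant.
6. **Senescence / productivity traits**: pixel-wise four-class
   (green, green-yellow, yellow, brown) HSV color scoring of masked leaf or
   panicle images; RGR = (ln W₂ − ln W₁)/(t₂ − t₁); percent yield change of
   near-isogenic lines vs parents with Student *t*; chlorophyll-trajectory
   summaries.
7. **Motif scanning**: overlapping IUPAC consensus counts (Dof AAAG/CTTT,
   WRKY W-box TTGAC by default) and per-motif differences between two
   promoter alleles.
8. **Synthetic data** for all of the above, each generator a pure function
   of (config, seed) that also emits a ground-truth record, so the whole
   pipeline is testable without any sequencing data.

## Worked example

```python
from promvar import (PanelConfig, simulate_promoter_panel, call_polymorphic_sites,
                     assign_haplotypes, haplotype_phenotype_summary,
                     associate_sites, classify_sites)

panel = simulate_promoter_panel(PanelConfig(seed=42))
aln = panel.cultivated_alignment()
sites = call_polymorphic_sites(aln)
print(f"{len(sites)} polymorphic sites "
      f"({sum(s.kind == 'indel' for s in sites)} indels), "
      f"first: {sites[0].site_id}")

haps = assign_haplotypes(sites, panel.phenotype.accessions)
print(haplotype_phenotype_summary(haps, panel.phenotype)
      .to_string(index=False, float_format="%.1f"))

assocs = associate_sites(sites, panel.phenotype, n_perm=1000, seed=42)
report = classify_sites(assocs, alpha=0.05)
print(f"{report.n_significant}/{report.n_sites} sites significant, "
      f"{report.n_significant_and_differential} also indica/japonica-differential")
```

prints

```
21 polymorphic sites (3 indels), first: snp@-1914
 hap_id  n  mean   se  size
      1 33 294.7  7.6    33
      2 20 152.8  8.2    20
      3 16 295.3  7.4    16
      4 10 152.9 11.6    10
      5 10 297.8 13.2    10
      6  6 162.3 16.2     6
      7  6 310.3 17.9     6
      8  4 127.2  7.7     4
15/21 sites significant, 15 also indica/japonica-differential
```

The 2-kb promoter panel carries 21 planted variants collapsing into eight
haplotypes; the indica-like haplotypes (2, 4, 6, 8 here — low chlorophyll,
~150 units) carry the 15-site differential block including an AAAAGCTC
insertion at −1377, while the japonica-like haplotypes sit near the 300-unit
baseline. All 15 differential sites are recovered as significant at
α = 0.05 and none of the 6 neutral sites is, in this run.

The same stages are available from the shell:

```sh
promvar simulate panel --seed 42 --out panel/
promvar variants --fasta panel/panel.fasta --reference TEJ001 --atg-column 2008 --out sites.tsv
promvar assoc --sites sites.tsv --pheno panel/phenotype.tsv --n-perm 1000 --seed 42
promvar run --config analysis.yaml --out run/       # full pipeline + summary.json
```

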