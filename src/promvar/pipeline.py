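"""End-to-end orchestration of the promoter-variation analysis.

Stages run in dependency order: variant calling -> haplotype partitioning ->
per-site association; phylogeny, sweep scan, motif comparison and trait
tables are independent and run when their inputs are configured.  Every run
directory gets per-stage TSV outputs plus a machine-readable
``summary.json`` stamped with the configuration hash and seed; reruns with
the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import alignment as aln_mod
from . import association as assoc_mod
from . import diversity as div_mod
from . import haplotypes as hap_mod
from . import motifs as motif_mod
from . import phylogeny as phylo_mod
from . import traits as traits_mod

log = logging.getLogger("promvar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Inputs and parameters for a full run; file paths may be omitted to
    skip the stages that need them."""

    fasta: str | None = None
    reference_id: str | None = None
    atg_column: int | None = None
    phenotype: str | None = None
    counts: str | None = None  # per-site allele counts for the sweep scan
    yields: str | None = None  # per-plant yield TSV (arm, grams)
    motifs_yaml: str | None = None

    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    distance_model: str = "p_distance"
    window_size: int = 20_000
    top_fraction: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_files(self) -> None:
        for name in ("fasta", "phenotype", "counts", "yields", "motifs_yaml"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"configured input {name} = {value!r} not found")


def run_pipeline(cfg: AnalysisConfig, out_dir) -> dict:
    """Execute all configured stages; returns the summary dict."""
    cfg.validate_files()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_sha256": cfg.config_hash(), "seed": cfg.seed}

    sites = None
    pheno = None
    panel = None

    if cfg.fasta is not None:
        try:
            if cfg.reference_id is None or cfg.atg_column is None:
                raise ValueError("fasta input needs reference_id and atg_column")
            panel = aln_mod.read_aligned_fasta(cfg.fasta, cfg.reference_id, cfg.atg_column)
            cultivated = panel.cultivated()
            sites = aln_mod.call_polymorphic_sites(cultivated)
            aln_mod.write_site_table(sites, out / "sites.tsv")
            summary["n_sites"] = len(sites)
            log.info("variants: %d polymorphic sites", len(sites))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("variants", str(exc)) from exc

    if sites is not None and cfg.phenotype is not None:
        try:
            pheno = hap_mod.PhenotypeTable.from_tsv(cfg.phenotype)
            haps = hap_mod.assign_haplotypes(sites, pheno.accessions)
            hap_mod.write_haplotype_table(haps, out / "haplotypes.tsv")
            summary_df = hap_mod.haplotype_phenotype_summary(haps, pheno)
            summary_df.to_csv(out / "haplotype_summary.tsv", sep="\t", index=False)
            summary["n_haplotypes"] = len(haps.haplotypes)
            summary["n_unassigned"] = len(haps.unassigned)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("haplotypes", str(exc)) from exc

        try:
            assocs = assoc_mod.associate_sites(
                sites, pheno, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
            )
            assoc_mod.write_association_tsv(
                assocs, out / "association.tsv", cfg.n_perm, cfg.alpha, cfg.seed
            )
            report = assoc_mod.classify_sites(assocs, cfg.alpha)
            summary["n_significant"] = report.n_significant
            summary["n_significant_and_differential"] = (
                report.n_significant_and_differential
            )
            summary["n_degenerate_sites"] = report.n_degenerate
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("association", str(exc)) from exc

    if panel is not None:
        try:
            dm = phylo_mod.pairwise_distance(panel, model=cfg.distance_model)
            dm.to_tsv(out / "distances.tsv")
            tree = phylo_mod.neighbor_joining(dm)
            phylo_mod.write_newick(tree, out / "tree.nwk")
            summary["n_tree_leaves"] = len(dm.labels)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("phylogeny", str(exc)) from exc

    if cfg.counts is not None:
        try:
            records = div_mod.read_counts_tsv(cfg.counts)
            windows = div_mod.sweep_scan(
                records, window_size=cfg.window_size, top_fraction=cfg.top_fraction
            )
            div_mod.write_sweep_tsv(windows, out / "sweep.tsv")
            summary["sweep"] = {
                "n_windows": len(windows),
                "n_significant": sum(w.significant for w in windows),
                "significant_windows": [
                    [w.start, w.end] for w in windows if w.significant
                ],
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("sweep", str(exc)) from exc

    if cfg.yields is not None:
        try:
            arms = traits_mod.read_yield_tsv(cfg.yields)
            comp = traits_mod.compare_groups(arms["parent"], arms["nil"])
            summary["yield"] = {
                "parent_mean": comp.parent_mean,
                "nil_mean": comp.nil_mean,
                "percent_change": traits_mod.round_half_up(comp.percent_change, 1),
                "t": comp.t,
                "p": comp.p,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("yield", str(exc)) from exc

    if panel is not None and cfg.motifs_yaml is not None:
        try:
            motifs = motif_mod.load_motifs_yaml(cfg.motifs_yaml)
            ref_seq = panel.reference_sequence.replace("-", "")
            counts = {
                m.name: motif_mod.count_motifs(ref_seq, m) for m in motifs
            }
            summary["motif_counts_reference"] = counts
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("motifs", str(exc)) from exc

    blob = json.dumps(summary, sort_keys=True, indent=1)
    (out / "summary.json").write_text(blob + "\n")
    return summary
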