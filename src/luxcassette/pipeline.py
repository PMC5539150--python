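"""End-to-end survey orchestration: mine -> reduce -> pair/classify -> AAC ->
conserve -> tree -> HGT -> co-transfer, with per-stage artifacts and a single
machine-readable report.

Stages consume files named in a :class:`PipelineConfig` (YAML-serialisable),
write TSV/FASTA/Newick artifacts into the output directory and accumulate
stage counts into a versioned JSON report.  Stage outputs are pure functions
of (inputs, config, seed); a stage failure aborts the run naming the stage,
with the artifacts of completed stages preserved.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import cassette_topology, composition, conservation, mining, phylo_hgt
from .redundancy import greedy_cluster
from .io_formats import (
    read_alignment,
    read_domain_hits,
    read_fasta,
    read_gff3,
    read_tip_metadata,
    write_fasta,
    write_newick,
)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    proteins_fasta: str
    domain_hits_tsv: str
    gff3: str
    outdir: str
    mining: mining.MiningConfig = field(default_factory=mining.MiningConfig)
    redundancy_threshold: float = 0.30
    max_gap_bp: int = cassette_topology.DEFAULT_MAX_GAP_BP
    aac_test: str = "welch"
    conservation_msas: dict[str, str] = field(default_factory=dict)
    conservation_refs: dict[str, str] = field(default_factory=dict)
    conservation_threshold: float = conservation.DEFAULT_THRESHOLD_PCT
    gene_msas: dict[str, str] = field(default_factory=dict)
    tip_metadata_tsv: str | None = None
    cassette_map: dict[str, str] = field(default_factory=dict)
    bootstrap_reps: int = 100
    min_support: float = phylo_hgt.DEFAULT_MIN_SUPPORT
    distance_correction: str = "poisson"
    seed: int = 0

    def input_paths(self) -> list[str]:
        paths = [self.proteins_fasta, self.domain_hits_tsv, self.gff3]
        paths += list(self.conservation_msas.values())
        paths += list(self.gene_msas.values())
        if self.tip_metadata_tsv:
            paths.append(self.tip_metadata_tsv)
        return paths

    def validate(self) -> None:
        missing = [p for p in self.input_paths() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"input files do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "mining" in raw and isinstance(raw["mining"], dict):
            m = dict(raw["mining"])
            for key in ("luxi_domains", "luxr_dna_domains", "luxr_abd_domains"):
                if key in m:
                    m[key] = frozenset(m[key])
            raw["mining"] = mining.MiningConfig(**m)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        m = raw["mining"]
        for key in ("luxi_domains", "luxr_dna_domains", "luxr_abd_domains"):
            m[key] = sorted(m[key])
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def validate_report(report: Mapping[str, Any]) -> None:
    required = {"schema_version", "seed", "counts", "stages"}
    missing = required - set(report)
    if missing:
        raise PipelineError(f"report lacks required keys: {sorted(missing)}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise PipelineError(
            f"unsupported report schema version {report['schema_version']}"
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage in order; returns the validated report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "counts": {},
        "stages": {},
    }
    counts = report["counts"]
    stages = report["stages"]
    stage = "load"
    try:
        proteins = read_fasta(config.proteins_fasta)
        hits = read_domain_hits(config.domain_hits_tsv)

        stage = "mine"
        luxi = mining.select_luxi(proteins, hits, config.mining)
        luxr = mining.select_luxr(proteins, hits, config.mining)
        write_fasta(luxi, outdir / "mined_luxI.fasta")
        write_fasta(luxr, outdir / "mined_luxR.fasta")
        counts["candidates_luxI"] = len(luxi)
        counts["candidates_luxR"] = len(luxr)
        stages["mine"] = {
            "luxI_lengths": mining.length_summary(luxi),
            "luxR_lengths": mining.length_summary(luxr),
        }

        stage = "reduce"
        if luxr:
            clusters = greedy_cluster(luxr, config.redundancy_threshold)
            rep_ids = {c.representative_id for c in clusters}
            reps = [p for p in luxr if p.id in rep_ids]
            write_fasta(reps, outdir / "representatives.fasta")
            _write_tsv(
                outdir / "clusters.tsv",
                ["representative_id", "member_ids", "threshold"],
                [[c.representative_id, ",".join(c.member_ids), c.threshold]
                 for c in clusters],
            )
            counts["representatives"] = len(clusters)
        else:
            counts["representatives"] = 0

        stage = "cassettes"
        class_map = {p.id: "luxI" for p in luxi}
        class_map.update({p.id: "luxR" for p in luxr})
        features = read_gff3(config.gff3)
        # map classes through protein ids where features carry them
        remapped = []
        for f in features:
            cls = class_map.get(f.protein_id, f.gene_class)
            remapped.append(dataclasses.replace(f, gene_class=cls))
        result = cassette_topology.pair_cassettes(remapped, config.max_gap_bp)
        _write_tsv(
            outdir / "cassettes.tsv",
            ["replicon", "luxI_locus", "luxR_locus", "gap_bp",
             "n_intervening", "pattern", "canonical"],
            [[p.replicon_id, p.luxI.locus_tag, p.luxR.locus_tag, p.gap_bp,
              p.n_intervening, p.pattern.render, p.canonical]
             for p in result.pairs],
        )
        counts["cassette_pairs"] = len(result.pairs)
        counts["solo_luxI"] = len(result.solo_luxi)
        counts["solo_luxR"] = len(result.solo_luxr)
        stages["cassettes"] = {
            "patterns": sorted(p.pattern.render for p in result.pairs),
        }

        stage = "aac"
        gram_pos = [p for p in luxr if p.gram == "positive"]
        gram_neg = [p for p in luxr if p.gram == "negative"]
        if len(gram_pos) >= 2 and len(gram_neg) >= 2:
            fc = composition.compare_groups(gram_pos, gram_neg, config.aac_test)
            _write_tsv(
                outdir / "aac.tsv",
                ["residue", "group1_mean", "group2_mean", "fold_change",
                 "p_value", "significant"],
                [[r.residue, f"{r.group1_mean:.6g}", f"{r.group2_mean:.6g}",
                  f"{r.fold_change:.6g}", f"{r.p_value:.6g}", r.significant]
                 for r in fc],
            )
            counts["significant_residues"] = sum(r.significant for r in fc)
            stages["aac"] = {
                "significant": [r.residue for r in fc if r.significant],
                "test": config.aac_test,
            }
        else:
            counts["significant_residues"] = 0
            stages["aac"] = {"skipped": "needs >= 2 sequences per gram group"}

        stage = "conserve"
        conserved_counts: dict[str, int] = {}
        for name, msa_path in config.conservation_msas.items():
            msa = read_alignment(msa_path)
            ref = config.conservation_refs.get(name)
            if ref is None:
                raise PipelineError(f"no conservation reference for MSA {name!r}")
            sites = conservation.site_conservation(
                msa, ref, config.conservation_threshold
            )
            _write_tsv(
                outdir / f"conservation_{name}.tsv",
                ["ref_position", "ref_residue", "alignment_column",
                 "identity_pct", "conserved"],
                [[s.ref_position, s.ref_residue, s.alignment_column,
                  f"{s.identity_pct:.4g}", s.conserved] for s in sites],
            )
            conserved_counts[name] = sum(s.conserved for s in sites)
        counts["conserved_sites"] = conserved_counts

        stage = "tree"
        trees: dict[str, Any] = {}
        builder = phylo_hgt.nj_builder(config.distance_correction)
        for k, (gene, msa_path) in enumerate(sorted(config.gene_msas.items())):
            msa = read_alignment(msa_path)
            tree = phylo_hgt.bootstrap_support(
                msa, builder, config.bootstrap_reps,
                seed=config.seed * 1000 + k,
            )
            trees[gene] = tree
            write_newick(tree, outdir / f"tree_{gene}.nwk")
        counts["trees"] = len(trees)

        stage = "hgt"
        metadata = (
            read_tip_metadata(config.tip_metadata_tsv)
            if config.tip_metadata_tsv
            else {}
        )
        calls = []
        if metadata and "16S" in trees:
            for gene in ("luxI", "luxR"):
                if gene not in trees:
                    continue
                for call in phylo_hgt.detect_hgt(
                    trees[gene], trees["16S"], metadata, config.min_support
                ):
                    calls.append((gene, call))
            _write_tsv(
                outdir / "hgt_calls.tsv",
                ["gene", "clade_tips", "support", "niche_match",
                 "reference_incongruent", "verdict"],
                [[g, ",".join(sorted(c.clade_tips)), f"{c.support:.4g}",
                  c.niche_match, c.reference_incongruent, c.verdict]
                 for g, c in calls],
            )
        counts["hgt_supported"] = sum(
            1 for _, c in calls if c.verdict == "hgt_supported"
        )
        counts["hgt_candidates"] = sum(
            1 for _, c in calls if c.verdict == "candidate"
        )

        stage = "cotransfer"
        modes = []
        if (
            metadata
            and config.cassette_map
            and all(g in trees for g in ("luxI", "luxR", "concat"))
        ):
            modes = phylo_hgt.classify_transfer_mode(
                trees["luxI"], trees["luxR"], trees["concat"],
                config.cassette_map, metadata, config.min_support,
            )
            _write_tsv(
                outdir / "transfer_modes.tsv",
                ["cassette_id", "mode", "partner_luxI", "partner_luxR",
                 "partner_concat", "reason"],
                [[m.cassette_id, m.mode, m.partner_luxi, m.partner_luxr,
                  m.partner_concat, m.reason] for m in modes],
            )
        counts["transfer_modes"] = {
            mode: sum(1 for m in modes if m.mode == mode)
            for mode in ("simultaneous", "individual", "unclear")
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    validate_report(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
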