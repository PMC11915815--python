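"""End-to-end pipeline: simulate -> filter -> rescue -> synteny ->
targeting -> sequence prep -> trees -> jackknife -> scenario call.

Every stage is a pure function of (inputs, config, seed); the manifest
records per-stage counts and SHA256 hashes of all emitted files, so two
runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import localization as loc
from . import orthogroups as og_mod
from . import phylo, scenarios, seqprep, simulate, synteny


@dataclass
class PipelineConfig:
    outdir: str = "panpm_run"
    seed: int = 0
    # orthogroup filters
    min_copy_mean_pos: float = 1.75
    max_copy_mean_neg: float = 1.25
    rescue_min_cov: float = 0.5
    rescue_min_ident: float = 0.3
    # synteny
    max_gap: int = 3
    min_taxa: int = 3
    adjacency_window: int = 3
    adjacency_consistency: float = 0.8
    # localization
    sp_prob_min: float = 0.1
    # seqprep
    dedup_identity: float = 0.65
    # jackknife / scenario
    scenario: str = "E"
    n_per_member: int = 8
    scenario_noise_sigma: float = 0.0
    k_per_member: int = 5
    n_replicates: int = 50
    min_support: float = 0.5
    # generator
    n_background_families: int = 200

    def validate(self) -> None:
        if self.min_copy_mean_pos <= 0 or self.max_copy_mean_neg <= 0:
            raise ValueError("copy-mean thresholds must be > 0")
        if not 0 < self.rescue_min_cov <= 1 or not 0 < self.rescue_min_ident <= 1:
            raise ValueError("rescue thresholds must be in (0, 1]")
        if self.max_gap < 0 or self.min_taxa < 1 or self.adjacency_window < 0:
            raise ValueError("synteny thresholds out of range")
        if not 0 < self.adjacency_consistency <= 1:
            raise ValueError("adjacency_consistency must be in (0, 1]")
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must be in (0, 1]")
        if self.scenario not in simulate.SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_replicates < 1 or self.k_per_member < 1 or self.n_per_member < 1:
            raise ValueError("replicate counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: crc32 of 'seed:stage', kept below 2^31."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    # --- simulate ----------------------------------------------------------
    spec = simulate.default_spec(seed=stage_seed(config.seed, "simulate"))
    spec.n_background_families = config.n_background_families
    spec.validate()
    bundle = simulate.generate_pangenome(spec)
    sim_dir = out / "simulate"
    bundle.write(sim_dir)
    part = spec.partition
    manifest["stages"]["simulate"] = {
        "n_taxa": len(bundle.taxa),
        "n_families": len(bundle.truth.families),
        "n_proteins": sum(len(v) for v in bundle.proteomes.values()),
    }

    # --- orthogroups & filters ---------------------------------------------
    ogs = og_mod.ogs_from_table(bundle.orthogroups)
    presence_hits = og_mod.filter_by_presence(ogs, part)
    paralog_hits = og_mod.filter_paralog_targeting(
        ogs, part, config.min_copy_mean_pos, config.max_copy_mean_neg
    )
    candidate_ids = sorted(
        {og.og_id for og, _ in presence_hits} | {og.og_id for og in paralog_hits}
    )
    with open(out / "candidates.tsv", "w") as fh:
        fh.write("og_id\tsource\tpattern\n")
        pattern_of = {og.og_id: pat for og, pat in presence_hits}
        paralog_set = {og.og_id for og in paralog_hits}
        for og_id in candidate_ids:
            src = []
            if og_id in pattern_of:
                src.append("presence")
            if og_id in paralog_set:
                src.append("paralog")
            fh.write(f"{og_id}\t{'+'.join(src)}\t{pattern_of.get(og_id, '.')}\n")
    manifest["stages"]["filter"] = {
        "n_presence": len(presence_hits),
        "n_paralog": len(paralog_hits),
        "n_candidates": len(candidate_ids),
    }

    # --- rescue & completeness ---------------------------------------------
    sequences = {
        rec.protein_id: rec.sequence
        for recs in bundle.proteomes.values()
        for rec in recs
    }
    genomes = {t: bundle.contigs[t] for t in bundle.taxa}
    by_id = {og.og_id: og for og in ogs}
    candidates = [by_id[i] for i in candidate_ids]
    rescued = []
    for og in candidates:
        missing = [t for t in part.pos_taxa if og.copy_count(t) == 0]
        if missing:
            og = og_mod.rescue_missing_members(
                og, sequences, genomes, part,
                config.rescue_min_cov, config.rescue_min_ident,
            )
        rescued.append(og)
    retained = og_mod.completeness_filter(rescued, part)
    with open(out / "retained.tsv", "w") as fh:
        fh.write("og_id\tn_members\tn_rescued\n")
        for og in retained:
            n_mem = sum(len(v) for v in og.members.values())
            fh.write(f"{og.og_id}\t{n_mem}\t{len(og.rescued)}\n")
    manifest["stages"]["rescue"] = {
        "n_before": len(candidates),
        "n_rescued_loci": sum(len(og.rescued) for og in rescued),
        "n_retained": len(retained),
    }

    # --- synteny -----------------------------------------------------------
    gene_to_og = {
        pid: og_id
        for og_id, members in bundle.orthogroups.items()
        for pids in members.values()
        for pid in pids
    }
    orders = {
        t: synteny.build_gene_order(bundle.features[t], gene_to_og, t)
        for t in bundle.taxa
    }
    # synteny runs on the full candidate set: completeness prunes the
    # catalog, but neighborhoods are informative for every candidate
    cand_id_set = set(candidate_ids)
    retained_ids = {og.og_id for og in retained}
    clusters = synteny.detect_clusters(
        cand_id_set, orders, config.max_gap, config.min_taxa
    )
    adjacent = synteny.rescue_adjacent(
        clusters, orders, cand_id_set,
        config.adjacency_window, config.adjacency_consistency,
    )
    synteny.write_clusters_tsv(out / "clusters.tsv", clusters)
    with open(out / "cluster_adjacent.tsv", "w") as fh:
        fh.write("og_id\tcluster_id\tconsistency\toffsets\n")
        for og_id, cid, frac, offsets in adjacent:
            fh.write(f"{og_id}\t{cid}\t{frac:.3f}\t{','.join(map(str, offsets))}\n")
    manifest["stages"]["synteny"] = {
        "n_clusters": len(clusters),
        "n_clustered_ogs": len(set().union(*(c.og_set for c in clusters)) if clusters else set()),
        "n_adjacent_rescued": len(adjacent),
    }

    # --- targeting ---------------------------------------------------------
    preds = {
        pid: loc.TargetingPrediction(pid, sp, prob, pos, tm)
        for pid, (sp, prob, pos, tm) in bundle.targeting.items()
    }
    with open(out / "localization.tsv", "w") as fh:
        fh.write("protein_id\tog_id\tlabel\n")
        n_by_label: dict[str, int] = {}
        for pid in sorted(preds):
            if gene_to_og.get(pid) not in cand_id_set:
                continue
            label = loc.classify_localization(preds[pid])
            n_by_label[label] = n_by_label.get(label, 0) + 1
            fh.write(f"{pid}\t{gene_to_og[pid]}\t{label}\n")
    manifest["stages"]["targeting"] = {"counts": dict(sorted(n_by_label.items()))}

    # --- seqprep (dedup of candidate sequences) ----------------------------
    cand_records = [
        rec
        for t in bundle.taxa
        for rec in bundle.proteomes[t]
        if gene_to_og.get(rec.protein_id) in retained_ids
    ]
    deduped = seqprep.dedup_sequences(cand_records, config.dedup_identity, True)
    manifest["stages"]["prep"] = {
        "n_candidate_seqs": len(cand_records),
        "n_after_dedup": len(deduped),
    }

    # --- scenario family: tree, jackknife, call ----------------------------
    sc_seed = stage_seed(config.seed, "scenario")
    tree = simulate.simulate_scenario_tree(
        config.scenario, config.n_per_member, config.scenario_noise_sigma, sc_seed
    )
    leaves = sorted(phylo.leaf_labels(tree))
    root_seq = simulate._random_protein(np.random.default_rng(sc_seed), 300)
    seqs = simulate.evolve_protein(tree, root_seq, 1.0, seed=sc_seed)
    ali = seqprep.Alignment(leaves, [seqs[label] for label in leaves])
    members: dict[str, list[str]] = {}
    for label in leaves:
        member = simulate.parse_leaf_label(label)[2]
        members.setdefault(member, []).append(label)
    queries = [
        phylo.ClanQuery("alpha_beta", frozenset({"Mur_alpha", "Mur_beta"})),
        phylo.ClanQuery("delta_C", frozenset({"Mur_delta", "MurC"})),
    ]
    table, rep_trees = phylo.jackknife_clan_support(
        members, ali, queries,
        k_per_member=config.k_per_member,
        n_replicates=config.n_replicates,
        seed=stage_seed(config.seed, "jackknife"),
    )
    table.to_tsv(out / "jackknife_support.tsv")
    phylo.write_newick(tree, out / "scenario_tree.nwk")
    call = scenarios.classify_origin_scenario(tree, config.min_support)
    (out / "scenario_call.json").write_text(
        json.dumps(
            {
                "label": call.label,
                "evidence": [[n, bool(v), s] for n, v, s in call.evidence],
                "notes": call.notes,
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest["stages"]["scenario"] = {
        "true_scenario": config.scenario,
        "called": call.label,
        "jackknife": {k: list(v) for k, v in sorted(table.rows.items())},
    }

    # --- manifest ----------------------------------------------------------
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(out, manifest)


def write_default_config(path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(PipelineConfig()), sort_keys=True))
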