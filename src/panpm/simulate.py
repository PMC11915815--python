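"""Synthetic pangenome generator with a planted-truth ledger.

The generator emulates the study design the downstream filters assume:
ten taxa split 5/5 into trait-positive (one subgroup-A lineage plus four
subgroup-B lineages, mimicking Methanopyrales/Methanobacteriales) and
trait-negative taxa.  It plants gene families with trait-specific
presence patterns, trait-specific paralog expansions, syntenic clusters,
degenerate genomic pseudogene copies, and signal-peptide/transmembrane
decorations, and records everything it planted in a truth ledger so the
pipeline's recovery can be scored exactly.

It also simulates annotated gene-family trees under the five origin
scenarios (single ancestral gene, paired paralogs, four ancestral genes,
single transfer plus duplications, two transfers) used to classify the
evolutionary history of the muramyl-ligase family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .partition import TraitPartition
from .seqio import GeneFeature, ProteinRecord, write_fasta, write_gff3, write_orthogroup_table

AA = "ACDEFGHIKLMNPQRSTVWY"
_HYDROPHOBIC = "LIVF"

# standard bacterial/archaeal code (table 11); one codon per amino acid is
# enough for reverse translation — six-frame translation only needs a
# consistent genetic code, not codon-usage realism
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

MEMBERS_BACTERIA = ("MurC", "MurD", "MurE", "MurF")
MEMBERS_ARCHAEA = ("Mur_alpha", "Mur_beta", "Mur_gamma", "Mur_delta")
MEMBER_DOMAIN = {m: "Bacteria" for m in MEMBERS_BACTERIA}
MEMBER_DOMAIN.update({m: "Archaea" for m in MEMBERS_ARCHAEA})

SCENARIOS = ("A", "B", "C", "D", "E")


# ---------------------------------------------------------------------------
# specification & truth ledger


@dataclass
class PangenomeSpec:
    """Declarative description of a synthetic pangenome.

    ``planted_strict`` lists one presence-pattern label per planted
    trait-specific family; ``planted_paralog`` lists background families
    that additionally carry extra copies in every trait-positive taxon;
    ``planted_clusters`` places families contiguously (up to ``max_gap``
    interleaved background genes) in the listed genomes.
    """

    partition: TraitPartition
    n_background_families: int = 200
    planted_strict: list[str] = field(default_factory=list)
    planted_paralog: list[tuple[str, int]] = field(default_factory=list)
    planted_clusters: list[tuple[list[str], list[str], int]] = field(default_factory=list)
    planted_pseudogenes: list[tuple[str, str]] = field(default_factory=list)
    planted_adjacent: tuple[str, int] | None = None  # (background family, cluster index)
    planted_decoy: tuple[str, int, int] | None = None  # (family, cluster index, gap)
    planted_signal: list[str] = field(default_factory=list)
    planted_tm: dict[str, int] = field(default_factory=dict)
    background_presence_p: float = 0.8
    root_length: int = 300
    subst_rate: float = 1.0
    taxon_divergence: float = 0.1
    paralog_divergence: float = 0.15
    spacer_length: int = 50
    # minimum number of background genes kept between separate candidate
    # loci, so planted clusters are the only candidate co-locations (real
    # genomes are an order of magnitude larger than these toy contigs,
    # where unconstrained placement would create chance adjacencies)
    candidate_min_separation: int = 5
    seed: int = 0

    @property
    def strict_ids(self) -> list[str]:
        return [f"FAMS{i + 1:02d}" for i in range(len(self.planted_strict))]

    @property
    def background_ids(self) -> list[str]:
        return [f"FAMB{i + 1:03d}" for i in range(self.n_background_families)]

    def validate(self) -> None:
        known = set(self.strict_ids) | {f for f, _ in self.planted_paralog}
        all_fams = set(self.background_ids) | set(self.strict_ids)
        for fam, _ in self.planted_paralog:
            if fam not in all_fams:
                raise ValueError(f"planted_paralog: unknown family {fam!r}")
        for ogs, taxa, gap in self.planted_clusters:
            for og in ogs:
                if og not in known:
                    raise ValueError(f"planted_clusters: unknown family {og!r}")
            for t in taxa:
                if t not in self.partition.groups:
                    raise ValueError(f"planted_clusters: unknown taxon {t!r}")
            if gap < 0:
                raise ValueError("planted_clusters: max intervening genes must be >= 0")
        for fam, taxon in self.planted_pseudogenes:
            if fam not in all_fams:
                raise ValueError(f"planted_pseudogenes: unknown family {fam!r}")
            if taxon not in self.partition.groups:
                raise ValueError(f"planted_pseudogenes: unknown taxon {taxon!r}")
        if self.planted_adjacent is not None:
            fam, ci = self.planted_adjacent
            if fam not in all_fams:
                raise ValueError(f"planted_adjacent: unknown family {fam!r}")
            if not 0 <= ci < len(self.planted_clusters):
                raise ValueError("planted_adjacent: cluster index out of range")
        if self.planted_decoy is not None:
            fam, ci, gap = self.planted_decoy
            if fam not in all_fams:
                raise ValueError(f"planted_decoy: unknown family {fam!r}")
            if not 0 <= ci < len(self.planted_clusters):
                raise ValueError("planted_decoy: cluster index out of range")
            if gap < 1:
                raise ValueError("planted_decoy: gap must be >= 1")
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be >= 0")


def default_spec(seed: int = 0) -> PangenomeSpec:
    """The default study conditions: 10 taxa, 200 background families,
    12 strict + 5 paralog-expanded planted families, two syntenic clusters
    (5 and 3 families, conserved in 4/5 and 3/5 trait-positive genomes),
    3 pseudogenes, one always-adjacent background gene and one 4-gene-gap
    decoy."""
    part = TraitPartition.default_ten_taxa()
    spec = PangenomeSpec(
        partition=part,
        n_background_families=200,
        planted_strict=(
            ["all_pos"] * 6 + ["one_posA_three_posB"] * 3 + ["four_posB"] * 3
        ),
        planted_paralog=[(f"FAMB{i:03d}", 1) for i in range(1, 6)],
        planted_clusters=[
            (["FAMS01", "FAMS02", "FAMS03", "FAMS04", "FAMS05"],
             ["T01", "T02", "T03", "T04"], 3),
            (["FAMS07", "FAMS08", "FAMS09"], ["T01", "T02", "T03"], 3),
        ],
        planted_pseudogenes=[("FAMS01", "T03"), ("FAMS02", "T04"), ("FAMS03", "T05")],
        planted_adjacent=("FAMB010", 0),
        planted_decoy=("FAMS06", 0, 4),
        planted_signal=["FAMS04"],
        planted_tm={"FAMS05": 2, "FAMS08": 1},
        seed=seed,
    )
    spec.validate()
    return spec


@dataclass
class FamilyTruth:
    family_id: str
    label: str  # "background", "paralog", or a strict presence-pattern label
    copies: dict[str, int]
    cluster: str | None = None
    pseudogene_taxa: list[str] = field(default_factory=list)
    scenario: str | None = None


@dataclass
class PlantedTruth:
    families: dict[str, FamilyTruth]
    clusters: dict[str, tuple[list[str], list[str]]]  # name -> (families, taxa)
    adjacent_family: str | None
    decoy_family: str | None

    def to_json(self) -> str:
        payload = {
            "families": {
                f: {
                    "label": t.label,
                    "copies": t.copies,
                    "cluster": t.cluster,
                    "pseudogene_taxa": t.pseudogene_taxa,
                    "scenario": t.scenario,
                }
                for f, t in sorted(self.families.items())
            },
            "clusters": {k: list(v) for k, v in sorted(self.clusters.items())},
            "adjacent_family": self.adjacent_family,
            "decoy_family": self.decoy_family,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class _Gene:
    gene_id: str
    family: str
    protein: str  # emitted (mature) protein sequence
    pseudo: bool = False


@dataclass
class SyntheticBundle:
    spec: PangenomeSpec
    proteomes: dict[str, list[ProteinRecord]]
    gene_orders: dict[str, list[_Gene]]
    contigs: dict[str, str]
    features: dict[str, list[GeneFeature]]
    orthogroups: dict[str, dict[str, list[str]]]
    targeting: dict[str, tuple[str, float, int | None, int]]
    truth: PlantedTruth

    @property
    def taxa(self) -> list[str]:
        return self.spec.partition.taxa

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        for sub in ("proteomes", "genomes", "gff"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        for taxon in self.taxa:
            write_fasta(
                out / "proteomes" / f"{taxon}.faa",
                [(r.protein_id, r.sequence) for r in self.proteomes[taxon]],
            )
            write_fasta(out / "genomes" / f"{taxon}.fna",
                        [(f"ctg_{taxon}", self.contigs[taxon])])
            write_gff3(out / "gff" / f"{taxon}.gff3", self.features[taxon])
        write_orthogroup_table(out / "orthogroups.tsv", self.orthogroups, self.taxa)
        with open(out / "targeting.tsv", "w") as fh:
            fh.write("protein_id\tsp_type\tcleavage_prob\tcleavage_pos\ttm_count\n")
            for pid in sorted(self.targeting):
                sp, prob, pos, tm = self.targeting[pid]
                pos_s = "" if pos is None else str(pos)
                fh.write(f"{pid}\t{sp}\t{prob}\t{pos_s}\t{tm}\n")
        (out / "truth.json").write_text(self.truth.to_json())
        with open(out / "partition.tsv", "w") as fh:
            for t in self.taxa:
                fh.write(f"{t}\t{self.spec.partition.group_of(t)}\n")


# ---------------------------------------------------------------------------
# sequence evolution


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    arr = list(seq)
    sites = rng.integers(0, len(arr), size=n_subs)
    for s in sites:
        alternatives = [a for a in AA if a != arr[s]]
        arr[s] = alternatives[rng.integers(0, 19)]
    return "".join(arr)


def evolve_protein(
    tree: dendropy.Tree,
    root_seq: str,
    rate: float,
    seed: int,
    rate_multipliers: dict[str, float] | None = None,
) -> dict[str, str]:
    """Evolve a protein along a tree under a Poisson substitution process.

    Along each branch the number of substitutions is
    Poisson(rate x branch length x sequence length), applied at uniformly
    chosen sites with uniform replacement among the 19 alternative
    residues.  ``rate_multipliers`` (keyed by the label of the node below
    a branch) scale individual branches to create long-branch leaves.
    Returns leaf label -> sequence.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not root_seq:
        raise ValueError("root_seq must be non-empty")
    rng = np.random.default_rng(seed)
    mult = rate_multipliers or {}
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("branch lengths must be >= 0")
        label = node.taxon.label if node.taxon else (node.label or "")
        lam = rate * length * len(parent_seq) * mult.get(label, 1.0)
        seq = _mutate(rng, parent_seq, int(rng.poisson(lam)))
        seqs[id(node)] = seq
        if node.is_leaf():
            out[label] = seq
    return out


# ---------------------------------------------------------------------------
# scenario trees


def make_leaf_label(seq_id: str, taxon: str, member: str, domain: str) -> str:
    return f"{seq_id}|{taxon}|{member}|{domain}"


def parse_leaf_label(label: str) -> tuple[str, str, str, str]:
    parts = label.split("|")
    if len(parts) != 4:
        raise ValueError(f"leaf label {label!r} is not 'id|taxon|member|domain'")
    return tuple(parts)  # type: ignore[return-value]


def _member_subtree(
    member: str, n_leaves: int, rng: np.random.Generator, noise: float, base: float = 0.1
) -> dendropy.Node:
    """Random bifurcating subtree whose leaves all carry one member label."""
    domain = MEMBER_DOMAIN.get(member, "outgroup")
    nodes = []
    for i in range(n_leaves):
        leaf = dendropy.Node()
        leaf.label = make_leaf_label(f"{member}_{i + 1}", f"{member}_{i + 1}", member, domain)
        leaf.edge.length = _noisy(base, rng, noise)
        nodes.append(leaf)
    while len(nodes) > 1:
        i = int(rng.integers(0, len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(0, len(nodes)))
        b = nodes.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = _noisy(base, rng, noise)
        nodes.append(parent)
    return nodes[0]


def _noisy(base: float, rng: np.random.Generator, sigma: float) -> float:
    if sigma <= 0:
        return base
    return float(base * rng.lognormal(0.0, sigma))


def _join(rng: np.random.Generator, noise: float, *children: dendropy.Node) -> dendropy.Node:
    parent = dendropy.Node()
    for c in children:
        parent.add_child(c)
    parent.edge.length = _noisy(0.1, rng, noise)
    return parent


def simulate_scenario_tree(
    scenario: str,
    n_per_member: int = 4,
    noise_sigma: float = 0.25,
    seed: int = 0,
) -> dendropy.Tree:
    """Simulate an annotated gene-family tree under one origin scenario.

    A: one ancestral gene in the universal ancestor, duplicated three
       times independently in each domain (domain bipartition).
    B: two ancestral paralogs, one further duplication per domain on each
       (two mirror clans of 2 + 2 members).
    C: four ancestral genes vertically inherited (four ortholog pair
       clans).
    D: a single bacterial gene transferred into the trait-positive
       archaea, then duplicated three times (all archaeal members one
       clan attached to a single bacterial member clan).
    E: two transfers — the MurD lineage gave rise to Mur_alpha/beta/gamma
       and the MurC lineage to Mur_delta.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if n_per_member < 1:
        raise ValueError("n_per_member must be >= 1")
    rng = np.random.default_rng(seed)

    def sub(member: str) -> dendropy.Node:
        return _member_subtree(member, n_per_member, rng, noise_sigma)

    J = lambda *ch: _join(rng, noise_sigma, *ch)  # noqa: E731
    C, D, E, F = MEMBERS_BACTERIA
    a, b, g, d = MEMBERS_ARCHAEA
    if scenario == "A":
        root = J(J(J(sub(C), sub(D)), J(sub(E), sub(F))),
                 J(J(sub(a), sub(b)), J(sub(g), sub(d))))
    elif scenario == "B":
        root = J(J(J(sub(C), sub(D)), J(sub(a), sub(b))),
                 J(J(sub(E), sub(F)), J(sub(g), sub(d))))
    elif scenario == "C":
        root = J(J(J(sub(C), sub(a)), J(sub(D), sub(b))),
                 J(J(sub(E), sub(g)), J(sub(F), sub(d))))
    elif scenario == "D":
        arch = J(J(sub(a), sub(b)), J(sub(g), sub(d)))
        root = J(J(arch, sub(C)), J(sub(D), J(sub(E), sub(F))))
    else:  # E
        root = J(J(J(J(J(sub(a), sub(b)), sub(g)), sub(D)), J(sub(d), sub(C))),
                 J(sub(E), sub(F)))
    tree = dendropy.Tree()
    tree.seed_node = root
    root.edge.length = None
    # promote node labels to taxa so dendropy bipartition machinery works
    tns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.new_taxon(label=leaf.label)
        leaf.label = None
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# pangenome generation


def _presence_for_pattern(
    pattern: str, part: TraitPartition, rng: np.random.Generator,
    forced_taxa: set[str],
) -> set[str]:
    pos_a, pos_b = part.pos_a_taxa, part.pos_b_taxa
    if pattern == "all_pos":
        return set(part.pos_taxa)
    if pattern == "one_posA_three_posB":
        if not pos_a or len(pos_b) < 3:
            raise ValueError("one_posA_three_posB needs >=1 pos_A and >=3 pos_B taxa")
        chosen = set(pos_a[:1])
        need = [t for t in sorted(forced_taxa) if t in pos_b]
        pool = [t for t in pos_b if t not in need]
        pool = [pool[i] for i in rng.permutation(len(pool))]
        chosen.update((need + pool)[:3])
        return chosen
    if pattern == "four_posB":
        if len(pos_b) < 4:
            raise ValueError("four_posB needs >=4 pos_B taxa")
        pool = [pos_b[i] for i in rng.permutation(len(pos_b))]
        return set(pool[:4])
    raise ValueError(f"unknown presence pattern {pattern!r}")


def _decorate(
    seq: str, fam: str, spec: PangenomeSpec, rng: np.random.Generator
) -> tuple[str, tuple[str, float, int | None, int]]:
    """Apply planted signal-peptide / transmembrane features to a protein."""
    sp_type, prob, pos, tm = "other", 0.0, None, 0
    if fam in spec.planted_tm:
        tm = spec.planted_tm[fam]
        arr = list(seq)
        # hydrophobic 19-mers spaced by >= 19 hydrophilic residues
        start = 25
        for _ in range(tm):
            stretch = rng.choice(list(_HYDROPHOBIC), size=19)
            arr[start:start + 19] = stretch
            start += 19 + 25
        seq = "".join(arr)
    if fam in spec.planted_signal:
        core = "".join(rng.choice(list(_HYDROPHOBIC), size=12))
        sp = "MKK" + core + "ASA"
        seq = sp + seq
        sp_type, prob, pos = "Sec", 0.9, len(sp)
    return seq, (sp_type, prob, pos, tm)


def _reverse_complement(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(s))


def _cds_for(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def _pseudogenize(cds: str, rng: np.random.Generator) -> str:
    """Degrade a CDS: one internal stop plus a 1-bp frameshift, both in the
    first 30% so a long single-frame remnant survives six-frame search."""
    n_codons = len(cds) // 3
    stop_at = int(rng.integers(2, max(3, int(n_codons * 0.15))))
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    codons[stop_at] = "TAA"
    out = "".join(codons)
    del_at = int(rng.integers(stop_at * 3 + 3, int(len(out) * 0.3)))
    return out[:del_at] + out[del_at + 1:]


def generate_pangenome(spec: PangenomeSpec) -> SyntheticBundle:
    """Generate a synthetic pangenome bundle from a validated spec.

    Deterministic: the same spec (including its seed) yields
    byte-identical files from :meth:`SyntheticBundle.write`.
    """
    spec.validate()
    part = spec.partition
    rng = np.random.default_rng(spec.seed)
    taxa = part.taxa

    paralog_extra = dict(spec.planted_paralog)
    cluster_names = {i: chr(ord("A") + i) for i in range(len(spec.planted_clusters))}
    cluster_of_fam: dict[str, str] = {}
    for i, (ogs, _taxa, _gap) in enumerate(spec.planted_clusters):
        for og in ogs:
            cluster_of_fam[og] = cluster_names[i]
    pseudo_by_fam: dict[str, list[str]] = {}
    for fam, taxon in spec.planted_pseudogenes:
        pseudo_by_fam.setdefault(fam, []).append(taxon)
    adjacent_fam = spec.planted_adjacent[0] if spec.planted_adjacent else None
    decoy_fam = spec.planted_decoy[0] if spec.planted_decoy else None

    # presence sets ---------------------------------------------------------
    presence: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    forced: dict[str, set[str]] = {}
    for i, (ogs, cl_taxa, _gap) in enumerate(spec.planted_clusters):
        for og in ogs:
            forced.setdefault(og, set()).update(cl_taxa)
        if adjacent_fam is not None and spec.planted_adjacent[1] == i:
            forced.setdefault(adjacent_fam, set()).update(cl_taxa)
        if decoy_fam is not None and spec.planted_decoy[1] == i:
            forced.setdefault(decoy_fam, set()).update(cl_taxa)

    for fam in spec.background_ids:
        labels[fam] = "paralog" if fam in paralog_extra else "background"
        if fam in paralog_extra:
            pres = set(taxa)  # expansions sit on top of a widespread gene
        else:
            pres = {t for t in taxa if rng.random() < spec.background_presence_p}
            pres |= forced.get(fam, set())
        presence[fam] = pres
    for fam, pattern in zip(spec.strict_ids, spec.planted_strict):
        labels[fam] = pattern
        presence[fam] = _presence_for_pattern(pattern, part, rng, forced.get(fam, set()))
        missing_forced = forced.get(fam, set()) - presence[fam]
        if missing_forced:
            raise ValueError(
                f"planted_clusters: family {fam} pattern {pattern!r} cannot "
                f"cover required taxa {sorted(missing_forced)}"
            )

    # sequences -------------------------------------------------------------
    family_ids = spec.background_ids + spec.strict_ids
    roots = {fam: _random_protein(rng, spec.root_length) for fam in family_ids}

    proteomes: dict[str, list[ProteinRecord]] = {t: [] for t in taxa}
    gene_pool: dict[str, list[_Gene]] = {t: [] for t in taxa}
    orthogroups: dict[str, dict[str, list[str]]] = {}
    targeting: dict[str, tuple[str, float, int | None, int]] = {}
    truth_fams: dict[str, FamilyTruth] = {}

    for fam in family_ids:
        root = roots[fam]
        copies: dict[str, int] = {}
        pseudo_taxa = sorted(pseudo_by_fam.get(fam, []))
        members: dict[str, list[str]] = {}
        for taxon in taxa:
            if taxon not in presence[fam]:
                copies[taxon] = 0
                continue
            n_copies = 1
            if fam in paralog_extra and taxon in set(part.pos_taxa):
                n_copies += paralog_extra[fam]
            emitted = 0
            for k in range(1, n_copies + 1):
                div = spec.taxon_divergence if k == 1 else spec.paralog_divergence
                lam = spec.subst_rate * div * len(root)
                seq = _mutate(rng, root, int(rng.poisson(lam)))
                seq, targ = _decorate(seq, fam, spec, rng)
                gene_id = f"{taxon}_{fam}_{k}"
                is_pseudo = k == 1 and taxon in pseudo_taxa
                gene_pool[taxon].append(_Gene(gene_id, fam, seq, pseudo=is_pseudo))
                if is_pseudo:
                    continue
                proteomes[taxon].append(ProteinRecord(gene_id, taxon, seq))
                members.setdefault(taxon, []).append(gene_id)
                targeting[gene_id] = targ
                emitted += 1
            copies[taxon] = emitted
        orthogroups[fam] = members
        truth_fams[fam] = FamilyTruth(
            family_id=fam,
            label=labels[fam],
            copies=copies,
            cluster=cluster_of_fam.get(fam),
            pseudogene_taxa=pseudo_taxa,
        )

    # gene order ------------------------------------------------------------
    orders: dict[str, list[_Gene]] = {}
    for taxon in taxa:
        pool = {g.gene_id: g for g in gene_pool[taxon]}
        placed: set[str] = set()
        blocks: list[list[_Gene]] = []
        for ci, (ogs, cl_taxa, _gap) in enumerate(spec.planted_clusters):
            if taxon not in cl_taxa:
                continue
            block = []
            for og in ogs:
                gid = f"{taxon}_{og}_1"
                if gid in pool:
                    block.append(pool[gid])
                    placed.add(gid)
            if adjacent_fam is not None and spec.planted_adjacent[1] == ci:
                gid = f"{taxon}_{adjacent_fam}_1"
                if gid in pool:
                    block.append(pool[gid])
                    placed.add(gid)
            if decoy_fam is not None and spec.planted_decoy[1] == ci:
                gid = f"{taxon}_{decoy_fam}_1"
                gap = spec.planted_decoy[2]
                # pad with background genes so the decoy sits exactly `gap`
                # non-candidate genes downstream of the cluster span;
                # pads are drawn at random per genome (a consistent pad
                # would itself look like a conserved neighbor) and must
                # be non-candidate: plain background families only
                n_pad = gap - (1 if adjacent_fam else 0)
                avail = [
                    g for g in gene_pool[taxon]
                    if g.gene_id not in placed and g.family.startswith("FAMB")
                    and g.family != adjacent_fam and g.family not in paralog_extra
                ]
                pick = rng.choice(len(avail), size=min(n_pad, len(avail)), replace=False)
                for p in (avail[i] for i in sorted(pick)):
                    block.append(p)
                    placed.add(p.gene_id)
                if gid in pool:
                    block.append(pool[gid])
                    placed.add(gid)
            blocks.append(block)

        # candidate families (trait-specific or paralog-expanded) outside
        # planted clusters are laid out with a minimum background-gene
        # separation, so planted clusters are the only candidate
        # co-locations in these deliberately small contigs
        candidate_fams = set(spec.strict_ids) | set(paralog_extra)
        rest = [g for g in gene_pool[taxon] if g.gene_id not in placed]
        backbone = [g for g in rest if g.family not in candidate_fams]
        loose = [g for g in rest if g.family in candidate_fams]
        idx = rng.permutation(len(backbone))
        backbone = [backbone[i] for i in idx]
        units: list[list[_Gene]] = [[g] for g in loose] + blocks
        units = [units[i] for i in rng.permutation(len(units))]
        sep = spec.candidate_min_separation
        if units:
            base = len(backbone) // len(units)
            if base < sep + 1:
                raise ValueError(
                    "not enough background genes to separate candidate loci; "
                    "increase n_background_families or lower "
                    "candidate_min_separation"
                )
            positions = [
                i * base + int(rng.integers(0, base - sep + 1))
                for i in range(len(units))
            ]
            for pos, unit in sorted(zip(positions, units), reverse=True, key=lambda x: x[0]):
                backbone[pos:pos] = unit
        orders[taxon] = backbone

    # contigs & features ----------------------------------------------------
    contigs: dict[str, str] = {}
    features: dict[str, list[GeneFeature]] = {}
    for taxon in taxa:
        parts: list[str] = []
        feats: list[GeneFeature] = []
        pos = 0
        contig = f"ctg_{taxon}"
        for gene in orders[taxon]:
            spacer = "".join(rng.choice(list("ACGT"), size=spec.spacer_length))
            parts.append(spacer)
            pos += len(spacer)
            cds = _cds_for(gene.protein)
            if gene.pseudo:
                cds = _pseudogenize(cds, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            emitted = cds if strand == "+" else _reverse_complement(cds)
            start = pos + 1
            end = pos + len(emitted)
            parts.append(emitted)
            pos = end
            feats.append(GeneFeature(contig, start, end, strand, gene.gene_id))
        contigs[taxon] = "".join(parts)
        features[taxon] = feats

    truth = PlantedTruth(
        families=truth_fams,
        clusters={
            cluster_names[i]: (list(ogs), list(cl_taxa))
            for i, (ogs, cl_taxa, _gap) in enumerate(spec.planted_clusters)
        },
        adjacent_family=adjacent_fam,
        decoy_family=decoy_fam,
    )
    return SyntheticBundle(
        spec=spec,
        proteomes=proteomes,
        gene_orders=orders,
        contigs=contigs,
        features=features,
        orthogroups=orthogroups,
        targeting=targeting,
        truth=truth,
    )
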