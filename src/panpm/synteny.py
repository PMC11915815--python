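"""Gene-neighborhood reconstruction and conserved synteny clusters.

Candidate genes that repeatedly co-locate across trait-positive genomes
form synteny clusters: per genome, maximal runs of candidate genes with
at most ``max_gap`` intervening non-candidate genes; runs from different
genomes are merged (transitive closure) when they share at least two
orthogroups, and a merged cluster is reported when supported by at least
``min_taxa`` genomes.  Non-candidate orthogroups that sit consistently
next to a cluster across the genomes bearing it are rescued into the
cluster with their observed offsets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from .seqio import GeneFeature, read_gff3


@dataclass(frozen=True)
class OrderedGene:
    gene_id: str
    og_id: str | None
    strand: str


@dataclass
class GeneOrder:
    """Per-taxon gene order: contig -> genes sorted by start coordinate."""

    taxon: str
    contigs: dict[str, list[OrderedGene]]


@dataclass
class ClusterSpan:
    taxon: str
    contig: str
    first_index: int
    last_index: int
    og_ids: list[str]
    strand_pattern: str


@dataclass
class SyntenyCluster:
    cluster_id: str
    og_set: set[str]
    spans: list[ClusterSpan]
    mobile_ogs: set[str] = field(default_factory=set)
    notes: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> set[str]:
        return {s.taxon for s in self.spans}


def build_gene_order(
    gff3: str | Path | list[GeneFeature],
    og_membership: dict[str, str],
    taxon: str,
) -> GeneOrder:
    """Order genes by (contig, start) and attach orthogroup membership."""
    feats = read_gff3(gff3) if isinstance(gff3, (str, Path)) else list(gff3)
    seen: set[str] = set()
    for f in feats:
        if f.gene_id in seen:
            raise ValueError(f"duplicate gene id {f.gene_id!r} in {taxon}")
        seen.add(f.gene_id)
    by_contig: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in feats:
        by_contig[f.contig].append(f)
    contigs = {
        contig: [
            OrderedGene(f.gene_id, og_membership.get(f.gene_id), f.strand)
            for f in sorted(fs, key=lambda f: (f.start, f.end, f.gene_id))
        ]
        for contig, fs in sorted(by_contig.items())
    }
    return GeneOrder(taxon, contigs)


def _candidate_runs(
    genes: list[OrderedGene], candidates: set[str], max_gap: int
) -> list[tuple[int, int]]:
    """Maximal runs (first, last gene index) of candidate genes with at
    most ``max_gap`` intervening non-candidate genes."""
    idx = [i for i, g in enumerate(genes) if g.og_id in candidates]
    runs = []
    start = prev = None
    for i in idx:
        if start is None:
            start = prev = i
        elif i - prev - 1 <= max_gap:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    if start is not None:
        runs.append((start, prev))
    return runs


def detect_clusters(
    candidate_ogs: set[str],
    orders: dict[str, GeneOrder],
    max_gap: int = 3,
    min_taxa: int = 3,
) -> list[SyntenyCluster]:
    """Detect conserved clusters of candidate orthogroups across genomes.

    Genome-level runs containing >= 2 candidate genes are merged across
    genomes when they share >= 2 orthogroups (transitive closure), and
    merged clusters supported by >= ``min_taxa`` genomes are reported.
    An orthogroup whose genes fall in different clusters depending on
    the genome is flagged mobile and reported in each.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    spans: list[ClusterSpan] = []
    for taxon in sorted(orders):
        order = orders[taxon]
        for contig in sorted(order.contigs):
            genes = order.contigs[contig]
            for first, last in _candidate_runs(genes, candidate_ogs, max_gap):
                window = genes[first:last + 1]
                ogs = [g.og_id for g in window if g.og_id in candidate_ogs]
                if len(ogs) < 2:
                    continue
                spans.append(
                    ClusterSpan(
                        taxon, contig, first, last, ogs,
                        "".join(g.strand for g in window),
                    )
                )

    # merge spans sharing >= 2 OGs (transitive closure via union-find)
    parent = list(range(len(spans)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            if len(set(spans[i].og_ids) & set(spans[j].og_ids)) >= 2:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(spans)):
        groups[find(i)].append(i)

    merged = []
    for idxs in groups.values():
        taxa = {spans[i].taxon for i in idxs}
        if len(taxa) < min_taxa:
            continue
        og_set = set()
        for i in idxs:
            og_set.update(spans[i].og_ids)
        merged.append((og_set, [spans[i] for i in idxs]))
    merged.sort(key=lambda m: (-len(m[0]), min(m[0])))

    clusters = []
    og_home: dict[str, list[str]] = defaultdict(list)
    for rank, (og_set, sp) in enumerate(merged):
        cid = chr(ord("A") + rank)
        for og in og_set:
            og_home[og].append(cid)
        clusters.append(SyntenyCluster(cid, og_set, sp))
    for og, homes in og_home.items():
        if len(homes) > 1:
            for c in clusters:
                if og in c.og_set:
                    c.mobile_ogs.add(og)
                    c.notes.append(f"{og} occurs in clusters {','.join(sorted(homes))}")
    return clusters


def rescue_adjacent(
    clusters: list[SyntenyCluster],
    orders: dict[str, GeneOrder],
    candidate_ogs: set[str],
    window: int = 3,
    consistency: float = 0.8,
) -> list[tuple[str, str, float, list[int]]]:
    """Attach consistently adjacent non-candidate orthogroups to clusters.

    A non-candidate OG joins a cluster when, in at least ``consistency``
    of the genomes bearing the cluster, one of its genes lies within
    ``window`` genes of the cluster span.  Returns
    (og_id, cluster_id, observed consistency, offsets).
    """
    out = []
    for cluster in clusters:
        span_by_taxon: dict[str, list[ClusterSpan]] = defaultdict(list)
        for s in cluster.spans:
            span_by_taxon[s.taxon].append(s)
        bearing = sorted(span_by_taxon)
        hits: dict[str, dict[str, int]] = defaultdict(dict)  # og -> taxon -> offset
        for taxon in bearing:
            order = orders[taxon]
            for span in span_by_taxon[taxon]:
                genes = order.contigs[span.contig]
                lo = max(0, span.first_index - window)
                hi = min(len(genes) - 1, span.last_index + window)
                for i in range(lo, hi + 1):
                    og = genes[i].og_id
                    if og is None or og in candidate_ogs or og in cluster.og_set:
                        continue
                    if i < span.first_index:
                        offset = span.first_index - i
                    elif i > span.last_index:
                        offset = i - span.last_index
                    else:
                        offset = 0
                    prev = hits[og].get(taxon)
                    if prev is None or offset < prev:
                        hits[og][taxon] = offset
        for og in sorted(hits):
            frac = len(hits[og]) / len(bearing)
            if frac >= consistency:
                offsets = [hits[og][t] for t in sorted(hits[og])]
                out.append((og, cluster.cluster_id, frac, offsets))
    return out


def write_clusters_tsv(
    path: str | Path,
    clusters: list[SyntenyCluster],
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tog_id\ttaxon\tcontig\tstart_index\tend_index\t"
            "strand_pattern\tmobile_flag\n"
        )
        for c in clusters:
            for span in sorted(c.spans, key=lambda s: (s.taxon, s.contig, s.first_index)):
                for og in sorted(set(span.og_ids)):
                    mobile = "mobile" if og in c.mobile_ogs else "."
                    fh.write(
                        f"{c.cluster_id}\t{og}\t{span.taxon}\t{span.contig}\t"
                        f"{span.first_index}\t{span.last_index}\t"
                        f"{span.strand_pattern}\t{mobile}\n"
                    )
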