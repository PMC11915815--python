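"""Ortholog groups and the trait-specific candidate filters.

The pipeline clusters proteins into orthologous groups (OGs) and then
selects candidates for trait-specific biosynthesis genes by their
presence/absence profile across the trait partition:

* presence patterns — a family present in all trait-positive taxa (or in
  the subgroup-A taxon plus three subgroup-B taxa, or in four subgroup-B
  taxa) and absent from every trait-negative taxon;
* paralog expansion — a widespread family whose mean copy number is at
  least 1.75 over trait-positive taxa and at most 1.25 over
  trait-negative taxa;
* six-frame rescue — taxa missing from a candidate OG are searched for a
  degenerate genomic copy (pseudogene / misannotation) by local
  alignment of the OG consensus against all six translation frames;
* completeness — after rescue, only OGs covering every trait-positive
  taxon are retained;
* profile selection — a position-specific scoring matrix built from a
  seed alignment recruits additional matching proteins per taxon;
* distribution classes — widespread / bacteria-and-trait-positive /
  archaea-only / trait-positive-only, from group-level homolog presence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .pairwise import best_local_hit
from .partition import TraitPartition
from .seqio import ProteinRecord, read_fasta

DISTRIBUTION_LABELS = ("widespread", "bacteria_and_PM", "archaea_only", "PM_only")
PATTERN_LABELS = ("all_pos", "one_posA_three_posB", "four_posB")


@dataclass
class OrthologousGroup:
    """A gene family: per-taxon member protein ids plus post-hoc rescues."""

    og_id: str
    members: dict[str, list[str]]
    rescued: list[tuple[str, str]] = field(default_factory=list)  # (taxon, locus)

    def copy_count(self, taxon: str) -> int:
        return len(self.members.get(taxon, []))

    def taxa_with_members(self) -> set[str]:
        return {t for t, ms in self.members.items() if ms}

    def taxa_covered(self) -> set[str]:
        return self.taxa_with_members() | {t for t, _ in self.rescued}


def ogs_from_table(table: dict[str, dict[str, list[str]]]) -> list[OrthologousGroup]:
    return [OrthologousGroup(og_id, dict(members)) for og_id, members in sorted(table.items())]


# ---------------------------------------------------------------------------
# clustering


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def cluster_orthogroups(
    proteins: list[ProteinRecord], k: int = 4, jaccard_min: float = 0.2
) -> list[OrthologousGroup]:
    """Single-linkage clustering on k-mer Jaccard similarity.

    Two proteins are joined when the Jaccard similarity of their k-mer
    sets reaches ``jaccard_min``; orthogroups are the connected
    components.  Ids are assigned OG%07d in order of decreasing size,
    ties broken by the lexicographically smallest member.  A k-mer
    inverted index restricts the exact Jaccard computation to pairs that
    share at least one k-mer.
    """
    if not proteins:
        raise ValueError("empty protein list")
    if k < 3:
        raise ValueError("k must be >= 3")
    if not 0 < jaccard_min <= 1:
        raise ValueError("jaccard_min must be in (0, 1]")
    keys = sorted((p.taxon, p.protein_id) for p in proteins)
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate (taxon, protein_id) in input")
    order = {key: i for i, key in enumerate(keys)}
    recs = sorted(proteins, key=lambda p: (p.taxon, p.protein_id))
    sets = [_kmer_set(p.sequence, k) for p in recs]

    index: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(sets):
        for kmer in s:
            index[kmer].append(i)
    shared: Counter[tuple[int, int]] = Counter()
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for a in range(len(bucket)):
            for b in range(a + 1, len(bucket)):
                shared[(bucket[a], bucket[b])] += 1

    parent = list(range(len(recs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j), inter in shared.items():
        union = len(sets[i]) + len(sets[j]) - inter
        if union and inter / union >= jaccard_min:
            parent[find(i)] = find(j)

    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(len(recs)):
        comps[find(i)].append(i)
    groups = sorted(
        comps.values(),
        key=lambda idxs: (-len(idxs), min((recs[i].taxon, recs[i].protein_id) for i in idxs)),
    )
    out = []
    for rank, idxs in enumerate(groups, 1):
        members: dict[str, list[str]] = defaultdict(list)
        for i in sorted(idxs, key=lambda i: order[(recs[i].taxon, recs[i].protein_id)]):
            members[recs[i].taxon].append(recs[i].protein_id)
        out.append(OrthologousGroup(f"OG{rank:07d}", dict(members)))
    return out


# ---------------------------------------------------------------------------
# presence / paralog filters


def _matches_pattern(og: OrthologousGroup, part: TraitPartition, pattern: str) -> bool:
    neg_absent = all(og.copy_count(t) == 0 for t in part.neg_taxa)
    if not neg_absent:
        return False
    if pattern == "all_pos":
        return all(og.copy_count(t) >= 1 for t in part.pos_taxa)
    if pattern == "one_posA_three_posB":
        part.require_nonempty("pos_A", "pos_B")
        in_a = any(og.copy_count(t) >= 1 for t in part.pos_a_taxa)
        n_b = sum(og.copy_count(t) >= 1 for t in part.pos_b_taxa)
        return in_a and n_b >= 3
    if pattern == "four_posB":
        part.require_nonempty("pos_B")
        n_b = sum(og.copy_count(t) >= 1 for t in part.pos_b_taxa)
        absent_a = all(og.copy_count(t) == 0 for t in part.pos_a_taxa)
        return n_b >= 4 and absent_a
    raise ValueError(f"unknown presence pattern {pattern!r}")


def filter_by_presence(
    ogs: list[OrthologousGroup],
    partition: TraitPartition,
    patterns: list[str] = list(PATTERN_LABELS),
) -> list[tuple[OrthologousGroup, str]]:
    """Select trait-specific OGs; each OG is reported once with the first
    matching pattern in the listed order."""
    if not patterns:
        raise ValueError("patterns must be non-empty")
    selected = []
    for og in ogs:
        for pattern in patterns:
            if _matches_pattern(og, partition, pattern):
                selected.append((og, pattern))
                break
    return selected


def filter_paralog_targeting(
    ogs: list[OrthologousGroup],
    partition: TraitPartition,
    min_mean_pos: float = 1.75,
    max_mean_neg: float = 1.25,
) -> list[OrthologousGroup]:
    """Select OGs with a trait-specific paralog expansion.

    Passing OGs have mean copy number over the trait-positive taxa of at
    least ``min_mean_pos``, mean copy number over the trait-negative
    taxa of at most ``max_mean_neg``, and at least one copy in every
    trait-positive taxon.  Absent taxa count as zero copies.
    """
    if min_mean_pos <= 0 or max_mean_neg <= 0:
        raise ValueError("copy-mean thresholds must be > 0")
    partition.require_nonempty("pos_B")
    pos, neg = partition.pos_taxa, partition.neg_taxa
    out = []
    for og in ogs:
        mean_pos = sum(og.copy_count(t) for t in pos) / len(pos)
        mean_neg = sum(og.copy_count(t) for t in neg) / len(neg) if neg else 0.0
        if (
            mean_pos >= min_mean_pos
            and mean_neg <= max_mean_neg
            and all(og.copy_count(t) >= 1 for t in pos)
        ):
            out.append(og)
    return out


# ---------------------------------------------------------------------------
# six-frame rescue & completeness


def _consensus(sequences: list[str]) -> str:
    """Majority-rule consensus from a star alignment to the longest member."""
    if len(sequences) == 1:
        return sequences[0]
    from .pairwise import make_aligner

    ref = max(sequences, key=len)
    aligner = make_aligner("global")
    columns: list[Counter[str]] = [Counter() for _ in ref]
    for seq in sequences:
        if seq == ref:
            for i, c in enumerate(ref):
                columns[i][c] += 1
            continue
        aln = next(iter(aligner.align(ref, seq)))
        for (rs, re_), (qs, _qe) in zip(aln.aligned[0], aln.aligned[1]):
            for off in range(re_ - rs):
                columns[rs + off][seq[qs + off]] += 1
    return "".join(max(sorted(col), key=col.__getitem__) if col else "X" for col in columns)


def six_frame_translations(contig: str) -> list[str]:
    """Conceptual translations of all six reading frames (stops as X)."""
    frames = []
    rc = str(Seq(contig).reverse_complement())
    for strand_seq in (contig, rc):
        for off in (0, 1, 2):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()).replace("*", "X"))
    return frames


def rescue_missing_members(
    og: OrthologousGroup,
    sequences: dict[str, str],
    genomes: dict[str, str | Path],
    partition: TraitPartition,
    min_cov: float = 0.5,
    min_ident: float = 0.3,
) -> OrthologousGroup:
    """Search genomes of missing trait-positive taxa for degenerate copies.

    Each contig of a missing taxon is translated in all six frames and
    locally aligned (BLOSUM62, affine gaps) against the OG consensus; a
    hit covering at least ``min_cov`` of the consensus at identity at
    least ``min_ident`` adds a rescued record for that taxon.  Member
    proteins are never modified.
    """
    missing = [t for t in partition.pos_taxa if og.copy_count(t) == 0]
    if not missing:
        return og
    absent = [t for t in missing if t not in genomes]
    if absent:
        raise ValueError(f"no genome provided for missing taxa: {absent}")
    member_seqs = [
        sequences[pid]
        for t in sorted(og.members)
        for pid in og.members[t]
        if pid in sequences
    ]
    if not member_seqs:
        raise ValueError(f"{og.og_id}: no member sequences available for consensus")
    consensus = _consensus(member_seqs)
    rescued = list(og.rescued)
    for taxon in missing:
        genome = genomes[taxon]
        # Path = FASTA on disk; plain str = a raw contig sequence
        contig_seqs = (
            read_fasta(genome) if isinstance(genome, Path) else [("contig", genome)]
        )
        found = None
        for contig_id, contig in contig_seqs:
            for frame_i, frame in enumerate(six_frame_translations(contig)):
                hit = best_local_hit(consensus, frame)
                if hit is None:
                    continue
                cov = hit.aligned_query / len(consensus)
                span = min(hit.aligned_query, hit.aligned_target)
                ident = hit.identities / span if span else 0.0
                if cov >= min_cov and ident >= min_ident:
                    found = f"{contig_id}:frame{frame_i}"
                    break
            if found:
                break
        if found:
            rescued.append((taxon, found))
    return OrthologousGroup(og.og_id, og.members, rescued)


def completeness_filter(
    ogs: list[OrthologousGroup], partition: TraitPartition
) -> list[OrthologousGroup]:
    """Retain OGs covering every trait-positive taxon (members or rescues)."""
    pos = set(partition.pos_taxa)
    return [og for og in ogs if pos <= og.taxa_covered()]


# ---------------------------------------------------------------------------
# profile selection


def build_pssm(alignment: list[tuple[str, str]], pseudocount: float = 1.0) -> np.ndarray:
    """Log-odds PSSM (vs uniform background) from an aligned FASTA block."""
    if len(alignment) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    from .seqprep import AA_ORDER

    length = len(alignment[0][1])
    counts = np.full((length, 20), pseudocount)
    for _id, row in alignment:
        if len(row) != length:
            raise ValueError("alignment rows differ in length")
        for i, c in enumerate(row):
            j = AA_ORDER.find(c)
            if j >= 0:
                counts[i, j] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log2(freqs / 0.05)


def profile_select(
    seed_alignment: list[tuple[str, str]],
    proteomes: dict[str, list[ProteinRecord]],
    min_cov: float = 0.7,
    max_copy: int = 20,
    score_min: float = 1.0,
) -> dict[str, list[tuple[str, float, float]]]:
    """Scan proteomes with a PSSM; report per-taxon hits.

    Hits are ungapped placements of the profile along the protein
    (partial overlaps at the ends allowed) covering at least ``min_cov``
    of the profile length with mean per-position score at least
    ``score_min``; at most ``max_copy`` best-scoring hits are kept per
    taxon.  Returns taxon -> [(protein_id, mean score, coverage)].
    """
    from .seqprep import AA_ORDER

    pssm = build_pssm(seed_alignment)
    L = pssm.shape[0]
    min_overlap = max(1, int(np.ceil(min_cov * L)))
    out: dict[str, list[tuple[str, float, float]]] = {}
    for taxon in sorted(proteomes):
        hits = []
        for rec in proteomes[taxon]:
            idx = np.array([AA_ORDER.find(c) for c in rec.sequence])
            n = len(idx)
            best = None
            for offset in range(-(L - min_overlap), n - min_overlap + 1):
                p0, p1 = max(0, -offset), min(L, n - offset)
                if p1 - p0 < min_overlap:
                    continue
                cols = idx[offset + p0: offset + p1]
                valid = cols >= 0
                if not valid.any():
                    continue
                scores = pssm[np.arange(p0, p1)[valid], cols[valid]]
                mean = float(scores.mean())
                cov = (p1 - p0) / L
                if mean >= score_min and (best is None or mean > best[0]):
                    best = (mean, cov)
            if best is not None:
                hits.append((rec.protein_id, best[0], best[1]))
        hits.sort(key=lambda h: (-h[1], h[0]))
        if hits:
            out[taxon] = hits[:max_copy]
    return out


# ---------------------------------------------------------------------------
# taxonomic distribution


def classify_distribution(group_presence: dict[str, bool]) -> str:
    """Classify an OG's homolog distribution across taxonomic groups.

    ``group_presence`` has boolean keys ``bacteria``, ``nonPM_archaea``
    and ``PM_archaea``; candidate OGs are by construction present in the
    trait-positive archaea, so ``PM_archaea`` must be true.
    """
    if not group_presence.get("PM_archaea", False):
        raise ValueError("candidate OGs must be present in trait-positive archaea")
    bacteria = bool(group_presence.get("bacteria", False))
    non_pm = bool(group_presence.get("nonPM_archaea", False))
    if bacteria and non_pm:
        return "widespread"
    if bacteria:
        return "bacteria_and_PM"
    if non_pm:
        return "archaea_only"
    return "PM_only"
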