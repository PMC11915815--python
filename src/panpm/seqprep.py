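"""Sequence-set and alignment-matrix preparation.

Covers the steps between homolog collection and tree inference: masking
of poorly covered alignment columns and sequences, splicing a domain out
of a masked alignment, splitting tandem-domain fusion proteins,
taxonomy-aware greedy deduplication, removal of significantly homologous
yet highly divergent outliers, and best-hit annotation against labeled
references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .pairwise import best_local_hit, evalue
from .seqio import ProteinRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AMBIG = "X"


@dataclass
class Alignment:
    """An aligned block: parallel lists of ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def subset(self, ids: list[str]) -> "Alignment":
        pos = {i: k for k, i in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment(list(ids), [self.rows[pos[i]] for i in ids])


def _unambiguous(c: str) -> bool:
    return c != GAP and c != AMBIG


def mask_sites(
    alignment: Alignment, min_seq_frac: float = 0.3, max_col_frac: float = 0.3
) -> Alignment:
    """Select well-covered columns, then drop poorly covered sequences.

    Step 1 keeps columns whose fraction of unambiguous residues (not
    gap, not X) is at least ``max_col_frac``; step 2 drops sequences
    whose unambiguous coverage of the kept columns is below
    ``min_seq_frac``.  Dropping a sequence can push a kept column back
    below the threshold, so the two steps are iterated to a fixed
    point, making the operation idempotent at fixed thresholds.
    """
    if not 0 <= min_seq_frac <= 1 or not 0 <= max_col_frac <= 1:
        raise ValueError("fractions must be within [0, 1]")
    ids, rows = list(alignment.ids), list(alignment.rows)
    while True:
        n = len(rows)
        kept_cols = [
            j for j in range(len(rows[0]) if rows else 0)
            if sum(_unambiguous(r[j]) for r in rows) / n >= max_col_frac
        ]
        if not kept_cols:
            raise ValueError(
                "all columns dropped; lower max_col_frac or check the alignment"
            )
        new_ids, new_rows = [], []
        for i, row in enumerate(rows):
            sub = "".join(row[j] for j in kept_cols)
            if sum(map(_unambiguous, sub)) / len(sub) >= min_seq_frac:
                new_ids.append(ids[i])
                new_rows.append(sub)
        if not new_rows:
            raise ValueError(
                "all sequences dropped; lower min_seq_frac or check the alignment"
            )
        stable = new_ids == ids and len(kept_cols) == len(rows[0])
        ids, rows = new_ids, new_rows
        if stable:
            return Alignment(ids, rows)


def splice_domain(alignment: Alignment, mask: list[int]) -> list[tuple[str, str]]:
    """Extract one domain: concatenate residues at the mask columns and
    drop gaps; sequences left empty are omitted with a warning."""
    if any(b <= a for a, b in zip(mask, mask[1:])):
        raise ValueError("mask indices must be strictly increasing")
    if mask and (mask[0] < 0 or mask[-1] >= alignment.n_cols):
        raise ValueError("mask outside alignment width")
    out = []
    for sid, row in zip(alignment.ids, alignment.rows):
        seq = "".join(row[j] for j in mask if row[j] != GAP)
        if not seq:
            warnings.warn(f"{sid}: empty after domain splicing; omitted", stacklevel=2)
            continue
        out.append((sid, seq))
    return out


def split_tandem(
    seq_id: str, sequence: str, mode: str = "half", boundary_pos: int | None = None
) -> list[tuple[str, str]]:
    """Split a tandem-domain protein into two pieces.

    ``half`` cuts at half-length (first piece gets the extra residue on
    odd lengths); ``boundary`` cuts at an explicit position.  The caller
    discards pieces lacking the target domain.
    """
    if mode == "half":
        if len(sequence) < 2:
            raise ValueError("sequence too short to split at half-length")
        cut = (len(sequence) + 1) // 2
    elif mode == "boundary":
        if boundary_pos is None or not 0 < boundary_pos < len(sequence):
            raise ValueError(f"invalid boundary position {boundary_pos!r}")
        cut = boundary_pos
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return [(f"{seq_id}_N", sequence[:cut]), (f"{seq_id}_C", sequence[cut:])]


def dedup_sequences(
    records: list[ProteinRecord],
    identity_min: float = 0.65,
    keep_all_taxa: bool = True,
) -> list[ProteinRecord]:
    """Greedy identity clustering, longest sequences first.

    A record joins the first cluster whose representative shares global
    identity (matches over the shorter sequence) >= ``identity_min``.
    Output is the representatives plus, when ``keep_all_taxa``, the
    longest member per additional taxon in each cluster.
    """
    if not 0 < identity_min <= 1:
        raise ValueError("identity_min must be in (0, 1]")
    from .pairwise import global_identity

    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.taxon, r.protein_id))
    reps: list[ProteinRecord] = []
    clusters: list[list[ProteinRecord]] = []
    for rec in ordered:
        placed = False
        for rep, members in zip(reps, clusters):
            if global_identity(rec.sequence, rep.sequence) >= identity_min:
                members.append(rec)
                placed = True
                break
        if not placed:
            reps.append(rec)
            clusters.append([rec])
    out = []
    for rep, members in zip(reps, clusters):
        out.append(rep)
        if keep_all_taxa:
            extra: dict[str, ProteinRecord] = {}
            for m in members:
                if m.taxon == rep.taxon or m is rep:
                    continue
                cur = extra.get(m.taxon)
                if cur is None or len(m.sequence) > len(cur.sequence):
                    extra[m.taxon] = m
            out.extend(extra[t] for t in sorted(extra))
    return out


def prune_divergent(
    records: list[ProteinRecord],
    references: list[ProteinRecord],
    evalue_max: float = 1e-3,
    min_hits: int = 1,
    ident_low: float = 0.01,
    ident_high: float = 0.2,
) -> list[ProteinRecord]:
    """Remove significantly homologous yet highly divergent sequences.

    A record is dropped when it has at least ``min_hits`` reference
    matches that are significant (e-value <= ``evalue_max``) with
    identity in [``ident_low``, ``ident_high``) — i.e., clearly related
    but too divergent to align reliably.  Records with no qualifying hit
    are retained.
    """
    if not references:
        raise ValueError("empty reference set")
    if not ident_low < ident_high:
        raise ValueError("ident_low must be < ident_high")
    db_residues = sum(len(r.sequence) for r in references)
    out = []
    for rec in records:
        qualifying = 0
        divergent_only = True
        for ref in references:
            hit = best_local_hit(rec.sequence, ref.sequence)
            if hit is None:
                continue
            ident = hit.identity_short
            if ident >= ident_high:
                # close to at least one reference: never an outlier
                divergent_only = False
                break
            e = evalue(hit.score, len(rec.sequence), db_residues)
            if e > evalue_max:
                continue
            if ident_low <= ident < ident_high:
                qualifying += 1
        if divergent_only and qualifying >= min_hits:
            continue
        out.append(rec)
    return out


def annotate_best_hit(
    records: list[ProteinRecord],
    references: list[tuple[ProteinRecord, str]],
    evalue_max: float = 1e-20,
) -> dict[str, str]:
    """Tag each record with the label of its best significant reference.

    The best hit is the reference with the highest raw local-alignment
    score whose e-value is <= ``evalue_max``; score ties go to the
    lexicographically smaller reference id.  Records without a
    significant hit are tagged "unannotated".  Returns record id ->
    label.
    """
    db_residues = sum(len(r.sequence) for r, _ in references)
    tags = {}
    for rec in records:
        best: tuple[float, str, str] | None = None
        for ref, label in sorted(references, key=lambda rl: rl[0].protein_id):
            hit = best_local_hit(rec.sequence, ref.sequence)
            if hit is None:
                continue
            if evalue(hit.score, len(rec.sequence), db_residues) > evalue_max:
                continue
            if best is None or hit.score > best[0]:
                best = (hit.score, ref.protein_id, label)
        tags[rec.protein_id] = best[2] if best else "unannotated"
    return tags
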