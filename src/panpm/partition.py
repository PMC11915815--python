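"""Trait partition of the taxon sample.

Every filter in the pipeline is driven by a three-way partition of the
taxa: trait-positive subgroup A (a Methanopyrales-like singleton lineage),
trait-positive subgroup B (Methanobacteriales-like), and trait-negative
taxa that lack the cell-wall polymer of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

POS_A = "pos_A"
POS_B = "pos_B"
NEG = "neg"

_GROUPS = (POS_A, POS_B, NEG)


@dataclass(frozen=True)
class TraitPartition:
    """Assignment of each taxon to one of {pos_A, pos_B, neg}."""

    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: g for t, g in self.groups.items() if g not in _GROUPS}
        if bad:
            raise ValueError(f"unknown partition group(s): {bad}")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.groups)

    def group_of(self, taxon: str) -> str:
        return self.groups[taxon]

    def taxa_in(self, group: str) -> list[str]:
        if group not in _GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return sorted(t for t, g in self.groups.items() if g == group)

    @property
    def pos_a_taxa(self) -> list[str]:
        return self.taxa_in(POS_A)

    @property
    def pos_b_taxa(self) -> list[str]:
        return self.taxa_in(POS_B)

    @property
    def pos_taxa(self) -> list[str]:
        return sorted(self.pos_a_taxa + self.pos_b_taxa)

    @property
    def neg_taxa(self) -> list[str]:
        return self.taxa_in(NEG)

    def require_nonempty(self, *groups: str) -> None:
        for g in groups:
            if not self.taxa_in(g):
                raise ValueError(f"partition group {g!r} is empty")

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "TraitPartition":
        return cls(dict(mapping))

    @classmethod
    def default_ten_taxa(cls) -> "TraitPartition":
        """The study design emulated by the synthetic generator.

        Ten taxa: one trait-positive subgroup-A lineage, four subgroup-B
        lineages, and five trait-negative taxa.
        """
        groups = {"T01": POS_A}
        groups.update({f"T{i:02d}": POS_B for i in range(2, 6)})
        groups.update({f"T{i:02d}": NEG for i in range(6, 11)})
        return cls(groups)
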