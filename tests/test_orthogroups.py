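"""Orthogroup clustering and the trait-specific candidate filters."""

import itertools

import numpy as np
import pytest

from panpm import orthogroups as og_mod
from panpm.orthogroups import OrthologousGroup
from panpm.partition import TraitPartition
from panpm.seqio import (
    ProteinRecord,
    read_orthogroup_table,
    write_orthogroup_table,
)

PART = TraitPartition.default_ten_taxa()


def _og(counts: dict[str, int], og_id: str = "OGX") -> OrthologousGroup:
    return OrthologousGroup(
        og_id, {t: [f"{t}_p{i}" for i in range(n)] for t, n in counts.items() if n}
    )


# ---------------------------------------------------------------------------
# clustering


def test_identical_sequences_cluster_together():
    seq = "MKVLAATGLVWELARRAYSTQPLD" * 5
    recs = [ProteinRecord("p1", "tA", seq), ProteinRecord("p2", "tB", seq)]
    ogs = og_mod.cluster_orthogroups(recs, k=4, jaccard_min=0.6)
    assert len(ogs) == 1
    assert sum(len(v) for v in ogs[0].members.values()) == 2


def test_random_sequences_stay_singletons():
    rng = np.random.default_rng(0)
    recs = [
        ProteinRecord(f"p{i}", "t", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 300)))
        for i in range(50)
    ]
    # independent oracle: directly compute the max pairwise 4-mer Jaccard
    kmers = [
        {r.sequence[i:i + 4] for i in range(len(r.sequence) - 3)} for r in recs
    ]
    max_j = max(
        len(a & b) / len(a | b) for a, b in itertools.combinations(kmers, 2)
    )
    assert max_j < 0.6
    ogs = og_mod.cluster_orthogroups(recs, k=4, jaccard_min=0.6)
    assert len(ogs) == 50


def test_cluster_table_round_trip(tmp_path, bundle):
    recs = [r for recs in bundle.proteomes.values() for r in recs][:200]
    ogs = og_mod.cluster_orthogroups(recs)
    table = {og.og_id: og.members for og in ogs}
    path = tmp_path / "ogs.tsv"
    write_orthogroup_table(path, table, sorted({r.taxon for r in recs}))
    back, _taxa = read_orthogroup_table(path)
    assert {k: {t: sorted(v) for t, v in m.items()} for k, m in table.items()} == {
        k: {t: sorted(v) for t, v in m.items()} for k, m in back.items()
    }


def test_cluster_empty_input_errors():
    with pytest.raises(ValueError):
        og_mod.cluster_orthogroups([])


# ---------------------------------------------------------------------------
# presence patterns


def test_all_pos_pattern_selected():
    og = _og({t: 1 for t in PART.pos_taxa})
    [(selected, label)] = og_mod.filter_by_presence([og], PART)
    assert label == "all_pos"


def test_present_everywhere_rejected():
    og = _og({t: 1 for t in PART.taxa})
    assert og_mod.filter_by_presence([og], PART) == []


def test_one_pos_a_three_pos_b_pattern():
    og = _og({"T01": 1, "T02": 1, "T03": 1, "T05": 1})
    [(selected, label)] = og_mod.filter_by_presence([og], PART)
    assert label == "one_posA_three_posB"


def test_four_pos_b_requires_pos_a_absence():
    og = _og({"T02": 1, "T03": 1, "T04": 1, "T05": 1})
    [(_, label)] = og_mod.filter_by_presence([og], PART)
    assert label == "four_posB"
    with_a = _og({"T01": 1, "T02": 1, "T03": 1, "T04": 1, "T05": 1})
    [(_, label)] = og_mod.filter_by_presence([with_a], PART)
    assert label == "all_pos"  # first matching pattern in listed order


def test_presence_invariant_to_member_permutation():
    counts = {"T01": 2, "T02": 1, "T03": 1, "T04": 1, "T05": 3}
    og = _og(counts)
    shuffled = OrthologousGroup(
        og.og_id, {t: list(reversed(ms)) for t, ms in og.members.items()}
    )
    assert [l for _, l in og_mod.filter_by_presence([og], PART)] == [
        l for _, l in og_mod.filter_by_presence([shuffled], PART)
    ]


# ---------------------------------------------------------------------------
# paralog filter


@pytest.mark.parametrize(
    "pos,neg,passes",
    [
        ([2, 2, 2, 1, 2], [1, 1, 1, 1, 1], True),   # means 1.8 / 1.0
        ([1, 1, 1, 1, 1], [1, 1, 1, 1, 1], False),  # mean 1.0 < 1.75
        ([2, 2, 2, 2, 2], [2, 2, 1, 1, 1], False),  # neg mean 1.4 > 1.25
        ([2, 2, 2, 2, 0], [1, 1, 1, 1, 1], False),  # absent pos taxon
    ],
)
def test_paralog_copy_mean_rule(pos, neg, passes):
    counts = dict(zip(PART.pos_taxa, pos)) | dict(zip(PART.neg_taxa, neg))
    result = og_mod.filter_paralog_targeting([_og(counts)], PART)
    assert bool(result) is passes


# ---------------------------------------------------------------------------
# rescue & completeness


@pytest.fixture(scope="module")
def bundle_sequences(bundle):
    return {r.protein_id: r.sequence for recs in bundle.proteomes.values() for r in recs}


def test_planted_pseudogene_rescued(bundle, default_spec, bundle_sequences):
    fam, taxon = default_spec.planted_pseudogenes[0]
    og = og_mod.ogs_from_table({fam: bundle.orthogroups[fam]})[0]
    assert og.copy_count(taxon) == 0
    rescued = og_mod.rescue_missing_members(
        og, bundle_sequences, {taxon: bundle.contigs[taxon]}, default_spec.partition
    )
    assert [t for t, _locus in rescued.rescued] == [taxon]
    assert rescued.members == og.members  # member proteins untouched


def test_random_genome_yields_no_rescue(bundle, default_spec, bundle_sequences):
    rng = np.random.default_rng(5)
    random_genome = "".join(rng.choice(list("ACGT"), size=30000))
    fam, taxon = default_spec.planted_pseudogenes[0]
    og = og_mod.ogs_from_table({fam: bundle.orthogroups[fam]})[0]
    rescued = og_mod.rescue_missing_members(
        og, bundle_sequences, {taxon: random_genome}, default_spec.partition
    )
    assert rescued.rescued == []


def test_complete_og_returned_unchanged(bundle, default_spec, bundle_sequences):
    og = og_mod.ogs_from_table({"FAMS04": bundle.orthogroups["FAMS04"]})[0]
    assert og_mod.rescue_missing_members(
        og, bundle_sequences, {}, default_spec.partition
    ) is og


def test_rescue_missing_genome_errors(bundle, default_spec, bundle_sequences):
    fam, taxon = default_spec.planted_pseudogenes[0]
    og = og_mod.ogs_from_table({fam: bundle.orthogroups[fam]})[0]
    with pytest.raises(ValueError, match=taxon):
        og_mod.rescue_missing_members(og, bundle_sequences, {}, default_spec.partition)


def test_completeness_filter_rules():
    complete = _og({t: 1 for t in PART.pos_taxa}, "OGA")
    partial = _og({t: 1 for t in PART.pos_taxa[:4]}, "OGB")
    patched = OrthologousGroup("OGC", partial.members, [(PART.pos_taxa[4], "ctg:frame1")])
    kept = og_mod.completeness_filter([complete, partial, patched], PART)
    assert [og.og_id for og in kept] == ["OGA", "OGC"]
    assert og_mod.completeness_filter([], PART) == []


def test_all_pos_selection_is_subset_of_completeness():
    ogs = [
        _og({t: 1 for t in PART.pos_taxa}, "OG1"),
        _og({t: 1 for t in PART.taxa}, "OG2"),
        _og({"T01": 1, "T02": 1, "T03": 1, "T04": 1}, "OG3"),
    ]
    all_pos = {
        og.og_id
        for og, label in og_mod.filter_by_presence(ogs, PART, ["all_pos"])
    }
    complete = {og.og_id for og in og_mod.completeness_filter(ogs, PART)}
    assert all_pos <= complete


# ---------------------------------------------------------------------------
# profile selection


def test_profile_exact_copy_is_top_hit():
    rng = np.random.default_rng(1)
    seed_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
    seed_ali = [("s1", seed_seq), ("s2", seed_seq)]
    decoys = [
        ProteinRecord(f"d{i}", "tX", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80)))
        for i in range(5)
    ]
    target = ProteinRecord("hit", "tX", seed_seq)
    hits = og_mod.profile_select(seed_ali, {"tX": decoys + [target]}, score_min=1.0)
    assert hits["tX"][0][0] == "hit"
    assert hits["tX"][0][2] == pytest.approx(1.0)  # full coverage


def test_profile_max_copy_cap():
    seed_seq = "MKVLAATGLVWELARRAYSTQPLD" * 3
    seed_ali = [("s1", seed_seq), ("s2", seed_seq)]
    prots = [ProteinRecord(f"m{i:02d}", "tY", seed_seq) for i in range(25)]
    hits = og_mod.profile_select(seed_ali, {"tY": prots}, max_copy=20)
    assert len(hits["tY"]) == 20


def test_profile_min_cov_excludes_short_overlap():
    seed_seq = "MKVLAATGLVWELARRAYSTQPLD" * 4  # 96 columns
    seed_ali = [("s1", seed_seq), ("s2", seed_seq)]
    short = ProteinRecord("sh", "tZ", seed_seq[:57])  # 0.59 of the profile
    hits = og_mod.profile_select(seed_ali, {"tZ": [short]}, min_cov=0.7)
    assert "tZ" not in hits


def test_profile_single_sequence_alignment_errors():
    with pytest.raises(ValueError):
        og_mod.build_pssm([("only", "MKV")])


# ---------------------------------------------------------------------------
# taxonomic distribution


@pytest.mark.parametrize(
    "bacteria,non_pm,expected",
    [
        (True, True, "widespread"),
        (True, False, "bacteria_and_PM"),
        (False, True, "archaea_only"),
        (False, False, "PM_only"),
    ],
)
def test_distribution_grid(bacteria, non_pm, expected):
    label = og_mod.classify_distribution(
        {"bacteria": bacteria, "nonPM_archaea": non_pm, "PM_archaea": True}
    )
    assert label == expected


def test_distribution_requires_trait_positive_presence():
    with pytest.raises(ValueError):
        og_mod.classify_distribution(
            {"bacteria": True, "nonPM_archaea": True, "PM_archaea": False}
        )
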