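"""The curation filter cascade, known-annotation, merging and presence
arithmetic."""

import numpy as np
import pytest

from mirovary import (
    CutoffPolicy,
    HairpinRecord,
    annotate_known,
    apply_expression_cutoff,
    apply_structural_filters,
    cross_sample_presence,
    filter_contaminants,
    merge_profiles,
    merge_shared_arm,
)
from mirovary.arm_profiling import ArmProfile
from mirovary.curation import CurationDecision, curate_sample, matches_mature


def _profile(gene, sample, c5, c3, h5=1.0, h3=1.0):
    return ArmProfile(gene, sample, c5, c3, h5 if c5 else None, h3 if c3 else None)


def _random_hairpin(rng, gene_id="hp"):
    seq = "".join(rng.choice(list("acgu"), size=70))
    return HairpinRecord(gene_id, seq, seq[5:27], seq[40:62])


# ---- contaminant filter ----

def test_contaminant_hit_on_embedded_fragment():
    rng = np.random.default_rng(0)
    rrna = "".join(rng.choice(list("acgu"), size=120))
    hp = _random_hairpin(rng)
    poisoned = HairpinRecord("bad", hp.precursor[:30] + rrna[:20] + hp.precursor[30:], hp.mature_5p, hp.mature_3p)
    survivors, flagged = filter_contaminants([hp, poisoned], [rrna])
    assert flagged == {"bad"}
    assert [h.gene_id for h in survivors] == ["hp"]


def test_contaminant_no_hit_verified_by_brute_force():
    rng = np.random.default_rng(1)
    hp = _random_hairpin(rng)
    catalogue = ["".join(rng.choice(list("acgu"), size=100)) for _ in range(5)]
    # brute-force: no shared 16-mer on either strand
    from mirovary.arm_profiling import reverse_complement

    kmers = {hp.precursor[i: i + 16] for i in range(len(hp.precursor) - 15)}
    for entry in catalogue:
        for strand in (entry, reverse_complement(entry)):
            for i in range(len(strand) - 15):
                assert strand[i: i + 16] not in kmers
    _, flagged = filter_contaminants([hp], catalogue)
    assert not flagged


def test_contaminant_min_hit_len_longer_than_hairpin_passes():
    rng = np.random.default_rng(2)
    hp = _random_hairpin(rng)
    _, flagged = filter_contaminants([hp], [hp.precursor], min_hit_len=len(hp.precursor) + 1)
    assert not flagged


# ---- structural filters ----

def test_single_arm_fails():
    d = apply_structural_filters(_profile("g", "s", 0, 500))
    assert not d.passed and d.failed_rule == "single_arm"


def test_low_homogeneity_fails_and_boundary_is_inclusive():
    d = apply_structural_filters(_profile("g", "s", 10, 10, 1.0, 0.94))
    assert d.failed_rule == "low_homogeneity"
    d = apply_structural_filters(_profile("g", "s", 10, 10, 0.95, 0.95))
    assert d.passed


# ---- expression cutoff ----

def test_cutoff_is_strict_greater_than():
    policy = CutoffPolicy({"sthubert": 18, "zonza": 50})
    assert apply_expression_cutoff(_profile("g", "sthubert", 19, 1), policy).passed
    assert not apply_expression_cutoff(_profile("g", "sthubert", 18, 1), policy).passed
    assert not apply_expression_cutoff(_profile("g", "zonza", 50, 1), policy).passed
    with pytest.raises(KeyError):
        apply_expression_cutoff(_profile("g", "unknown", 10, 1), policy)


def test_cascade_order_and_first_failure_recorded():
    policy = CutoffPolicy({"s": 1000})
    decisions = curate_sample(
        {"g": _profile("g", "s", 5, 0)}, policy, contaminant_ids={"g"}
    )
    assert decisions["g"].failed_rule == "contaminant"  # first rule wins
    decisions = curate_sample({"g": _profile("g", "s", 5, 0)}, policy)
    assert decisions["g"].failed_rule == "single_arm"
    # known genes skip structural rules but not the cutoff
    decisions = curate_sample({"g": _profile("g", "s", 5, 0)}, policy, known_ids={"g"})
    assert decisions["g"].failed_rule == "below_cutoff"


def test_cascade_monotone_in_thresholds():
    """Relaxing any threshold never shrinks the pass set."""
    rng = np.random.default_rng(3)
    profiles = {
        f"g{i}": _profile(f"g{i}", "s", int(rng.integers(0, 100)), int(rng.integers(0, 100)),
                          float(rng.uniform(0.9, 1)), float(rng.uniform(0.9, 1)))
        for i in range(50)
    }
    strict = curate_sample(profiles, CutoffPolicy({"s": 40}), min_homogeneity=0.97)
    relaxed = curate_sample(profiles, CutoffPolicy({"s": 10}), min_homogeneity=0.92)
    passed_strict = {g for g, d in strict.items() if d.passed}
    passed_relaxed = {g for g, d in relaxed.items() if d.passed}
    assert passed_strict <= passed_relaxed


def test_decision_invariant_checks():
    with pytest.raises(ValueError):
        CurationDecision("g", "s", True, "single_arm", 10)


# ---- known annotation ----

def test_annotate_known_exact_and_mismatched_matches():
    rng = np.random.default_rng(4)
    hp = _random_hairpin(rng)
    catalogue = {"miR-2763": [hp.mature_3p]}
    assert annotate_known(hp, catalogue) == "miR-2763"
    # two substitutions still match; an unrelated catalogue does not
    mutated = list(hp.mature_3p)
    mutated[3] = "a" if mutated[3] != "a" else "c"
    mutated[10] = "g" if mutated[10] != "g" else "u"
    assert annotate_known(hp, {"miR-2763": ["".join(mutated)]}) == "miR-2763"
    random_cat = {f"k{i}": ["".join(rng.choice(list("acgu"), size=22))] for i in range(20)}
    # brute-force confirm >2 mismatches against every entry at every offset
    for seqs in random_cat.values():
        assert not matches_mature(hp.mature_5p, seqs[0]) and not matches_mature(hp.mature_3p, seqs[0])
    assert annotate_known(hp, random_cat) is None


# ---- shared-arm merging ----

def test_merge_shared_arm_groups_identical_products():
    rng = np.random.default_rng(5)
    a, b, c = (_random_hairpin(rng, g) for g in ("Par-340", "Par-341", "Par-247"))
    b = HairpinRecord("Par-341", b.precursor[: b.arm3_interval[0]] + a.mature_3p + b.precursor[b.arm3_interval[1]:], b.mature_5p, a.mature_3p)
    groups = merge_shared_arm([a, b, c])
    ids = sorted(g.group_id for g in groups)
    assert ids == ["Par-247", "Par-340/Par-341"]


def test_merge_is_transitive_and_counts_take_max():
    rng = np.random.default_rng(6)
    base = _random_hairpin(rng, "A")
    shared_5p = base.mature_5p
    shared_3p = base.mature_3p
    mk = lambda gid, m5, m3: HairpinRecord(
        gid, "aaaa" + m5 + "u" * 12 + m3 + "gggg", m5, m3
    )
    m_other = "".join(rng.choice(list("acgu"), size=22))
    a = mk("A", shared_5p, shared_3p)
    b = mk("B", m_other, shared_3p)  # shares 3' with A
    c = mk("C", m_other, "".join(rng.choice(list("acgu"), size=22)))  # shares 5' with B
    groups = merge_shared_arm([a, b, c])
    assert len(groups) == 1 and groups[0].group_id == "A/B/C"

    profiles = {
        "A": _profile("A", "s", 51, 1),
        "B": _profile("B", "s", 30, 2),
        "C": _profile("C", "s", 10, 7),
    }
    merged = merge_profiles(groups, profiles)
    assert merged["A/B/C"].count_5p == 51 and merged["A/B/C"].count_3p == 7


# ---- presence arithmetic ----

def test_cross_sample_presence_set_arithmetic():
    """58 and 57 known genes with 52 shared union to 63; adding 11 novel
    (3 shared) gives 74 expressed, 55 common, and a 139+11=150 catalogue."""
    known_shared = [f"k{i}" for i in range(52)]
    known_a_only = [f"ka{i}" for i in range(6)]   # 58 total in A
    known_b_only = [f"kb{i}" for i in range(5)]   # 57 total in B
    novel_shared = [f"n{i}" for i in range(3)]
    novel_a_only = [f"na{i}" for i in range(6)]
    novel_b_only = [f"nb{i}" for i in range(2)]

    def _decide(genes, sample):
        return {g: CurationDecision(g, sample, True, "none", 100) for g in genes}

    decisions = {
        "sthubert": _decide(known_shared + known_a_only + novel_shared + novel_a_only, "sthubert"),
        "zonza": _decide(known_shared + known_b_only + novel_shared + novel_b_only, "zonza"),
    }
    known_ids = known_shared + known_a_only + known_b_only
    summary = cross_sample_presence(decisions, known_ids, n_previously_known=139)
    assert len(summary.per_sample["sthubert"]) == 58 + 9
    assert summary.known_union == 63
    assert summary.known_shared == 52
    assert summary.novel_union == 11
    assert summary.novel_shared == 3
    assert summary.expressed_total == 74
    assert summary.shared_total == 55
    assert summary.catalogue_total == 150
    with pytest.raises(ValueError):
        cross_sample_presence({"one": decisions["zonza"]}, known_ids)
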