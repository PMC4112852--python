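"""Rubric scoring: category scorers, composite totals, and rubric invariants."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicescore import (
    Category,
    Dossier,
    EvidenceItem,
    Factor,
    Phenotype,
    RubricConfig,
    classify,
    score_dossier,
    score_experimental,
    score_informatic,
    score_omic,
)
from dicescore.evidence_model import item_is_significant
from dicescore.scoring import InvalidDossierError

GWS = 5e-8


def omic(item_id, subtype="discovery", p=None, override=None, key=None, reviewed=True):
    return EvidenceItem(
        item_id=item_id,
        category=Category.omic,
        subtype=subtype,
        result_key=key or item_id,
        p_value=p,
        significant_override=override,
        reviewed=reviewed,
    )


def flat(item_id, category, subtype=None, reviewed=True, key=None):
    default_subtype = {"informatic": "literature", "experimental": "animal_model"}
    return EvidenceItem(
        item_id=item_id,
        category=Category(category),
        subtype=subtype or default_subtype[category],
        result_key=key or item_id,
        reviewed=reviewed,
    )


def dossier(items):
    return Dossier(Factor("G"), Phenotype("ph"), list(items))


# --- independent brute-force oracle -----------------------------------------


def oracle_total(items, config):
    """Naive recomputation of the composite total, written independently.

    Enumerates every way of keeping one item per result_key and takes the
    best naive category-by-category sum.
    """

    def naive(kept):
        if config.require_reviewed:
            kept = [i for i in kept if i.reviewed]
        sig = lambda i: (
            i.significant_override
            if i.significant_override is not None
            else (i.p_value is not None and i.p_value < config.discovery_threshold)
        )
        omics = [i for i in kept if i.category is Category.omic]
        has_disc = any(i.subtype == "discovery" and sig(i) for i in omics)
        single = config.points_single_finding if has_disc else 0
        if any(i.subtype == "standard_validation" and sig(i) for i in omics):
            val = config.points_standard_validation
        elif any(i.subtype == "alternative_validation" and sig(i) for i in omics):
            val = config.points_alternative_validation
        else:
            val = 0
        if config.validation_requires_discovery and not has_disc:
            val = 0
        info = (
            config.points_informatic
            if any(i.category is Category.informatic for i in kept)
            else 0
        )
        exp = (
            config.points_experimental
            if any(i.category is Category.experimental for i in kept)
            else 0
        )
        return single + val + info + exp

    groups = {}
    for i in items:
        groups.setdefault(i.result_key, []).append(i)
    best = 0
    for combo in itertools.product(*groups.values()):
        best = max(best, naive(list(combo)))
    return best


# --- category scorers --------------------------------------------------------


class TestScoreOmic:
    def test_significant_discovery_alone(self, default_config):
        single, val, attr = score_omic([omic("d1", p=6.1e-9)], default_config)
        assert (single, val) == (1, 0)
        assert attr["single_finding"] == ("d1",)

    def test_override_discovery_with_alternative_validation(self, default_config):
        items = [
            omic("d1", override=True),
            omic("v1", "alternative_validation", override=True),
        ]
        assert score_omic(items, default_config)[:2] == (1, 2)

    def test_validation_gated_without_discovery(self, default_config):
        # sub-threshold scans plus a meta-analysis hit: nothing qualifies
        items = [
            omic("d1", p=0.019),
            omic("d2", p=0.0013),
            omic("v1", "alternative_validation", p=1.7e-6),
        ]
        assert score_omic(items, default_config)[:2] == (0, 0)

    def test_ungated_when_rule_disabled(self):
        config = RubricConfig(validation_requires_discovery=False)
        items = [omic("v1", "alternative_validation", p=1e-9)]
        assert score_omic(items, config)[:2] == (0, 2)

    def test_standard_supersedes_alternative_never_both(self, default_config):
        items = [
            omic("d", p=1e-9),
            omic("s", "standard_validation", p=1e-9),
            omic("a", "alternative_validation", p=1e-9),
        ]
        single, val, attr = score_omic(items, default_config)
        assert (single, val) == (1, 3)
        assert attr["validation"] == ("s",)

    def test_empty(self, default_config):
        assert score_omic([], default_config)[:2] == (0, 0)

    def test_wrong_category_is_misuse(self, default_config):
        with pytest.raises(ValueError, match="category"):
            score_omic([flat("x", "informatic")], default_config)

    def test_override_supersedes_p_value(self, default_config):
        # explicit non-significant call wins over a tiny p, and vice versa
        assert not item_is_significant(omic("a", p=1e-12, override=False),
                                       default_config)
        assert item_is_significant(omic("b", p=0.9, override=True), default_config)


class TestFlatScorers:
    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 3), (5, 3)])
    def test_no_accumulation(self, default_config, n, expected):
        items = [flat(f"i{k}", "informatic") for k in range(n)]
        points, _ = score_informatic(items, default_config)
        assert points == expected

    def test_experimental_mirrors_informatic(self, default_config):
        assert score_experimental([flat("e", "experimental")], default_config)[0] == 3
        assert score_experimental([], default_config)[0] == 0

    def test_unreviewed_items_do_not_score(self, default_config):
        items = [flat("i1", "informatic", reviewed=False)]
        assert score_informatic(items, default_config)[0] == 0
        relaxed = RubricConfig(require_reviewed=False)
        assert score_informatic(items, relaxed)[0] == 3

    def test_wrong_category_is_misuse(self, default_config):
        with pytest.raises(ValueError, match="category"):
            score_informatic([flat("e", "experimental")], default_config)


class TestClassify:
    @pytest.mark.parametrize("total,expected", [(9, "strong"), (6, "strong"),
                                                (5, "weak"), (0, "weak")])
    def test_cutoff(self, default_config, total, expected):
        assert classify(total, default_config) == expected

    def test_negative_total_rejected(self, default_config):
        with pytest.raises(ValueError):
            classify(-1, default_config)


# --- composite ---------------------------------------------------------------


class TestScoreDossier:
    def test_empty_dossier(self, default_config):
        score = score_dossier(dossier([]), default_config)
        assert score.total == 0 and score.classification == "weak"

    def test_invalid_dossier_rejected_with_violations(self, default_config):
        d = dossier([omic("x", p=2.0)])
        with pytest.raises(InvalidDossierError) as exc:
            score_dossier(d, default_config)
        assert any("p_value" in v for v in exc.value.violations)

    def test_additivity_and_attribution_cover_points(self, canonical):
        for d in canonical.values():
            s = score_dossier(d)
            assert s.total == (
                s.single_finding_points
                + s.validation_points
                + s.informatic_points
                + s.experimental_points
            )
            for comp, pts in [
                ("single_finding", s.single_finding_points),
                ("validation", s.validation_points),
                ("informatic", s.informatic_points),
                ("experimental", s.experimental_points),
            ]:
                assert (pts > 0) == bool(s.attribution.get(comp))

    def test_order_invariance(self, canonical):
        for d in canonical.values():
            shuffled = Dossier(d.factor, d.phenotype, d.items[::-1], d.notes)
            assert score_dossier(shuffled).to_dict()["total"] == score_dossier(d).total

    def test_single_category_cannot_reach_strong_under_defaults(self, default_config):
        # max per category: omic 1+3=4, informatic 3, experimental 3 — all < 6
        omic_only = [omic("d", p=1e-9), omic("s", "standard_validation", p=1e-9)]
        info_only = [flat(f"i{k}", "informatic") for k in range(5)]
        exp_only = [flat(f"e{k}", "experimental") for k in range(5)]
        for items in (omic_only, info_only, exp_only):
            s = score_dossier(dossier(items), default_config)
            assert s.classification == "weak" and s.total < 6

    def test_strong_reachable_from_exactly_two_categories(self, default_config):
        # omic 1 + 2 + informatic 3 = 6
        items = [
            omic("d", override=True),
            omic("a", "alternative_validation", override=True),
            flat("i", "informatic"),
        ]
        s = score_dossier(dossier(items), default_config)
        assert s.total == 6 and s.classification == "strong"


# --- property tests against the oracle ---------------------------------------

item_strategy = st.builds(
    lambda i, cat, sub_idx, key, p, override, reviewed: _make_item(
        i, cat, sub_idx, key, p, override, reviewed
    ),
    i=st.integers(0, 10_000),
    cat=st.sampled_from(["omic", "informatic", "experimental"]),
    sub_idx=st.integers(0, 3),
    key=st.sampled_from(["r1", "r2", "r3", "r4"]),
    p=st.sampled_from([None, 1e-9, 4.9e-8, 5e-8, 1e-3, 0.83]),
    override=st.sampled_from([None, True, False]),
    reviewed=st.booleans(),
)

_SUBTYPES = {
    "omic": ["discovery", "discovery", "standard_validation", "alternative_validation"],
    "informatic": ["literature", "pathway_db", "expression_db", "other_db"],
    "experimental": ["animal_model", "cell_molecular", "treatment", "treatment"],
}


def _make_item(i, cat, sub_idx, key, p, override, reviewed):
    return EvidenceItem(
        item_id=f"it{i}",
        category=Category(cat),
        subtype=_SUBTYPES[cat][sub_idx],
        result_key=key,
        p_value=p if cat == "omic" else None,
        significant_override=override if cat == "omic" else None,
        reviewed=reviewed,
    )


def _uniquify(items):
    return [
        EvidenceItem(
            item_id=f"u{k}",
            category=i.category,
            subtype=i.subtype,
            result_key=i.result_key,
            p_value=i.p_value,
            significant_override=i.significant_override,
            reviewed=i.reviewed,
        )
        for k, i in enumerate(items)
    ]


@given(st.lists(item_strategy, max_size=6))
@settings(derandomize=True, max_examples=200, deadline=None)
def test_engine_matches_brute_force_oracle(items):
    """For small dossiers the engine total equals an exhaustive naive scorer."""
    items = _uniquify(items)
    config = RubricConfig()
    assert score_dossier(dossier(items), config).total == oracle_total(items, config)


@given(st.lists(item_strategy, max_size=5), item_strategy)
@settings(derandomize=True, max_examples=200, deadline=None)
def test_total_monotone_under_evidence_addition(items, extra):
    """Appending any evidence item never decreases the composite total."""
    items = _uniquify(items)
    extra = _uniquify([extra])[0]
    extra = EvidenceItem(
        item_id="extra",
        category=extra.category,
        subtype=extra.subtype,
        result_key=extra.result_key,
        p_value=extra.p_value,
        significant_override=extra.significant_override,
        reviewed=extra.reviewed,
    )
    config = RubricConfig()
    before = score_dossier(dossier(items), config).total
    after = score_dossier(dossier(items + [extra]), config).total
    assert after >= before
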