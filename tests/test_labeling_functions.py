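"""Rule semantics of each labeling function and the application contract."""

import numpy as np
import pytest

from rxnminer.candidates import extract_candidates
from rxnminer.labeling_functions import (
    ABSTAIN,
    DEFAULT_LFS,
    FALSE,
    NEGATIVE,
    POSITIVE,
    TRUE,
    LabelingFunction,
    LFRegistry,
    PolarityViolation,
    apply_lfs,
    build_context,
    lf_argument_order,
    lf_chemical_elements,
    lf_followed_ase,
    lf_group,
    lf_kb_match,
    lf_keyword_context,
    lf_sep_or,
    lf_sep_verb,
    lf_treatment,
)
from rxnminer.resources import ReactionKB, Resources

from .conftest import candidate_pair, make_document


def run_lf(lf, sentence, surfaces, i, j, resources, annotator):
    doc, mentions = make_document(sentence, surfaces, annotator)
    cand = candidate_pair(doc, mentions, i, j)
    return lf(cand, build_context(cand, doc), resources)


class TestKeywordContext:
    @pytest.mark.parametrize("i,j", [(0, 1), (1, 0)])
    def test_keyword_between_fires_for_both_argument_orders(
            self, resources, annotator, i, j):
        # the between-span is textual, so the reversed candidate also fires;
        # the resulting conflict with the order veto is expected signal
        label = run_lf(lf_keyword_context, "glucose is oxidized to ethanol.",
                       ["glucose", "ethanol"], i, j, resources, annotator)
        assert label == TRUE

    def test_no_keyword_abstains(self, resources, annotator):
        assert run_lf(lf_keyword_context, "glucose and ethanol were measured.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN

    def test_keyword_outside_span_abstains(self, resources, annotator):
        # "converted" precedes both mentions: not between them
        assert run_lf(lf_keyword_context,
                      "converted samples contained glucose and ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestSepVerb:
    def test_verb_between(self, resources, annotator):
        assert run_lf(lf_sep_verb, "glucose yields ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == TRUE

    def test_list_without_verb(self, resources, annotator):
        assert run_lf(lf_sep_verb, "glucose, ethanol and lactate.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestArgumentOrder:
    def test_reversed_candidate_vetoed(self, resources, annotator):
        assert run_lf(lf_argument_order, "glucose was converted to ethanol.",
                      ["glucose", "ethanol"], 1, 0, resources, annotator) == FALSE

    def test_forward_candidate_abstains(self, resources, annotator):
        assert run_lf(lf_argument_order, "glucose was converted to ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN

    def test_coverage_exactly_half_on_distinct_starts(self, default_corpus):
        j = default_corpus.matrix.lf_names.index("lf_argument_order")
        col = default_corpus.matrix.data[:, j]
        assert (col != 0).mean() == 0.5


class TestFollowedAse:
    def test_enzyme_modifier_vetoed(self, resources, annotator):
        label = run_lf(lf_followed_ase,
                       "glucose dehydrogenase converts xylose to xylitol.",
                       ["glucose", "xylose"], 0, 1, resources, annotator)
        assert label == FALSE

    def test_plain_reaction_abstains(self, resources, annotator):
        assert run_lf(lf_followed_ase, "glucose yields ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN

    def test_mention_at_sentence_end(self, resources, annotator):
        # no following token: must abstain rather than fail
        assert run_lf(lf_followed_ase, "xylose is converted to xylitol",
                      ["xylose", "xylitol"], 0, 1, resources, annotator) == ABSTAIN

    def test_short_ase_token_not_matched(self, resources, annotator):
        assert run_lf(lf_followed_ase, "glucose base and ethanol were mixed.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestSepOr:
    @pytest.mark.parametrize("i,j", [(0, 1), (1, 0)])
    def test_alternatives_vetoed_either_order(self, resources, annotator, i, j):
        assert run_lf(lf_sep_or, "glucose or ethanol was added.",
                      ["glucose", "ethanol"], i, j, resources, annotator) == FALSE

    def test_or_between_distant_pair(self, resources, annotator):
        # "or" lies between the first and third mention as well
        assert run_lf(lf_sep_or, "glucose or ethanol was converted to lactate.",
                      ["glucose", "ethanol", "lactate"], 0, 2,
                      resources, annotator) == FALSE

    def test_no_or_abstains(self, resources, annotator):
        assert run_lf(lf_sep_or, "glucose to ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestKBMatch:
    def test_known_pair_fires(self, annotator):
        res = Resources(kb=ReactionKB(pairs=frozenset({("gluconic acid", "ethanol")})))
        assert run_lf(lf_kb_match, "Gluconic acid was fermented to ethanol.",
                      ["Gluconic acid", "ethanol"], 0, 1, res, annotator) == TRUE

    def test_reversed_pair_abstains(self, annotator):
        res = Resources(kb=ReactionKB(pairs=frozenset({("gluconic acid", "ethanol")})))
        assert run_lf(lf_kb_match, "Gluconic acid was fermented to ethanol.",
                      ["Gluconic acid", "ethanol"], 1, 0, res, annotator) == ABSTAIN

    def test_empty_kb_abstains(self, annotator):
        res = Resources(kb=ReactionKB(pairs=frozenset()))
        assert run_lf(lf_kb_match, "Gluconic acid was fermented to ethanol.",
                      ["Gluconic acid", "ethanol"], 0, 1, res, annotator) == ABSTAIN


class TestChemicalElements:
    def test_element_vetoed(self, resources, annotator):
        assert run_lf(lf_chemical_elements, "iron and glucose were measured.",
                      ["iron", "glucose"], 0, 1, resources, annotator) == FALSE

    def test_capitalized_element_vetoed(self, resources, annotator):
        assert run_lf(lf_chemical_elements, "Zinc and glucose were measured.",
                      ["Zinc", "glucose"], 0, 1, resources, annotator) == FALSE

    def test_non_elements_abstain(self, resources, annotator):
        assert run_lf(lf_chemical_elements, "glucose yields ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestGroup:
    def test_group_term_in_window(self, resources, annotator):
        assert run_lf(lf_group, "the methyl ester of glucose reacted with ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == FALSE

    def test_group_term_outside_window(self, resources, annotator):
        # "methyl" sits 5 tokens before the first mention: outside window 3
        sentence = "methyl donors were not required because glucose yields ethanol."
        assert run_lf(lf_group, sentence,
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN

    def test_no_group_terms(self, resources, annotator):
        assert run_lf(lf_group, "glucose yields ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN


class TestTreatment:
    def test_clinical_sentence_vetoed(self, resources, annotator):
        assert run_lf(lf_treatment, "patients received glucose and ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == FALSE

    def test_reaction_sentence_abstains(self, resources, annotator):
        assert run_lf(lf_treatment, "glucose is reduced to ethanol.",
                      ["glucose", "ethanol"], 0, 1, resources, annotator) == ABSTAIN

    def test_sentence_scoped(self, resources, annotator):
        # treatment vocabulary in a *different* sentence must not veto
        doc, mentions = make_document(
            "glucose yields ethanol. patients improved with therapy.",
            ["glucose", "ethanol"], annotator)
        cand = candidate_pair(doc, mentions, 0, 1)
        assert lf_treatment(cand, build_context(cand, doc), resources) == ABSTAIN


class TestApplyLFs:
    def test_single_rule_single_candidate(self, resources, annotator):
        doc, mentions = make_document("glucose was converted to ethanol.",
                                      ["glucose", "ethanol"], annotator)
        cand = candidate_pair(doc, mentions, 1, 0)  # reversed
        lf = LabelingFunction("lf_argument_order", NEGATIVE, lf_argument_order)
        L = apply_lfs([cand], [doc], [lf], resources)
        assert L.tolist() == [[-1]]

    def test_zero_candidates(self, resources):
        L = apply_lfs([], [], list(DEFAULT_LFS), resources)
        assert L.shape == (0, len(DEFAULT_LFS))

    def test_polarity_violation_raises_in_strict_mode(self, resources, annotator):
        doc, mentions = make_document("glucose yields ethanol.",
                                      ["glucose", "ethanol"], annotator)
        cand = candidate_pair(doc, mentions, 0, 1)
        bad = LabelingFunction("bad_positive", POSITIVE, lambda c, ctx, r: FALSE)
        with pytest.raises(PolarityViolation):
            apply_lfs([cand], [doc], [bad], resources, strict=True)
        L = apply_lfs([cand], [doc], [bad], resources, strict=False)
        assert L.tolist() == [[0]]

    def test_crashing_lf_records_abstain(self, resources, annotator):
        doc, mentions = make_document("glucose yields ethanol.",
                                      ["glucose", "ethanol"], annotator)
        cand = candidate_pair(doc, mentions, 0, 1)

        def boom(c, ctx, r):
            raise KeyError("bug")

        lfs = [LabelingFunction("crashy", POSITIVE, boom),
               LabelingFunction("lf_sep_verb", POSITIVE, lf_sep_verb)]
        L = apply_lfs([cand], [doc], lfs, resources)
        assert L.tolist() == [[0, 1]]

    def test_unipolarity_over_corpus(self, default_corpus):
        polarity = {lf.name: (1 if lf.polarity == POSITIVE else -1)
                    for lf in DEFAULT_LFS}
        for j, name in enumerate(default_corpus.matrix.lf_names):
            col = set(np.unique(default_corpus.matrix.data[:, j]).tolist())
            assert col <= {0, polarity[name]}

    def test_purity(self, resources, default_corpus):
        sub = default_corpus.candidates[:50]
        L1 = apply_lfs(sub, default_corpus.documents, resources=resources)
        L2 = apply_lfs(sub, default_corpus.documents, resources=resources)
        assert (L1 == L2).all()


class TestRegistry:
    def test_default_registry_and_custom_lf(self):
        reg = LFRegistry()
        assert len(reg) == len(DEFAULT_LFS)
        custom = LabelingFunction("lf_custom", NEGATIVE, lambda c, ctx, r: ABSTAIN)
        reg.register(custom)
        assert reg.get("lf_custom") is custom
        assert [lf.name for lf in reg.select(["lf_sep_or", "lf_custom"])] == \
            ["lf_sep_or", "lf_custom"]
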