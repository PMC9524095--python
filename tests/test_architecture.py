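"""Domain-hit normalisation and the rule mini-grammar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_hit
from oracles import brute_rule_eval, brute_select_hits
from sodnox.architecture import (
    DomainAnnotation,
    RuleParseError,
    annotate,
    count_domains,
    match_rule,
    parse_rule,
)
from sodnox.config import PipelineConfig, RuleSet


def ann_of(hits, length=1000, config=None, rules=None):
    config = config or PipelineConfig()
    lengths = {h.seq_id: length for h in hits}
    return annotate(hits, lengths, config, rules or RuleSet())[hits[0].seq_id]


class TestAnnotate:
    def test_dominance_keeps_higher_score(self, config, rules):
        hits = [
            make_hit(start=10, end=160, score=80.0),
            make_hit(start=50, end=200, score=40.0),
        ]
        ann = ann_of(hits, config=config, rules=rules)
        assert len(ann) == 1 and ann.domains[0][4] == 80.0

    def test_three_disjoint_domains_all_kept(self, config, rules):
        hits = [make_hit(start=s, end=s + 140) for s in (1, 200, 400)]
        ann = ann_of(hits, config=config, rules=rules)
        assert count_domains(ann, "Sod_Cu", rules) == 3

    def test_subthreshold_hits_dropped(self, config, rules):
        hits = [make_hit(i_evalue=1e-20), make_hit(start=300, end=400, i_evalue=0.5)]
        ann = ann_of(hits, config=config, rules=rules)
        assert len(ann) == 1

    def test_envelope_beyond_length_raises(self, config, rules):
        with pytest.raises(ValueError, match="exceeds"):
            annotate([make_hit(start=10, end=160)], {"s1": 100}, config, rules)

    def test_idempotent(self, config, rules):
        hits = [
            make_hit(start=10, end=160, score=80.0),
            make_hit(start=100, end=260, score=75.0),
            make_hit(start=400, end=500, score=60.0),
        ]
        ann = ann_of(hits, config=config, rules=rules)
        again = [
            make_hit(start=s, end=e, score=sc)
            for _, _, s, e, sc in ann.domains
        ]
        assert ann_of(again, config=config, rules=rules).domains == ann.domains

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_maximal_selection(self, data):
        """Retained hits equal max-pick selection under the dominance order."""
        n = data.draw(st.integers(1, 6))
        hits = []
        for k in range(n):
            start = data.draw(st.integers(1, 300))
            end = start + data.draw(st.integers(0, 200))
            score = float(data.draw(st.integers(5, 99)))
            hits.append(make_hit(start=start, end=end, score=score, i_evalue=1e-9))
        cfg = PipelineConfig(overlap_tolerance=data.draw(st.integers(0, 30)))
        ann = ann_of(hits, config=cfg)
        expect = brute_select_hits(hits, cfg.overlap_tolerance)
        assert [(d[2], d[3], d[4]) for d in ann.domains] == [
            (h.env_start, h.env_end, h.score) for h in expect
        ]

    def test_lower_cutoff_never_adds_domains(self, rules):
        hits = [
            make_hit(start=1, end=100, i_evalue=1e-20),
            make_hit(start=200, end=300, i_evalue=1e-5),
            make_hit(start=400, end=500, i_evalue=1e-2),
        ]
        sizes = []
        for cut in (1e-1, 1e-4, 1e-10, 1e-30):
            cfg = PipelineConfig(i_evalue_max=cut)
            sizes.append(len(ann_of(hits, config=cfg, rules=rules)))
        assert sizes == sorted(sizes, reverse=True)


class TestCountDomains:
    def test_counts_and_additivity(self, rules):
        a = ann_of([make_hit(start=s, end=s + 100) for s in (1, 200, 400, 600)])
        assert count_domains(a, "Sod_Cu", rules) == 4
        empty = DomainAnnotation("e", 100, [])
        assert count_domains(empty, "Sod_Cu", rules) == 0
        merged = DomainAnnotation("m", 2000, a.domains + a.domains)
        assert count_domains(merged, "Sod_Cu", rules) == 8

    def test_unknown_class_raises(self, rules):
        with pytest.raises(KeyError, match="unknown domain class"):
            count_domains(DomainAnnotation("e", 10, []), "NoSuchClass", rules)


def _mn_like(rules):
    return ann_of(
        [
            make_hit(domain="Sod_Fe_N", accession="PF00081", start=1, end=90),
            make_hit(domain="Sod_Fe_C", accession="PF02777", start=120, end=220),
        ],
        rules=rules,
    )


class TestRules:
    def test_mnsod_conjunction(self, rules):
        ok, witness = match_rule(_mn_like(rules), "has(Sod_Fe_N) AND has(Sod_Fe_C)", rules)
        assert ok and witness == [0, 1]

    def test_count_boundary(self, rules):
        two = ann_of([make_hit(start=1, end=100), make_hit(start=200, end=300)])
        ok, _ = match_rule(two, "count(Sod_Cu) >= 3", rules)
        assert not ok
        ok, _ = match_rule(two, "count(Sod_Cu) >= 2", rules)
        assert ok

    def test_order_and_region(self, rules):
        ann = _mn_like(rules)
        assert match_rule(ann, "order(Sod_Fe_N before Sod_Fe_C)", rules)[0]
        assert not match_rule(ann, "order(Sod_Fe_C before Sod_Fe_N)", rules)[0]
        assert match_rule(ann, "region(Sod_Fe_N within [1, 100])", rules)[0]
        assert not match_rule(ann, "region(Sod_Fe_N within [2, 100])", rules)[0]

    def test_parse_error_carries_position(self):
        with pytest.raises(RuleParseError, match="position"):
            parse_rule("has(Sod_Cu) AND AND has(PAS)")
        with pytest.raises(RuleParseError):
            parse_rule("count(Sod_Cu) > ")

    @given(data=st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_random_expressions_match_bruteforce(self, rules, data):
        classes = ["Sod_Cu", "Sod_Fe_N", "Sod_Fe_C", "PAS", "EF_hand"]
        acc = {
            "Sod_Cu": "PF00080",
            "Sod_Fe_N": "PF00081",
            "Sod_Fe_C": "PF02777",
            "PAS": "PF00989",
            "EF_hand": "PF00036",
        }

        def expr(depth: int) -> str:
            kind = data.draw(
                st.sampled_from(
                    ["has", "count", "order", "region", "and", "or", "not"]
                    if depth > 0
                    else ["has", "count", "order", "region"]
                )
            )
            c = data.draw(st.sampled_from(classes))
            if kind == "has":
                return f"has({c})"
            if kind == "count":
                op = data.draw(st.sampled_from([">=", "<=", "=="]))
                return f"count({c}) {op} {data.draw(st.integers(0, 3))}"
            if kind == "order":
                return f"order({c} before {data.draw(st.sampled_from(classes))})"
            if kind == "region":
                a = data.draw(st.integers(1, 500))
                return f"region({c} within [{a}, {a + data.draw(st.integers(0, 500))}])"
            if kind == "not":
                return f"NOT ({expr(depth - 1)})"
            joiner = " AND " if kind == "and" else " OR "
            return "(" + joiner.join(expr(depth - 1) for _ in range(2)) + ")"

        n = data.draw(st.integers(0, 5))
        domains = []
        pos = 1
        for _ in range(n):
            c = data.draw(st.sampled_from(classes))
            width = data.draw(st.integers(20, 120))
            domains.append((c, acc[c], pos, pos + width, 50.0))
            pos += width + data.draw(st.integers(1, 60))
        ann = DomainAnnotation("s1", pos + 200, domains)
        text = expr(2)
        node = parse_rule(text)
        got, witness = match_rule(ann, node, rules)
        assert got == brute_rule_eval(node, ann, rules)
        if got and not isinstance(node, (type(None),)):
            # witnesses always point at real retained domains
            assert all(0 <= i < len(ann.domains) for i in witness)
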