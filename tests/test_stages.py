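"""SOD and NOX stage semantics: partitions, gates, subfamily decisions."""

import numpy as np
import pytest

from conftest import make_hit
from sodnox.architecture import annotate
from sodnox.config import PipelineConfig
from sodnox.features import FeatureProfile, build_profile
from sodnox.nox_stage import (
    classify_dspnox,
    classify_nox_subfamily,
    filter_nox_candidates,
    motif_gate,
)
from sodnox.seqio import FeatureOverrides
from sodnox.sod_stage import (
    assign_sod_subfamily,
    classify_rsod,
    filter_sod_candidates,
)
from sodnox.synthetic_data import generate_protein


def anns_from(hit_lists, config, rules, length=1200):
    hits = [h for hl in hit_lists for h in hl]
    lengths = {h.seq_id: length for h in hits}
    return annotate(hits, lengths, config, rules)


def profile_of(seq_id, **kw):
    defaults = dict(
        seq_id=seq_id,
        signal_peptide=False,
        sp_region=None,
        tm_segments=[],
        ef_hand_count=0,
        idp_intervals=[],
        localization=["Cytoplasm"],
    )
    defaults.update(kw)
    return FeatureProfile(**defaults)


def cu_hits(sid, n, score=100.0):
    return [
        make_hit(seq_id=sid, start=1 + 200 * i, end=150 + 200 * i, score=score)
        for i in range(n)
    ]


def mn_hits(sid, both=True):
    out = [make_hit(seq_id=sid, domain="Sod_Fe_C", accession="PF02777", start=200, end=300)]
    if both:
        out.append(
            make_hit(seq_id=sid, domain="Sod_Fe_N", accession="PF00081", start=1, end=90)
        )
    return out


def nox_core_hits(sid, fad=True, nad=True, ferric=True, offset=0):
    out = []
    if ferric:
        out.append(
            make_hit(seq_id=sid, domain="Ferric_reduct", accession="PF01794",
                     start=offset + 1, end=offset + 160)
        )
    if fad:
        out.append(
            make_hit(seq_id=sid, domain="FAD_binding_8", accession="PF08022",
                     start=offset + 200, end=offset + 320)
        )
    if nad:
        out.append(
            make_hit(seq_id=sid, domain="NAD_binding_6", accession="PF08030",
                     start=offset + 340, end=offset + 460)
        )
    return out


class TestSodPartition:
    def test_partition_rules(self, config, rules):
        anns = anns_from(
            [mn_hits("mn1"), mn_hits("half", both=False), cu_hits("cu1", 1)],
            config, rules,
        )
        part = filter_sod_candidates(anns, rules)
        assert part.mn == ["mn1"]
        assert part.cuzn == ["cu1"]
        assert part.rejected == ["half"]  # a single Mn/Fe terminal is not enough

    def test_dual_candidate_flagged_in_both_lists(self, config, rules):
        anns = anns_from([cu_hits("dual", 1) + [
            make_hit(seq_id="dual", domain="Sod_Fe_N", accession="PF00081", start=300, end=390),
            make_hit(seq_id="dual", domain="Sod_Fe_C", accession="PF02777", start=420, end=520),
        ]], config, rules)
        part = filter_sod_candidates(anns, rules)
        assert "dual" in part.cuzn and "dual" in part.mn and part.dual == ["dual"]

    def test_planted_cohort_partition_sizes(self, config, rules):
        anns = anns_from(
            [cu_hits(f"c{i}", 1) for i in range(4)]
            + [mn_hits(f"m{i}") for i in range(3)],
            config, rules,
        )
        part = filter_sod_candidates(anns, rules)
        assert (len(part.cuzn), len(part.mn)) == (4, 3)

    def test_every_sequence_reaches_one_state(self, config, rules):
        anns = anns_from(
            [cu_hits("a", 2), mn_hits("b"), [make_hit(seq_id="c", domain="PAS",
             accession="PF00989", start=1, end=100)]],
            config, rules,
        )
        part = filter_sod_candidates(anns, rules)
        assert len(part.cuzn) + len(part.mn) + len(part.rejected) >= len(anns)
        assert set(part.cuzn) | set(part.mn) | set(part.rejected) == set(anns)


class TestRsod:
    @pytest.mark.parametrize("n_cu,expect", [(2, False), (3, True), (6, True)])
    def test_threshold(self, n_cu, expect, config, rules):
        ann = anns_from([cu_hits("r", n_cu)], config, rules, length=2000)["r"]
        assert classify_rsod(ann, config, rules) is expect

    def test_monotone_adding_domains_never_revokes(self, config, rules):
        for n in range(3, 7):
            ann = anns_from([cu_hits("r", n)], config, rules, length=2000)["r"]
            assert classify_rsod(ann, config, rules)

    def test_two_domain_case_is_flagged_not_called(self, config, rules):
        ann = anns_from([cu_hits("r", 2)], config, rules)["r"]
        res = assign_sod_subfamily(
            ann, "CuZn", None, profile_of("r"), config, rules
        )
        assert res.subfamily != "Rsod"
        assert any(rid == "sod.rsod-possible" for rid, _ in res.evidence)


class TestSodAssignment:
    def test_extracellular_signature_fallback(self, config, rules, panels):
        from sodnox.phylo_place import PhyloPlacement

        ann = anns_from([cu_hits("q", 1)], config, rules)["q"]
        placement = PhyloPlacement(tree=None, assignments={"q": (None, 10)})
        prof = profile_of("q", signal_peptide=True, localization=["Extracellular"])
        res = assign_sod_subfamily(ann, "CuZn", placement, prof, config, rules)
        assert res.subfamily == "SOD3-like"

        prof2 = profile_of("q")  # no signal peptide, not extracellular
        res2 = assign_sod_subfamily(ann, "CuZn", placement, prof2, config, rules)
        assert res2.subfamily == "CuZnSOD-other"

    def test_mn_without_confident_clade(self, config, rules):
        from sodnox.phylo_place import PhyloPlacement

        ann = anns_from([mn_hits("q")], config, rules)["q"]
        placement = PhyloPlacement(tree=None, assignments={"q": (None, 40)})
        res = assign_sod_subfamily(ann, "Mn", placement, profile_of("q"), config, rules)
        assert res.subfamily == "MnSOD-other"

    def test_missing_placement_warns_unclassified(self, config, rules):
        ann = anns_from([mn_hits("q")], config, rules)["q"]
        with pytest.warns(UserWarning):
            res = assign_sod_subfamily(ann, "Mn", None, profile_of("q"), config, rules)
        assert res.subfamily == "unclassified"

    def test_retained_calls_always_carry_evidence(self, config, rules):
        ann = anns_from([cu_hits("q", 4)], config, rules, length=2000)["q"]
        res = assign_sod_subfamily(ann, "CuZn", None, profile_of("q"), config, rules)
        assert res.subfamily == "Rsod" and res.evidence


class TestNoxPartition:
    def test_core_architecture_rule(self, config, rules):
        anns = anns_from(
            [
                nox_core_hits("full"),
                nox_core_hits("fad_only", nad=False),
                nox_core_hits("noferric", ferric=False),
            ],
            config, rules,
        )
        part = filter_nox_candidates(anns, rules)
        assert sorted(part.candidates) == ["fad_only", "full"]
        assert part.rejected == ["noferric"]


class TestMotifGate:
    def test_partition_matches_planted_intactness(self, library, nox2_ref, motif_spec, config):
        rng = np.random.default_rng(21)
        records, truth_intact = [], {}
        for i in range(12):
            ablate = i < 2
            rec, truth = generate_protein(
                "NOX5", library, rng, f"n{i}",
                mutation_rate=0.05, indel_rate=0.01, ablate_motif=ablate,
            )
            records.append(rec)
            truth_intact[rec.id] = truth.motif_intact
        retained, removed, checks = motif_gate(records, motif_spec, nox2_ref, config)
        assert set(retained) == {s for s, ok in truth_intact.items() if ok}
        assert set(removed) == {s for s, ok in truth_intact.items() if not ok}
        assert len(retained) == 10 and len(removed) == 2


class TestDspNox:
    def _dsp_case(self, library, config, rules, label="DspNOX", mut=0.0):
        rng = np.random.default_rng(8)
        rec, truth = generate_protein(label, library, rng, "d1", mutation_rate=mut)
        hits = [
            make_hit(
                seq_id="d1",
                domain=cls,
                accession={
                    "Ferric_reduct": "PF01794", "FAD_binding_8": "PF08022",
                    "NAD_binding_6": "PF08030", "PAS": "PF00989",
                    "EF_hand": "PF13499", "An_peroxidase": "PF03098",
                    "Sod_Cu": "PF00080",
                }[cls],
                start=s, end=e,
            )
            for cls, s, e in truth.domains
        ]
        ann = annotate(hits, {"d1": len(rec)}, config, rules)["d1"]
        ov = FeatureOverrides()
        scores = np.full(len(rec), 0.05)
        for s, e in truth.idp_intervals:
            scores[s - 1 : e] = 0.9
        ov.disorder["d1"] = scores
        prof = build_profile(rec, ann, ov, config, rules)
        return ann, prof

    def test_full_architecture_is_dspnox(self, library, config, rules):
        ann, prof = self._dsp_case(library, config, rules)
        ok, evidence = classify_dspnox(ann, prof, config, rules)
        assert ok
        assert {rid for rid, _ in evidence} >= {
            "dspnox.cterm-core", "dspnox.pas-sensor", "dspnox.long-idp", "dspnox.extra-tm",
        }

    def test_canonical_nox5_is_not_dspnox(self, library, config, rules):
        ann, prof = self._dsp_case(library, config, rules, label="NOX5")
        assert classify_dspnox(ann, prof, config, rules)[0] is False

    def test_three_tm_variant_without_ef_hand_passes(self, library, config, rules):
        """The freshwater-sponge-style variant: 3 extra helices, no EF-hand."""
        ann, prof = self._dsp_case(library, config, rules)
        prof.tm_segments = prof.tm_segments[:3]
        prof.ef_hand_count = 0
        assert classify_dspnox(ann, prof, config, rules)[0] is True
        prof.tm_segments = prof.tm_segments[:2]
        assert classify_dspnox(ann, prof, config, rules)[0] is False

    def test_decision_order_dspnox_beats_nox5(self, library, config, rules):
        ann, prof = self._dsp_case(library, config, rules)
        res = classify_nox_subfamily(ann, prof, None, config, rules)
        assert res.subfamily == "DspNOX"

    def test_ef_and_peroxidase_rules(self, library, config, rules):
        rng = np.random.default_rng(10)
        for label, expect in (("Duox", "Duox"), ("NOX5", "NOX5")):
            rec, truth = generate_protein(label, library, rng, "x1")
            hits = [
                make_hit(seq_id="x1", domain=cls, accession={
                    "Ferric_reduct": "PF01794", "FAD_binding_8": "PF08022",
                    "NAD_binding_6": "PF08030", "EF_hand": "PF13499",
                    "An_peroxidase": "PF03098"}[cls], start=s, end=e)
                for cls, s, e in truth.domains
            ]
            ann = annotate(hits, {"x1": len(rec)}, config, rules)["x1"]
            prof = build_profile(rec, ann, FeatureOverrides(), config, rules)
            res = classify_nox_subfamily(ann, prof, None, config, rules)
            assert res.subfamily == expect
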