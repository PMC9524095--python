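"""NOX candidate filtering, the superoxide-motif gate, and subfamily calls.

Gate order is fixed: architecture -> motif -> subfamily. A candidate must
carry the ferric-reductase transmembrane domain plus at least one of the
FAD- or NAD-binding domains; survivors must map all four heme-ligand
histidines onto the NOX2 reference; retained sequences are then labelled in
decision order - the demosponge DspNOX composite rule first, then the
calcium-sensitive subfamilies by EF-hand/peroxidase content (Duox, NOX5),
then clade placement (NOX1-3 or NOX4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .architecture import DomainAnnotation, count_domains, match_rule
from .config import MotifSpec, PipelineConfig, RuleSet
from .features import FeatureProfile
from .motif_map import MotifCheck, check_hhhh
from .phylo_place import PhyloPlacement
from .seqio import SequenceRecord
from .sod_stage import ClassificationResult

__all__ = [
    "filter_nox_candidates",
    "motif_gate",
    "classify_dspnox",
    "classify_nox_subfamily",
    "RULE_NOX_CORE",
    "RULE_DSPNOX_PAS",
]

RULE_NOX_CORE = "has(Ferric_reduct) AND (has(FAD_binding_8) OR has(NAD_binding_6))"
RULE_DSPNOX_PAS = "has(PAS) OR has(PAS_9)"


@dataclass
class NoxPartition:
    candidates: List[str]
    rejected: List[str]
    evidence: Dict[str, List[Tuple[str, str]]]


def filter_nox_candidates(
    annotations: Dict[str, DomainAnnotation], rules: Optional[RuleSet] = None
) -> NoxPartition:
    """Retain sequences with the NOX core architecture.

    Core = ferric reductase plus at least one of the FAD- or NAD-binding
    domains; everything else is rejected with reason "architecture".
    """
    rules = rules or RuleSet()
    part = NoxPartition(candidates=[], rejected=[], evidence={})
    for sid in annotations:
        ok, witness = match_rule(annotations[sid], RULE_NOX_CORE, rules)
        if ok:
            part.candidates.append(sid)
            part.evidence[sid] = [("nox.core-architecture", str(witness))]
        else:
            part.rejected.append(sid)
            part.evidence[sid] = []
    return part


def motif_gate(
    candidates: List[SequenceRecord],
    spec: MotifSpec,
    reference: SequenceRecord,
    config: PipelineConfig,
) -> Tuple[List[str], List[str], Dict[str, MotifCheck]]:
    """Partition candidates by the four-histidine superoxide motif.

    Returns (retained ids, removed ids, per-sequence motif checks); a
    candidate is retained iff all four reference positions map to the
    required residue.
    """
    retained, removed, checks = [], [], {}
    for rec in candidates:
        chk = check_hhhh(
            rec,
            spec,
            reference,
            matrix=config.matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        checks[rec.id] = chk
        (retained if chk.full_motif else removed).append(rec.id)
    return retained, removed, checks


def classify_dspnox(
    ann: DomainAnnotation,
    profile: FeatureProfile,
    config: PipelineConfig,
    rules: Optional[RuleSet] = None,
) -> Tuple[bool, List[Tuple[str, str]]]:
    """Composite demosponge-NOX (DspNOX) architecture rule.

    All of: (1) the NOX core confined to the C-terminal part of the protein
    (core start beyond ``core_cterm_fraction`` of the length); (2) a PAS or
    PAS_9 domain N-terminal of the core; (3) at least one long disordered
    tract N-terminal of the core; (4) at least ``dspnox_min_extra_tm``
    transmembrane segments N-terminal of the core, beyond the core's own
    transmembrane region. DUF2427 / cytochrome-b561 hits over those
    segments are recorded as supporting evidence but are not required, and
    EF-hand content is not required (the freshwater variant lacks it).
    """
    rules = rules or RuleSet()
    evidence: List[Tuple[str, str]] = []
    core_classes = ("Ferric_reduct", "FAD_binding_8", "NAD_binding_6")
    core_starts = [
        s
        for (name, acc, s, e, sc) in ann.domains
        if rules.class_of(acc) in core_classes
    ]
    if not core_starts:
        return False, evidence
    core_start = min(core_starts)
    if core_start < config.core_cterm_fraction * ann.length:
        return False, evidence
    evidence.append(("dspnox.cterm-core", f"core_start={core_start}/{ann.length}"))

    ok_pas, w_pas = match_rule(ann, RULE_DSPNOX_PAS, rules)
    pas_before_core = ok_pas and all(
        ann.domains[i][2] < core_start for i in w_pas
    )
    if not pas_before_core:
        return False, evidence
    evidence.append(("dspnox.pas-sensor", str(w_pas)))

    idp_nterm = [iv for iv in profile.idp_intervals if iv[1] < core_start]
    if not idp_nterm:
        return False, evidence
    evidence.append(("dspnox.long-idp", str(idp_nterm[0])))

    extra_tm = [iv for iv in profile.tm_segments if iv[1] < core_start]
    if len(extra_tm) < config.dspnox_min_extra_tm:
        return False, evidence
    evidence.append(("dspnox.extra-tm", f"n={len(extra_tm)}"))

    support = [
        (name, s, e)
        for (name, acc, s, e, sc) in ann.domains
        if rules.class_of(acc) in ("DUF2427", "Cytochrome_b561") and e < core_start
    ]
    if support:
        evidence.append(("dspnox.tm-domain-support", str(support)))
    return True, evidence


def classify_nox_subfamily(
    ann: DomainAnnotation,
    profile: FeatureProfile,
    placement: Optional[PhyloPlacement],
    config: PipelineConfig,
    rules: Optional[RuleSet] = None,
    base_evidence: Optional[List[Tuple[str, str]]] = None,
) -> ClassificationResult:
    """Label one motif-verified NOX candidate.

    Decision order: DspNOX composite rule; EF-hand + peroxidase -> Duox;
    EF-hand alone -> NOX5; otherwise the clade label (NOX1-3 or NOX4);
    no confident clade -> unclassified. DspNOX calls are asserted disjoint
    from Duox (a peroxidase-bearing architecture is never DspNOX).
    """
    rules = rules or RuleSet()
    res = ClassificationResult(seq_id=ann.seq_id, family="NOX")
    res.evidence.extend(base_evidence or [])

    is_dsp, dsp_ev = classify_dspnox(ann, profile, config, rules)
    if is_dsp:
        if count_domains(ann, "An_peroxidase", rules) > 0:
            raise AssertionError(
                f"{ann.seq_id}: DspNOX call on a peroxidase-bearing architecture"
            )
        res.subfamily = "DspNOX"
        res.evidence.extend(dsp_ev)
        return res

    has_ef = profile.ef_hand_count >= 1
    has_perox = count_domains(ann, "An_peroxidase", rules) > 0
    if has_ef and has_perox:
        res.subfamily = "Duox"
        res.add_evidence("nox.ef-hand", f"n={profile.ef_hand_count}")
        res.add_evidence("nox.peroxidase", "present")
        return res
    if has_ef:
        res.subfamily = "NOX5"
        res.add_evidence("nox.ef-hand", f"n={profile.ef_hand_count}")
        return res

    if placement is not None:
        label = placement.label_of(ann.seq_id)
        support = placement.assignments.get(ann.seq_id, (None, 0))[1]
        if label in ("NOX1-3", "NOX4"):
            res.subfamily = label
            res.add_evidence("nox.clade", f"{label}@{support}")
            return res
        res.add_evidence("nox.no-confident-clade", f"support={support}")
    res.subfamily = "unclassified"
    return res
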