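"""End-to-end orchestration: annotate -> SOD stage -> NOX stage -> features
-> placement -> reports.

Every input sequence reaches exactly one terminal state: retained with a
subfamily (classification table) or removed with a reason (removal log).
All randomness derives from one seed; rerunning with an identical config
and seed is byte-identical (the manifest carries a config hash, never a
timestamp).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .architecture import DomainAnnotation, annotate, count_domains
from .config import MotifSpec, PipelineConfig, RuleSet
from .features import FeatureProfile, build_profile
from .motif_map import MotifCheck
from .nox_stage import (
    classify_nox_subfamily,
    filter_nox_candidates,
    motif_gate,
)
from .phylo_place import PhyloPlacement, place_queries
from .references import nox2_reference, reference_panels
from .report import count_table, localization_matrix, presence_matrix
from .seqio import (
    FeatureOverrides,
    SequenceRecord,
    join_species,
    read_domtbl,
    read_fasta,
    read_feature_tables,
    read_species_map,
    write_newick,
)
from .sod_stage import (
    ClassificationResult,
    assign_sod_subfamily,
    classify_rsod,
    filter_sod_candidates,
)

__all__ = ["RunInputs", "PipelineResult", "run_pipeline"]

_NOX_ASSOC = ("Ferric_reduct", "FAD_binding_8", "NAD_binding_6")


@dataclass
class RunInputs:
    fasta: Path
    domtbl: Path
    species_map: Path
    localization: Optional[Path] = None
    signal: Optional[Path] = None
    disorder: Optional[Path] = None

    def validate(self) -> None:
        for name in ("fasta", "domtbl", "species_map"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input missing: {p}")
        for name in ("localization", "signal", "disorder"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input missing: {p}")


@dataclass
class PipelineResult:
    results: Dict[str, ClassificationResult]
    profiles: Dict[str, FeatureProfile]
    annotations: Dict[str, DomainAnnotation]
    motif_checks: Dict[str, MotifCheck]
    placements: Dict[str, PhyloPlacement]
    records: Dict[str, SequenceRecord]
    species_order: List[Tuple[str, str]]
    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    paths: Dict[str, Path] = field(default_factory=dict)

    @property
    def retained(self) -> Dict[str, ClassificationResult]:
        return {k: v for k, v in self.results.items() if v.retained}

    @property
    def removed(self) -> Dict[str, ClassificationResult]:
        return {k: v for k, v in self.results.items() if not v.retained}


def _placement_seeds(seed: int) -> Tuple[int, int, int]:
    ss = np.random.SeedSequence(seed)
    return tuple(int(c.generate_state(1)[0]) for c in ss.spawn(3))


def classify_cohort(
    records: List[SequenceRecord],
    annotations: Dict[str, DomainAnnotation],
    overrides: FeatureOverrides,
    config: PipelineConfig,
    rules: RuleSet,
    motif: MotifSpec,
    panels=None,
    reference: Optional[SequenceRecord] = None,
) -> PipelineResult:
    """Run every analysis stage in memory (no file IO)."""
    panels = panels or reference_panels()
    reference = reference or nox2_reference()
    by_id = {r.id: r for r in records}
    results: Dict[str, ClassificationResult] = {}
    profiles: Dict[str, FeatureProfile] = {}

    sod = filter_sod_candidates(annotations, rules)
    nox = filter_nox_candidates(annotations, rules)
    nox_candidates = [s for s in nox.candidates if s not in set(sod.cuzn) | set(sod.mn)]

    # metalloform resolution (dual candidates go to the stronger signal)
    metalloform: Dict[str, str] = {}
    for sid in sod.cuzn:
        metalloform[sid] = "CuZn"
    for sid in sod.mn:
        metalloform[sid] = "Mn"
    for sid in sod.dual:
        ann = annotations[sid]
        cu = sum(d[4] for d in ann.domains if rules.class_of(d[1]) == "Sod_Cu")
        fe = sum(
            d[4]
            for d in ann.domains
            if rules.class_of(d[1]) in ("Sod_Fe_N", "Sod_Fe_C")
        )
        metalloform[sid] = "CuZn" if cu >= fe else "Mn"

    # removals: neither family's architecture
    for rec in records:
        sid = rec.id
        if sid in metalloform or sid in nox_candidates:
            continue
        ann = annotations[sid]
        has_nox_assoc = any(
            count_domains(ann, cls, rules) > 0 for cls in _NOX_ASSOC
        )
        reason = "architecture" if has_nox_assoc else "no-domain"
        results[sid] = ClassificationResult(
            seq_id=sid, family="none", subfamily="removed", removal_reason=reason
        )

    # motif gate on NOX candidates
    retained_nox, removed_nox, checks = motif_gate(
        [by_id[s] for s in nox_candidates], motif, reference, config
    )
    for sid in removed_nox:
        res = ClassificationResult(
            seq_id=sid, family="NOX", subfamily="removed", removal_reason="motif"
        )
        res.evidence.extend(nox.evidence.get(sid, []))
        failed = [str(p) for p, _, r, ok in checks[sid].records if not ok]
        res.add_evidence("nox.motif-failed", ",".join(failed))
        results[sid] = res

    # feature profiles for everything that survives architecture gates
    for sid in list(metalloform) + retained_nox:
        profiles[sid] = build_profile(
            by_id[sid], annotations[sid], overrides, config, rules
        )

    # architecture-decided NOX calls happen before placement
    nox_arch_results: Dict[str, ClassificationResult] = {}
    nox_to_place: List[str] = []
    for sid in retained_nox:
        res = classify_nox_subfamily(
            annotations[sid],
            profiles[sid],
            placement=None,
            config=config,
            rules=rules,
            base_evidence=nox.evidence.get(sid, []),
        )
        if res.subfamily == "unclassified":
            nox_to_place.append(sid)
        else:
            nox_arch_results[sid] = res

    cuzn_to_place = [
        sid
        for sid in sod.cuzn
        if metalloform[sid] == "CuZn" and not classify_rsod(annotations[sid], config, rules)
    ]
    mn_to_place = [sid for sid in sod.mn if metalloform[sid] == "Mn"]

    s1, s2, s3 = _placement_seeds(config.rng_seed)
    placements = {
        "sod_cuzn": place_queries(
            [by_id[s] for s in cuzn_to_place], panels["sod_cuzn"], config, s1
        ),
        "sod_mn": place_queries(
            [by_id[s] for s in mn_to_place], panels["sod_mn"], config, s2
        ),
        "nox": place_queries(
            [by_id[s] for s in nox_to_place], panels["nox"], config, s3
        ),
    }

    for sid in sorted(metalloform):
        mf = metalloform[sid]
        placement = placements["sod_cuzn"] if mf == "CuZn" else placements["sod_mn"]
        results[sid] = assign_sod_subfamily(
            annotations[sid],
            mf,
            placement,
            profiles[sid],
            config,
            rules,
            base_evidence=sod.evidence.get(sid, []),
        )
    for sid, res in nox_arch_results.items():
        results[sid] = res
    for sid in nox_to_place:
        results[sid] = classify_nox_subfamily(
            annotations[sid],
            profiles[sid],
            placements["nox"],
            config,
            rules,
            base_evidence=nox.evidence.get(sid, []),
        )

    assert set(results) == {r.id for r in records}, "conservation check failed"

    species_order: List[Tuple[str, str]] = []
    for rec in records:
        key = (rec.species, rec.phylum)
        if key not in species_order:
            species_order.append(key)

    return PipelineResult(
        results=results,
        profiles=profiles,
        annotations=annotations,
        motif_checks=checks,
        placements=placements,
        records=by_id,
        species_order=species_order,
    )


def _config_hash(config: PipelineConfig, motif: MotifSpec, rules: RuleSet) -> str:
    blob = json.dumps(
        {
            "pipeline": config.to_dict(),
            "motif": {
                "reference_id": motif.reference_id,
                "positions": list(motif.positions),
                "required_residue": motif.required_residue,
            },
            "classes": {k: list(v) for k, v in sorted(rules.classes.items())},
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def _evidence_str(res: ClassificationResult) -> str:
    return ";".join(f"{rid}={w}" for rid, w in res.evidence)


def run_pipeline(
    inputs: RunInputs,
    outdir,
    config: Optional[PipelineConfig] = None,
    rules: Optional[RuleSet] = None,
    motif: Optional[MotifSpec] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run all stages from files and write every output artefact.

    Outputs under ``outdir``: annotations.tsv, classification.tsv,
    removal_log.tsv, sod_counts.tsv, nox_counts.tsv, presence_matrix.tsv,
    localization_matrix.tsv, trees/<group>.nwk, manifest.json.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = config.with_(rng_seed=seed)
    rules = rules or RuleSet()
    motif = motif or MotifSpec()
    inputs.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "trees").mkdir(exist_ok=True)

    records = read_fasta(inputs.fasta)
    join_species(records, read_species_map(inputs.species_map))
    lengths = {r.id: len(r) for r in records}
    hits = read_domtbl(inputs.domtbl)
    annotations = annotate(hits, lengths, config, rules)
    overrides = read_feature_tables(
        inputs.localization, inputs.signal, inputs.disorder, known_ids=set(lengths)
    )

    result = classify_cohort(
        records, annotations, overrides, config, rules, motif
    )

    # ---- stage artefacts
    ann_rows = [
        {
            "seq_id": sid,
            "length": ann.length,
            "domains": ";".join(
                f"{name}:{acc}:{s}-{e}:{sc:.1f}" for name, acc, s, e, sc in ann.domains
            ),
        }
        for sid, ann in sorted(result.annotations.items())
    ]
    pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    cls_rows, removal_rows = [], []
    for rec in records:
        res = result.results[rec.id]
        if res.retained:
            cls_rows.append(
                {
                    "seq_id": rec.id,
                    "species": rec.species,
                    "phylum": rec.phylum,
                    "family": res.family,
                    "metalloform": res.metalloform,
                    "subfamily": res.subfamily,
                    "evidence": _evidence_str(res),
                }
            )
        else:
            removal_rows.append(
                {
                    "seq_id": rec.id,
                    "species": rec.species,
                    "reason": res.removal_reason,
                    "evidence": _evidence_str(res),
                }
            )
    pd.DataFrame(cls_rows).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    pd.DataFrame(removal_rows).to_csv(outdir / "removal_log.tsv", sep="\t", index=False)

    result.tables["sod_counts"] = count_table(
        result.results, result.records, result.species_order, "SOD"
    )
    result.tables["nox_counts"] = count_table(
        result.results, result.records, result.species_order, "NOX"
    )
    result.tables["presence"] = presence_matrix(result.results, result.records)
    result.tables["localization"] = localization_matrix(
        result.results, result.records, result.profiles, result.species_order, "SOD"
    )
    result.tables["sod_counts"].to_csv(outdir / "sod_counts.tsv", sep="\t", index=False)
    result.tables["nox_counts"].to_csv(outdir / "nox_counts.tsv", sep="\t", index=False)
    result.tables["presence"].to_csv(
        outdir / "presence_matrix.tsv", sep="\t", index=False
    )
    result.tables["localization"].to_csv(
        outdir / "localization_matrix.tsv", sep="\t", index=False
    )

    for group, placement in result.placements.items():
        if placement.tree is not None:
            tree = placement.tree.copy()
            leafset_all = frozenset(t.name for t in tree.tips())
            anchor = min(leafset_all)
            for node in tree.non_tips(include_self=False):
                ls = frozenset(t.name for t in node.tips())
                key = ls if anchor not in ls else leafset_all - ls
                sup = placement.supports.get(key)
                node.name = str(sup) if sup is not None else None
            (outdir / "trees" / f"{group}.nwk").write_text(write_newick(tree) + "\n")

    manifest = {
        "config_hash": _config_hash(config, motif, rules),
        "seed": config.rng_seed,
        "version": __version__,
        "n_sequences": len(records),
        "n_retained": len(result.retained),
        "n_removed": len(result.removed),
        "removal_reasons": {
            str(k): int(v)
            for k, v in pd.Series(
                [r.removal_reason for r in result.removed.values()]
            )
            .value_counts()
            .sort_index()
            .items()
        }
        if result.removed
        else {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    result.paths = {
        "annotations": outdir / "annotations.tsv",
        "classification": outdir / "classification.tsv",
        "removal_log": outdir / "removal_log.tsv",
        "sod_counts": outdir / "sod_counts.tsv",
        "nox_counts": outdir / "nox_counts.tsv",
        "presence": outdir / "presence_matrix.tsv",
        "localization": outdir / "localization_matrix.tsv",
        "manifest": outdir / "manifest.json",
    }
    return result
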