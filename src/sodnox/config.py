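"""Pipeline configuration, domain-class vocabulary and motif specification.

All thresholds that drive filtering decisions live in :class:`PipelineConfig`
so that a run is fully described by one declarative object (serialisable to
YAML). Coordinates are 1-based inclusive everywhere at the interface level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, Tuple

import yaml

__all__ = ["PipelineConfig", "RuleSet", "MotifSpec", "load_config_yaml"]

#: The nine subcellular compartments used for localization calls.
COMPARTMENTS = (
    "Cytoplasm",
    "Nucleus",
    "Extracellular",
    "Cell membrane",
    "Mitochondrion",
    "Endoplasmic reticulum",
    "Lysosome/Vacuole",
    "Golgi",
    "Peroxisome",
)


@dataclass
class PipelineConfig:
    """Tunable thresholds for every pipeline stage.

    Defaults: the independent e-value cutoff (1e-3) and the 10-residue
    envelope-overlap tolerance follow common Pfam practice; the Rsod
    multi-domain criterion (>=3 Cu/Zn domains), the long-disorder rule
    (>=30 consecutive residues at score >=0.5), the >50%-gap column trim
    and the 1000-replicate bootstrap are the published survey settings.
    """

    i_evalue_max: float = 1e-3
    overlap_tolerance: int = 10
    rsod_min_cu_domains: int = 3
    idp_min_run: int = 30
    disorder_score_min: float = 0.5
    trim_max_gap_fraction: float = 0.5
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    # pairwise / profile alignment scoring
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    # clade-placement confidence
    min_support: int = 70
    distance_model: str = "poisson"  # or "p"
    # novelty guard: a clade label is kept only if the query is closer to
    # that label's exemplars than to any other label's by a clear margin
    # (nearest-assigned / nearest-other distance ratio below this bound);
    # queries roughly equidistant from every subfamily stay unclassified
    placement_margin_ratio: float = 0.7

    # signal-peptide heuristic (stand-in for a neural predictor)
    sp_search_len: int = 30
    sp_window: int = 8
    sp_hydropathy_min: float = 2.0

    # transmembrane heuristic
    tm_window: int = 17
    tm_hydropathy_min: float = 1.6
    tm_merge_gap: int = 5

    # DspNOX composite rule
    dspnox_min_extra_tm: int = 3
    core_cterm_fraction: float = 0.5

    # localization thresholds (single default applied to all nine classes)
    localization_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.trim_max_gap_fraction < 1.0):
            raise ValueError("trim_max_gap_fraction must lie in (0, 1)")
        for name in (
            "i_evalue_max",
            "rsod_min_cu_domains",
            "idp_min_run",
            "disorder_score_min",
            "bootstrap_reps",
            "sp_window",
            "tm_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.overlap_tolerance < 0:
            raise ValueError("overlap_tolerance must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


#: Default Pfam-style accession vocabulary, one class per accession.
DEFAULT_CLASSES: Dict[str, Tuple[str, ...]] = {
    "Sod_Cu": ("PF00080",),
    "Sod_Fe_C": ("PF02777",),
    "Sod_Fe_N": ("PF00081",),
    "Ferric_reduct": ("PF01794",),
    "FAD_binding_8": ("PF08022",),
    "NAD_binding_6": ("PF08030",),
    "An_peroxidase": ("PF03098",),
    "PAS": ("PF00989",),
    "PAS_9": ("PF13426",),
    "DUF2427": ("PF10348",),
    "Cytochrome_b561": ("PF03188",),
    # The published scan did not name the EF-hand model it matched; this
    # accession list is configurable (common Pfam EF-hand families).
    "EF_hand": ("PF13499", "PF00036", "PF13833"),
}


@dataclass
class RuleSet:
    """Vocabulary of named domain classes, each a list of accessions.

    Every accession may appear in exactly one class; rule expressions and
    all family filters refer to class names, never raw accessions.
    """

    classes: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_CLASSES.items()}
    )

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for cls, accs in self.classes.items():
            for acc in accs:
                if acc in seen:
                    raise ValueError(
                        f"accession {acc} appears in both {seen[acc]} and {cls}"
                    )
                seen[acc] = cls
        self._acc_to_class = seen

    def class_of(self, accession: str) -> str | None:
        """Class name for a (version-stripped) accession, or None."""
        return self._acc_to_class.get(accession.split(".")[0])

    def accessions(self, cls: str) -> Tuple[str, ...]:
        try:
            return self.classes[cls]
        except KeyError:
            raise KeyError(f"unknown domain class: {cls!r}") from None

    def __contains__(self, cls: str) -> bool:
        return cls in self.classes


@dataclass
class MotifSpec:
    """The four-histidine superoxide motif in NOX2 reference numbering.

    The four histidines (positions 101, 115, 209 and 222 on the NOX2
    reference) ligate the two heme groups of the ferric-reductase
    transmembrane core and are required for superoxide generation; a
    candidate lacking any of the four mapped residues fails the motif gate.
    """

    reference_id: str = "NOX2_reference_synthetic"
    positions: Tuple[int, ...] = (101, 115, 209, 222)
    required_residue: str = "H"

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("motif positions must be strictly increasing")
        if len(self.required_residue) != 1:
            raise ValueError("required_residue must be a single letter")


def load_config_yaml(path) -> tuple[PipelineConfig, RuleSet, MotifSpec, dict]:
    """Load a declarative run config.

    Returns (pipeline config, rule set, motif spec, remaining keys).
    Unknown top-level keys (input paths etc.) are returned verbatim in the
    fourth element for the orchestrator to interpret.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw.pop("pipeline", {}))
    classes = raw.pop("classes", None)
    rules = RuleSet({k: tuple(v) for k, v in classes.items()}) if classes else RuleSet()
    mraw = raw.pop("motif", {})
    if "positions" in mraw:
        mraw["positions"] = tuple(mraw["positions"])
    motif = MotifSpec(**mraw)
    return cfg, rules, motif, raw
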