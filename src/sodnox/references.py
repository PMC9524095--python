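"""Packaged reference material: subfamily exemplar panels and the motif
reference.

The exemplars are synthetic consensus-like sequences generated from the
canonical template library (never database extracts): for each subfamily,
a handful of lightly diverged copies (2% substitutions) of the subfamily
template. They play the role real curated exemplars play in the survey -
labelled anchors that candidate sequences are placed against.

The motif reference is likewise a SYNTHETIC stand-in for the human NOX2
protein: it is constructed so the four heme-ligand histidines sit at
exactly 101, 115, 209 and 222 in its own numbering, which is the published
NOX2 coordinate convention for the superoxide motif.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from .seqio import SequenceRecord
from .synthetic_data import (
    DEFAULT_LIBRARY_SEED,
    generate_protein,
    make_domain_library,
)

__all__ = ["nox2_reference", "reference_panels", "REFERENCE_SEED"]

#: Internal seed for reference-panel divergence; independent of cohort seeds.
REFERENCE_SEED = 1729

_PANEL_LABELS = {
    "sod_cuzn": ("SOD1", "Rsod"),
    "sod_mn": ("SOD2", "SOD2X"),
    "nox": ("NOX1-3", "NOX4", "NOX5", "Duox"),
}
_EXEMPLARS_PER_LABEL = 4


def nox2_reference(library_seed: int = DEFAULT_LIBRARY_SEED) -> SequenceRecord:
    """Synthetic NOX2-like motif reference (id ``NOX2_reference_synthetic``).

    71-residue prefix + ferric-reductase transmembrane block (with the four
    histidines at reference positions 101/115/209/222) + FAD- and
    NAD-binding blocks. Deterministic.
    """
    lib = make_domain_library(library_seed)
    residues = (
        lib["ref_prefix"]
        + lib["Ferric_reduct"]
        + lib["FAD_binding_8"]
        + lib["NAD_binding_6"]
    )
    rec = SequenceRecord(id="NOX2_reference_synthetic", residues=residues)
    for pos in (101, 115, 209, 222):
        assert rec.residues[pos - 1] == "H"
    return rec


def reference_panels(
    library_seed: int = DEFAULT_LIBRARY_SEED,
    n_per_label: int = _EXEMPLARS_PER_LABEL,
) -> Dict[str, List[Tuple[SequenceRecord, str]]]:
    """Labelled exemplar panels for the three placement groups.

    Returns ``{"sod_cuzn": [...], "sod_mn": [...], "nox": [...]}`` where each
    entry is a list of (record, subfamily label). Exemplars diverge 2% from
    the subfamily template; deterministic.
    """
    library = make_domain_library(library_seed)
    rng = np.random.default_rng(REFERENCE_SEED)
    panels: Dict[str, List[Tuple[SequenceRecord, str]]] = {}
    for panel, labels in _PANEL_LABELS.items():
        entries: List[Tuple[SequenceRecord, str]] = []
        for label in labels:
            for k in range(n_per_label):
                sid = f"REF_{label.replace('-', '')}_{k + 1}"
                rec, _ = generate_protein(
                    label,
                    library,
                    rng,
                    seq_id=sid,
                    species="reference",
                    phylum="reference",
                    mutation_rate=0.02,
                    indel_rate=0.0,
                )
                entries.append((rec, label))
        panels[panel] = entries
    return panels
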