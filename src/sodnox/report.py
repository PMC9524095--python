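"""Survey-style result tables: per-species counts, phylum presence, and
species-by-compartment localization.

Exact duplicate protein sequences are counted once in the main counts and
reported in a separate duplicates column. Row order follows the species
map; all sorts are stable so re-running a report on identical results is
byte-identical.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple
import warnings

import pandas as pd

from .config import COMPARTMENTS
from .features import FeatureProfile
from .seqio import SequenceRecord
from .sod_stage import ClassificationResult

__all__ = ["count_table", "presence_matrix", "localization_matrix"]

SOD_COLUMNS = ("CuZnSOD", "MnSOD")
NOX_COLUMNS = ("NOX1-3", "NOX4", "NOX5", "DspNOX", "Duox", "unclassified")

_CUZN = ("SOD1", "Rsod", "SOD3-like", "CuZnSOD-other")
_MN = ("SOD2", "SOD2X", "MnSOD-other")


def _dedup(
    results: Dict[str, ClassificationResult],
    records: Dict[str, SequenceRecord],
) -> Tuple[Dict[str, ClassificationResult], Dict[str, int]]:
    """Keep one representative per exact residue string (per species).

    Returns (representative results, per-representative duplicate count).
    Representatives are the first occurrence in input order.
    """
    reps: Dict[str, ClassificationResult] = {}
    dup_count: Dict[str, int] = {}
    seen: Dict[Tuple[str, str], str] = {}
    for sid, res in results.items():
        rec = records[sid]
        key = (rec.species, rec.residues)
        if key in seen:
            dup_count[seen[key]] += 1
        else:
            seen[key] = sid
            reps[sid] = res
            dup_count[sid] = 0
    return reps, dup_count


def count_table(
    results: Dict[str, ClassificationResult],
    records: Dict[str, SequenceRecord],
    species_order: Sequence[Tuple[str, str]],  # (species, phylum) in map order
    family: str,
) -> pd.DataFrame:
    """Per-species count table for one family ("SOD" or "NOX").

    SOD: CuZnSOD / MnSOD / duplicates / Total. NOX: one column per
    subfamily (+ unclassified) / duplicates / Total. Total = sum of the
    main columns (duplicates excluded, as in the published tables where
    exact variants are superscripts).
    """
    if family not in ("SOD", "NOX"):
        raise ValueError(f"family must be SOD or NOX, got {family!r}")
    reps, dup_count = _dedup(
        {sid: r for sid, r in results.items() if r.retained and r.family == family},
        records,
    )
    rows = []
    for species, phylum in species_order:
        sub = [sid for sid, r in reps.items() if records[sid].species == species]
        if not sub:
            warnings.warn(f"species {species!r} has zero retained {family} sequences")
        row: Dict[str, object] = {"Species": species, "Phylum": phylum}
        if family == "SOD":
            row["CuZnSOD"] = sum(1 for sid in sub if reps[sid].subfamily in _CUZN)
            row["MnSOD"] = sum(1 for sid in sub if reps[sid].subfamily in _MN)
            main = ["CuZnSOD", "MnSOD"]
        else:
            for col in NOX_COLUMNS:
                row[col] = sum(1 for sid in sub if reps[sid].subfamily == col)
            main = list(NOX_COLUMNS)
        row["duplicates"] = sum(dup_count[sid] for sid in sub)
        row["Total"] = sum(int(row[c]) for c in main)
        rows.append(row)
    df = pd.DataFrame(rows)
    for _, row in df.iterrows():  # per-row conservation assertion
        main_cols = SOD_COLUMNS if family == "SOD" else NOX_COLUMNS
        assert row["Total"] == sum(int(row[c]) for c in main_cols)
    return df


def presence_matrix(
    results: Dict[str, ClassificationResult],
    records: Dict[str, SequenceRecord],
) -> pd.DataFrame:
    """Phylum x subfamily presence (1/0), aggregated as any-species-present."""
    retained = [r for r in results.values() if r.retained]
    subfamilies = sorted({r.subfamily for r in retained})
    phyla: List[str] = []
    for r in retained:
        ph = records[r.seq_id].phylum
        if ph not in phyla:
            phyla.append(ph)
    data = []
    for ph in phyla:
        row = {"Phylum": ph}
        for sub in subfamilies:
            row[sub] = int(
                any(
                    r.subfamily == sub and records[r.seq_id].phylum == ph
                    for r in retained
                )
            )
        data.append(row)
    return pd.DataFrame(data, columns=["Phylum", *subfamilies])


def localization_matrix(
    results: Dict[str, ClassificationResult],
    records: Dict[str, SequenceRecord],
    profiles: Dict[str, FeatureProfile],
    species_order: Sequence[Tuple[str, str]],
    family: str = "SOD",
) -> pd.DataFrame:
    """Species x compartment table; cells list the subfamilies present.

    A protein predicted in several compartments appears in each of them.
    Subfamily labels within a cell are sorted and unique.
    """
    rows = []
    for species, _ in species_order:
        cell: Dict[str, set] = {c: set() for c in COMPARTMENTS}
        for sid, r in results.items():
            if not r.retained or r.family != family:
                continue
            if records[sid].species != species or sid not in profiles:
                continue
            for comp in profiles[sid].localization:
                if comp in cell:
                    cell[comp].add(r.subfamily)
        rows.append(
            {
                "Species": species,
                **{c: ";".join(sorted(cell[c])) for c in COMPARTMENTS},
            }
        )
    return pd.DataFrame(rows, columns=["Species", *COMPARTMENTS])
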