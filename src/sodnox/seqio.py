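"""Readers and writers for the external formats the pipeline touches.

FASTA (protein), HMMER3 per-domain tabular output (domtblout), Newick,
a 3-column species map TSV, and the three optional external feature
tables (DeepLoc-2.0-style localization CSV, TargetP-2.0-style signal
peptide TSV, IUPred3-style per-residue disorder TSV).

Conventions: a sequence id is the first whitespace-delimited FASTA header
token (HMMER convention), so FASTA and domtblout join cleanly; all residue
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
import skbio

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "FeatureOverrides",
    "read_fasta",
    "write_fasta",
    "read_domtbl",
    "write_domtbl",
    "read_species_map",
    "write_species_map",
    "join_species",
    "read_feature_tables",
    "read_newick",
    "write_newick",
]


@dataclass
class SequenceRecord:
    """One protein sequence with optional species metadata."""

    id: str
    residues: str
    species: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id}: residues must be non-empty")
        self.residues = self.residues.upper()

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One envelope of one domain model on one protein (domtblout row)."""

    seq_id: str
    domain: str
    accession: str
    env_start: int  # 1-based inclusive
    env_end: int  # 1-based inclusive
    score: float
    i_evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.seq_id}/{self.domain}: bad envelope "
                f"{self.env_start}..{self.env_end}"
            )
        if not np.isfinite(self.score):
            raise ValueError(f"{self.seq_id}/{self.domain}: score must be finite")
        if self.i_evalue < 0:
            raise ValueError(f"{self.seq_id}/{self.domain}: i_evalue must be >= 0")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> List[SequenceRecord]:
    """Read protein FASTA; id = first whitespace-delimited header token."""
    records: List[SequenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in FASTA: {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# HMMER3 domtblout

# hmmscan per-domain table: 22 fixed whitespace-delimited columns followed by
# a free-text description. Envelope coordinates are columns 20/21 (1-based).
_DOMTBL_MIN_COLS = 22


def read_domtbl(path) -> List[DomainHit]:
    """Parse a HMMER3 per-domain table; '#' lines are comments.

    All hits are returned unfiltered; thresholding is the annotator's job.
    """
    hits: List[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    DomainHit(
                        seq_id=cols[3],
                        domain=cols[0],
                        accession=cols[1].split(".")[0],
                        env_start=int(cols[19]),
                        env_end=int(cols[20]),
                        score=float(cols[13]),
                        i_evalue=float(cols[12]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
    return hits


def write_domtbl(hits: Iterable[DomainHit], path, seq_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write hits in hmmscan domtblout layout (inverse of :func:`read_domtbl`)."""
    seq_lengths = seq_lengths or {}
    lines = [
        "# target name        accession   tlen query name           accession   qlen"
        "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
        "  from    to  from    to  acc description of target",
        "#" + "-" * 30,
    ]
    for h in hits:
        qlen = seq_lengths.get(h.seq_id, h.env_end)
        tlen = h.env_end - h.env_start + 1
        lines.append(
            f"{h.domain:<20s} {h.accession:<11s} {tlen:5d} {h.seq_id:<20s} "
            f"{'-':<11s} {qlen:5d} {h.i_evalue:9.2g} {h.score:6.1f}   0.0   1   1 "
            f"{h.i_evalue:9.2g} {h.i_evalue:9.2g} {h.score:6.1f}   0.0 "
            f"{h.env_start:5d} {h.env_end:5d} {h.env_start:5d} {h.env_end:5d} "
            f"{h.env_start:5d} {h.env_end:5d} 0.99 -"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Species map (3-column TSV: id-or-prefix, species, phylum)


def read_species_map(path) -> List[tuple]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: species map needs 3 tab-separated columns"
                )
            rows.append(tuple(parts))
    return rows


def write_species_map(rows: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for key, species, phylum in rows:
            fh.write(f"{key}\t{species}\t{phylum}\n")


def join_species(records: Sequence[SequenceRecord], rows: Sequence[tuple]) -> None:
    """Attach species/phylum to records in place.

    A map key matches a record either exactly or as a prefix of its id;
    exact matches win, then the longest matching prefix.
    """
    exact = {k: (s, p) for k, s, p in rows}
    prefixes = sorted(rows, key=lambda r: -len(r[0]))
    for rec in records:
        if rec.id in exact:
            rec.species, rec.phylum = exact[rec.id]
            continue
        for key, species, phylum in prefixes:
            if rec.id.startswith(key):
                rec.species, rec.phylum = species, phylum
                break
        else:
            warnings.warn(f"no species-map entry matches sequence {rec.id}")
            rec.species, rec.phylum = "unknown", "unknown"


# ---------------------------------------------------------------------------
# External feature tables


@dataclass
class FeatureOverrides:
    """Per-sequence external predictions, preferred over built-in heuristics."""

    localization: Dict[str, Dict[str, float]] = field(default_factory=dict)
    signal_peptide: Dict[str, bool] = field(default_factory=dict)
    disorder: Dict[str, np.ndarray] = field(default_factory=dict)

    def __bool__(self) -> bool:
        return bool(self.localization or self.signal_peptide or self.disorder)


def read_feature_tables(
    loc_path=None,
    sp_path=None,
    idp_path=None,
    known_ids: Optional[set] = None,
) -> FeatureOverrides:
    """Read optional external feature tables keyed by sequence id.

    Layouts (documented in the README):

    * localization: CSV with a ``Protein_ID`` column plus one probability
      column per compartment (DeepLoc-2.0 layout);
    * signal peptide: TSV with columns ``ID``, ``Prediction`` (``SP`` or
      ``noTP``) and ``SP`` probability (TargetP-2.0 layout);
    * disorder: TSV with columns ``seq_id``, ``pos``, ``residue``,
      ``score`` (IUPred3 long layout, one row per residue).

    Rows whose seq_id is absent from ``known_ids`` (when given) are ignored
    with a warning. Missing files yield empty overrides.
    """
    ov = FeatureOverrides()

    def _known(sid: str, source: str) -> bool:
        if known_ids is not None and sid not in known_ids:
            warnings.warn(f"{source}: unknown sequence id {sid!r}, row ignored")
            return False
        return True

    if loc_path is not None:
        df = pd.read_csv(loc_path)
        prob_cols = [c for c in df.columns if c not in ("Protein_ID", "Localizations")]
        for _, row in df.iterrows():
            sid = str(row["Protein_ID"])
            if _known(sid, "localization table"):
                ov.localization[sid] = {c: float(row[c]) for c in prob_cols}

    if sp_path is not None:
        df = pd.read_csv(sp_path, sep="\t", comment="#")
        for _, row in df.iterrows():
            sid = str(row["ID"])
            if _known(sid, "signal-peptide table"):
                ov.signal_peptide[sid] = str(row["Prediction"]).upper() == "SP"

    if idp_path is not None:
        df = pd.read_csv(idp_path, sep="\t", comment="#")
        for sid, grp in df.groupby("seq_id", sort=False):
            sid = str(sid)
            if _known(sid, "disorder table"):
                ov.disorder[sid] = (
                    grp.sort_values("pos")["score"].to_numpy(dtype=float)
                )
    return ov


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> skbio.TreeNode:
    """Parse a Newick string into a tree; internal labels kept verbatim."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise ValueError(f"unbalanced '(' ({depth} unclosed) in newick text")
    return skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)


def write_newick(tree: skbio.TreeNode) -> str:
    """Serialise a tree with branch lengths rounded to 6 decimals."""
    for node in tree.traverse(include_self=True):
        if node.length is not None:
            node.length = round(float(node.length), 6)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
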