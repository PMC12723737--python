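"""Reading and writing sequences, labeled datasets, annotations and predictions.

All user-facing coordinates are 1-based inclusive (UniProt convention: the
mutation ``H44C`` and the site position ``D46`` refer to the 44th and 46th
residue of the sequence). Any 0-based indexing is internal and converted at
this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes tolerated in input sequences.
AMBIGUOUS_AA = "XBZUO"
ALPHABET = set(STANDARD_AA) | set(AMBIGUOUS_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the 20 standard letters plus X/B/Z/U/O."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace(" ", "").replace("\n", "")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledRecord:
    """A protein with an experimental optimal pH and optional metadata.

    ``identity_score`` is the maximum sequence identity of this protein to any
    training-set protein, in [0, 1]; ``ec_class`` is the top-level Enzyme
    Commission class (1-7).
    """

    id: str
    sequence: str
    ph_opt: float
    ec_class: int | None = None
    identity_score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 0.0 <= self.ph_opt <= 14.0:
            raise ValidationError(
                f"record {self.id!r}: ph_opt {self.ph_opt} outside [0, 14]"
            )
        if self.ec_class is not None and self.ec_class not in range(1, 8):
            raise ValidationError(
                f"record {self.id!r}: ec_class {self.ec_class} not in 1..7"
            )

    def as_protein(self) -> ProteinRecord:
        return ProteinRecord(self.id, self.sequence)


@dataclass
class AnnotationTrack:
    """Active-site and binding-site positions (1-based) for one protein.

    A residue may be both an active and a binding site; the sets need not be
    disjoint.
    """

    id: str
    active_sites: set[int] = field(default_factory=set)
    binding_sites: set[int] = field(default_factory=set)

    def validate_against(self, sequence: str) -> None:
        """Cross-check every position against the paired sequence length."""
        for name, sites in (("active", self.active_sites),
                            ("binding", self.binding_sites)):
            for pos in sites:
                if not 1 <= pos <= len(sequence):
                    raise ValidationError(
                        f"{self.id}: {name} site {pos} exceeds sequence "
                        f"length {len(sequence)}"
                    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Order is preserved and sequences are uppercased. Empty sequences raise a
    :class:`ParseError` naming the offending entry.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise ParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        try:
            records.append(ProteinRecord(entry.id, seq))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
               for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# Labeled dataset tables
# ---------------------------------------------------------------------------

def _sniff_sep(path: str | Path) -> str:
    """Tab/comma auto-detection from the header line."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


#: Default column names; override with ``colmap`` for tables that use others.
DEFAULT_COLMAP = {
    "id": "id",
    "sequence": "sequence",
    "ph_opt": "ph_opt",
    "ec": "ec",
    "identity": "identity",
}


def read_dataset(path: str | Path,
                 colmap: Mapping[str, str] | None = None) -> list[LabeledRecord]:
    """Read a labeled (sequence, pH_opt) table (TSV or CSV, auto-detected).

    Required columns: id, sequence, ph_opt (under ``colmap`` renaming).
    Optional columns ``ec`` and ``identity`` are parsed when present. Rows
    whose pH_opt falls outside [0, 14] are dropped and the count is logged.
    """
    cm = dict(DEFAULT_COLMAP)
    if colmap:
        cm.update(colmap)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    required = [cm["id"], cm["sequence"], cm["ph_opt"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    has_ec = cm["ec"] in df.columns
    has_identity = cm["identity"] in df.columns

    records: list[LabeledRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        ph = float(row[cm["ph_opt"]])
        if not 0.0 <= ph <= 14.0:
            dropped += 1
            continue
        ec = row.get(cm["ec"]) if has_ec else None
        ec = int(ec) if ec is not None and pd.notna(ec) else None
        ident = row.get(cm["identity"]) if has_identity else None
        ident = float(ident) if ident is not None and pd.notna(ident) else None
        records.append(LabeledRecord(str(row[cm["id"]]),
                                     str(row[cm["sequence"]]),
                                     ph, ec_class=ec, identity_score=ident))
    if dropped:
        logger.warning("%s: dropped %d row(s) with ph_opt outside [0, 14]",
                       path, dropped)
    return records


def write_dataset(records: Iterable[LabeledRecord], path: str | Path) -> None:
    """Write a labeled dataset as a TSV readable by :func:`read_dataset`."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "sequence": r.sequence, "ph_opt": r.ph_opt,
            "ec": r.ec_class if r.ec_class is not None else "",
            "identity": r.identity_score if r.identity_score is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Residue annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, AnnotationTrack]:
    """Read a flattened site-annotation table.

    Expected columns: ``id``, ``site_type`` in {active, binding}, ``position``
    (1-based). Duplicate rows collapse under set semantics.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in ("id", "site_type", "position") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; "
                          f"found {list(df.columns)}")
    tracks: dict[str, AnnotationTrack] = {}
    for row in df.itertuples(index=False):
        pos = int(row.position)
        if pos <= 0:
            raise ValidationError(
                f"{path}: position {pos} for {row.id!r} is not 1-based positive"
            )
        site_type = str(row.site_type).strip().lower()
        if site_type not in ("active", "binding"):
            raise ValidationError(
                f"{path}: unknown site_type {row.site_type!r} for {row.id!r}"
            )
        track = tracks.setdefault(str(row.id), AnnotationTrack(str(row.id)))
        (track.active_sites if site_type == "active"
         else track.binding_sites).add(pos)
    return tracks


def write_annotations(tracks: Mapping[str, AnnotationTrack],
                      path: str | Path) -> None:
    rows = []
    for track in tracks.values():
        for pos in sorted(track.active_sites):
            rows.append({"id": track.id, "site_type": "active", "position": pos})
        for pos in sorted(track.binding_sites):
            rows.append({"id": track.id, "site_type": "binding", "position": pos})
    pd.DataFrame(rows, columns=["id", "site_type", "position"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------

def write_predictions(ids: Iterable[str], values: Iterable[float],
                      path: str | Path) -> None:
    pd.DataFrame({"id": list(ids), "predicted_ph_opt": list(values)}).to_csv(
        path, sep="\t", index=False)


def read_predictions(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    missing = [c for c in ("id", "predicted_ph_opt") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return {str(i): float(v)
            for i, v in zip(df["id"], df["predicted_ph_opt"])}
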