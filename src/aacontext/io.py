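"""Reading and writing the package's external formats.

Sequences and secondary-structure tracks travel as FASTA (tracks are
FASTA-like files whose "sequence" lines are per-residue H/E/C letters);
aligned ancestor/descendant pairs as paired FASTA where entries come in
consecutive couples sharing a pair identifier (``>pair|anc`` /
``>pair|desc``); entropy profiles as tab-separated tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AMINO_ACIDS, GAP, sanitize

logger = logging.getLogger(__name__)

STRUCTURE_CLASSES = "HEC"


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, optional H/E/C track and group label."""

    id: str
    sequence: str
    structure_track: str | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.structure_track is not None:
            if len(self.structure_track) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: structure track length "
                    f"{len(self.structure_track)} != sequence length {len(self.sequence)}"
                )
            bad = set(self.structure_track) - set(STRUCTURE_CLASSES)
            if bad:
                raise ValueError(
                    f"record {self.id!r}: structure letters outside H/E/C: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedPair:
    """A gapped ancestor/descendant alignment for one branch of a tree.

    Both rows have equal length and no column is a gap in both.
    """

    pair_id: str
    ancestor: str
    descendant: str
    branch_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.ancestor) != len(self.descendant):
            raise ValueError(
                f"pair {self.pair_id!r}: ancestor length {len(self.ancestor)} "
                f"!= descendant length {len(self.descendant)}"
            )
        for i, (a, d) in enumerate(zip(self.ancestor, self.descendant)):
            if a == GAP and d == GAP:
                raise ValueError(
                    f"pair {self.pair_id!r}: column {i + 1} is a gap in both rows"
                )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein sequences from FASTA.

    Sequences are upper-cased; letters outside the canonical 20 are mapped
    to the unknown symbol (the number of replacements is logged). Duplicate
    identifiers and empty files are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_replaced = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate identifier {entry.id!r}")
        seen.add(entry.id)
        seq, n = sanitize(str(entry.seq))
        n_replaced += n
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    if n_replaced:
        logger.info(
            "%s: mapped %d non-canonical residues to the unknown symbol",
            path, n_replaced,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def read_structure_tracks(
    path: str | Path, records: list[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach per-residue H/E/C tracks (FASTA-like, same identifiers).

    Returns new records; the inputs are not mutated. A track whose
    identifier matches no record, whose length mismatches, or that uses
    letters outside H/E/C is an error.
    """
    path = Path(path)
    by_id = {r.id: r for r in records}
    tracks: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id not in by_id:
            raise ValueError(f"{path}: track {entry.id!r} matches no record")
        tracks[entry.id] = str(entry.seq).upper()
    out = []
    for rec in records:
        track = tracks.get(rec.id)
        if track is None:
            out.append(rec)
            continue
        # ProteinRecord validates length and the H/E/C alphabet
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence=rec.sequence,
                structure_track=track,
                group_label=rec.group_label,
            )
        )
    return out


def write_structure_tracks(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.structure_track), id=r.id, description="")
        for r in records
        if r.structure_track is not None
    ]
    SeqIO.write(entries, str(Path(path)), "fasta")


def _split_pair_header(header: str) -> tuple[str, str]:
    """``g1|anc`` -> (``g1``, ``anc``); a header without ``|`` keeps its full id."""
    if "|" in header:
        pair_id, role = header.split("|", 1)
        return pair_id, role
    return header, ""


def read_aligned_pairs(path: str | Path) -> list[AlignedPair]:
    """Read ancestor/descendant couples from paired FASTA.

    Entries come in consecutive couples sharing a pair identifier
    (``>g1|anc`` then ``>g1|desc``). Gap characters are kept; other
    letters are sanitized like sequences.
    """
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"{path}: no FASTA entries found")
    if len(entries) % 2:
        raise ValueError(f"{path}: odd number of entries ({len(entries)})")
    pairs = []
    for anc_entry, desc_entry in zip(entries[::2], entries[1::2]):
        anc_id, _ = _split_pair_header(anc_entry.id)
        desc_id, _ = _split_pair_header(desc_entry.id)
        if anc_id != desc_id:
            raise ValueError(
                f"{path}: consecutive entries {anc_entry.id!r} and "
                f"{desc_entry.id!r} do not share a pair identifier"
            )
        pairs.append(
            AlignedPair(
                pair_id=anc_id,
                ancestor=_sanitize_gapped(str(anc_entry.seq)),
                descendant=_sanitize_gapped(str(desc_entry.seq)),
            )
        )
    return pairs


def write_aligned_pairs(pairs: Iterable[AlignedPair], path: str | Path) -> None:
    entries = []
    for p in pairs:
        entries.append(SeqRecord(Seq(p.ancestor), id=f"{p.pair_id}|anc", description=""))
        entries.append(SeqRecord(Seq(p.descendant), id=f"{p.pair_id}|desc", description=""))
    SeqIO.write(entries, str(Path(path)), "fasta")


def _sanitize_gapped(seq: str) -> str:
    out = []
    for chunk in seq.upper().split(GAP):
        out.append(sanitize(chunk)[0] if chunk else "")
    return GAP.join(out)


_PROFILE_BASE_COLUMNS = [
    "offset",
    "n_contexts",
    "total_relative_entropy",
    "threshold",
    "bootstrap_sd",
    "significant",
    "outlier_residues",
]
_COMPONENT_COLUMNS = [f"component_{aa}" for aa in AMINO_ACIDS]


def write_profile_tsv(profile, path: str | Path) -> None:
    """Serialize an :class:`~aacontext.entropy.EntropyProfile` to TSV.

    One row per populated offset; numeric fields survive a round trip to
    12 significant digits. An empty profile writes the header only.
    """
    rows = []
    for offset in profile.offsets():
        site = profile.sites[offset]
        row = {
            "offset": offset,
            "n_contexts": site.n,
            "total_relative_entropy": site.total,
            "threshold": site.threshold if site.threshold is not None else math.nan,
            "bootstrap_sd": site.sd if site.sd is not None else math.nan,
            "significant": bool(site.significant) if site.significant is not None else False,
            "outlier_residues": ",".join(
                f"{aa}:{direction}" for aa, direction in site.outliers
            ),
        }
        for aa, value in zip(AMINO_ACIDS, site.components):
            row[f"component_{aa}"] = value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_PROFILE_BASE_COLUMNS + _COMPONENT_COLUMNS)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_profile_tsv(path: str | Path) -> pd.DataFrame:
    """Read a profile TSV back as a DataFrame (column order preserved)."""
    frame = pd.read_csv(Path(path), sep="\t")
    missing = set(_PROFILE_BASE_COLUMNS + _COMPONENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing profile columns {sorted(missing)}")
    return frame
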