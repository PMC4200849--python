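"""Context dependence of amino-acid substitutions.

Substitution events are read off aligned ancestor/descendant pairs: one
event per alignment column where both rows carry canonical residues and
they differ. Columns with a gap or an unknown residue in either row are
skipped. Each event keeps the flanking residues of the ANCESTRAL
sequence (in ungapped ancestral coordinates) — the background correction
is keyed to the pre-substituted residue, so its contexts are the
consistent choice.

For a substitution type X→Y the entropy profile is computed against the
per-offset background of X: the background at offset k is the residue
distribution at offset k over all X occurrences in the reference
dataset. This removes X's own neighbor preference from the signal, so a
nonzero profile reflects context dependence of the substitution itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alphabet import AMINO_ACIDS, GAP, UNKNOWN, is_canonical
from .contexts import ContextCountTable
from .entropy import (
    BackgroundDistribution,
    EntropyProfile,
    background_from_table,
    per_offset_background,
    profile,
)
from .io import AlignedPair, ProteinRecord

SubType = tuple[str, str]


@dataclass
class SubstitutionEvent:
    """One inferred X→Y replacement with its ancestral flanking context.

    ``position`` is 1-based in the ungapped ancestral sequence;
    ``context_n``/``context_c`` hold up to ``window`` ancestral residues
    on each side (shorter near the termini), gap-free.
    """

    pair_id: str
    position: int
    from_aa: str
    to_aa: str
    context_n: str
    context_c: str
    branch_label: str | None = None

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("substitution requires from_aa != to_aa")
        if not (is_canonical(self.from_aa) and is_canonical(self.to_aa)):
            raise ValueError(
                f"substitution {self.from_aa}->{self.to_aa} uses non-canonical residues"
            )
        if GAP in self.context_n or GAP in self.context_c:
            raise ValueError("contexts must not contain gap characters")

    @property
    def sub_type(self) -> SubType:
        return (self.from_aa, self.to_aa)


def infer_events(pair: AlignedPair, window: int = 20) -> list[SubstitutionEvent]:
    """Events from pair-wise comparison of the two aligned rows.

    A column yields an event iff both rows hold canonical residues and
    they differ; gap and unknown columns yield none. Contexts come from
    the ungapped ancestral sequence (up to ``window`` residues per side).
    """
    anc_ungapped = pair.ancestor.replace(GAP, "")
    events: list[SubstitutionEvent] = []
    anc_pos = 0  # 0-based position in the ungapped ancestor
    for a, d in zip(pair.ancestor, pair.descendant):
        if a == GAP:
            continue
        if d != GAP and a != d and a != UNKNOWN and d != UNKNOWN:
            events.append(
                SubstitutionEvent(
                    pair_id=pair.pair_id,
                    branch_label=pair.branch_label,
                    position=anc_pos + 1,
                    from_aa=a,
                    to_aa=d,
                    context_n=anc_ungapped[max(0, anc_pos - window) : anc_pos],
                    context_c=anc_ungapped[anc_pos + 1 : anc_pos + 1 + window],
                )
            )
        anc_pos += 1
    return events


def enumerate_types() -> list[SubType]:
    """All 380 ordered substitution types (X, Y), X != Y, lexicographic."""
    return [
        (x, y) for x, y in itertools.product(AMINO_ACIDS, repeat=2) if x != y
    ]


def events_to_table(
    events: Sequence[SubstitutionEvent], window: int = 20
) -> ContextCountTable:
    """Context count table of the events of one substitution type.

    Per-side completeness as for residue contexts: a side contributes
    iff the event carries at least ``window`` ancestral residues there
    (the innermost ``window`` are used). Mixing types is an error; an
    empty event list gives an empty table of unknown type.
    """
    types = {ev.sub_type for ev in events}
    if len(types) > 1:
        raise ValueError(f"events mix substitution types: {sorted(types)}")
    focal = next(iter(types)) if types else ("?", "?")
    store: dict[str, list[str]] = {"N": [], "C": []}
    for ev in events:
        if len(ev.context_n) >= window:
            store["N"].append(ev.context_n[-window:])
        if len(ev.context_c) >= window:
            store["C"].append(ev.context_c[:window])
    return ContextCountTable(focal=focal, window=window, store=store)


def substitution_profile(
    sub_type: SubType,
    table: ContextCountTable,
    reference_records: Iterable[ProteinRecord] | None = None,
    window: int | None = None,
    background: BackgroundDistribution | None = None,
    pseudocount: bool = False,
    quartile_method: str = "linear",
) -> EntropyProfile:
    """Entropy profile of an X→Y table against X's per-offset background.

    The background is built from ``reference_records`` (all X contexts at
    the same window), or passed directly via ``background`` — e.g. a
    structure-scoped table run through
    :func:`~aacontext.entropy.background_from_table`.
    """
    window = window if window is not None else table.window
    if background is None:
        if reference_records is None:
            raise ValueError("provide reference_records or a prebuilt background")
        background = per_offset_background(
            reference_records, sub_type[0], window, pseudocount=pseudocount
        )
    return profile(table, background, quartile_method=quartile_method)


def filter_types(
    tables: dict[SubType, ContextCountTable], min_events_per_side: int = 100
) -> list[SubType]:
    """Types with enough data: max(n_N, n_C) >= ``min_events_per_side``."""
    kept = []
    for sub_type, table in tables.items():
        n_side = table.n_side
        if max(n_side["N"], n_side["C"]) >= min_events_per_side:
            kept.append(sub_type)
    return sorted(kept)


_EVENT_COLUMNS = [
    "pair_id",
    "branch_label",
    "position",
    "from_aa",
    "to_aa",
    "context_N",
    "context_C",
]


def write_events_tsv(events: Iterable[SubstitutionEvent], path: str | Path) -> None:
    rows = [
        {
            "pair_id": ev.pair_id,
            "branch_label": ev.branch_label if ev.branch_label is not None else "",
            "position": ev.position,
            "from_aa": ev.from_aa,
            "to_aa": ev.to_aa,
            "context_N": ev.context_n,
            "context_C": ev.context_c,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(
        Path(path), sep="\t", index=False
    )


def read_events_tsv(path: str | Path) -> list[SubstitutionEvent]:
    frame = pd.read_csv(
        Path(path), sep="\t", dtype=str, keep_default_na=False
    )
    missing = set(_EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    return [
        SubstitutionEvent(
            pair_id=row.pair_id,
            branch_label=row.branch_label or None,
            position=int(row.position),
            from_aa=row.from_aa,
            to_aa=row.to_aa,
            context_n=row.context_N,
            context_c=row.context_C,
        )
        for row in frame.itertuples()
    ]


def group_events(
    events: Iterable[SubstitutionEvent],
) -> dict[SubType, list[SubstitutionEvent]]:
    """Events bucketed by ordered substitution type."""
    grouped: dict[SubType, list[SubstitutionEvent]] = {}
    for ev in events:
        grouped.setdefault(ev.sub_type, []).append(ev)
    return grouped


def events_in_structure(
    events: Iterable[SubstitutionEvent],
    ancestor_tracks: dict[str, str],
    structure_class: str,
) -> list[SubstitutionEvent]:
    """Events whose ancestral focal residue lies in a segment of the class.

    ``ancestor_tracks`` maps pair_id to the H/E/C track of the ungapped
    ancestral sequence. Events from pairs without a track are an error.
    """
    kept = []
    for ev in events:
        track = ancestor_tracks.get(ev.pair_id)
        if track is None:
            raise ValueError(f"no ancestral structure track for pair {ev.pair_id!r}")
        if track[ev.position - 1] == structure_class:
            kept.append(ev)
    return kept
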