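"""Flanking-context extraction around focal residues.

For every occurrence of a focal amino acid, the W residues on its
N-terminal side (offsets -W..-1) and the W residues on its C-terminal
side (offsets +1..+W) are collected into per-offset count tables. The
two sides are independent: an occurrence contributes its N-side flank
iff at least W residues precede it, and its C-side flank iff at least W
residues follow it, so an occurrence near one terminus still counts on
the other side. Occurrences with an incomplete window on a side are
excluded on that side only.

Structure-stratified extraction restricts both the focal residue and its
flank to a single maximal segment of one secondary-structure class, with
the default window of 6 (segments are short relative to whole chains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .alphabet import N_AA, UNKNOWN_CODE, encode, is_canonical
from .io import ProteinRecord

Focal = str | tuple[str, str]

SIDES = ("N", "C")


def _offsets_for_side(side: str, window: int) -> list[int]:
    if side == "N":
        return list(range(-window, 0))
    return list(range(1, window + 1))


@dataclass
class ContextCountTable:
    """Per-offset amino-acid counts around a focal residue or substitution.

    ``store`` keeps every contributing flanking string per side (N-side
    strings read left-to-right as offsets -W..-1; C-side as +1..+W); the
    counts are always derived from it, so shuffling and bootstrap can
    resample the exact contexts that were counted.
    """

    focal: Focal
    window: int
    store: dict[str, list[str]] = field(default_factory=lambda: {"N": [], "C": []})

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for side in SIDES:
            for s in self.store[side]:
                if len(s) != self.window:
                    raise ValueError(
                        f"{side}-side flank {s!r} has length {len(s)}, "
                        f"expected window {self.window}"
                    )

    @property
    def n_side(self) -> dict[str, int]:
        return {side: len(self.store[side]) for side in SIDES}

    def encoded(self, side: str) -> np.ndarray:
        """Flanks on ``side`` as a (n, window) uint8 code matrix."""
        flanks = self.store[side]
        if not flanks:
            return np.empty((0, self.window), dtype=np.uint8)
        return np.vstack([encode(s) for s in flanks])

    @property
    def counts(self) -> dict[int, np.ndarray]:
        """offset -> 20-vector of canonical-residue counts (unknowns excluded)."""
        out: dict[int, np.ndarray] = {}
        for side in SIDES:
            mat = self.encoded(side)
            offsets = _offsets_for_side(side, self.window)
            if mat.shape[0] == 0:
                for off in offsets:
                    out[off] = np.zeros(N_AA, dtype=np.int64)
                continue
            for j, off in enumerate(offsets):
                out[off] = np.bincount(mat[:, j], minlength=N_AA + 1)[:N_AA]
        return out

    def unknown_counts(self) -> dict[int, int]:
        """offset -> number of unknown-symbol slots at that offset."""
        out: dict[int, int] = {}
        for side in SIDES:
            mat = self.encoded(side)
            for j, off in enumerate(_offsets_for_side(side, self.window)):
                out[off] = int(np.sum(mat[:, j] == UNKNOWN_CODE)) if mat.size else 0
        return out

    def offsets(self, side: str | None = None) -> list[int]:
        if side is not None:
            return _offsets_for_side(side, self.window)
        return _offsets_for_side("N", self.window) + _offsets_for_side("C", self.window)

    def __add__(self, other: "ContextCountTable") -> "ContextCountTable":
        if (self.focal, self.window) != (other.focal, other.window):
            raise ValueError("can only add tables with identical focal and window")
        return ContextCountTable(
            focal=self.focal,
            window=self.window,
            store={side: self.store[side] + other.store[side] for side in SIDES},
        )


def extract_contexts(
    records: Iterable[ProteinRecord], focal_aa: str, window: int = 20
) -> ContextCountTable:
    """Collect flanking contexts of every ``focal_aa`` occurrence.

    Per-side completeness: the N-side flank of an occurrence at 0-based
    position i in a sequence of length L is kept iff i >= W; the C-side
    flank iff L - 1 - i >= W.
    """
    if not is_canonical(focal_aa):
        raise ValueError(f"focal residue {focal_aa!r} is not one of the 20 canonical codes")
    if window < 1:
        raise ValueError("window must be >= 1")
    store: dict[str, list[str]] = {"N": [], "C": []}
    for rec in records:
        seq = rec.sequence
        length = len(seq)
        start = seq.find(focal_aa)
        while start != -1:
            if start >= window:
                store["N"].append(seq[start - window : start])
            if length - 1 - start >= window:
                store["C"].append(seq[start + 1 : start + 1 + window])
            start = seq.find(focal_aa, start + 1)
    return ContextCountTable(focal=focal_aa, window=window, store=store)


def segmentize(track: str) -> list[tuple[str, int, int]]:
    """Maximal runs of one structure class as (class, start, end) half-open.

    The intervals tile the track exactly.
    """
    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(track) + 1):
        if i == len(track) or track[i] != track[start]:
            segments.append((track[start], start, i))
            start = i
    return segments


def extract_contexts_in_structure(
    records: Iterable[ProteinRecord],
    focal_aa: str,
    structure_class: str,
    window: int = 6,
    confine_to_segment: bool = True,
) -> ContextCountTable:
    """Like :func:`extract_contexts` but restricted to one structure class.

    The focal occurrence must lie in a segment of ``structure_class``.
    With ``confine_to_segment`` (default) a side contributes only when the
    whole flank fits inside that same segment; otherwise completeness is
    evaluated on the full sequence as in whole-chain extraction.
    """
    if not is_canonical(focal_aa):
        raise ValueError(f"focal residue {focal_aa!r} is not one of the 20 canonical codes")
    if structure_class not in "HEC":
        raise ValueError(f"structure class {structure_class!r} not in H/E/C")
    store: dict[str, list[str]] = {"N": [], "C": []}
    for rec in records:
        if rec.structure_track is None:
            raise ValueError(f"record {rec.id!r} has no structure track")
        seq = rec.sequence
        length = len(seq)
        for cls, seg_start, seg_end in segmentize(rec.structure_track):
            if cls != structure_class:
                continue
            for i in range(seg_start, seg_end):
                if seq[i] != focal_aa:
                    continue
                if confine_to_segment:
                    n_ok = i - seg_start >= window
                    c_ok = seg_end - 1 - i >= window
                else:
                    n_ok = i >= window
                    c_ok = length - 1 - i >= window
                if n_ok:
                    store["N"].append(seq[i - window : i])
                if c_ok:
                    store["C"].append(seq[i + 1 : i + 1 + window])
    return ContextCountTable(focal=focal_aa, window=window, store=store)
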