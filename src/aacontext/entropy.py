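"""Relative entropy (Kullback-Leibler divergence) of flanking-site profiles.

The divergence of an observed flanking-site distribution P from a
background Q decomposes into the 20 per-residue components

    d(a) = P(a) * log2(P(a) / Q(a)),

and the site total D = sum_a d(a) is nonnegative, zero iff P == Q
(Gibbs' inequality). P(a) is the frequency of residue ``a`` among the
canonical residues observed at the offset — unknown-symbol slots are
excluded from the normalizer, so P sums to 1 over exactly 20 terms.

Two background modes mirror the two analyses:

* ``global`` — residue frequencies of a whole dataset (optionally scoped
  to one secondary-structure class or one group label), used for the
  neighbor-preference analysis;
* ``per_offset`` — the flanking-site distributions of one residue type,
  used to correct substitution profiles for the neighbor preference of
  the pre-substituted residue: the background of the X→Y profile at
  offset k is the distribution at offset k of all X occurrences.

A residue preferred (or avoided) at one offset is flagged with the Tukey
boxplot rule: its component lies above Q3 + 1.5*IQR (or below
Q1 - 1.5*IQR) of the 20 components at that offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .alphabet import AMINO_ACIDS, AA_INDEX, N_AA, UNKNOWN
from .contexts import ContextCountTable, extract_contexts
from .io import ProteinRecord

#: Pseudocount added to every background count when requested.
PSEUDOCOUNT_ALPHA = 0.5

_SUM_TOL = 1e-9


@dataclass
class BackgroundDistribution:
    """The background Q: one 20-vector (global) or one per offset."""

    mode: Literal["global", "per_offset"]
    q: np.ndarray | dict[int, np.ndarray]

    def __post_init__(self) -> None:
        vectors = [self.q] if self.mode == "global" else list(self.q.values())
        for vec in vectors:
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (N_AA,):
                raise ValueError("background vectors must have 20 entries")
            if np.any(vec < 0):
                raise ValueError("background frequencies must be nonnegative")
            if abs(vec.sum() - 1.0) > _SUM_TOL:
                raise ValueError(f"background frequencies sum to {vec.sum()}, not 1")

    def at(self, offset: int) -> np.ndarray:
        if self.mode == "global":
            return np.asarray(self.q, dtype=float)
        try:
            return np.asarray(self.q[offset], dtype=float)
        except KeyError:
            raise KeyError(f"background has no vector for offset {offset}") from None


@dataclass
class SiteEntropy:
    """Entropy bookkeeping for one flanking offset."""

    n: int
    total: float
    components: np.ndarray
    outliers: list[tuple[str, str]] = field(default_factory=list)
    threshold: float | None = None
    sd: float | None = None
    significant: bool | None = None


@dataclass
class EntropyProfile:
    """Per-offset relative entropies around one focal residue/substitution.

    Offsets whose side had no complete contexts are absent, not zero.
    """

    focal: str | tuple[str, str]
    window: int
    sites: dict[int, SiteEntropy]
    side_thresholds: dict[str, float] = field(default_factory=dict)

    def offsets(self) -> list[int]:
        return sorted(self.sites)

    def totals(self) -> dict[int, float]:
        return {off: site.total for off, site in self.sites.items()}

    def max_offset(self) -> int:
        """Offset with the largest total relative entropy."""
        return max(self.sites, key=lambda off: self.sites[off].total)

    def significant_offsets(self) -> list[int]:
        return sorted(
            off for off, site in self.sites.items() if site.significant
        )


def background_from_records(
    records: Iterable[ProteinRecord],
    scope: Literal["all", "structure", "group"] = "all",
    structure_class: str | None = None,
    group_label: str | None = None,
    pseudocount: bool = False,
) -> BackgroundDistribution:
    """Global background: canonical-residue frequencies of the scoped dataset.

    ``scope="structure"`` counts only residues whose track letter equals
    ``structure_class``; ``scope="group"`` only records whose group label
    equals ``group_label``. Unknown symbols are excluded from numerator
    and denominator.
    """
    counts = np.zeros(N_AA, dtype=float)
    for rec in records:
        if scope == "group" and rec.group_label != group_label:
            continue
        if scope == "structure":
            if rec.structure_track is None:
                raise ValueError(f"record {rec.id!r} has no structure track")
            residues = (
                aa
                for aa, cls in zip(rec.sequence, rec.structure_track)
                if cls == structure_class
            )
        else:
            residues = iter(rec.sequence)
        for aa in residues:
            if aa != UNKNOWN:
                counts[AA_INDEX[aa]] += 1
    if pseudocount:
        counts += PSEUDOCOUNT_ALPHA
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no canonical residues in scope {scope!r}")
    return BackgroundDistribution(mode="global", q=counts / total)


def background_from_table(
    table: ContextCountTable, pseudocount: bool = False
) -> BackgroundDistribution:
    """Per-offset background from a context count table.

    Each populated offset is normalized independently. An offset on a
    populated side with zero canonical counts is an error (insufficient
    data) unless a pseudocount is requested.
    """
    q: dict[int, np.ndarray] = {}
    counts = table.counts
    n_side = table.n_side
    for side in ("N", "C"):
        if n_side[side] == 0:
            continue
        for off in table.offsets(side):
            vec = counts[off].astype(float)
            if pseudocount:
                vec = vec + PSEUDOCOUNT_ALPHA
            total = vec.sum()
            if total == 0:
                raise ValueError(
                    f"offset {off:+d} of focal {table.focal!r} has zero counts; "
                    "insufficient data for a per-offset background"
                )
            q[off] = vec / total
    if not q:
        raise ValueError(
            f"focal {table.focal!r}: no populated offsets to build a background from"
        )
    return BackgroundDistribution(mode="per_offset", q=q)


def per_offset_background(
    records: Iterable[ProteinRecord],
    focal_aa: str,
    window: int = 20,
    pseudocount: bool = False,
) -> BackgroundDistribution:
    """Flanking-site distributions of ``focal_aa``, one 20-vector per offset."""
    table = extract_contexts(records, focal_aa, window)
    return background_from_table(table, pseudocount=pseudocount)


def component_entropy(p_a: float, q_a: float) -> float:
    """One per-residue term: p * log2(p/q), with the p == 0 limit of 0."""
    if not (0.0 <= p_a <= 1.0 and 0.0 <= q_a <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if p_a == 0.0:
        return 0.0
    if q_a == 0.0:
        raise ValueError(
            "observed frequency positive where background is zero "
            "(enable the pseudocount to allow this)"
        )
    return p_a * np.log2(p_a / q_a)


def site_entropy(
    counts: np.ndarray, background: np.ndarray, n: int | None = None
) -> tuple[float, np.ndarray]:
    """Total and per-residue relative entropy of one offset.

    ``counts`` are the 20 canonical-residue counts at the offset (unknown
    slots already excluded); P(a) = counts[a] / counts.sum(). ``n``, if
    given, is the number of contributing contexts and upper-bounds the
    count sum. Raises if counts are all zero or a positive count meets a
    zero background frequency.
    """
    counts = np.asarray(counts, dtype=float)
    q = np.asarray(background, dtype=float)
    if counts.shape != (N_AA,) or q.shape != (N_AA,):
        raise ValueError("counts and background must have 20 entries")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total_count = counts.sum()
    if total_count == 0:
        raise ValueError("all counts are zero at this offset")
    if n is not None and total_count > n:
        raise ValueError(f"counts sum to {total_count} > n = {n}")
    bad = (counts > 0) & (q == 0.0)
    if np.any(bad):
        bad_aas = [AMINO_ACIDS[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"residues {bad_aas} observed but have zero background frequency "
            "(enable the pseudocount to allow this)"
        )
    p = counts / total_count
    components = np.zeros(N_AA, dtype=float)
    pos = p > 0
    components[pos] = p[pos] * np.log2(p[pos] / q[pos])
    return float(components.sum()), components


def component_outliers(
    components: np.ndarray, method: str = "linear"
) -> list[tuple[str, str]]:
    """Tukey 1.5*IQR outliers among the 20 per-residue components.

    Returns (residue, "high"/"low") pairs; quartiles use numpy's
    ``method`` convention (default linear interpolation, i.e. type 7).
    """
    values = np.asarray(components, dtype=float)
    if values.shape != (N_AA,):
        raise ValueError("exactly 20 component values are required")
    q1, q3 = np.percentile(values, [25, 75], method=method)
    iqr = q3 - q1
    high = q3 + 1.5 * iqr
    low = q1 - 1.5 * iqr
    flags = []
    for i, value in enumerate(values):
        if value > high:
            flags.append((AMINO_ACIDS[i], "high"))
        elif value < low:
            flags.append((AMINO_ACIDS[i], "low"))
    return flags


def profile(
    table: ContextCountTable,
    background: BackgroundDistribution,
    quartile_method: str = "linear",
) -> EntropyProfile:
    """Entropy profile of a context table against a background.

    One :class:`SiteEntropy` per populated offset; sides with no complete
    contexts contribute no offsets. Outlier residues are flagged
    immediately; thresholds, SDs and significance flags are attached by
    the significance module.
    """
    n_side = table.n_side
    if n_side["N"] == 0 and n_side["C"] == 0:
        raise ValueError(f"focal {table.focal!r}: table is empty on both sides")
    counts = table.counts
    sites: dict[int, SiteEntropy] = {}
    for side in ("N", "C"):
        if n_side[side] == 0:
            continue
        for off in table.offsets(side):
            total, components = site_entropy(
                counts[off], background.at(off), n=n_side[side]
            )
            sites[off] = SiteEntropy(
                n=n_side[side],
                total=total,
                components=components,
                outliers=component_outliers(components, method=quartile_method),
            )
    return EntropyProfile(focal=table.focal, window=table.window, sites=sites)
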