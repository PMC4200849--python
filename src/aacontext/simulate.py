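"""Synthetic protein datasets with planted, recoverable signals.

Each generator emulates one statistical feature the analysis is meant to
detect, at desk scale, and returns machine-readable ground truth
alongside the records so recovery can be scored without re-deriving it:

* :func:`gen_iid` — no positional structure at all; the null model used
  to calibrate the shuffle thresholds.
* :func:`gen_collagen_mix` — a fraction of records carry a collagen-like
  (G-X-Y)n block, planting the 3n-periodic glycine signal.
* :func:`gen_self_clustering` — homopolymer runs of one residue placed
  at a Poisson rate, emulating the self-preference that replication
  slippage produces.
* :func:`gen_helix_pairing` — an i,i+d pairing (d = 3 or 4) inside
  all-helix chains: wherever residue X sits at position i, residue Y is
  enriched at i+d.
* :func:`gen_context_substitutions` — gapless ancestor/descendant pairs
  in which one substitution type's rate is multiplied when a given
  neighbor residue is present at a given offset.

All generators are deterministic under a fixed seed. Default lengths are
uniform in [150, 400] so full 20-site windows exist on both sides.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, UNKNOWN, encode
from .io import AlignedPair, ProteinRecord
from .substitutions import SubstitutionEvent


def uniform_composition() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


@dataclass
class GeneratorConfig:
    """Shared knobs: dataset size, length range, residue composition, seed."""

    n_sequences: int = 100
    length_min: int = 150
    length_max: int = 400
    composition: np.ndarray = field(default_factory=uniform_composition)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be positive")
        if not (1 <= self.length_min <= self.length_max):
            raise ValueError("need 1 <= length_min <= length_max")
        if self.composition.shape != (N_AA,):
            raise ValueError("composition must have 20 entries")
        if np.any(self.composition < 0) or abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be nonnegative and sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


def _decode(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] for c in codes)


def _lengths(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(config.length_min, config.length_max + 1, size=config.n_sequences)


def gen_iid(config: GeneratorConfig, id_prefix: str = "iid") -> list[ProteinRecord]:
    """Sequences drawn i.i.d. from the configured composition."""
    rng = config.rng()
    records = []
    for i, length in enumerate(_lengths(config, rng)):
        codes = rng.choice(N_AA, size=int(length), p=config.composition)
        records.append(ProteinRecord(id=f"{id_prefix}{i:05d}", sequence=_decode(codes)))
    return records


def gen_collagen_mix(
    config: GeneratorConfig,
    collagen_fraction: float,
    n_repeats: int = 30,
    id_prefix: str = "col",
) -> tuple[list[ProteinRecord], dict[str, dict]]:
    """A fraction of records carry a (G-X-Y)n block inside i.i.d. flanks.

    X and Y positions are drawn per site from the composition with G
    removed (renormalized). Ground truth maps each record id to whether
    it is collagen-like and where its block sits (0-based half-open).
    """
    if not 0.0 <= collagen_fraction <= 1.0:
        raise ValueError("collagen_fraction must lie in [0, 1]")
    block_len = 3 * n_repeats
    if collagen_fraction > 0 and block_len > config.length_min:
        raise ValueError(
            f"(G-X-Y)x{n_repeats} block of length {block_len} exceeds length_min "
            f"{config.length_min}"
        )
    rng = config.rng()
    g_idx = AA_INDEX["G"]
    no_g = config.composition.copy()
    no_g[g_idx] = 0.0
    if collagen_fraction > 0 and no_g.sum() == 0:
        raise ValueError("composition places all mass on G; cannot draw X/Y sites")
    if no_g.sum() > 0:
        no_g = no_g / no_g.sum()
    n_collagen = int(round(collagen_fraction * config.n_sequences))
    collagen_idx = set(
        rng.choice(config.n_sequences, size=n_collagen, replace=False).tolist()
    )
    records = []
    truth: dict[str, dict] = {}
    for i, length in enumerate(_lengths(config, rng)):
        length = int(length)
        rec_id = f"{id_prefix}{i:05d}"
        codes = rng.choice(N_AA, size=length, p=config.composition)
        if i in collagen_idx:
            start = int(rng.integers(0, length - block_len + 1))
            block = rng.choice(N_AA, size=block_len, p=no_g)
            block[::3] = g_idx
            codes[start : start + block_len] = block
            truth[rec_id] = {
                "is_collagen": True,
                "block_start": start,
                "block_end": start + block_len,
                "n_repeats": n_repeats,
            }
        else:
            truth[rec_id] = {"is_collagen": False}
        records.append(ProteinRecord(id=rec_id, sequence=_decode(codes)))
    return records, truth


def gen_self_clustering(
    config: GeneratorConfig,
    run_aa: str,
    run_rate: float,
    run_length: int = 5,
    id_prefix: str = "run",
) -> tuple[list[ProteinRecord], dict[str, list[tuple[int, int]]]]:
    """Homopolymer runs of ``run_aa`` overwritten into i.i.d. background.

    The number of runs per sequence is Poisson with mean
    ``run_rate * length``; each run of ``run_length`` starts uniformly.
    Ground truth maps record id to its run intervals (0-based half-open;
    runs may overlap).
    """
    if run_aa not in AA_INDEX:
        raise ValueError(f"run residue {run_aa!r} is not canonical")
    if run_rate < 0:
        raise ValueError("run_rate must be nonnegative")
    rng = config.rng()
    aa_idx = AA_INDEX[run_aa]
    records = []
    truth: dict[str, list[tuple[int, int]]] = {}
    for i, length in enumerate(_lengths(config, rng)):
        length = int(length)
        rec_id = f"{id_prefix}{i:05d}"
        codes = rng.choice(N_AA, size=length, p=config.composition)
        runs: list[tuple[int, int]] = []
        if run_rate > 0 and length >= run_length:
            for _ in range(rng.poisson(run_rate * length)):
                start = int(rng.integers(0, length - run_length + 1))
                codes[start : start + run_length] = aa_idx
                runs.append((start, start + run_length))
        truth[rec_id] = runs
        records.append(ProteinRecord(id=rec_id, sequence=_decode(codes)))
    return records, truth


def gen_helix_pairing(
    config: GeneratorConfig,
    pair: tuple[str, str],
    offset_d: int = 4,
    enrichment: float = 1.0,
    id_prefix: str = "hlx",
) -> tuple[list[ProteinRecord], dict]:
    """All-helix chains with a planted i,i+d pairing.

    Chains are generated left to right; at a position whose residue d
    sites upstream is X, the sampling distribution has Y's probability
    multiplied by ``enrichment`` and is renormalized. Tracks are all H so
    structure-stratified extraction sees one segment per chain.
    """
    x_aa, y_aa = pair
    if x_aa not in AA_INDEX or y_aa not in AA_INDEX:
        raise ValueError("pair residues must be canonical")
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    rng = config.rng()
    x_idx = AA_INDEX[x_aa]
    boosted = config.composition.copy()
    boosted[AA_INDEX[y_aa]] *= enrichment
    if x_aa != y_aa and boosted[x_idx] < 1.0:
        # keep the trigger residue's own probability unchanged while
        # renormalizing, so X stays i.i.d. and the only planted positional
        # signal is Y at +d (otherwise X would be depleted at +d, which
        # reads back as a spurious X signal at -d of the X profile)
        others = np.arange(N_AA) != x_idx
        boosted[others] *= (1.0 - boosted[x_idx]) / boosted[others].sum()
    else:
        boosted = boosted / boosted.sum()
    cum_base = np.cumsum(config.composition).tolist()
    cum_boost = np.cumsum(boosted).tolist()
    records = []
    for i, length in enumerate(_lengths(config, rng)):
        length = int(length)
        u = rng.random(length)
        codes = np.empty(length, dtype=np.int64)
        for j in range(length):
            cum = (
                cum_boost
                if j >= offset_d and codes[j - offset_d] == x_idx
                else cum_base
            )
            codes[j] = min(bisect_right(cum, u[j]), N_AA - 1)
        records.append(
            ProteinRecord(
                id=f"{id_prefix}{i:05d}",
                sequence=_decode(codes),
                structure_track="H" * length,
            )
        )
    truth = {"pair": pair, "offset_d": offset_d, "enrichment": enrichment}
    return records, truth


class SubstitutionRule(NamedTuple):
    """Rate rule: from_aa→to_aa is ``multiplier`` times more likely when
    ``neighbor_aa`` sits at signed ``neighbor_offset`` from the site."""

    from_aa: str
    to_aa: str
    neighbor_offset: int
    neighbor_aa: str
    multiplier: float


def gen_context_substitutions(
    ancestors: Sequence[ProteinRecord],
    base_rate: float,
    rule: SubstitutionRule,
    rng_seed: int = 0,
    context_window: int = 20,
) -> tuple[list[AlignedPair], list[SubstitutionEvent]]:
    """Gapless ancestor/descendant pairs with context-dependent rates.

    Each ancestral residue substitutes independently: a ``rule.from_aa``
    site goes to ``rule.to_aa`` with probability ``base_rate *
    multiplier`` when the neighbor condition holds and ``base_rate``
    otherwise; every other canonical residue substitutes with
    probability ``base_rate`` to a uniformly random different residue.
    Unknown residues never substitute. Returns the aligned pairs and the
    exact event list (ancestral contexts, ``context_window`` per side).
    """
    rule = SubstitutionRule(*rule)
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must lie in (0, 1)")
    if rule.multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    if base_rate * rule.multiplier > 1.0:
        raise ValueError(
            f"base_rate * multiplier = {base_rate * rule.multiplier} exceeds 1"
        )
    for aa in (rule.from_aa, rule.to_aa, rule.neighbor_aa):
        if aa not in AA_INDEX:
            raise ValueError(f"rule residue {aa!r} is not canonical")
    if rule.from_aa == rule.to_aa:
        raise ValueError("rule requires from_aa != to_aa")
    rng = np.random.default_rng(rng_seed)
    from_idx = AA_INDEX[rule.from_aa]
    to_idx = AA_INDEX[rule.to_aa]
    nb_idx = AA_INDEX[rule.neighbor_aa]
    pairs: list[AlignedPair] = []
    events: list[SubstitutionEvent] = []
    for rec in ancestors:
        codes = encode(rec.sequence).astype(np.int64)
        length = codes.size
        u = rng.random(length)
        canonical = codes < N_AA
        is_from = codes == from_idx
        # neighbor condition at each site: rule residue at the signed offset
        cond = np.zeros(length, dtype=bool)
        d = rule.neighbor_offset
        if d > 0:
            cond[: length - d] = codes[d:] == nb_idx
        elif d < 0:
            cond[-d:] = codes[: length + d] == nb_idx
        p_from = np.where(cond, base_rate * rule.multiplier, base_rate)
        sub_from = is_from & (u < p_from)
        sub_other = canonical & ~is_from & (u < base_rate)
        desc = codes.copy()
        desc[sub_from] = to_idx
        other_pos = np.flatnonzero(sub_other)
        draws = rng.integers(0, N_AA - 1, size=other_pos.size)
        desc[other_pos] = draws + (draws >= codes[other_pos])
        anc_seq = rec.sequence
        desc_seq = "".join(
            AMINO_ACIDS[c] if c < N_AA else UNKNOWN for c in desc
        )
        pairs.append(
            AlignedPair(pair_id=rec.id, ancestor=anc_seq, descendant=desc_seq)
        )
        for pos in np.flatnonzero(sub_from | sub_other):
            pos = int(pos)
            events.append(
                SubstitutionEvent(
                    pair_id=rec.id,
                    position=pos + 1,
                    from_aa=anc_seq[pos],
                    to_aa=desc_seq[pos],
                    context_n=anc_seq[max(0, pos - context_window) : pos],
                    context_c=anc_seq[pos + 1 : pos + 1 + context_window],
                )
            )
    return pairs, events
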