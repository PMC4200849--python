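"""Shuffle-based significance thresholds and bootstrap error bars.

The null model for "no positional preference" permutes the W positions
within each stored flanking string (composition of every context is
preserved, positional signal is destroyed) and recomputes the W
per-offset totals; over 500 repeats this yields a pool of W*500
simulated entropies per side, and the 0.001-level threshold is the
k-th highest pool value with k = max(1, round(alpha * pool size)) —
the tenth-highest of 10,000 for W=20, the third-highest of 3,000 for
W=6. The N and C sides are pooled and thresholded separately because
their data sizes generally differ.

Bootstrap standard deviations resample the stored flanking strings per
side with replacement (100 replicates) and take the per-offset SD of
the recomputed totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import N_AA
from .contexts import ContextCountTable, _offsets_for_side
from .entropy import BackgroundDistribution, EntropyProfile

DEFAULT_REPEATS = 500
DEFAULT_ALPHA = 1e-3
DEFAULT_N_BOOT = 100


@dataclass
class ShuffleNull:
    """Null pool of per-offset entropies for one side of a context table."""

    side: str
    window: int
    repeats: int
    alpha: float
    pool: np.ndarray
    k: int
    threshold: float

    def __post_init__(self) -> None:
        if self.pool.size != self.repeats * self.window:
            raise ValueError(
                f"pool size {self.pool.size} != repeats*window = "
                f"{self.repeats * self.window}"
            )


def threshold_rank(alpha: float, pool_size: int) -> int:
    """Rank of the pool value used as threshold: k-th highest."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if pool_size < 1:
        raise ValueError("pool must be non-empty")
    return max(1, int(round(alpha * pool_size)))


def _background_matrix(
    background: BackgroundDistribution, side: str, window: int
) -> np.ndarray:
    """(window, 20) matrix of Q vectors in the side's offset order."""
    offsets = _offsets_for_side(side, window)
    return np.vstack([background.at(off) for off in offsets])


def _column_totals(mat: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-column (per-offset) entropy totals of an encoded flank matrix.

    ``mat`` is (n, W) with codes 0..19 and 20 = unknown; ``q`` is (W, 20).
    Unknown slots are excluded from each column's normalizer.
    """
    window = mat.shape[1]
    counts = np.empty((window, N_AA), dtype=np.int64)
    for j in range(window):
        counts[j] = np.bincount(mat[:, j], minlength=N_AA + 1)[:N_AA]
    sums = counts.sum(axis=1, dtype=float)
    if np.any(sums == 0):
        raise ValueError("an offset has zero canonical counts")
    p = counts / sums[:, None]
    bad = (counts > 0) & (q == 0.0)
    if np.any(bad):
        raise ValueError(
            "observed residue has zero background frequency "
            "(enable the pseudocount to allow this)"
        )
    terms = np.zeros_like(p)
    pos = p > 0
    terms[pos] = p[pos] * np.log2(p[pos] / q[pos])
    return terms.sum(axis=1)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_null(
    table: ContextCountTable,
    side: str,
    background: BackgroundDistribution,
    repeats: int = DEFAULT_REPEATS,
    alpha: float = DEFAULT_ALPHA,
    rng_seed: int | np.random.Generator | None = 0,
    granularity: str = "per_string",
) -> ShuffleNull:
    """Build the shuffled null pool and threshold for one side.

    ``granularity="per_string"`` (default) permutes each flanking string
    independently per repeat; ``"global"`` applies one position
    permutation to all strings of the repeat. Both preserve per-string
    composition.
    """
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    if granularity not in ("per_string", "global"):
        raise ValueError("granularity must be 'per_string' or 'global'")
    mat = table.encoded(side)
    if mat.shape[0] == 0:
        raise ValueError(f"no stored contexts on the {side} side")
    rng = _as_rng(rng_seed)
    window = table.window
    q = _background_matrix(background, side, window)
    pool = np.empty(repeats * window, dtype=float)
    for r in range(repeats):
        if granularity == "per_string":
            shuffled = rng.permuted(mat, axis=1)
        else:
            shuffled = mat[:, rng.permutation(window)]
        pool[r * window : (r + 1) * window] = _column_totals(shuffled, q)
    k = threshold_rank(alpha, pool.size)
    threshold = float(np.sort(pool)[-k])
    return ShuffleNull(
        side=side,
        window=window,
        repeats=repeats,
        alpha=alpha,
        pool=pool,
        k=k,
        threshold=threshold,
    )


def bootstrap_sd(
    table: ContextCountTable,
    background: BackgroundDistribution,
    n_boot: int = DEFAULT_N_BOOT,
    rng_seed: int | np.random.Generator | None = 0,
) -> dict[int, float | None]:
    """Per-offset bootstrap SD of the entropy totals.

    Stored flanks are resampled with replacement per side at the original
    n; the SD over replicates uses the n_boot - 1 denominator. A side
    with fewer than two contexts reports ``None`` at its offsets.
    """
    if table.n_side["N"] == 0 and table.n_side["C"] == 0:
        raise ValueError("table has no stored contexts")
    rng = _as_rng(rng_seed)
    out: dict[int, float | None] = {}
    for side in ("N", "C"):
        mat = table.encoded(side)
        offsets = _offsets_for_side(side, table.window)
        n = mat.shape[0]
        if n == 0:
            continue
        if n < 2:
            for off in offsets:
                out[off] = None
            continue
        q = _background_matrix(background, side, table.window)
        totals = np.empty((n_boot, table.window), dtype=float)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            totals[b] = _column_totals(mat[idx], q)
        sds = totals.std(axis=0, ddof=1)
        for j, off in enumerate(offsets):
            out[off] = float(sds[j])
    return out


def annotate_significance(
    profile: EntropyProfile,
    nulls: dict[str, ShuffleNull],
    sds: dict[int, float | None] | None = None,
) -> EntropyProfile:
    """Attach per-side thresholds and per-offset significance flags.

    Each offset is significant iff its total exceeds the threshold of its
    side's null. A populated side without a null is an error. ``sds``
    (from :func:`bootstrap_sd`) is attached when given. The profile is
    modified in place and returned.
    """
    populated_sides = {"N" if off < 0 else "C" for off in profile.sites}
    for side in sorted(populated_sides):
        if side not in nulls:
            raise ValueError(f"no shuffle null provided for populated side {side!r}")
        profile.side_thresholds[side] = nulls[side].threshold
    for off, site in profile.sites.items():
        side = "N" if off < 0 else "C"
        site.threshold = nulls[side].threshold
        site.significant = bool(site.total > site.threshold)
        if sds is not None:
            site.sd = sds.get(off)
    return profile


def annotate_profile(
    table: ContextCountTable,
    background: BackgroundDistribution,
    profile: EntropyProfile,
    repeats: int = DEFAULT_REPEATS,
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = DEFAULT_N_BOOT,
    rng_seed: int = 0,
    granularity: str = "per_string",
    with_bootstrap: bool = True,
) -> EntropyProfile:
    """Convenience: shuffle nulls for every populated side, bootstrap SDs,
    and significance flags, all from one seed (shuffle and bootstrap use
    independent sub-streams)."""
    shuffle_rng, boot_rng = (
        np.random.default_rng(child)
        for child in np.random.SeedSequence(rng_seed).spawn(2)
    )
    nulls = {}
    for side in ("N", "C"):
        if table.n_side[side] > 0:
            nulls[side] = shuffle_null(
                table,
                side,
                background,
                repeats=repeats,
                alpha=alpha,
                rng_seed=shuffle_rng,
                granularity=granularity,
            )
    sds = bootstrap_sd(table, background, n_boot=n_boot, rng_seed=boot_rng) if with_bootstrap else None
    return annotate_significance(profile, nulls, sds)
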