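"""Null models: dinucleotide-pool random hexamer sets, windowed codon
shuffling, and per-motif dinucleotide-permutation control sets.

The dinucleotide pool collects, for every real motif, its five overlapping
dinucleotides (both reading frames). Control hexamers are three pool draws
with replacement, rejecting members of the real set, so each control set
preserves the aggregate dinucleotide composition of the real motifs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .motifs import MOTIF_LENGTH, MotifSet

DINUCS_PER_MOTIF = MOTIF_LENGTH - 1  # the 5 overlapping pairs of a hexamer
REJECTION_BOUND = 10000


@dataclass(frozen=True)
class DinucleotidePool:
    """Multiset of overlapping dinucleotides drawn from a motif set."""

    entries: tuple[str, ...]
    source: str

    @property
    def counts(self) -> Counter:
        return Counter(self.entries)


def dinucleotide_pool(motifs: MotifSet) -> DinucleotidePool:
    entries = tuple(
        m[i : i + 2] for m in motifs.motifs for i in range(DINUCS_PER_MOTIF)
    )
    return DinucleotidePool(entries, motifs.name)


@dataclass(frozen=True)
class ControlSetCollection:
    sets: tuple[MotifSet, ...]
    seed: int | None

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def code_arrays(self) -> list[np.ndarray]:
        return [s.codes for s in self.sets]


def _draw_hexamers(
    pool: np.ndarray,
    n: int,
    forbidden: frozenset[str],
    rng: np.random.Generator,
    dedupe: bool,
) -> tuple[str, ...]:
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        idx = rng.integers(0, len(pool), size=3)
        hexamer = "".join(pool[idx])
        attempts += 1
        if hexamer in forbidden or (dedupe and hexamer in seen):
            if attempts > REJECTION_BOUND * n:
                raise ValueError(
                    "rejection sampling failed: the dinucleotide pool cannot "
                    "produce enough hexamers outside the real set"
                )
            continue
        out.append(hexamer)
        seen.add(hexamer)
    return tuple(out)


def build_control_sets(
    real: MotifSet,
    n_sets: int = 10000,
    rng: np.random.Generator | None = None,
    dedupe: bool = False,
) -> ControlSetCollection:
    """Random hexamer sets matched to the real set's dinucleotide composition.

    Each control hexamer concatenates three draws (with replacement) from the
    pool of the real motifs' overlapping dinucleotides; hexamers belonging to
    the real set are rejected and redrawn. ``dedupe=True`` additionally
    forbids duplicate hexamers within one control set (the default mirrors
    plain sampling with replacement).
    """
    if len(real) == 0:
        raise ValueError("empty real motif set")
    if rng is None:
        rng = np.random.default_rng()
    pool = np.array(dinucleotide_pool(real).entries)
    forbidden = frozenset(real.motifs)
    # fail fast on degenerate pools where every constructible hexamer is real
    constructible = {
        a + b + c for a in set(pool) for b in set(pool) for c in set(pool)
    }
    if constructible <= forbidden:
        raise ValueError(
            "infeasible: every hexamer constructible from the pool belongs "
            "to the real set"
        )
    sets = tuple(
        MotifSet(
            _draw_hexamers(pool, len(real), forbidden, rng, dedupe),
            name=f"{real.name}_ctrl{i}",
            multiset=not dedupe,
        )
        for i in range(n_sets)
    )
    return ControlSetCollection(sets, None)


def codon_shuffle(
    seq: str, window: int = 294, rng: np.random.Generator | None = None
) -> str:
    """Shuffle codons within consecutive subregions of a CDS.

    The sequence is split into floor(L/window) subregions of ``window`` bp
    with any remainder merged into the 3'-most subregion (a single subregion
    when floor(L/window) <= 1). Codon multisets are preserved per subregion.
    """
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    if window % 3:
        raise ValueError("window must be a multiple of 3")
    if rng is None:
        rng = np.random.default_rng()
    L = len(seq)
    n_regions = max(1, L // window)
    bounds = [i * window for i in range(n_regions)] + [L]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        codons = [seq[i : i + 3] for i in range(a, b, 3)]
        rng.shuffle(codons)
        out.append("".join(codons))
    return "".join(out)


def permutation_controls(motif: str, exclude_original: bool = False) -> MotifSet:
    """All hexamers from ordered selections of 3 of a motif's 5 dinucleotides.

    Each of the five overlapping dinucleotides occupies one list position;
    selections never reuse a position. With five distinct dinucleotides this
    yields exactly 60 control motifs (deduplicated otherwise). The identity
    tiling (positions 0, 2, 4) reproduces the motif itself and is kept unless
    ``exclude_original``.
    """
    if len(motif) != MOTIF_LENGTH:
        raise ValueError("motif must be a hexamer")
    dinucs = [motif[i : i + 2] for i in range(DINUCS_PER_MOTIF)]
    out: list[str] = []
    seen: set[str] = set()
    for i in range(5):
        for j in range(5):
            for k in range(5):
                if i == j or i == k or j == k:
                    continue
                hexamer = dinucs[i] + dinucs[j] + dinucs[k]
                if hexamer in seen:
                    continue
                if exclude_original and hexamer == motif:
                    continue
                seen.add(hexamer)
                out.append(hexamer)
    return MotifSet(tuple(out), f"{motif}_perm")
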