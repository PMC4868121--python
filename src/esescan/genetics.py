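"""Standard-genetic-code machinery shared across the package.

Everything here is derived once, at import time, from the NCBI standard codon
table (via Biopython): per-codon fractional synonymous site counts, pairwise
synonymous/nonsynonymous difference tables with pathway averaging (Nei &
Gojobori 1986), per-position degeneracy classes, and the Leu/Arg codon repair
map used when trimming motif-hit blocks to codon boundaries.

Sequences are encoded as uint8 arrays with A=0, C=1, G=2, T=3; a codon is the
base-4 integer ``16*b0 + 4*b1 + b2``.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_INT.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

STOP_STRINGS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon string for each of the 64 codon indices
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_TO_INT = {c: i for i, c in enumerate(CODONS)}

#: amino acid (one letter, '*' for stop) per codon index
AMINO = np.array(
    ["*" if c in _table.stop_codons else _table.forward_table[c] for c in CODONS]
)
STOP_CODONS = np.array([CODON_TO_INT[c] for c in STOP_STRINGS])
IS_STOP = np.zeros(64, dtype=bool)
IS_STOP[STOP_CODONS] = True


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (raises on other bases)."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-canonical base {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def codons_of(arr: np.ndarray) -> np.ndarray:
    """Codon indices of an encoded array whose length is a multiple of 3."""
    if len(arr) % 3:
        raise ValueError("sequence length not a multiple of 3")
    a = arr.reshape(-1, 3).astype(np.int32)
    return a[:, 0] * 16 + a[:, 1] * 4 + a[:, 2]


def codon_array_to_bases(codons: np.ndarray) -> np.ndarray:
    out = np.empty(len(codons) * 3, dtype=np.uint8)
    out[0::3] = codons // 16
    out[1::3] = (codons // 4) % 4
    out[2::3] = codons % 4
    return out


def translate(seq: str) -> str:
    return "".join(AMINO[codons_of(encode(seq))])


# ---------------------------------------------------------------------------
# degeneracy classes
# ---------------------------------------------------------------------------

# DEGENERACY[codon, pos] = number of bases at pos (self included) preserving
# the amino acid: 1 = nondegenerate, 2 = twofold, 3 = threefold, 4 = fourfold.
DEGENERACY = np.zeros((64, 3), dtype=np.int8)
for _ci, _codon in enumerate(CODONS):
    for _pos in range(3):
        same = 0
        for _alt in BASES:
            alt_codon = _codon[:_pos] + _alt + _codon[_pos + 1 :]
            if AMINO[CODON_TO_INT[alt_codon]] == AMINO[_ci]:
                same += 1
        DEGENERACY[_ci, _pos] = same

DEGENERACY_LABELS = {1: "nondegenerate", 2: "twofold", 3: "threefold", 4: "fourfold"}


def annotate_degeneracy(cds: str) -> np.ndarray:
    """Per-position degeneracy class (1/2/3/4) of a CDS under the standard code."""
    arr = encode(cds)
    cods = codons_of(arr)
    return DEGENERACY[cods].reshape(-1)


def gc4_fraction(cds: str) -> float:
    """G+C fraction at fourfold-degenerate third positions (nan if none)."""
    arr = encode(cds)
    cods = codons_of(arr)
    third = arr[2::3]
    four = DEGENERACY[cods, 2] == 4
    if not four.any():
        return float("nan")
    sel = third[four]
    return float(np.mean((sel == 1) | (sel == 2)))


# ---------------------------------------------------------------------------
# NG86 site and difference tables
# ---------------------------------------------------------------------------

# Fractional synonymous sites per codon: at each position, the fraction of the
# three possible changes that are synonymous (changes to stop codons count as
# nonsynonymous). Stop codons themselves carry zero countable sites and are
# excluded from rate computations.
SYN_SITES = np.zeros(64)
for _ci, _codon in enumerate(CODONS):
    if IS_STOP[_ci]:
        continue
    s = 0.0
    for _pos in range(3):
        for _alt in BASES:
            if _alt == _codon[_pos]:
                continue
            alt_i = CODON_TO_INT[_codon[:_pos] + _alt + _codon[_pos + 1 :]]
            if not IS_STOP[alt_i] and AMINO[alt_i] == AMINO[_ci]:
                s += 1.0 / 3.0
    SYN_SITES[_ci] = s


def _pathway_counts(c1: int, c2: int) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over mutational pathways.

    Pathways passing through stop codons are excluded; if every pathway is
    excluded (possible only when an endpoint neighbourhood is all-stop, which
    does not occur for sense codons) stops are tolerated as intermediates.
    """
    s1, s2 = CODONS[c1], CODONS[c2]
    diff = [p for p in range(3) if s1[p] != s2[p]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = s1
        sd = nd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + s2[p] + cur[p + 1 :]
            i_cur, i_nxt = CODON_TO_INT[cur], CODON_TO_INT[nxt]
            if IS_STOP[i_nxt] and nxt != s2:
                ok = False
                break
            if AMINO[i_nxt] == AMINO[i_cur] and not IS_STOP[i_nxt] and not IS_STOP[i_cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # fall back to counting through stops
        for order in itertools.permutations(diff):
            cur = s1
            sd = nd = 0.0
            for p in order:
                nxt = cur[:p] + s2[p] + cur[p + 1 :]
                if AMINO[CODON_TO_INT[nxt]] == AMINO[CODON_TO_INT[cur]]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


SD_TABLE = np.zeros((64, 64))
ND_TABLE = np.zeros((64, 64))
for _i in range(64):
    for _j in range(_i, 64):
        _sd, _nd = _pathway_counts(_i, _j)
        SD_TABLE[_i, _j] = SD_TABLE[_j, _i] = _sd
        ND_TABLE[_i, _j] = ND_TABLE[_j, _i] = _nd

#: synonymous single-base neighbours of each codon: list of (position, alt codon
#: index); used by the synthetic ortholog evolver.
SYN_NEIGHBORS: list[list[tuple[int, int]]] = [[] for _ in range(64)]
for _ci, _codon in enumerate(CODONS):
    if IS_STOP[_ci]:
        continue
    for _pos in range(3):
        for _alt in BASES:
            if _alt == _codon[_pos]:
                continue
            alt_i = CODON_TO_INT[_codon[:_pos] + _alt + _codon[_pos + 1 :]]
            if not IS_STOP[alt_i] and AMINO[alt_i] == AMINO[_ci]:
                SYN_NEIGHBORS[_ci].append((_pos, alt_i))

SENSE_CODONS = np.array([i for i in range(64) if not IS_STOP[i]])

# codons of each amino acid, for codon-usage-driven sequence generation
AA_TO_CODONS: dict[str, np.ndarray] = {
    aa: np.array([i for i in range(64) if AMINO[i] == aa])
    for aa in sorted(set(AMINO))
    if aa != "*"
}

# ---------------------------------------------------------------------------
# Leu/Arg block-repair map
# ---------------------------------------------------------------------------

# When a motif-hit block starts mid-codon and is expanded upstream to a full
# codon, an initial Leucine or Arginine codon is rewritten so that only the
# block's original third-position synonymous site is retained: first two bases
# become GA (Glu/Asp) if the third position is twofold degenerate, GC (Ala) if
# fourfold. The rewrite preserves the degeneracy class of the third position.
REPAIR_MAP = np.arange(64)
for _ci in range(64):
    if AMINO[_ci] in ("L", "R"):
        third = _ci % 4
        if DEGENERACY[_ci, 2] == 2:
            REPAIR_MAP[_ci] = CODON_TO_INT["GA" + BASES[third]]
        elif DEGENERACY[_ci, 2] == 4:
            REPAIR_MAP[_ci] = CODON_TO_INT["GC" + BASES[third]]


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites (nan if p >= 3/4)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * float(np.log1p(-4.0 * p / 3.0))
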