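"""Hexamer motif sets: loading, validation, composition splits.

The analysis works with literal 6-mers over {A,C,G,T} (no IUPAC wildcards).
Motif files are plain text, one hexamer per line, ``#`` starting a comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import genetics

MOTIF_LENGTH = 6

_POW4 = 4 ** np.arange(MOTIF_LENGTH - 1, -1, -1)


def hexamer_code(motif: str) -> int:
    """Base-4 integer code of a hexamer (A=0, C=1, G=2, T=3)."""
    arr = genetics.encode(motif)
    if len(arr) != MOTIF_LENGTH:
        raise ValueError(f"motif {motif!r} is not a hexamer")
    return int(arr @ _POW4)


def code_to_hexamer(code: int) -> str:
    out = []
    for _ in range(MOTIF_LENGTH):
        out.append(genetics.BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class MotifSet:
    """A named set of distinct hexamers.

    ``multiset=True`` relaxes the distinctness check; it is used only for
    null sets sampled with replacement, where duplicates are legitimate.
    """

    motifs: tuple[str, ...]
    name: str = ""
    multiset: bool = False
    _codes: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        seen = set()
        codes = []
        for m in self.motifs:
            codes.append(hexamer_code(m))  # validates length/alphabet
            if m in seen and not self.multiset:
                raise ValueError(f"duplicate motif {m!r} in set {self.name!r}")
            seen.add(m)
        object.__setattr__(self, "_codes", np.sort(np.array(codes, dtype=np.int64)))

    @property
    def codes(self) -> np.ndarray:
        """Sorted integer codes of the motifs."""
        return self._codes

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in self.motifs

    def __iter__(self):
        return iter(self.motifs)


def load_motifs(path: str | Path, name: str | None = None) -> MotifSet:
    motifs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().upper()
        if line:
            motifs.append(line)
    return MotifSet(tuple(motifs), name or Path(path).stem)


def save_motifs(motifs: MotifSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(motifs.motifs) + "\n")


def packaged_fixture_set() -> MotifSet:
    """The packaged *synthetic* 84-hexamer fixture set.

    A purine/adenine-biased stand-in with the cardinality and compositional
    flavour of high-confidence ESE collections, for use when no real motif
    file is supplied. It is not a published ESE set.
    """
    text = (
        resources.files("esescan") / "data" / "synthetic_ese_fixture_84.txt"
    ).read_text()
    motifs = tuple(
        l.split("#", 1)[0].strip() for l in text.splitlines()
        if l.split("#", 1)[0].strip()
    )
    return MotifSet(motifs, "synthetic_ese_fixture_84")


def _base_count(motif: str, bases: str) -> int:
    return sum(motif.count(b) for b in bases)


def split_motifs(motifs: MotifSet, property: str) -> tuple[MotifSet, MotifSet]:
    """Median split of a motif set by purine (A+G) or GC (G+C) content.

    Motifs falling exactly on the median go to the high set.
    """
    if len(motifs) == 0:
        raise ValueError("empty motif set")
    if property == "purine":
        bases = "AG"
    elif property == "gc":
        bases = "GC"
    else:
        raise ValueError(f"unknown property {property!r}")
    counts = np.array([_base_count(m, bases) for m in motifs.motifs])
    med = float(np.median(counts))
    high = tuple(m for m, c in zip(motifs.motifs, counts) if c >= med)
    low = tuple(m for m, c in zip(motifs.motifs, counts) if c < med)
    return (
        MotifSet(high, f"{motifs.name}_high_{property}"),
        MotifSet(low, f"{motifs.name}_low_{property}"),
    )
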