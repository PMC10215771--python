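"""Pedigrees and pedigree inbreeding coefficients.

A pedigree is a list of individuals with optional sire/dam references;
founders have neither parent.  The expected inbreeding coefficient of an
individual is the kinship of its parents, computed by the classical
recursive (tabular-method) kinship:

    phi(a, a) = (1 + F_a) / 2 = (1 + phi(sire_a, dam_a)) / 2
    phi(a, b) = (phi(sire_b, a) + phi(dam_b, a)) / 2   (b not ancestor of a)

with phi = 0 whenever a parent is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["Pedigree"]

_FOUNDER = "0"  # sire/dam code for "unknown / founder" in pedigree TSVs


@dataclass
class Pedigree:
    """Ordered pedigree; parents must be listed before their offspring."""

    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ind, (sire, dam) in self.parents.items():
            for par in (sire, dam):
                if par is not None and par not in seen:
                    raise ValueError(
                        f"individual {ind!r} references parent {par!r} that is "
                        "unknown or listed later"
                    )
            if (sire is None) != (dam is None):
                raise ValueError(f"individual {ind!r} has exactly one known parent")
            seen.add(ind)
        self._order = {ind: i for i, ind in enumerate(self.parents)}
        self._kinship_cache: dict[tuple[str, str], float] = {}

    # -- construction ------------------------------------------------------

    def add_founder(self, ind: str) -> str:
        self._add(ind, None, None)
        return ind

    def add_offspring(self, ind: str, sire: str, dam: str) -> str:
        self._add(ind, sire, dam)
        return ind

    def _add(self, ind: str, sire: str | None, dam: str | None) -> None:
        if ind in self.parents:
            raise ValueError(f"duplicate individual {ind!r}")
        for par in (sire, dam):
            if par is not None and par not in self.parents:
                raise ValueError(f"unknown parent {par!r} for {ind!r}")
        self.parents[ind] = (sire, dam)
        self._order[ind] = len(self._order)

    @classmethod
    def from_tsv(cls, path) -> "Pedigree":
        """Read an ``id<TAB>sire<TAB>dam`` table ("0" marks a founder)."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["id", "sire", "dam"],
            dtype=str, comment="#",
        )
        ped = cls()
        for r in df.itertuples(index=False):
            sire = None if r.sire == _FOUNDER else r.sire
            dam = None if r.dam == _FOUNDER else r.dam
            ped._add(str(r.id), sire, dam)
        return ped

    def to_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            for ind, (sire, dam) in self.parents.items():
                fh.write(f"{ind}\t{sire or _FOUNDER}\t{dam or _FOUNDER}\n")

    # -- queries -----------------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.parents)

    def founders(self) -> list[str]:
        return [i for i, (s, d) in self.parents.items() if s is None]

    def is_founder(self, ind: str) -> bool:
        return self.parents[ind][0] is None

    def kinship(self, a: str | None, b: str | None) -> float:
        """Coefficient of kinship phi(a, b); 0 when either is unknown."""
        if a is None or b is None:
            return 0.0
        # order so that b is the later-listed individual; recursion then
        # always descends toward founders and terminates on any valid pedigree
        if self._order[a] > self._order[b]:
            a, b = b, a
        key = (a, b)
        cached = self._kinship_cache.get(key)
        if cached is not None:
            return cached
        sire_b, dam_b = self.parents[b]
        if a == b:
            phi = 0.5 * (1.0 + self.kinship(sire_b, dam_b))
        elif sire_b is None:
            phi = 0.0
        else:
            phi = 0.5 * (self.kinship(a, sire_b) + self.kinship(a, dam_b))
        self._kinship_cache[key] = phi
        return phi

    def inbreeding(self, ind: str) -> float:
        """F_ped of one individual = kinship of its parents."""
        sire, dam = self.parents[ind]
        return self.kinship(sire, dam)

    def inbreeding_table(self) -> pd.Series:
        return pd.Series(
            {i: self.inbreeding(i) for i in self.parents}, name="f_ped"
        )
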